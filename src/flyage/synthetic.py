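"""Synthetic data generator emulating the pupal-ageing study design.

Emulates a constant-temperature rearing experiment on *Sarcophaga
peregrina* pupae: 20 pupae sampled every 24 h until eclosion (pupal
duration 16 / 10 / 8 days at 20 / 25 / 30 °C), three replicate
experiments, samples split equally between the ATR-FTIR and the
cuticular-hydrocarbon (CHC) assays. Spectra are sums of Gaussian bands at
the canonical biochemical band positions (amide I/II, C-O/PO2⁻ region,
lipid ester ...) whose amplitudes drift linearly with pupal age, corrupted
by multiplicative scatter, a baseline offset and additive noise — exactly
the artifact classes SNV is designed to remove. CHC profiles follow
exponential-plus-offset abundance kinetics per compound, with the C24
n-alkane planted as a monotonically declining, age-informative marker.

All randomness flows from one integer seed through counter-based
``numpy.random.SeedSequence`` substreams, so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .containers import CHCProfile, Spectrum, SpectraSet

#: Pupal development duration in days at each supported rearing temperature.
PUPAL_DURATION_DAYS = {20: 16, 25: 10, 30: 8}

#: Number of technical spectra acquired per FTIR pupa.
TECHNICAL_SPECTRA_PER_PUPA = 3

ASSAYS = ("FTIR", "CHC")


def duration_days(temperature_C: int) -> int:
    """Pupal duration (days) at a supported constant temperature."""
    try:
        return PUPAL_DURATION_DAYS[int(temperature_C)]
    except (KeyError, ValueError):
        raise ValueError(
            f"unsupported temperature {temperature_C!r}; "
            f"supported: {sorted(PUPAL_DURATION_DAYS)} (deg C)"
        ) from None


# ---------------------------------------------------------------------------
# sampling design
# ---------------------------------------------------------------------------

def make_design(temperature_C: int, pupae_per_day: int = 20,
                n_replicates: int = 3) -> pd.DataFrame:
    """Build the sampling design table for one rearing temperature.

    Every 24 h, ``pupae_per_day`` pupae are collected and divided equally
    between the FTIR and CHC assays, in each of ``n_replicates`` replicate
    experiments, until adult eclosion.

    Returns a DataFrame with columns sample_id, temperature_C, age_days,
    replicate, pupa_index, assay; row count equals
    ``pupae_per_day × duration(temperature_C) × n_replicates``.
    """
    days = duration_days(temperature_C)
    if pupae_per_day < 2 or pupae_per_day % 2:
        raise ValueError(
            "pupae_per_day must be an even number >= 2 "
            "(collections are divided equally between the two assays)"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    half = pupae_per_day // 2
    rows = []
    for rep in range(1, n_replicates + 1):
        for age in range(1, days + 1):
            for pupa in range(1, pupae_per_day + 1):
                assay = "FTIR" if pupa <= half else "CHC"
                rows.append({
                    "sample_id": f"T{temperature_C}_R{rep}_D{age:02d}_P{pupa:02d}_{assay}",
                    "temperature_C": int(temperature_C),
                    "age_days": age,
                    "replicate": rep,
                    "pupa_index": pupa,
                    "assay": assay,
                })
    return pd.DataFrame(rows)


def make_measurement_design(temperature_C: int, n_replicates: int = 3) -> pd.DataFrame:
    """Design of the pupae actually measured: one FTIR pupa (ground whole,
    three technical spectra) and one CHC pupa (one hexane extract) per
    collection — yielding 3 × 3 = 9 spectra per age × temperature cell."""
    return make_design(temperature_C, pupae_per_day=2, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# compound catalog
# ---------------------------------------------------------------------------

def default_compound_catalog() -> pd.DataFrame:
    """Default cuticular-hydrocarbon catalog: 37 compounds (13 n-alkanes,
    20 methyl-branched alkanes, 4 alkenes), carbon chain length C11–C35.

    Compound names are synthetic placeholders; the class composition,
    carbon range and retention-index layout are what downstream code relies
    on. n-Alkanes sit exactly at ``RI = 100 × carbon_number``; mono-methyl
    branched alkanes at ``100 n + 65``; dimethyl at ``100 n + 35``; alkenes
    just ahead of their parent alkane at ``100 n − 20``.
    """
    rows: list[dict] = []

    def add(name, cls, n, ri):
        rows.append({"name": name, "compound_class": cls,
                     "carbon_number": int(n), "nominal_ri": float(ri)})

    for n in (11, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31):
        add(f"C{n}", "n-alkane", n, 100 * n)
    mono = (18, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33)
    for n in mono:
        add(f"x-MeC{n}", "branched", n, 100 * n + 65)
    for n in (25, 27, 29, 31, 33, 35):
        add(f"x,y-DiMeC{n}", "branched", n, 100 * n + 35)
    for n in (23, 25, 27, 35):
        add(f"C{n}:1", "alkene", n, 100 * n - 20)

    cat = pd.DataFrame(rows).sort_values("nominal_ri").reset_index(drop=True)
    assert len(cat) == 37
    return cat


# ---------------------------------------------------------------------------
# generator parameters
# ---------------------------------------------------------------------------

@dataclass
class Band:
    """One Gaussian absorption band: centre/width in cm⁻¹, amplitude in
    absorbance units, age_slope in absorbance per day."""
    center: float
    width: float
    amplitude: float
    age_slope: float = 0.0


def _default_bands() -> list[Band]:
    # Fingerprint-region bands at the canonical biochemical positions plus
    # the C-H / amide-A stretches above 1800 cm-1. Age-dependent signal is
    # planted on the amide I/II bands and the 1040 cm-1 C-O/PO2- band (the
    # regions reported age-discriminative), giving VIP selection a known
    # ground truth.
    return [
        Band(3290.0, 90.0, 0.45),
        Band(2925.0, 35.0, 0.55),
        Band(1741.0, 12.0, 0.20),
        Band(1647.0, 22.0, 1.00, age_slope=+0.020),
        Band(1540.0, 20.0, 0.70, age_slope=+0.012),
        Band(1454.0, 12.0, 0.30),
        Band(1398.0, 12.0, 0.32),
        Band(1313.0, 14.0, 0.18),
        Band(1145.0, 14.0, 0.25),
        Band(1040.0, 28.0, 0.90, age_slope=-0.030),
    ]


def _default_chc_coefficients() -> dict[str, tuple[float, float, float]]:
    """Per-compound abundance kinetics (a, k, c): expected abundance at age
    t is ``a·exp(−k t) + c`` (arbitrary units, later normalized to percent).

    Age-dependent compounds come in compensating pairs (a, k) / (−a, k) so
    the expected total is age-constant; the normalized percentage of each
    informative compound is then itself an exact exponential-plus-offset
    with the same planted rate k. Cuticle turnover during metamorphosis
    remodels essentially the whole hydrocarbon profile, so every compound
    (bar one) carries age kinetics, with turnover rates spread over more
    than an order of magnitude; C24 is the dominant, fastest-amplitude
    decliner, mirroring the reported long-chain n-alkane decrease.
    """
    catalog = default_compound_catalog()
    names = list(catalog["name"])
    coeffs: dict[str, tuple[float, float, float]] = {}
    # planted headline marker: C24 declines with age at every temperature
    coeffs["C24"] = (18.0, 0.25, 4.0)
    coeffs["x-MeC26"] = (-18.0, 0.25, 22.0)   # compensating riser
    remaining = [n for n in names if n not in coeffs]
    # 16 decliner/riser pairs plus one exactly compensated triplet (one
    # decliner split over two risers), so every compound carries age
    # kinetics and the expected total stays exactly age-constant. A small
    # group of major markers (led by C24) carries strong turnover with
    # rates spread over 0.05..1.3 per day; the rest drift weakly near the
    # noise floor, as most minor cuticular components do. Floor abundances
    # keep every compound's expected share well above the 0.5% reporting
    # threshold, so minor-compound filtering never flickers per sample.
    strong = [(4.0, 0.08), (5.0, 0.5), (4.0, 1.0)]
    n_pairs = (len(remaining) - 3) // 2
    weak_ks = np.geomspace(0.06, 1.1, n_pairs + 1 - len(strong))
    weak = [(0.3 + 0.02 * i, float(k)) for i, k in enumerate(weak_ks)]
    specs = strong + weak
    for i in range(n_pairs):
        dec, ris = remaining[2 * i], remaining[2 * i + 1]
        a, k = specs[i]
        coeffs[dec] = (a, k, 3.5)
        coeffs[ris] = (-a, k, a + 3.5)
    dec, ris1, ris2 = remaining[2 * n_pairs:2 * n_pairs + 3]
    a, k = specs[-1]
    coeffs[dec] = (a, k, 3.5)
    coeffs[ris1] = (-0.6 * a, k, 0.6 * a + 3.5)
    coeffs[ris2] = (-0.4 * a, k, 0.4 * a + 3.5)
    return coeffs


@dataclass
class GeneratorParams:
    """All knobs of the synthetic generator.

    Spectral artifacts: per-spectrum multiplicative gain ``(1 + g)`` with
    ``g ~ N(0, scatter_slope_sd)``, additive baseline ``N(0, baseline_sd)``
    and white noise ``N(0, spectral_noise_sd)`` per point (absorbance
    units). CHC noise is additive Gaussian on the pre-normalization
    abundance (percent-scale units).
    """
    bands: list[Band] = field(default_factory=_default_bands)
    scatter_slope_sd: float = 0.10
    baseline_sd: float = 0.02
    spectral_noise_sd: float = 0.005
    chc_coefficients: dict = field(default_factory=_default_chc_coefficients)
    chc_noise_sd: float = 0.2
    wn_high: float = 4000.0
    wn_low: float = 900.0
    n_points: int = 1608
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scatter_slope_sd", "baseline_sd", "spectral_noise_sd",
                     "chc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for b in self.bands:
            if not (self.wn_low <= b.center <= self.wn_high):
                raise ValueError(f"band centre {b.center} outside grid "
                                 f"[{self.wn_low}, {self.wn_high}]")
        a, k, c = self.chc_coefficients.get("C24", (0.0, 0.0, 0.0))
        if not (a > 0 and k > 0):
            raise ValueError("C24 must have a > 0 and decay rate k > 0 "
                             "(planted monotone decline)")

    @property
    def grid(self) -> np.ndarray:
        """Canonical descending wavenumber grid (≈1.93 cm⁻¹ spacing)."""
        return np.linspace(self.wn_high, self.wn_low, self.n_points)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        d["chc_coefficients"] = {k: list(v) for k, v in self.chc_coefficients.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        if "bands" in d:
            d["bands"] = [Band(**b) for b in d["bands"]]
        if "chc_coefficients" in d:
            d["chc_coefficients"] = {k: tuple(v) for k, v in d["chc_coefficients"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def expected_spectrum(age_days: float, params: GeneratorParams) -> np.ndarray:
    """Noise- and artifact-free absorbance at a given age."""
    grid = params.grid
    y = np.zeros_like(grid)
    for b in params.bands:
        amp = b.amplitude + b.age_slope * age_days
        y += amp * np.exp(-0.5 * ((grid - b.center) / b.width) ** 2)
    return y


def simulate_spectrum(age_days: int, temperature_C: int,
                      params: GeneratorParams, seed) -> Spectrum:
    """One ATR-FTIR spectrum: band model × (1 + scatter) + baseline + noise.

    Deterministic given ``seed`` (an int, SeedSequence or Generator).
    """
    days = duration_days(temperature_C)
    if not 1 <= age_days <= days:
        raise ValueError(
            f"age {age_days} outside pupal duration 1..{days} days at "
            f"{temperature_C} C")
    rng = _rng(seed)
    clean = expected_spectrum(age_days, params)
    gain = 1.0 + rng.normal(0.0, params.scatter_slope_sd)
    baseline = rng.normal(0.0, params.baseline_sd)
    noise = rng.normal(0.0, params.spectral_noise_sd, size=clean.size)
    return Spectrum(
        wavenumbers=params.grid,
        absorbance=clean * gain + baseline + noise,
        meta={"temperature_C": int(temperature_C), "age_days": int(age_days)},
    )


def expected_chc_abundance(age_days: float, params: GeneratorParams) -> pd.Series:
    """Expected (pre-noise, pre-normalization) compound abundances at an age."""
    names, vals = [], []
    for name, (a, k, c) in params.chc_coefficients.items():
        names.append(name)
        vals.append(max(a * np.exp(-k * age_days) + c, 0.0))
    return pd.Series(vals, index=names, dtype=float)


def simulate_chc_profile(age_days: int, temperature_C: int,
                         params: GeneratorParams, seed) -> CHCProfile:
    """One CHC profile: exponential-kinetics abundances + noise, truncated
    at zero and renormalized to sum to 100 percent."""
    days = duration_days(temperature_C)
    if not 1 <= age_days <= days:
        raise ValueError(
            f"age {age_days} outside pupal duration 1..{days} days at "
            f"{temperature_C} C")
    rng = _rng(seed)
    abund = expected_chc_abundance(age_days, params)
    noisy = np.clip(abund.to_numpy() + rng.normal(0.0, params.chc_noise_sd, abund.size), 0.0, None)
    total = noisy.sum()
    if total <= 0:
        raise RuntimeError("degenerate CHC draw: all abundances zero")
    return CHCProfile(
        percents=pd.Series(100.0 * noisy / total, index=abund.index),
        meta={"temperature_C": int(temperature_C), "age_days": int(age_days)},
    )


def simulate_dataset(design: pd.DataFrame, params: GeneratorParams
                     ) -> tuple[SpectraSet, list[CHCProfile]]:
    """Simulate measurements for every row of a design table.

    Each FTIR row yields :data:`TECHNICAL_SPECTRA_PER_PUPA` technical
    spectra (suffix ``_S1..``); each CHC row yields one profile. Substreams
    are keyed by row order and technical index, so the output is
    bit-identical for identical (design, params).
    """
    spectra: list[Spectrum] = []
    profiles: list[CHCProfile] = []
    root = params.seed
    for i, row in enumerate(design.itertuples(index=False)):
        common = {"sample_id": row.sample_id, "temperature_C": int(row.temperature_C),
                  "age_days": int(row.age_days), "replicate": int(row.replicate),
                  "pupa_index": int(row.pupa_index)}
        if row.assay == "FTIR":
            for j in range(1, TECHNICAL_SPECTRA_PER_PUPA + 1):
                ss = np.random.SeedSequence(entropy=root, spawn_key=(i, j))
                s = simulate_spectrum(int(row.age_days), int(row.temperature_C),
                                      params, np.random.default_rng(ss))
                s.meta.update(common)
                s.meta["sample_id"] = f"{row.sample_id}_S{j}"
                s.meta["technical"] = j
                spectra.append(s)
        elif row.assay == "CHC":
            ss = np.random.SeedSequence(entropy=root, spawn_key=(i, 0))
            p = simulate_chc_profile(int(row.age_days), int(row.temperature_C),
                                     params, np.random.default_rng(ss))
            p.meta.update(common)
            profiles.append(p)
        else:
            raise ValueError(f"unknown assay {row.assay!r}")
    return SpectraSet(spectra), profiles


# ---------------------------------------------------------------------------
# CSV writers (wide/long spectra, profiles, design)
# ---------------------------------------------------------------------------

def write_spectra_wide(spectra: SpectraSet, path) -> None:
    """Wide CSV: first column wavenumber, one column per sample."""
    cols = {"wavenumber": spectra.grid}
    for s in spectra:
        cols[s.meta.get("sample_id", f"s{id(s)}")] = s.absorbance
    pd.DataFrame(cols).to_csv(path, index=False)


def write_spectra_long(spectra: SpectraSet, path) -> None:
    frames = []
    for s in spectra:
        frames.append(pd.DataFrame({
            "sample_id": s.meta.get("sample_id"),
            "wavenumber": s.wavenumbers,
            "absorbance": s.absorbance,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_profiles(profiles: Iterable[CHCProfile], path) -> None:
    rows = []
    for p in profiles:
        for compound, percent in p.percents.items():
            rows.append({"sample_id": p.sample_id, "compound": compound,
                         "percent": percent})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)
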