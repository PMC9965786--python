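"""ATR-FTIR preprocessing: SNV, Savitzky–Golay smoothing, fingerprint-region
cropping and replicate averaging.

The processing chain is fixed as SNV → Savitzky–Golay → crop (then
averaging): SNV removes per-spectrum multiplicative scatter and offset, the
Savitzky–Golay convolution (15-point window by default) suppresses white
noise while preserving band shape, and cropping to the 1800–900 cm⁻¹
"biological fingerprint" region keeps the biomolecule-specific bands.
Scikit-learn-style transformers operating on sample × wavenumber matrices
are provided alongside per-:class:`~flyage.containers.Spectrum` functions.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import FeatureTable, Spectrum, SpectraSet

FINGERPRINT_HIGH = 1800.0
FINGERPRINT_LOW = 900.0
DEFAULT_WINDOW = 15
DEFAULT_POLYORDER = 3


# ---------------------------------------------------------------------------
# matrix-level primitives
# ---------------------------------------------------------------------------

def snv_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise standard normal variate: (x − mean) / sd, sd with n−1."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined for zero variance")
    return (X - mu) / sd


def _check_savgol(window: int, polyorder: int, n: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > n:
        raise ValueError(f"window ({window}) exceeds spectrum length ({n})")


def savgol_matrix(X: np.ndarray, window: int = DEFAULT_WINDOW,
                  polyorder: int = DEFAULT_POLYORDER) -> np.ndarray:
    """Row-wise Savitzky–Golay smoothing; edges by polynomial extrapolation
    of the terminal-window fit (scipy mode="interp")."""
    X = np.asarray(X, dtype=float)
    _check_savgol(window, polyorder, X.shape[-1])
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         axis=-1, mode="interp")


def region_mask(wavenumbers: np.ndarray, high: float = FINGERPRINT_HIGH,
                low: float = FINGERPRINT_LOW) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    mask = (wn >= low) & (wn <= high)
    if not mask.any():
        raise ValueError(f"region [{low}, {high}] cm-1 does not overlap the grid")
    return mask


# ---------------------------------------------------------------------------
# Spectrum-level operations
# ---------------------------------------------------------------------------

def snv(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate of one spectrum (mean 0, sd 1, ddof=1)."""
    return spectrum.replace(absorbance=snv_matrix(spectrum.absorbance))


def savgol_smooth(spectrum: Spectrum, window: int = DEFAULT_WINDOW,
                  polyorder: int = DEFAULT_POLYORDER) -> Spectrum:
    return spectrum.replace(
        absorbance=savgol_matrix(spectrum.absorbance, window, polyorder))


def crop_region(spectrum: Spectrum, high: float = FINGERPRINT_HIGH,
                low: float = FINGERPRINT_LOW) -> Spectrum:
    """Retain exactly the grid points with low ≤ wavenumber ≤ high.

    Never interpolates: output wavenumbers are a subset of the input's.
    """
    mask = region_mask(spectrum.wavenumbers, high, low)
    return spectrum.replace(absorbance=spectrum.absorbance[mask],
                            wavenumbers=spectrum.wavenumbers[mask])


def preprocess_spectrum(spectrum: Spectrum, window: int = DEFAULT_WINDOW,
                        polyorder: int = DEFAULT_POLYORDER,
                        high: float = FINGERPRINT_HIGH,
                        low: float = FINGERPRINT_LOW,
                        apply_snv: bool = True) -> Spectrum:
    """Fixed-order chain: SNV (full range) → Savitzky–Golay → crop."""
    s = snv(spectrum) if apply_snv else spectrum
    s = savgol_smooth(s, window, polyorder)
    return crop_region(s, high, low)


def preprocess_set(spectra: SpectraSet, **kwargs) -> SpectraSet:
    return SpectraSet([preprocess_spectrum(s, **kwargs) for s in spectra])


def average_replicates(spectra: SpectraSet,
                       group_key: Sequence[str] = ("temperature_C", "age_days"),
                       ) -> SpectraSet:
    """Pointwise mean of (already preprocessed) spectra per metadata group.

    The default group key collapses technical and biological replicates to
    one spectrum per age × temperature cell; pass
    ``("temperature_C", "age_days", "replicate")`` to keep replicate
    experiments separate for modeling.
    """
    if not len(spectra):
        return SpectraSet([])
    grid = spectra.grid
    bad = [s.sample_id for s in spectra
           if not np.array_equal(s.wavenumbers, grid)]
    if bad:
        raise ValueError(f"spectra on mismatched grids: {bad}")
    groups: "OrderedDict[tuple, list[Spectrum]]" = OrderedDict()
    for s in spectra:
        key = tuple(s.meta.get(k) for k in group_key)
        groups.setdefault(key, []).append(s)
    out = []
    for key, members in groups.items():
        mean = np.mean([m.absorbance for m in members], axis=0)
        meta = dict(zip(group_key, key))
        meta["n_averaged"] = len(members)
        meta["sample_id"] = "AVG_" + "_".join(f"{k}={v}" for k, v in zip(group_key, key))
        out.append(Spectrum(wavenumbers=grid, absorbance=mean, meta=meta))
    return SpectraSet(out)


def spectra_to_feature_table(spectra: SpectraSet) -> FeatureTable:
    """Samples × wavenumbers matrix; feature ids are wavenumbers (cm⁻¹)."""
    if not len(spectra):
        raise ValueError("empty spectra set")
    meta = spectra.meta_frame()
    ids = meta["sample_id"].astype(str)
    data = pd.DataFrame(spectra.absorbance_matrix(),
                        index=pd.Index(ids, name="sample_id"),
                        columns=[f"{w:.2f}" for w in spectra.grid])
    keep = [c for c in ("temperature_C", "age_days", "replicate") if c in meta]
    meta_df = meta[keep].set_index(pd.Index(ids, name="sample_id"))
    return FeatureTable(data, meta_df)


# ---------------------------------------------------------------------------
# sklearn-style transformers (rows = samples, columns = wavenumbers)
# ---------------------------------------------------------------------------

class SNVScaler(TransformerMixin, BaseEstimator):
    """Row-wise standard normal variate transform (stateless)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return snv_matrix(check_array(X))


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """Row-wise Savitzky–Golay smoothing along the wavenumber axis."""

    def __init__(self, window: int = DEFAULT_WINDOW,
                 polyorder: int = DEFAULT_POLYORDER):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = check_array(X)
        _check_savgol(self.window, self.polyorder, X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return savgol_matrix(check_array(X), self.window, self.polyorder)


class RegionCropper(TransformerMixin, BaseEstimator):
    """Column selector keeping wavenumbers within [low, high] cm⁻¹."""

    def __init__(self, wavenumbers, high: float = FINGERPRINT_HIGH,
                 low: float = FINGERPRINT_LOW):
        self.wavenumbers = wavenumbers
        self.high = high
        self.low = low

    def fit(self, X, y=None):
        X = check_array(X)
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.size != X.shape[1]:
            raise ValueError("wavenumbers length does not match n_features")
        self.mask_ = region_mask(wn, self.high, self.low)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return check_array(X)[:, self.mask_]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_spectra_wide(path, meta: pd.DataFrame | None = None) -> SpectraSet:
    """Read the wide CSV layout (first column wavenumber, one column per
    sample); optional design table supplies per-sample metadata keyed on
    the measured-sample id prefix."""
    df = pd.read_csv(path)
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    spectra = []
    meta_idx = None
    if meta is not None:
        meta_idx = meta.set_index("sample_id")
    for col in df.columns[1:]:
        m = {"sample_id": str(col)}
        if meta_idx is not None:
            base = str(col).rsplit("_S", 1)[0]
            if base in meta_idx.index:
                row = meta_idx.loc[base]
                m.update({"temperature_C": int(row["temperature_C"]),
                          "age_days": int(row["age_days"]),
                          "replicate": int(row["replicate"])})
        spectra.append(Spectrum(wn, df[col].to_numpy(dtype=float), meta=m))
    return SpectraSet(spectra)


def read_spectra_long(path) -> SpectraSet:
    df = pd.read_csv(path)
    spectra = []
    for sid, sub in df.groupby("sample_id", sort=False):
        m = {"sample_id": str(sid)}
        for key in ("temperature_C", "age_days", "replicate"):
            if key in sub.columns:
                m[key] = int(sub[key].iloc[0])
        spectra.append(Spectrum(sub["wavenumber"].to_numpy(dtype=float),
                                sub["absorbance"].to_numpy(dtype=float), meta=m))
    return SpectraSet(spectra)


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader: single block, ##XYDATA=(X++(Y..Y)) with
    AFFN (plain decimal) values, honoring XFACTOR/YFACTOR.

    Lines carry one X value followed by one or more Y values; for multi-Y
    lines the X axis is rebuilt from FIRSTX/LASTX/NPOINTS.
    """
    headers: dict[str, str] = {}
    in_xy = False
    line_x: list[float] = []
    line_ys: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                headers[key] = value.strip()
                in_xy = key == "XYDATA"
                continue
            if in_xy:
                vals = [float(p) for p in line.replace(",", " ").split()]
                if len(vals) >= 2:
                    line_x.append(vals[0])
                    line_ys.append(vals[1:])
    if not line_ys:
        raise ValueError(f"no XYDATA parsed from {path}")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    ys = np.array([y for row in line_ys for y in row]) * yfactor
    if all(len(row) == 1 for row in line_ys):
        xs = np.asarray(line_x) * xfactor
    else:
        try:
            firstx = float(headers["FIRSTX"])
            lastx = float(headers["LASTX"])
            npoints = int(headers["NPOINTS"])
        except KeyError as exc:
            raise ValueError(
                "multi-Y JCAMP lines need FIRSTX/LASTX/NPOINTS headers") from exc
        if npoints != ys.size:
            raise ValueError(
                f"NPOINTS={npoints} but {ys.size} Y values parsed")
        # FIRSTX/LASTX are in actual units already (unlike tabulated X)
        xs = np.linspace(firstx, lastx, npoints)
    return Spectrum(xs, ys, meta={"sample_id": headers.get("TITLE") or str(path)})


def write_jcamp(spectrum: Spectrum, path, title: str | None = None) -> None:
    wn = spectrum.wavenumbers
    ab = spectrum.absorbance
    with open(path, "w") as fh:
        fh.write(f"##TITLE={title or spectrum.sample_id or 'spectrum'}\n")
        fh.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
        fh.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        fh.write(f"##FIRSTX={wn[0]}\n##LASTX={wn[-1]}\n##NPOINTS={wn.size}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        for x, y in zip(wn, ab):
            fh.write(f"{x:.4f} {y:.8f}\n")
        fh.write("##END=\n")
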