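"""Configuration-driven orchestration: generate (or load) → preprocess →
feature tables → per-temperature models → report.

A :class:`PipelineConfig` (YAML-loadable) either points at input files
(design + wide-spectra CSV + CHC profiles or peak tables) or requests
synthetic data; the two are mutually exclusive. :func:`run_pipeline` runs
every stage, writes CSV tables plus a machine-readable ``summary.json``
with a provenance block (config hash, seed, package version), and returns
the artifact paths with headline metrics. Runs are deterministic: the same
config and seed produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_models import (ModelSettings, classify_by_age, feature_trends,
                         regress_age, select_markers,
                         spectral_window_features)
from .chc import (AlkaneLadder, build_feature_table, default_alkane_ladder,
                  filter_minor, peaks_from_profile, peaks_to_profile,
                  read_peak_tables, read_profiles)
from .containers import FeatureTable, SpectraSet
from .spectra import (average_replicates, preprocess_set, read_spectra_wide,
                      spectra_to_feature_table)
from .synthetic import (GeneratorParams, default_compound_catalog,
                        make_measurement_design, simulate_dataset,
                        write_design, write_profiles, write_spectra_wide)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "flyage_out"
    temperatures: tuple = (20, 25, 30)
    assays: tuple = ("ftir", "chc")
    synthetic: dict | None = None
    inputs: dict | None = None
    preprocessing: dict = field(default_factory=dict)
    chc: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.synthetic is not None and self.inputs is not None:
            raise ValueError(
                "config must give exactly one of 'synthetic' or 'inputs'")
        if self.synthetic is None and self.inputs is None:
            self.synthetic = {}
        self.temperatures = tuple(int(t) for t in self.temperatures)
        self.assays = tuple(str(a).lower() for a in self.assays)
        bad = set(self.assays) - {"ftir", "chc"}
        if bad:
            raise ValueError(f"unknown assay(s): {sorted(bad)}")
        if self.inputs is not None:
            missing = [p for p in self.inputs.values()
                       if isinstance(p, str) and not Path(p).exists()]
            if missing:
                raise ValueError(f"input path(s) do not exist: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "outdir": str(self.outdir),
                "temperatures": list(self.temperatures),
                "assays": list(self.assays),
                "synthetic": self.synthetic, "inputs": self.inputs,
                "preprocessing": self.preprocessing, "chc": self.chc,
                "model": self.model}

    def content_hash(self) -> str:
        """Hash of the scientifically relevant configuration (the output
        location does not change results)."""
        d = self.to_dict()
        d.pop("outdir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    artifacts: dict
    summary: dict


def _settings(config: PipelineConfig) -> ModelSettings:
    kwargs = dict(config.model)
    kwargs.setdefault("seed", config.seed)
    return ModelSettings(**kwargs)


def _stage(name: str):
    """Decorator naming the failing stage in the raised error."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


@_stage("generate")
def _generate(config: PipelineConfig, outdir: Path):
    syn = dict(config.synthetic or {})
    params = GeneratorParams.from_dict({**syn.get("params", {}),
                                        "seed": int(config.seed)})
    n_replicates = int(syn.get("n_replicates", 3))
    spectra_by_T: dict[int, SpectraSet] = {}
    profiles_by_T: dict[int, list] = {}
    designs = []
    for T in config.temperatures:
        design = make_measurement_design(T, n_replicates=n_replicates)
        designs.append(design)
        spectra, profiles = simulate_dataset(design, params)
        spectra_by_T[T] = spectra
        profiles_by_T[T] = profiles
        logger.info("generated %d spectra and %d CHC profiles at %d C",
                    len(spectra), len(profiles), T)
    design_all = pd.concat(designs, ignore_index=True)
    write_design(design_all, outdir / "design.csv")
    for T in config.temperatures:
        write_spectra_wide(spectra_by_T[T], outdir / f"spectra_raw_{T}C.csv")
        write_profiles(profiles_by_T[T], outdir / f"chc_profiles_{T}C.csv")
    return spectra_by_T, profiles_by_T, params


@_stage("load")
def _load(config: PipelineConfig):
    inp = config.inputs or {}
    design = pd.read_csv(inp["design_csv"]) if "design_csv" in inp else None
    spectra_by_T: dict[int, SpectraSet] = {}
    profiles_by_T: dict[int, list] = {}
    if "spectra_csv" in inp:
        spectra = read_spectra_wide(inp["spectra_csv"], meta=design)
        for T in config.temperatures:
            subset = [s for s in spectra if s.meta.get("temperature_C") == T]
            if subset:
                spectra_by_T[T] = SpectraSet(subset)
    if "profiles_csv" in inp:
        profiles = read_profiles(inp["profiles_csv"])
        for T in config.temperatures:
            sub = [p for p in profiles if p.meta.get("temperature_C") == T]
            if sub:
                profiles_by_T[T] = sub
    elif "peaks_csv" in inp:
        ladder = (AlkaneLadder.from_csv(inp["ladder_csv"])
                  if "ladder_csv" in inp else default_alkane_ladder())
        catalog = default_compound_catalog()
        tables = read_peak_tables(inp["peaks_csv"])
        meta_idx = design.set_index("sample_id") if design is not None else None
        ri_window = float(config.chc.get("ri_window", 5.0))
        for sid, peaks in tables.items():
            meta = {"sample_id": sid}
            if meta_idx is not None and sid in meta_idx.index:
                row = meta_idx.loc[sid]
                meta.update(temperature_C=int(row["temperature_C"]),
                            age_days=int(row["age_days"]),
                            replicate=int(row["replicate"]))
            prof = peaks_to_profile(peaks, catalog, ladder, meta=meta,
                                    ri_window=ri_window)
            profiles_by_T.setdefault(int(meta.get("temperature_C", -1)), []).append(prof)
    return spectra_by_T, profiles_by_T


@_stage("preprocess")
def _ftir_table(config: PipelineConfig, spectra: SpectraSet,
                outdir: Path, T: int) -> FeatureTable:
    pp = config.preprocessing
    processed = preprocess_set(
        spectra,
        window=int(pp.get("window", 15)),
        polyorder=int(pp.get("polyorder", 3)),
        high=float(pp.get("high", 1800.0)),
        low=float(pp.get("low", 900.0)),
        apply_snv=bool(pp.get("snv", True)),
    )
    # one averaged spectrum per age for reporting (Fig-1-style export) ...
    per_age = average_replicates(processed, ("temperature_C", "age_days"))
    write_spectra_wide(per_age, outdir / f"spectra_avg_{T}C.csv")
    # ... and per-replicate averages as the modeling samples
    per_rep = average_replicates(processed,
                                 ("temperature_C", "age_days", "replicate"))
    table = spectra_to_feature_table(per_rep)
    table.to_csv(outdir / f"features_ftir_{T}C.csv")
    return table


@_stage("chc-features")
def _chc_table(config: PipelineConfig, profiles: list, outdir: Path,
               T: int, seed: int) -> FeatureTable:
    threshold = float(config.chc.get("threshold", 0.5))
    ri_window = float(config.chc.get("ri_window", 5.0))
    route_via_peaks = bool(config.chc.get("emulate_peak_tables", True))
    catalog = default_compound_catalog()
    ladder = default_alkane_ladder()
    out = []
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(T, 99)))
    for p in profiles:
        if route_via_peaks and set(p.compounds) <= set(catalog["name"]):
            # exercise the instrument-level path: profile -> integrated
            # peak table -> retention indexing -> assignment -> percents
            peaks = peaks_from_profile(p, catalog, ladder,
                                       rt_jitter_sd=float(config.chc.get("rt_jitter_sd", 0.0)),
                                       rng=rng)
            p = peaks_to_profile(peaks, catalog, ladder, meta=p.meta,
                                 ri_window=ri_window)
        out.append(filter_minor(p, threshold=threshold))
    table = build_feature_table(out, catalog)
    table.to_csv(outdir / f"features_chc_{T}C.csv")
    return table


@_stage("model")
def _model_one(table: FeatureTable, T: int, settings: ModelSettings):
    clf = classify_by_age(table, T, settings)
    reg = regress_age(table, T, settings)
    markers = select_markers([clf, reg], vip_threshold=settings.vip_threshold)
    return clf, reg, markers


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = _settings(config)

    if config.synthetic is not None:
        spectra_by_T, profiles_by_T, _ = _generate(config, outdir)
    else:
        spectra_by_T, profiles_by_T = _load(config)

    tables: dict[tuple[str, int], FeatureTable] = {}
    for T in config.temperatures:
        if "ftir" in config.assays and T in spectra_by_T:
            tables[("ftir", T)] = _ftir_table(config, spectra_by_T[T], outdir, T)
        if "chc" in config.assays and T in profiles_by_T:
            tables[("chc", T)] = _chc_table(config, profiles_by_T[T], outdir,
                                            T, config.seed)

    table2_rows, table3_rows, marker_rows, trend_rows, pred_frames = [], [], [], [], []
    markers_by = {}
    for (assay, T), table in tables.items():
        logger.info("modeling %s at %d C (%d samples x %d features)",
                    assay, T, len(table), len(table.feature_ids))
        clf, reg, markers = _model_one(table, T, settings)
        markers_by[(assay, T)] = markers
        row2 = {"assay": assay, **clf.table2_row()}
        row3 = {"assay": assay, **reg.table3_row()}
        table2_rows.append(row2)
        table3_rows.append(row3)
        for rank, m in enumerate(markers, 1):
            marker_rows.append({"assay": assay, "temperature_C": T,
                                "rank": rank, "feature_id": m,
                                "VIP_classification": float(clf.vip[m]),
                                "VIP_regression": float(reg.vip[m])})
        preds = reg.predictions.copy()
        preds.insert(0, "temperature_C", T)
        preds.insert(0, "assay", assay)
        pred_frames.append(preds)
        # trend reporting: selected markers for CHC, the C-O/PO2- window for FTIR
        if assay == "chc":
            trend_features = markers
        else:
            trend_features = spectral_window_features(table)
        for tf in feature_trends(table, T, trend_features):
            trend_rows.append({"assay": assay, "temperature_C": T,
                               "feature_id": tf.feature_id,
                               "family": tf.family,
                               "equation": tf.equation(), "R2": tf.r2,
                               "degenerate": tf.degenerate})

    artifacts = {}
    for name, rows in (("table2.csv", table2_rows), ("table3.csv", table3_rows),
                       ("markers.csv", marker_rows), ("trends.csv", trend_rows)):
        path = outdir / name
        pd.DataFrame(rows).to_csv(path, index=False)
        artifacts[name] = str(path)
    if pred_frames:
        path = outdir / "predictions.csv"
        pd.concat(pred_frames).to_csv(path, index_label="sample_id")
        artifacts["predictions.csv"] = str(path)

    summary = {
        "provenance": {"config_hash": config.content_hash(),
                       "seed": int(config.seed),
                       "package_version": __version__},
        "classification": table2_rows,
        "regression": table3_rows,
        "markers": {f"{assay}_{T}C": m for (assay, T), m in markers_by.items()},
    }
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["summary.json"] = str(summary_path)
    logger.info("wrote %s", summary_path)
    return RunReport(artifacts=artifacts, summary=summary)
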