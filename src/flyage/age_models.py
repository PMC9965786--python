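"""Per-temperature analysis stages: OPLS-DA age-class discrimination, PLS
age regression with predicted-vs-actual diagnostics, VIP > 1 marker
selection, and marker-vs-age trend fitting.

Each temperature (20/25/30 °C) is modeled separately, per assay (FTIR
spectra or CHC percentages). The classification treats age in days as the
class label; the regression predicts age directly and reports RMSECV in
days plus the least-squares line of in-sample predicted on actual age
(slope ≈ 1 with a numerically tiny intercept characterizes a good fit).
Marker selection intersects the VIP > 1 features of the classification and
regression models; trend fitting chooses among linear,
exponential-plus-offset and quadratic least squares by R² (with a small
margin favoring fewer parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .containers import FeatureTable
from .cross_decomposition import NIPALSPLS, OPLSDA, vip_scores
from .model_selection import (PermutationResult, ValidationReport,
                              cross_validate, permutation_test,
                              select_n_components)

logger = logging.getLogger(__name__)

#: Default spectral reporting window for the age-informative C-O/PO2- band
#: region (cm-1): the seven ~1.93 cm-1-spaced points around 1040-1051.
SPECTRAL_TREND_WINDOW = (1039.45, 1051.02)


@dataclass
class ModelSettings:
    """Shared modeling knobs; defaults mirror common chemometrics practice
    (autoscaling, 7-fold CV, 200 permutations, VIP > 1)."""
    scale: str = "uv"
    n_folds: int = 7
    n_perm: int = 200
    vip_threshold: float = 1.0
    gain_min: float = 0.01
    max_components: int = 8
    n_orth: int = 1
    seed: int = 0


@dataclass
class AgeClassificationResult:
    temperature_C: int
    model: OPLSDA
    report: ValidationReport
    permutation: PermutationResult
    scores: pd.DataFrame = field(repr=False)
    vip: pd.Series = field(repr=False)

    def table2_row(self) -> dict:
        row = {"temperature_C": self.temperature_C,
               "R2X_cum": self.report.r2x_cum,
               "R2Y_cum": self.report.r2y_cum,
               "Q2_cum": self.report.q2_cum}
        if self.permutation is not None:
            row["perm_R2_intercept"] = self.permutation.r2_intercept
            row["perm_Q2_intercept"] = self.permutation.q2_intercept
        return row


@dataclass
class AgeRegressionResult:
    temperature_C: int
    model: NIPALSPLS
    report: ValidationReport
    permutation: PermutationResult
    fitted_line: tuple[float, float]          # (slope, intercept)
    predictions: pd.DataFrame = field(repr=False)  # actual vs predicted age
    vip: pd.Series = field(repr=False)

    def table3_row(self) -> dict:
        slope, intercept = self.fitted_line
        row = {"temperature_C": self.temperature_C,
               "slope": slope, "intercept": intercept,
               "R2": self.report.r2y_cum,
               "RMSECV": self.report.rmsecv}
        if self.permutation is not None:
            row["perm_R2_intercept"] = self.permutation.r2_intercept
            row["perm_Q2_intercept"] = self.permutation.q2_intercept
        return row


@dataclass
class TrendFit:
    feature_id: str
    family: str
    parameters: tuple
    r2: float
    ages: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    degenerate: bool = False

    def equation(self) -> str:
        p = self.parameters
        if self.family == "linear":
            return f"y = {p[0]:.4g} x + {p[1]:.4g}"
        if self.family == "quadratic":
            return f"y = {p[0]:.4g} x^2 + {p[1]:.4g} x + {p[2]:.4g}"
        return f"y = {p[0]:.4g} exp(-{p[1]:.4g} x) + {p[2]:.4g}"


# ---------------------------------------------------------------------------
# classification / regression
# ---------------------------------------------------------------------------

def _subset(table: FeatureTable, temperature_C: int) -> FeatureTable:
    return table.subset_temperature(temperature_C)


def classify_by_age(table: FeatureTable, temperature_C: int,
                    settings: ModelSettings | None = None,
                    run_permutation: bool = True) -> AgeClassificationResult:
    """OPLS-DA with pupal age (days) as the class label at one temperature."""
    s = settings or ModelSettings()
    sub = _subset(table, temperature_C)
    ages = sub.meta["age_days"].to_numpy()
    levels, counts = np.unique(ages, return_counts=True)
    if levels.size < 2:
        raise ValueError(f"single age class at {temperature_C} C")
    if counts.min() < 2:
        bad = levels[counts < 2].tolist()
        raise ValueError(f"age class(es) with one sample: {bad}")
    n_folds = max(2, min(s.n_folds, len(sub) // 2))
    n_pred = select_n_components(OPLSDA(n_orth=s.n_orth, scale=s.scale),
                                 sub.X, ages,
                                 max_components=min(s.max_components,
                                                    levels.size - 1),
                                 gain_min=s.gain_min, n_folds=n_folds,
                                 seed=s.seed)
    model = OPLSDA(n_orth=s.n_orth, n_pred=n_pred, scale=s.scale)
    report = cross_validate(model, sub.X, ages, n_folds=n_folds, seed=s.seed)
    fitted = OPLSDA(n_orth=s.n_orth, n_pred=n_pred, scale=s.scale).fit(sub.X, ages)
    perm = permutation_test(model, sub.X, ages, n_perm=s.n_perm,
                            seed=s.seed, n_folds=n_folds) if run_permutation else None
    scores = pd.DataFrame(fitted.transform(sub.X),
                          index=sub.data.index,
                          columns=[f"t{i+1}" for i in range(fitted.n_pred_)])
    if fitted.n_orth_:
        orth = fitted.orthogonal_scores(sub.X)
        for i in range(orth.shape[1]):
            scores[f"to{i+1}"] = orth[:, i]
    scores["age_days"] = ages
    vip = pd.Series(vip_scores(fitted), index=sub.feature_ids)
    return AgeClassificationResult(temperature_C=int(temperature_C),
                                   model=fitted, report=report,
                                   permutation=perm, scores=scores, vip=vip)


def regress_age(table: FeatureTable, temperature_C: int,
                settings: ModelSettings | None = None,
                run_permutation: bool = True) -> AgeRegressionResult:
    """PLS regression of pupal age (days) on the feature matrix at one
    temperature; RMSECV in days."""
    s = settings or ModelSettings()
    sub = _subset(table, temperature_C)
    ages = sub.meta["age_days"].to_numpy(dtype=float)
    if np.unique(ages).size < 3:
        raise ValueError(f"need >= 3 distinct ages at {temperature_C} C "
                         f"(constant or near-constant age)")
    n_folds = max(2, min(s.n_folds, len(sub) // 2))
    n_comp = select_n_components(NIPALSPLS(scale=s.scale), sub.X, ages,
                                 max_components=s.max_components,
                                 gain_min=s.gain_min, n_folds=n_folds,
                                 seed=s.seed)
    model = NIPALSPLS(n_components=n_comp, scale=s.scale)
    report = cross_validate(model, sub.X, ages, n_folds=n_folds, seed=s.seed)
    fitted = NIPALSPLS(n_components=n_comp, scale=s.scale).fit(sub.X, ages)
    predicted = fitted.predict(sub.X)
    slope, intercept = np.polyfit(ages, predicted, 1)
    perm = permutation_test(model, sub.X, ages, n_perm=s.n_perm,
                            seed=s.seed, n_folds=n_folds) if run_permutation else None
    predictions = pd.DataFrame({"actual_age": ages, "predicted_age": predicted},
                               index=sub.data.index)
    vip = pd.Series(vip_scores(fitted), index=sub.feature_ids)
    return AgeRegressionResult(temperature_C=int(temperature_C), model=fitted,
                               report=report, permutation=perm,
                               fitted_line=(float(slope), float(intercept)),
                               predictions=predictions, vip=vip)


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def select_markers(vip_tables, vip_threshold: float = 1.0,
                   mode: str = "intersection") -> list[str]:
    """Features exceeding the VIP threshold in all given models
    (``mode="intersection"``, default) or in any (``"union"``), ordered by
    descending worst-case VIP. An empty selection is returned (and logged),
    not raised."""
    tables = [t.vip if hasattr(t, "vip") else t for t in vip_tables]
    if not tables:
        raise ValueError("no VIP tables given")
    sets = [set(t.index[t > vip_threshold]) for t in tables]
    if mode == "intersection":
        chosen = set.intersection(*sets)
    elif mode == "union":
        chosen = set.union(*sets)
    else:
        raise ValueError("mode must be 'intersection' or 'union'")
    if not chosen:
        logger.info("no features with VIP > %s in %s", vip_threshold, mode)
        return []
    score = {f: min(float(t.get(f, 0.0)) for t in tables) for f in chosen}
    return sorted(chosen, key=lambda f: (-score[f], f))


# ---------------------------------------------------------------------------
# trend fitting
# ---------------------------------------------------------------------------

def _exp_offset(x, a, k, c):
    return a * np.exp(-k * x) + c


def _fit_family(x: np.ndarray, y: np.ndarray, family: str):
    """(parameters, fitted, r2) for one family; r2 may be nan on failure."""
    if family == "linear":
        p = np.polyfit(x, y, 1)
        fit = np.polyval(p, x)
    elif family == "quadratic":
        p = np.polyfit(x, y, 2)
        fit = np.polyval(p, x)
    elif family == "exponential-offset":
        # data-driven start: offset near the tail, rate from a log-linear fit
        c0 = y[-1]
        a0 = y[0] - c0 if abs(y[0] - c0) > 1e-12 else (1.0 if y[0] >= c0 else -1.0)
        span = max(x.max() - x.min(), 1.0)
        try:
            p, _ = curve_fit(_exp_offset, x, y, p0=(a0, 1.0 / span, c0),
                             bounds=([-np.inf, 1e-9, -np.inf],
                                     [np.inf, 50.0 / span, np.inf]),
                             maxfev=20000)
        except RuntimeError:
            return None, None, -np.inf
        fit = _exp_offset(x, *p)
    else:
        raise ValueError(f"unknown trend family {family!r}")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fit) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return tuple(float(v) for v in p), fit, r2


_FAMILY_NPARAMS = {"linear": 2, "quadratic": 3, "exponential-offset": 3}


def fit_trend(values, ages, family: str = "auto",
              feature_id: str = "") -> TrendFit:
    """Least-squares trend of a feature series against pupal age.

    ``family="auto"`` tries linear, exponential-plus-offset and quadratic
    (those whose parameter count is below the number of age points) and
    keeps the highest R², with a 0.01 margin favoring fewer parameters.
    A constant series is reported as a degenerate linear fit with R² = 0.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValueError("values and ages differ in length")
    if x.size < 3:
        raise ValueError("need >= 3 age points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in trend input")
    order = np.argsort(x)
    x, y = x[order], y[order]

    if np.ptp(y) == 0:  # constant series: slope-0 line, R2 undefined -> 0
        return TrendFit(feature_id=feature_id, family="linear",
                        parameters=(0.0, float(y[0])), r2=0.0,
                        ages=x, fitted=y.copy(), degenerate=True)

    candidates = ([family] if family != "auto"
                  else ["linear", "exponential-offset", "quadratic"])
    fits = {}
    for fam in candidates:
        if _FAMILY_NPARAMS[fam] >= x.size:
            continue
        p, fit, r2 = _fit_family(x, y, fam)
        if p is not None:
            fits[fam] = (p, fit, r2)
    if not fits:
        raise ValueError("no admissible trend family for this many points")
    best_r2 = max(r2 for _, _, r2 in fits.values())
    # prefer fewer parameters within a 0.01 R2 margin of the best
    chosen = min(
        (fam for fam, (_, _, r2) in fits.items() if r2 >= best_r2 - 0.01),
        key=lambda fam: (_FAMILY_NPARAMS[fam], -fits[fam][2]),
    )
    p, fit, r2 = fits[chosen]
    return TrendFit(feature_id=feature_id, family=chosen, parameters=p,
                    r2=float(np.clip(r2, 0.0, 1.0)), ages=x, fitted=fit)


def feature_trends(table: FeatureTable, temperature_C: int,
                   feature_ids, family: str = "auto",
                   aggregate: str = "mean") -> list[TrendFit]:
    """Fit per-age trends for selected features at one temperature,
    aggregating replicates per age by the mean."""
    sub = _subset(table, temperature_C)
    grouped = sub.to_frame().groupby("age_days")
    trends = []
    for fid in feature_ids:
        series = grouped[fid].mean() if aggregate == "mean" else grouped[fid].median()
        trends.append(fit_trend(series.to_numpy(), series.index.to_numpy(),
                                family=family, feature_id=str(fid)))
    return trends


def spectral_window_features(table: FeatureTable,
                             window: tuple[float, float] = SPECTRAL_TREND_WINDOW,
                             ) -> list[str]:
    """Feature ids (wavenumber columns) falling inside a cm⁻¹ window."""
    lo, hi = min(window), max(window)
    out = []
    for fid in table.feature_ids:
        try:
            w = float(fid)
        except ValueError:
            continue
        if lo <= w <= hi:
            out.append(fid)
    return out
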