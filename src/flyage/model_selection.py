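"""Model validation for the latent-variable models: stratified K-fold
cross-validation (Q², RMSECV), response-permutation testing with R²/Q²
intercepts, and Q²-gain component selection.

Q² = 1 − PRESS/TSS, with PRESS accumulated from out-of-fold predictions of
the model refit on each training fold and TSS taken about the full-data
response mean; RMSECV = √(PRESS/n) (days, for the age regressions). Folds
are assigned deterministically from a seed: round-robin within class for
discriminant models, round-robin within response-sorted order (venetian
blinds) for regressions, so every fold spans the age range.

The permutation test refits the model on row-shuffled responses and
records (|corr(y_perm, y)|, R², Q²) per permutation plus the unpermuted
reference at correlation 1; the intercepts of the least-squares lines of
R² and Q² on correlation diagnose overfitting — a negative Q² intercept
supports model validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone, is_classifier


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    rmsecv: float
    n_folds: int
    fold_assignment: np.ndarray = field(repr=False)
    n_components: int = 0

    def to_row(self) -> dict:
        return {"R2X_cum": self.r2x_cum, "R2Y_cum": self.r2y_cum,
                "Q2_cum": self.q2_cum, "RMSECV": self.rmsecv,
                "n_folds": self.n_folds, "n_components": self.n_components}


@dataclass
class PermutationResult:
    correlations: np.ndarray   # includes the unpermuted reference at 1.0
    r2s: np.ndarray
    q2s: np.ndarray
    r2_intercept: float
    q2_intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"correlation": self.correlations,
                             "R2": self.r2s, "Q2": self.q2s})


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def stratified_folds(y, n_folds: int, seed: int = 0,
                     classification: bool = False) -> np.ndarray:
    """Deterministic fold labels in 0..n_folds−1 for every sample."""
    y = np.asarray(y)
    n = y.shape[0]
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds={n_folds} outside 2..{n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if classification:
        offset = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = (offset + np.arange(idx.size)) % n_folds
            offset += idx.size  # rotate starting fold between classes
    else:
        # venetian blinds on the sorted response, random tie order
        order = np.lexsort((rng.random(n), np.asarray(y, dtype=float)))
        folds[order] = np.arange(n) % n_folds
    return folds


def _one_hot(y, classes) -> np.ndarray:
    classes = np.asarray(classes)
    Y = np.zeros((len(y), classes.size))
    for j, cls in enumerate(classes):
        Y[np.asarray(y) == cls, j] = 1.0
    return Y


def _response_matrix(model, y) -> tuple[np.ndarray, np.ndarray | None]:
    """(numeric response matrix, class list or None) for PRESS bookkeeping."""
    if is_classifier(model):
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least 2 response levels")
        return _one_hot(y, classes), classes
    y = np.asarray(y, dtype=float)
    return (y[:, None] if y.ndim == 1 else y), None


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(model, X, y, n_folds: int = 7, seed: int = 0,
                   folds: np.ndarray | None = None) -> ValidationReport:
    """Q²/RMSECV by stratified K-fold refitting of a (cloned) model spec;
    R2X/R2Y come from the full-data fit. A precomputed per-sample fold
    assignment may be passed to pin folds across reorderings."""
    X = np.asarray(X, dtype=float)
    da = is_classifier(model)
    Ymat, classes = _response_matrix(model, y)
    if folds is None:
        folds = stratified_folds(y, n_folds, seed=seed, classification=da)
    else:
        folds = np.asarray(folds, dtype=int)
        n_folds = int(folds.max()) + 1
    if da:
        for f in range(n_folds):
            train_classes = np.unique(np.asarray(y)[folds != f])
            if train_classes.size < classes.size:
                raise ValueError(
                    f"fold {f}: training data misses class level(s); "
                    "reduce n_folds or add samples")
    press = 0.0
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        m = clone(model).fit(X[tr], np.asarray(y)[tr])
        Yhat = m.predict_response(X[te])
        if da:
            # map fold columns onto the global class order
            full = np.full((te.sum(), classes.size), np.nan)
            pos = {c: j for j, c in enumerate(classes)}
            for jf, c in enumerate(m.classes_):
                full[:, pos[c]] = Yhat[:, jf]
            Yhat = full
        press += float(((Ymat[te] - Yhat) ** 2).sum())
    tss = float(((Ymat - Ymat.mean(axis=0)) ** 2).sum())
    q2 = 1.0 - press / tss
    rmsecv = float(np.sqrt(press / Ymat.size))
    full_model = clone(model).fit(X, y)
    return ValidationReport(
        r2x_cum=float(full_model.r2x_), r2y_cum=float(full_model.r2y_),
        q2_cum=float(q2), rmsecv=rmsecv, n_folds=n_folds,
        fold_assignment=folds,
        n_components=getattr(full_model, "n_components_",
                             getattr(full_model, "n_pred_", 0)),
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _label_correlation(y_perm, y, da: bool) -> float:
    """|Pearson correlation| between permuted and original response,
    averaged over indicator columns for discriminant models."""
    if da:
        classes = np.unique(y)
        A, B = _one_hot(y_perm, classes), _one_hot(y, classes)
        cors = []
        for j in range(classes.size):
            a, b = A[:, j], B[:, j]
            if a.std() == 0 or b.std() == 0:
                continue
            cors.append(abs(np.corrcoef(a, b)[0, 1]))
        return float(np.mean(cors)) if cors else 0.0
    a = np.asarray(y_perm, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate response: single level")
    return float(abs(np.corrcoef(a, b)[0, 1]))


def permutation_test(model, X, y, n_perm: int = 200, seed: int = 0,
                     n_folds: int = 7) -> PermutationResult:
    """Row-shuffle the response, refit, and summarize R²/Q² against label
    correlation, including the unpermuted reference point."""
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    y = np.asarray(y)
    da = is_classifier(model)
    if np.unique(y).size < 2:
        raise ValueError("degenerate response: single level")
    rng = np.random.default_rng(seed)
    ref = cross_validate(model, X, y, n_folds=n_folds, seed=seed)
    cors, r2s, q2s = [1.0], [ref.r2y_cum], [ref.q2_cum]
    for _ in range(n_perm):
        y_perm = y[rng.permutation(y.shape[0])]
        rep = cross_validate(model, X, y_perm, n_folds=n_folds, seed=seed)
        cors.append(_label_correlation(y_perm, y, da))
        r2s.append(rep.r2y_cum)
        q2s.append(rep.q2_cum)
    cors_a, r2s_a, q2s_a = map(np.asarray, (cors, r2s, q2s))
    r2_int = float(np.polyfit(cors_a, r2s_a, 1)[1])
    q2_int = float(np.polyfit(cors_a, q2s_a, 1)[1])
    return PermutationResult(cors_a, r2s_a, q2s_a, r2_int, q2_int)


# ---------------------------------------------------------------------------
# component selection
# ---------------------------------------------------------------------------

def _with_components(model, a: int):
    m = clone(model)
    if is_classifier(m):
        m.set_params(n_pred=a)
    else:
        m.set_params(n_components=a)
    return m


def select_n_components(model, X, y, max_components: int = 10,
                        gain_min: float = 0.01, n_folds: int = 7,
                        seed: int = 0) -> int:
    """Smallest component count after which the cross-validated Q² gain
    drops to ``gain_min`` or less; always returns at least 1."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    # components must stay fittable on every training fold
    max_test = int(np.ceil(n / n_folds))
    cap = max(1, min(max_components, n - max_test - 1, p))
    best = 1
    q2_prev = cross_validate(_with_components(model, 1), X, y,
                             n_folds=n_folds, seed=seed).q2_cum
    for a in range(2, cap + 1):
        q2_a = cross_validate(_with_components(model, a), X, y,
                              n_folds=n_folds, seed=seed).q2_cum
        if q2_a - q2_prev > gain_min:
            best, q2_prev = a, q2_a
        else:
            break
    return best
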