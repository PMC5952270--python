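"""Model validation: repeated stratified 2-fold cross-validation (Q²),
permutation testing with R²/Q² regression intercepts, and ROC/AUROC from
cross-validated predictions.

Q² = 1 − PRESS/SS measures out-of-sample prediction of the encoded class
contrast; by the usual chemometric reading a model with Q² > 0.40 is
good and Q² > 0.70 robust, while Q² ≤ 0 predicts worse than the mean.
The permutation test refits the model under shuffled labels and
regresses R²/Q² on the |correlation| between permuted and true labels;
a near-zero Q² intercept together with every permuted Q² falling below
the real one indicates the model is not an overfitting artifact.
AUROC is computed by pair counting (the probability a random positive
scores above a random negative, ties counted ½), which equals the
trapezoidal area under the threshold-swept ROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BinnedMatrix
from .opls import ClassVector, _fit_core, _predict_core


def quality_label(q2: float) -> str:
    """Chemometric quality reading of a Q² value."""
    if q2 > 0.70:
        return "robust"
    if q2 > 0.40:
        return "good"
    return "poor"


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _pareto_fold(train: np.ndarray, test: np.ndarray):
    """Center/Pareto-scale a training fold; apply its constants to the
    held-out fold."""
    means = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    denom = np.where(sd == 0, 1.0, np.sqrt(sd))
    return (train - means) / denom, (test - means) / denom


def _stratified_two_fold(labels: np.ndarray, rng: np.random.Generator):
    """Random stratified split into two folds; each class is split as
    evenly as possible, so both folds contain both classes whenever each
    class has ≥ 2 members."""
    fold = np.empty(labels.size, dtype=int)
    for lev in np.unique(labels):
        idx = np.where(labels == lev)[0]
        if idx.size < 2:
            raise ValueError(f"class {lev!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        half = idx.size // 2
        fold[idx[:half]] = 0
        fold[idx[half:]] = 1
    return fold


@dataclass
class CVResult:
    q2: float
    predictions: np.ndarray       # per-sample mean out-of-fold prediction
    sample_ids: tuple[str, ...]
    n_repeats: int
    seed: int


def cross_validate(
    B: BinnedMatrix,
    cv: ClassVector,
    n_ortho: int = 1,
    n_repeats: int = 50,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified 2-fold cross-validation of the OPLS-DA model.

    Scaling is refitted inside each training fold and applied to the
    held-out fold, so a PQN-normalized unscaled matrix is the natural
    input; a scaled matrix is accepted and simply rescaled per fold.
    Returns Q² = 1 − PRESS/SS(y centered) and the per-sample mean of
    out-of-fold predictions across repeats.
    """
    if tuple(B.sample_ids) != cv.sample_ids:
        raise ValueError("sample ids of X and y do not match")
    X = B.data
    y = cv.y
    labels = np.asarray(cv.labels)
    rng = np.random.default_rng(seed)

    press = 0.0
    pred_sum = np.zeros(y.size)
    pred_cnt = np.zeros(y.size)
    for _ in range(n_repeats):
        fold = _stratified_two_fold(labels, rng)
        for held in (0, 1):
            tr = fold != held
            te = ~tr
            Xtr, Xte = _pareto_fold(X[tr], X[te])
            y_mean = y[tr].mean()
            fit = _fit_core(Xtr, y[tr] - y_mean, n_ortho)
            t_new, _ = _predict_core(Xte, fit)
            y_pred = t_new * fit["c"] + y_mean
            press += float(((y[te] - y_pred) ** 2).sum())
            pred_sum[te] += y_pred
            pred_cnt[te] += 1
    ss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / (n_repeats * ss)
    return CVResult(q2=q2, predictions=pred_sum / pred_cnt,
                    sample_ids=cv.sample_ids, n_repeats=n_repeats, seed=seed)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    records: pd.DataFrame         # columns: correlation, r2, q2
    r2_actual: float
    q2_actual: float
    r2_intercept: float
    q2_intercept: float
    n_perm: int
    valid: bool
    seed: int


def _ols_intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept, *_ = stats.linregress(x, y)
    return float(intercept)


def permutation_test(
    B: BinnedMatrix,
    cv: ClassVector,
    n_perm: int = 2000,
    n_ortho: int = 1,
    n_repeats: int = 5,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation validation of an OPLS-DA model.

    Per permutation the labels are shuffled, the model refitted (same
    n_ortho) and R²/Q² recorded together with the |Pearson correlation|
    between permuted and original encoded labels.  OLS lines through the
    (correlation, R²) and (correlation, Q²) points — including the
    unpermuted model at correlation 1 — give the intercepts at
    correlation 0.  The verdict is valid when the Q² intercept is below
    0.05 and every permuted Q² falls below the actual Q².
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    y = cv.y
    if np.allclose(y, 0):
        raise ValueError("response has zero variance")
    rng = np.random.default_rng(seed)
    labels = np.asarray(cv.labels)

    Xs, _ = _pareto_fold(B.data, B.data)

    def r2_training(cvec: ClassVector) -> float:
        fit = _fit_core(Xs, cvec.y, n_ortho)
        resid = cvec.y - fit["y_hat"]
        return 1.0 - float(resid @ resid) / float(cvec.y @ cvec.y)

    r2_actual = r2_training(cv)
    q2_actual = cross_validate(B, cv, n_ortho, n_repeats,
                               seed=int(rng.integers(2**31))).q2

    rows = [{"correlation": 1.0, "r2": r2_actual, "q2": q2_actual,
             "permuted": False}]
    y_sd = y.std()
    for _ in range(n_perm):
        perm = rng.permutation(labels.size)
        cvec = ClassVector(
            sample_ids=cv.sample_ids, labels=tuple(labels[perm]),
            positive_label=cv.positive_label,
            negative_label=cv.negative_label, y=y[perm],
        )
        corr = abs(float(np.corrcoef(y, y[perm])[0, 1])) if y_sd > 0 else 0.0
        r2p = r2_training(cvec)
        q2p = cross_validate(B, cvec, n_ortho, n_repeats,
                             seed=int(rng.integers(2**31))).q2
        rows.append({"correlation": corr, "r2": r2p, "q2": q2p,
                     "permuted": True})

    rec = pd.DataFrame(rows)
    r2_int = _ols_intercept(rec["correlation"].to_numpy(),
                            rec["r2"].to_numpy())
    q2_int = _ols_intercept(rec["correlation"].to_numpy(),
                            rec["q2"].to_numpy())
    perm_q2 = rec.loc[rec["permuted"], "q2"].to_numpy()
    valid = bool(q2_int < 0.05 and np.all(perm_q2 < q2_actual))
    return PermutationResult(records=rec, r2_actual=r2_actual,
                             q2_actual=q2_actual, r2_intercept=r2_int,
                             q2_intercept=q2_int, n_perm=n_perm,
                             valid=valid, seed=seed)


def permutation_pvalue(result: PermutationResult) -> float:
    """Empirical p-value: (1 + #{Q²_perm ≥ Q²_actual}) / (n_perm + 1)."""
    perm_q2 = result.records.loc[result.records["permuted"], "q2"].to_numpy()
    return (1.0 + int((perm_q2 >= result.q2_actual).sum())) / (result.n_perm + 1)


# ---------------------------------------------------------------------------
# ROC / AUROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float


def roc_auroc(predictions: np.ndarray, labels, positive_label=None) -> RocResult:
    """ROC curve and AUROC from continuous scores.

    AUROC is the fraction of (positive, negative) pairs ranked correctly
    with ties counted ½ (computed via the rank formula); the ROC is a
    threshold sweep over the unique score values, whose trapezoidal area
    equals the pair-counting AUROC.
    """
    scores = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("labels must contain exactly two classes, "
                         f"got {levels.tolist()}")
    if positive_label is None:
        positive_label = levels[1]
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one class is absent")

    ranks = stats.rankdata(scores)  # midranks handle ties at ½ per pair
    auroc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # threshold sweep, descending unique scores
    order = np.argsort(-scores, kind="mergesort")
    sorted_pos = pos[order].astype(float)
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(1.0 - sorted_pos)
    distinct = np.r_[np.where(np.diff(scores[order]))[0], scores.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, scores[order][distinct]]
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds,
                     auroc=float(auroc))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Validation summary of one two-group comparison."""

    comparison: str
    r2: float
    q2: float
    label: str
    auroc: float
    roc: RocResult
    permutation: PermutationResult | None
    n_repeats: int
    seed: int

    def to_dict(self) -> dict:
        d = {
            "comparison": self.comparison,
            "r2": self.r2,
            "q2": self.q2,
            "quality": self.label,
            "auroc": self.auroc,
            "n_cv_repeats": self.n_repeats,
            "seed": self.seed,
            "roc": {"fpr": self.roc.fpr.tolist(),
                    "tpr": self.roc.tpr.tolist()},
        }
        if self.permutation is not None:
            d["permutation"] = {
                "n_perm": self.permutation.n_perm,
                "r2_intercept": self.permutation.r2_intercept,
                "q2_intercept": self.permutation.q2_intercept,
                "valid": self.permutation.valid,
                "p_value": permutation_pvalue(self.permutation),
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def validate_comparison(
    B_norm: BinnedMatrix,
    cv: ClassVector,
    n_ortho: int = 1,
    n_repeats: int = 50,
    n_perm: int = 0,
    perm_repeats: int = 5,
    seed: int = 0,
) -> ValidationReport:
    """Cross-validate, optionally permutation-test, and compute ROC for
    one two-group OPLS-DA comparison on the normalized matrix."""
    rng = np.random.default_rng(seed)
    cvres = cross_validate(B_norm, cv, n_ortho, n_repeats,
                           seed=int(rng.integers(2**31)))
    Xs, _ = _pareto_fold(B_norm.data, B_norm.data)
    fit = _fit_core(Xs, cv.y, n_ortho)
    resid = cv.y - fit["y_hat"]
    r2 = 1.0 - float(resid @ resid) / float(cv.y @ cv.y)
    roc = roc_auroc(cvres.predictions, np.asarray(cv.labels),
                    positive_label=cv.positive_label)
    perm = None
    if n_perm:
        perm = permutation_test(B_norm, cv, n_perm, n_ortho, perm_repeats,
                                seed=int(rng.integers(2**31)))
    name = f"{cv.positive_label}_vs_{cv.negative_label}"
    return ValidationReport(comparison=name, r2=r2, q2=cvres.q2,
                            label=quality_label(cvres.q2), auroc=roc.auroc,
                            roc=roc, permutation=perm,
                            n_repeats=n_repeats, seed=seed)
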