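"""Two-class OPLS-DA by orthogonal-filtering NIPALS.

Orthogonal projections to latent structures split X-variation into one
predictive component (correlated with the class contrast) and ``n_ortho``
components orthogonal to it.  The algorithm per orthogonal round, on the
current (deflated) matrix:

    w  ∝ Xᵀy,  ‖w‖ = 1          predictive weight candidate
    t  = Xw                      predictive score candidate
    p  = Xᵀt / (tᵀt)             loading
    w⊥ ∝ p − (wᵀp)w, ‖w⊥‖ = 1    orthogonal weight
    t⊥ = Xw⊥;  p⊥ = Xᵀt⊥/(t⊥ᵀt⊥)
    X  ← X − t⊥p⊥ᵀ               deflation

after which the final predictive component is computed on the filtered
matrix.  With ``n_ortho = 0`` this reduces exactly to one-component
NIPALS PLS1.  Per-variable cov(t, X_j) and corr(t, X_j) against the
undeflated matrix drive S-plots and correlation-colored loadings;
covariances are reported on back-scaled (original-SD) data so they keep
spectral magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import BinnedMatrix

_TOL = 1e-12


@dataclass(frozen=True)
class ClassVector:
    """Two-level class labels with the ±1 mean-centered encoding used as
    the PLS response."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    positive_label: str
    negative_label: str
    y: np.ndarray  # encoded, mean-centered

    @classmethod
    def from_labels(cls, sample_ids, labels, positive_label: str | None = None):
        sample_ids = tuple(sample_ids)
        labels = tuple(str(l) for l in labels)
        levels = sorted(set(labels))
        if len(levels) != 2:
            raise ValueError(f"need exactly two class levels, got {levels}")
        if positive_label is None:
            positive_label = levels[1]
        if positive_label not in levels:
            raise ValueError(f"{positive_label!r} not among {levels}")
        negative_label = next(l for l in levels if l != positive_label)
        raw = np.where(np.array(labels) == positive_label, 1.0, -1.0)
        return cls(sample_ids, labels, positive_label, negative_label,
                   y=raw - raw.mean())


def encode_labels(labels) -> np.ndarray:
    """±1 mean-centered encoding of a two-level label vector."""
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError("need exactly two class levels")
    raw = np.where(np.asarray(labels) == levels[1], 1.0, -1.0)
    return raw - raw.mean()


def _fit_core(X: np.ndarray, y: np.ndarray, n_ortho: int) -> dict:
    """Numpy core of the fit; X is already centered/scaled, y centered."""
    Xf = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        w = Xf.T @ y
        nw = np.linalg.norm(w)
        if nw < _TOL:
            raise np.linalg.LinAlgError("degenerate X'y during deflation")
        w /= nw
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        no = np.linalg.norm(w_o)
        if no < _TOL:
            raise np.linalg.LinAlgError(
                "no orthogonal variation left to extract"
            )
        w_o /= no
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf -= np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    w = Xf.T @ y
    nw = np.linalg.norm(w)
    if nw < _TOL:
        raise np.linalg.LinAlgError("X carries no covariance with y")
    w /= nw
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    c = (y @ t) / (t @ t)  # response loading
    y_hat = t * c
    return {
        "w": w, "t": t, "p": p, "c": float(c), "y_hat": y_hat,
        "W_o": np.array(W_o).reshape(n_ortho, X.shape[1]),
        "T_o": np.array(T_o).reshape(n_ortho, X.shape[0]),
        "P_o": np.array(P_o).reshape(n_ortho, X.shape[1]),
    }


def _predict_core(Xnew: np.ndarray, fit: dict) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal filtering + predictive score for new rows."""
    Xf = Xnew.copy()
    t_ortho1 = None
    for k in range(fit["W_o"].shape[0]):
        t_o = Xf @ fit["W_o"][k]
        if k == 0:
            t_ortho1 = t_o
        Xf -= np.outer(t_o, fit["P_o"][k])
    t = Xf @ fit["w"]
    if t_ortho1 is None:
        t_ortho1 = np.zeros_like(t)
    return t, t_ortho1


@dataclass
class OplsModel:
    """A fitted two-class OPLS-DA model."""

    class_vector: ClassVector
    n_ortho: int
    weights: np.ndarray          # predictive weight w, unit norm
    scores: np.ndarray           # predictive scores t
    loadings: np.ndarray         # predictive loading p
    response_loading: float      # c, ŷ = t·c
    ortho_weights: np.ndarray    # n_ortho × p
    ortho_scores: np.ndarray     # n_ortho × n
    ortho_loadings: np.ndarray   # n_ortho × p
    fitted_values: np.ndarray
    covariance: np.ndarray       # cov(t, X_j) on back-scaled data
    correlation: np.ndarray      # corr(t, X_j)
    degenerate_bins: np.ndarray  # zero-variance flags
    r2y: float
    r2x: float
    bin_centers: np.ndarray
    training: BinnedMatrix       # carries scaling constants

    def to_dict(self) -> dict:
        """JSON-serializable summary (weights, loadings, constants)."""
        return {
            "positive_label": self.class_vector.positive_label,
            "negative_label": self.class_vector.negative_label,
            "n_ortho": self.n_ortho,
            "r2y": self.r2y,
            "r2x": self.r2x,
            "response_loading": self.response_loading,
            "bin_centers": self.bin_centers.tolist(),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "ortho_weights": self.ortho_weights.tolist(),
            "ortho_loadings": self.ortho_loadings.tolist(),
            "correlation": self.correlation.tolist(),
            "covariance": self.covariance.tolist(),
            "col_means": self.training.col_means.tolist(),
            "original_sd": self.training.original_sd.tolist(),
        }


def fit_oplsda(B: BinnedMatrix, cv: ClassVector, n_ortho: int = 1) -> OplsModel:
    """Fit a two-class OPLS-DA model on a centered/Pareto-scaled matrix."""
    if not B.scaled:
        raise ValueError("fit_oplsda expects a centered/scaled matrix")
    if tuple(B.sample_ids) != cv.sample_ids:
        raise ValueError("sample ids of X and y do not match")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    y = cv.y
    if np.allclose(y, 0):
        raise ValueError("response has zero variance")
    rank = np.linalg.matrix_rank(B.data)
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} must be below rank(X)={rank}")

    fit = _fit_core(B.data, y, n_ortho)
    t = fit["t"]
    n = B.data.shape[0]

    # cov/corr of t against the undeflated matrix, cov back-scaled
    denom = np.where(B.zero_variance, 1.0, np.sqrt(B.original_sd))
    Xback = B.data * denom  # restores original column SDs (still centered)
    cov = (t @ Xback) / (n - 1)
    sd_t = t.std(ddof=1)
    sd_cols = B.data.std(axis=0, ddof=1)
    degenerate = sd_cols == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = ((t - t.mean()) @ (B.data - B.data.mean(axis=0))) / (
            (n - 1) * sd_t * np.where(degenerate, 1.0, sd_cols)
        )
    corr = np.where(degenerate, 0.0, corr)

    ss_y = float(y @ y)
    r2y = 1.0 - float((y - fit["y_hat"]) @ (y - fit["y_hat"])) / ss_y
    X_model = np.outer(t, fit["p"])
    for k in range(n_ortho):
        X_model += np.outer(fit["T_o"][k], fit["P_o"][k])
    ss_x = float((B.data ** 2).sum())
    r2x = 1.0 - float(((B.data - X_model) ** 2).sum()) / ss_x

    return OplsModel(
        class_vector=cv, n_ortho=n_ortho,
        weights=fit["w"], scores=t, loadings=fit["p"],
        response_loading=fit["c"],
        ortho_weights=fit["W_o"], ortho_scores=fit["T_o"],
        ortho_loadings=fit["P_o"],
        fitted_values=fit["y_hat"],
        covariance=cov, correlation=corr, degenerate_bins=degenerate,
        r2y=r2y, r2x=r2x, bin_centers=B.centers.copy(), training=B,
    )


def predict(model: OplsModel, Xnew) -> pd.DataFrame:
    """Predict scores and class for new (already scaled) samples.

    ``Xnew`` may be a BinnedMatrix (its data must be scaled with the
    training constants) or a bare samples × bins array.  Returns a frame
    with predictive score t, first orthogonal score t_ortho1, continuous
    class score ŷ and the sign-assigned label.
    """
    if isinstance(Xnew, BinnedMatrix):
        ids = list(Xnew.sample_ids)
        A = Xnew.data
    else:
        A = np.atleast_2d(np.asarray(Xnew, dtype=float))
        ids = [f"sample{i}" for i in range(A.shape[0])]
    if A.shape[1] != model.weights.size:
        raise ValueError(
            f"column count {A.shape[1]} does not match model "
            f"({model.weights.size} bins)"
        )
    fit = {"w": model.weights, "W_o": model.ortho_weights,
           "P_o": model.ortho_loadings}
    t, t_o1 = _predict_core(A, fit)
    y_score = t * model.response_loading
    label = np.where(y_score >= 0, model.class_vector.positive_label,
                     model.class_vector.negative_label)
    return pd.DataFrame({"sample_id": ids, "t": t, "t_ortho1": t_o1,
                         "y_score": y_score, "predicted_label": label})


def splot(model: OplsModel) -> pd.DataFrame:
    """S-plot table: per retained bin, cov(t, X_j) on back-scaled data
    and corr(t, X_j); zero-variance bins flagged with corr reported 0."""
    return pd.DataFrame({
        "ppm": model.bin_centers,
        "covariance": model.covariance,
        "correlation": model.correlation,
        "degenerate": model.degenerate_bins,
    })


def trajectory(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    groups,
    period_order,
) -> pd.DataFrame:
    """Mean (t, t_ortho1) per group per period, in period order.

    ``scores`` is the frame from :func:`predict` (or training scores with
    columns sample_id/t/t_ortho1).  Group-period cells with no samples
    are omitted with a warning.
    """
    merged = scores.merge(metadata[["sample_id", "group", "period"]],
                          on="sample_id", validate="one_to_one")
    rows = []
    for g in groups:
        for p in period_order:
            cell = merged[(merged["group"] == g) & (merged["period"] == p)]
            if cell.empty:
                warnings.warn(f"no samples for group {g} period {p}; "
                              "cell omitted", stacklevel=2)
                continue
            rows.append({"group": g, "period": p,
                         "mean_t": cell["t"].mean(),
                         "mean_t_ortho1": cell["t_ortho1"].mean(),
                         "n": len(cell)})
    return pd.DataFrame(rows, columns=["group", "period", "mean_t",
                                       "mean_t_ortho1", "n"])


def training_scores(model: OplsModel) -> pd.DataFrame:
    """Training-set scores in the same layout predict() returns."""
    t_o1 = (model.ortho_scores[0] if model.n_ortho >= 1
            else np.zeros_like(model.scores))
    y_score = model.scores * model.response_loading
    label = np.where(y_score >= 0, model.class_vector.positive_label,
                     model.class_vector.negative_label)
    return pd.DataFrame({
        "sample_id": list(model.class_vector.sample_ids),
        "t": model.scores, "t_ortho1": t_o1,
        "y_score": y_score, "predicted_label": label,
    })
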