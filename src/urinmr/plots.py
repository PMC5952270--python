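"""Figure helpers: score and trajectory planes, correlation-colored
loadings, S-plots, permutation scatters, ROC curves, z-score heatmaps
and STOCSY traces.  All functions write to a path and return it."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_GROUP_COLORS = {"NC": "tab:green", "HLD": "tab:olive", "TAA": "tab:red",
                 "THC": "tab:orange", "BDL": "tab:purple", "BHD": "tab:blue"}


def _color(group: str):
    return _GROUP_COLORS.get(group, "tab:gray")


def plot_scores(scores: pd.DataFrame, metadata: pd.DataFrame, path,
                title: str = "") -> str:
    """Scatter of (t, t_ortho1) colored by group."""
    merged = scores.merge(metadata[["sample_id", "group"]], on="sample_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in merged.groupby("group"):
        ax.scatter(sub["t"], sub["t_ortho1"], s=18, label=g, color=_color(g))
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("t (predictive)")
    ax.set_ylabel("t_ortho 1")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def plot_trajectory(traj: pd.DataFrame, path, title: str = "") -> str:
    """Mean score trajectories ordered by collection period."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in traj.groupby("group", sort=False):
        ax.plot(sub["mean_t"], sub["mean_t_ortho1"], "-o", ms=4,
                label=g, color=_color(g))
        for _, row in sub.iterrows():
            ax.annotate(row["period"], (row["mean_t"], row["mean_t_ortho1"]),
                        fontsize=6)
    ax.set_xlabel("mean t")
    ax.set_ylabel("mean t_ortho 1")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def plot_loadings(splot_table: pd.DataFrame, path, title: str = "") -> str:
    """Back-scaled covariance trace colored by |corr(t, X_j)|."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    sc = ax.scatter(splot_table["ppm"], splot_table["covariance"], s=6,
                    c=np.abs(splot_table["correlation"]), cmap="viridis",
                    vmin=0, vmax=1)
    ax.invert_xaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("cov(t, X)")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="|corr(t, X)|")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def plot_splot(splot_table: pd.DataFrame, path, title: str = "") -> str:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(splot_table["covariance"], splot_table["correlation"], s=8)
    ax.set_xlabel("cov(t, X)")
    ax.set_ylabel("corr(t, X)")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def plot_permutation(perm, path, title: str = "") -> str:
    """R²/Q² vs label-correlation scatter with the OLS lines."""
    rec = perm.records
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(rec["correlation"], rec["r2"], s=10, label="R²",
               color="tab:green")
    ax.scatter(rec["correlation"], rec["q2"], s=10, label="Q²",
               color="tab:blue")
    x = np.array([0.0, 1.0])
    for col, intercept, actual, color in (
            ("r2", perm.r2_intercept, perm.r2_actual, "tab:green"),
            ("q2", perm.q2_intercept, perm.q2_actual, "tab:blue")):
        ax.plot(x, intercept + (actual - intercept) * x, color=color, lw=1)
    ax.set_xlabel("|corr(permuted y, y)|")
    ax.set_ylabel("R² / Q²")
    ax.set_title(title or
                 f"intercepts R²₀={perm.r2_intercept:.3f}, "
                 f"Q²₀={perm.q2_intercept:.3f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def plot_roc(roc, path, title: str = "") -> str:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, "-", lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title or f"AUROC = {roc.auroc:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def plot_zscore_heatmap(z: pd.DataFrame, path, stars: pd.DataFrame | None = None,
                        clip: float = 3.0, title: str = "") -> str:
    """Metabolite × period heatmap of clipped z-scores, optionally
    annotated with significance stars."""
    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * z.shape[1],
                                    1.0 + 0.28 * z.shape[0]))
    im = ax.imshow(z.to_numpy(), cmap="coolwarm", vmin=-clip, vmax=clip,
                   aspect="auto")
    ax.set_xticks(range(z.shape[1]), z.columns, fontsize=8)
    ax.set_yticks(range(z.shape[0]), z.index, fontsize=7)
    if stars is not None:
        stars = stars.reindex(index=z.index, columns=z.columns).fillna("")
        for i in range(z.shape[0]):
            for j in range(z.shape[1]):
                s = stars.iat[i, j]
                if s:
                    ax.text(j, i, s, ha="center", va="center", fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def plot_stocsy(result, path, title: str = "") -> str:
    """Covariance trace colored by r² with the driver marked."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    sc = ax.scatter(result.ppm, result.covariance, s=6,
                    c=result.correlation ** 2, cmap="jet", vmin=0, vmax=1)
    ax.axvline(result.driver_ppm, color="k", lw=0.6, ls="--")
    ax.invert_xaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("cov(driver, X)")
    ax.set_title(title or f"STOCSY driver {result.driver_ppm:.3f} ppm")
    fig.colorbar(sc, ax=ax, label="r²")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)
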