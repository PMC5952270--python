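"""Univariate metabolite profiling.

Metabolite levels are the normalized average integration of area: the
mean of the PQN-normalized bin values whose centers fall inside the
metabolite's ppm windows.  Group levels are expressed relative to a
reference group per collection period — relative level mean_t/mean_ref
and z-score (mean_t − mean_ref)/SD_ref — and significance is assessed
with a normality-gated two-group test: Shapiro–Wilk on each group, both
normal → Welch t-test, otherwise a rank test (unpaired rank-sum by
default; a paired signed-rank mode is available).  The declared
significance level is p < 0.05, uncorrected; an optional
Benjamini–Hochberg adjustment can be applied on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BinnedMatrix

ALPHA_SIGNIFICANT = 0.05

_WINDOW_RANGE = (0.5, 9.8)
_WINDOW_AVOID = (4.2, 5.9)


@dataclass(frozen=True)
class MetaboliteWindowTable:
    """Metabolite name → list of closed ppm intervals."""

    windows: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("window table is empty")
        for name, spans in self.windows.items():
            prev_hi = None
            for lo, hi in sorted(spans):
                if hi <= lo:
                    raise ValueError(f"{name}: malformed interval ({lo}, {hi})")
                if not (_WINDOW_RANGE[0] <= lo and hi <= _WINDOW_RANGE[1]):
                    raise ValueError(
                        f"{name}: interval ({lo}, {hi}) outside "
                        f"{_WINDOW_RANGE} ppm")
                if lo < _WINDOW_AVOID[1] and hi > _WINDOW_AVOID[0]:
                    raise ValueError(
                        f"{name}: interval ({lo}, {hi}) overlaps the "
                        f"excluded water/urea region {_WINDOW_AVOID}")
                if prev_hi is not None and lo < prev_hi:
                    raise ValueError(f"{name}: overlapping intervals")
                prev_hi = hi

    @classmethod
    def from_dict(cls, d: dict) -> "MetaboliteWindowTable":
        return cls({k: tuple((float(a), float(b)) for a, b in v)
                    for k, v in d.items()})

    @classmethod
    def read_tsv(cls, path) -> "MetaboliteWindowTable":
        df = pd.read_csv(path, sep="\t")
        need = {"metabolite", "ppm_low", "ppm_high"}
        if not need.issubset(df.columns):
            raise ValueError(f"window table needs columns {sorted(need)}")
        d: dict[str, list] = {}
        for _, row in df.iterrows():
            d.setdefault(row["metabolite"], []).append(
                (float(row["ppm_low"]), float(row["ppm_high"])))
        return cls.from_dict(d)

    def to_tsv(self, path) -> None:
        rows = [{"metabolite": m, "ppm_low": lo, "ppm_high": hi}
                for m, spans in self.windows.items() for lo, hi in spans]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def integrate_metabolites(B: BinnedMatrix,
                          W: MetaboliteWindowTable) -> pd.DataFrame:
    """Per-sample metabolite levels from a PQN-normalized unscaled matrix.

    Level = mean of bin values whose centers lie in the metabolite's
    windows; metabolites overlapping no retained bin are flagged absent
    (all-NaN column) with a warning.
    """
    if not B.normalized:
        raise ValueError("integrate on a PQN-normalized matrix")
    if B.scaled:
        raise ValueError("integrate before centering/scaling")
    cols = {}
    for name, spans in W.windows.items():
        mask = np.zeros(B.centers.size, dtype=bool)
        for lo, hi in spans:
            mask |= (B.centers >= lo) & (B.centers <= hi)
        if not mask.any():
            warnings.warn(f"metabolite {name!r} overlaps no retained bin; "
                          "flagged absent", stacklevel=2)
            cols[name] = np.full(B.n_samples, np.nan)
        else:
            cols[name] = B.data[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(B.sample_ids, name="sample_id"))


def test_metabolite(
    a: np.ndarray,
    b: np.ndarray,
    alpha_normality: float = 0.05,
    paired: bool = False,
) -> dict:
    """Normality-gated two-group test.

    Shapiro–Wilk on each group at ``alpha_normality``; both pass → Welch
    t-test, otherwise a rank test (Mann–Whitney, or Wilcoxon signed-rank
    when ``paired``).  All-tied values in both groups give p = 1 with a
    degenerate flag.  Returns dict(p_value, test, significant, degenerate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return {"p_value": 1.0, "test": "degenerate",
                "significant": False, "degenerate": True}

    def normal(x) -> bool:
        if np.ptp(x) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(x).pvalue > alpha_normality

    if normal(a) and normal(b):
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        test = "t-test"
    elif paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        diff = a - b
        if np.ptp(diff) == 0 and diff[0] == 0:
            return {"p_value": 1.0, "test": "degenerate",
                    "significant": False, "degenerate": True}
        p = float(stats.wilcoxon(a, b).pvalue)
        test = "Wilcoxon"
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        test = "Wilcoxon"
    return {"p_value": p, "test": test,
            "significant": bool(p < ALPHA_SIGNIFICANT), "degenerate": False}


#: the study's reference-group mapping: every treated/model group is
#: expressed relative to the normal controls, and the two formula-treated
#: model groups additionally relative to the formula-only healthy group.
REFERENCE_MAPPING = {
    "NC": ("HLD", "TAA", "BDL", "THC", "BHD"),
    "HLD": ("THC", "BHD"),
}


def relative_levels(
    levels: pd.DataFrame,
    metadata: pd.DataFrame,
    target_group: str,
    reference_group: str,
    periods=None,
    alpha_normality: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Per (metabolite, period) relative levels of target vs reference.

    Returns a tidy frame with relative level mean_t/mean_ref, z-score
    (mean_t − mean_ref)/SD_ref, the gated p-value and test used.
    Zero reference SD leaves z undefined (NaN) with a flag.
    """
    meta = metadata.set_index("sample_id")
    if periods is None:
        periods = list(dict.fromkeys(
            meta.loc[meta["group"].isin([target_group, reference_group]),
                     "period"]))
    rows = []
    for period in periods:
        for grp in (target_group, reference_group):
            if not ((meta["group"] == grp) & (meta["period"] == period)).any():
                raise ValueError(f"group {grp!r} missing in period {period!r}")
        t_ids = meta.index[(meta["group"] == target_group)
                           & (meta["period"] == period)]
        r_ids = meta.index[(meta["group"] == reference_group)
                           & (meta["period"] == period)]
        for metab in levels.columns:
            tv = levels.loc[t_ids, metab].to_numpy()
            rv = levels.loc[r_ids, metab].to_numpy()
            if np.isnan(tv).all() or np.isnan(rv).all():
                continue
            mean_t, mean_r = tv.mean(), rv.mean()
            sd_r = rv.std(ddof=1)
            z = (mean_t - mean_r) / sd_r if sd_r > 0 else np.nan
            res = test_metabolite(tv, rv, alpha_normality, paired)
            rows.append({
                "metabolite": metab, "period": period,
                "target_group": target_group,
                "reference_group": reference_group,
                "mean_target": mean_t, "mean_reference": mean_r,
                "relative_level": mean_t / mean_r if mean_r != 0 else np.nan,
                "z": z, "zero_reference_sd": sd_r == 0,
                "p_value": res["p_value"], "test": res["test"],
                "significant": res["significant"],
            })
    return pd.DataFrame(rows)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n /
                                        np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def zscore_table(rel: pd.DataFrame, clip: float = 3.0,
                 period_order=None) -> pd.DataFrame:
    """Metabolite × period matrix of z-scores clipped to ±clip for color
    mapping (values used for the heatmap; the tidy table keeps the raw z)."""
    if rel.empty:
        raise ValueError("relative-level table is empty")
    piv = rel.pivot_table(index="metabolite", columns="period", values="z")
    if period_order is not None:
        piv = piv.reindex(columns=[p for p in period_order
                                   if p in piv.columns])
    return piv.clip(-clip, clip)


def significance_stars(rel: pd.DataFrame, period_order=None) -> pd.DataFrame:
    """Matching metabolite × period matrix of star annotations
    ('' / '*' p<0.05 / '**' p<0.01)."""
    stars = rel.assign(stars=np.select(
        [rel["p_value"] < 0.01, rel["p_value"] < ALPHA_SIGNIFICANT],
        ["**", "*"], default=""))
    piv = stars.pivot_table(index="metabolite", columns="period",
                            values="stars", aggfunc="first")
    if period_order is not None:
        piv = piv.reindex(columns=[p for p in period_order
                                   if p in piv.columns])
    return piv.fillna("")
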