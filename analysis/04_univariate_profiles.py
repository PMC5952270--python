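#!/usr/bin/env python
"""Univariate metabolite profiling with z-score tables.

Integrates metabolite windows on the PQN-normalized matrix, expresses
every treated group relative to the normal controls (and the two
formula-treated model groups additionally relative to HLD), computes
per-period z-scores with normality-gated significance, and writes the
color-coded z-score tables and heatmaps under results/univariate/.
"""

from pathlib import Path

import pandas as pd

import urinmr as u
from urinmr import plots

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "univariate"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    X = u.read_spectral_matrix(COHORT / "spectra.tsv")
    meta = u.read_metadata(COHORT / "metadata.tsv")
    windows = u.read_windows(COHORT / "windows.tsv")
    normalized, _ = u.standard_preprocess(X)
    levels = u.integrate_metabolites(normalized, windows)
    levels.to_csv(OUT / "metabolite_levels.tsv", sep="\t")

    for ref, targets in u.REFERENCE_MAPPING.items():
        for target in targets:
            rel = u.relative_levels(levels, meta, target, ref)
            rel.to_csv(OUT / f"relative_{target}_vs_{ref}.tsv", sep="\t",
                       index=False)
            z = u.zscore_table(rel, clip=3.0, period_order=u.PERIODS)
            stars = u.significance_stars(rel, u.PERIODS)
            z.to_csv(OUT / f"zscores_{target}_vs_{ref}.tsv", sep="\t")
            plots.plot_zscore_heatmap(z, OUT / f"zscores_{target}_vs_{ref}.png",
                                      stars, 3.0, f"{target} vs {ref}")
            n_sig = int(rel["significant"].sum())
            top = (rel.reindex(rel["z"].abs().sort_values(ascending=False)
                               .index).drop_duplicates("metabolite").head(3))
            summary = ", ".join(f"{r.metabolite} ({r.period}, z={r.z:+.1f})"
                                for r in top.itertuples())
            print(f"{target} vs {ref}: {n_sig}/{len(rel)} cells significant; "
                  f"largest shifts: {summary}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
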