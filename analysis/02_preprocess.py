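#!/usr/bin/env python
"""Preprocess the simulated cohort.

Runs the fixed chain — alignment, water/urea exclusion (4.2–5.9 ppm),
0.04-ppm sum binning over 0.5–9.8 ppm, probabilistic quotient
normalization, mean-centering with Pareto scaling — and reports how well
PQN recovered the planted dilution factors (their correlation is the
pipeline's dilution-removal diagnostic).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import urinmr as u

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "preprocess"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    X = u.read_spectral_matrix(COHORT / "spectra.tsv")
    meta = u.read_metadata(COHORT / "metadata.tsv")
    u.check_consistency(X, meta)

    normalized, scaled = u.standard_preprocess(X)
    df = pd.DataFrame(normalized.data, index=normalized.sample_ids,
                      columns=[f"{c:.3f}" for c in normalized.centers])
    df.rename_axis("sample_id").to_csv(OUT / "binned_normalized.tsv",
                                       sep="\t")

    planted = meta.set_index("sample_id").loc[normalized.sample_ids,
                                              "dilution"].to_numpy()
    r = np.corrcoef(normalized.dilution_estimates, planted)[0, 1]

    print(f"retained {normalized.centers.size} bins of width 0.04 ppm "
          f"(water/urea excluded)")
    print(f"PQN dilution estimates vs planted factors: r = {r:.4f}")
    print(f"scaled matrix: {scaled.data.shape[0]} samples x "
          f"{scaled.data.shape[1]} bins, "
          f"{int(scaled.zero_variance.sum())} zero-variance bins")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
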