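#!/usr/bin/env python
"""Fit and validate the OPLS-DA contrasts.

Runs the five standard two-group contrasts (HLD vs NC, TAA vs NC,
THC vs TAA, BDL vs NC, BHD vs BDL) through the full pipeline: OPLS-DA
with one orthogonal component, repeated stratified 2-fold
cross-validation (50 repeats), a 200-permutation test with R²/Q²
intercepts, and ROC from the averaged out-of-fold predictions.  Writes
scores, S-plots, figures and validation JSONs under results/analysis/.
"""

from pathlib import Path

import urinmr as u

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    cfg = u.AnalysisConfig(
        spectra_path=str(COHORT / "spectra.tsv"),
        metadata_path=str(COHORT / "metadata.tsv"),
        windows_path=None,          # univariate stage runs in script 04
        output_dir=str(OUT),
        comparisons=u.DEFAULT_COMPARISONS,
        seed=11, n_ortho=1, n_repeats=50, n_perm=200,
    )
    report = u.run_pipeline(cfg)

    print(f"{'comparison':<12} {'R2':>6} {'Q2':>7} {'quality':>8} "
          f"{'AUROC':>6} {'Q2 icpt':>8} {'perm p':>7}")
    for name, rep in report.validation.items():
        if "error" in rep:
            print(f"{name:<12} failed: {rep['error']}")
            continue
        perm = rep["permutation"]
        print(f"{name:<12} {rep['r2']:6.3f} {rep['q2']:7.3f} "
              f"{rep['quality']:>8} {rep['auroc']:6.3f} "
              f"{perm['q2_intercept']:8.3f} {perm['p_value']:7.4f}")
    print(f"{len(report.manifest)} artifacts written to {OUT}")


if __name__ == "__main__":
    main()
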