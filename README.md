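# urinmr

Urinary ¹H NMR metabolomics in Python: synthetic cohort simulation,
spectral preprocessing, OPLS-DA modelling with rigorous validation,
univariate z-score profiling and STOCSY.

## The problem

Urinary ¹H NMR profiling tracks the metabolic state of an organism over
time from nothing but serial urine collections.  A typical rodent
design — here six treatment arms (normal controls NC, a herbal-formula
arm HLD, a thioacetamide hepatotoxin model TAA and its treated
counterpart THC, a bile-duct-ligation model BDL and its treated
counterpart BHD), twelve animals per arm, eight collection periods
T1–T8 spanning 0–144 h — produces hundreds of spectra whose analysis
has to survive several nuisance processes: several-fold dilution
differences between voids, pH-driven chemical-shift drift, baseline and
thermal noise, and the weakness of any single biomarker.

`urinmr` implements the standard analysis chain for such cohorts as a
tested library:

1. **Preprocessing** — segment-wise spectral alignment, removal of the
   water/urea region (4.2–5.9 ppm), 0.04-ppm sum binning over
   0.5–9.8 ppm, probabilistic quotient normalization (PQN), and
   mean-centering with Pareto scaling.
2. **OPLS-DA** — two-class orthogonal projections to latent structures
   by orthogonal-filtering NIPALS, with scores, per-period trajectories,
   S-plots and correlation-colored loadings.
3. **Validation** — repeated stratified 2-fold cross-validation
   (Q² = 1 − PRESS/SS; Q² > 0.40 good, > 0.70 robust), label-permutation
   testing with R²/Q² regression intercepts, and ROC/AUROC computed from
   averaged out-of-fold predictions by pair counting.
4. **Univariate profiling** — metabolite-window integration, levels
   relative to a reference group (treated arms vs NC; THC/BHD
   additionally vs HLD), z-scores, and normality-gated two-group testing
   (Shapiro–Wilk → Welch t-test or rank test, p < 0.05).
5. **STOCSY** — statistical total correlation spectroscopy to connect
   multiplets that belong to the same molecule.

Because no public spectra accompany this design, the package ships a
first-class **synthetic cohort generator**: Lorentzian multiplets of
~30 urinary metabolites with planted group × period fold-changes,
log-normal dilution, per-metabolite shift jitter, baseline and noise —
so every stage can be tested against exact ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study-shaped
analysis on a simulated cohort (6 groups × 6 subjects × 8 periods,
desk scale):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_model_validation.py
python analysis/04_univariate_profiles.py
python analysis/05_stocsy.py
```

`02_preprocess.py` reports how much of the planted dilution PQN
recovered, and `03_model_validation.py` prints the validation table:

```
retained 189 bins of width 0.04 ppm (water/urea excluded)
PQN dilution estimates vs planted factors: r = 0.9669

comparison       R2      Q2  quality  AUROC  Q2 icpt  perm p
HLD_vs_NC     0.581   0.411     good  0.920   -0.434  0.0050
TAA_vs_NC     0.753   0.680     good  0.988   -0.316  0.0050
THC_vs_TAA    0.489   0.314     poor  0.853   -0.305  0.0050
BDL_vs_NC     0.751   0.604     good  0.991   -0.319  0.0050
BHD_vs_BDL    0.471   0.169     poor  0.805   -0.357  0.0050
```

Reading: the two disease models separate well from controls (Q² 0.60 and
0.68, "good"; AUROC ≈ 0.99), while the treated-vs-model contrasts are
weaker (Q² 0.17–0.31, "poor") — the planted treatment effect is an
attenuation, not a reversal, of the model signature.  Negative Q²
intercepts and permutation p = 1/201 say none of the models is an
overfitting artifact.  `04_univariate_profiles.py` then localizes the
signal (e.g. `TAA vs NC: glutamate (T3, z=+13.2), taurine (T6, z=+9.3),
hippurate (T3, z=-8.2)`), and `05_stocsy.py` shows a citrate driver at
2.54 ppm connecting exactly the 2.52–2.68 ppm doublet pair (|r| ≥ 0.8).

The same machinery is available programmatically:

```python
import urinmr as u

library = u.build_default_library(seed=1)
design = u.CohortDesign(groups=("NC", "TAA"), n_subjects=12,
                        periods=("T1", "T2"))
effects = [u.EffectSpec("citrate", ("TAA",), {"T1": 0.5, "T2": 0.5})]
X, meta, truth = u.generate_cohort(design, library, effects,
                                   u.NoiseModel(seed=3))
normalized, scaled = u.standard_preprocess(X)
cv = u.ClassVector.from_labels(scaled.sample_ids,
                               meta["group"], positive_label="TAA")
model = u.fit_oplsda(scaled, cv, n_ortho=1)
report = u.validate_comparison(normalized, cv, n_perm=200)
print(report.q2, report.label, report.auroc)
```

Full runs (all contrasts, univariate tables, STOCSY, figures, manifest)
are driven by `u.AnalysisConfig` + `u.run_pipeline`, configurable from a
YAML file; rerunning with the same seed reproduces every numeric output
bit for bit.

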