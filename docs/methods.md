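# Methods

## Synthetic cohorts

The generator emulates 1D ¹H NMR spectra of rodent urine on a uniform
ppm grid (default step 0.001 ppm over 0.5–9.8 ppm, ≥10 points per
typical 0.01-ppm linewidth).  Each sample is

    dilution × Σ_m  fold(m, group, period) · biovar · c_m · L_m(ppm + δ_m)
    + baseline + ε

where `L_m` is the sum of the metabolite's Lorentzian multiplets (the
standard solution-state line shape), `c_m` its base concentration in
arbitrary units, and the nuisance terms are:

| parameter | default | meaning |
|---|---|---|
| `dilution_log_sd` | 0.3 | log-normal per-sample dilution factor; urine concentration varies multiplicatively and this gives PQN real work |
| `concentration_rsd` | 0.15 | log-normal per-sample, per-metabolite biological variation between animals |
| `shift_jitter_sd` | 0.002 ppm | per-sample, per-metabolite displacement of whole multiplets (pH-driven shifts move whole multiplets, not single lines) |
| `additive_sd` | 0.02 | thermal noise per grid point |
| `baseline_amplitude` | 0.05 | three low-frequency random cosines |

The default library holds 33 metabolites at standard urinary ppm
positions (creatinine, citrate, hippurate, 2-oxoglutarate, TMAO,
taurine, amino acids, aromatic excretion products, urea, ...), with a
mild seed-controlled jitter on base concentrations.  Planted effects
are multiplicative fold-changes per (metabolite, group, period);
`default_effects()` encodes a hepatotoxin/cholestasis-like pattern
(model groups strongly shifted with a mid-study peak, treated groups
attenuated, the formula-only healthy arm mildly shifted).

`concentration_rsd` matters: with zero between-animal variance PQN
removes the only multiplicative spread and every group comparison
degenerates (zero within-group variance, infinite z).  No published
inter-animal variance estimates back the 0.15 default; it was chosen
once as a plausible urinary relative SD and is a free knob.

What the generator does **not** emulate: J-coupling physics, water
suppression artifacts, peak-shape distortions, correlated metabolite
panels (each metabolite varies independently unless an effect is
planted), or realistic baseline chemistry.  Passing tests therefore
demonstrate that the statistics behave correctly under a faithful noise
model, not that the pipeline's numbers would reproduce any specific
animal study.

Determinism: one `NoiseModel.seed` drives a single `default_rng`; the
same seed yields a bit-identical cohort.

## Preprocessing

Fixed stage order, recorded in provenance flags and enforced
(running a stage out of order raises):

1. **Alignment** — segment-wise (default 0.2 ppm) integer-lag
   cross-correlation against the median spectrum, lags bounded by
   0.02 ppm.  Scores are computed on the lag overlap only (edge-padded
   points would bias monotone tail segments toward spurious shifts);
   ties prefer the smaller |lag|; vacated points are filled by edge
   extension.
2. **Exclusion** — closed ppm intervals removed by variable center;
   default 4.2–5.9 ppm (water and urea).  Closed endpoints err on the
   side of removing residual water shoulders.
3. **Binning** — half-open 0.04-ppm buckets tiling 0.5–9.8 ppm, value =
   **sum** of point intensities (conserves integrals, matching the
   integration-of-area reading used downstream); the trailing partial
   bin, empty bins, and bins whose centers fall in an excluded region
   are dropped.
4. **PQN** — integral normalization, then division by the median
   quotient against the element-wise median spectrum (configurable to a
   control-group median or an explicit reference).  The product
   total × median-quotient per sample estimates its dilution factor and
   is retained as a diagnostic.  PQN is idempotent against a fixed
   reference.
5. **Centering + Pareto scaling** — each bin centered and divided by
   √SD; zero-variance bins are centered, left unscaled and flagged.
   Original SDs and means are stored so loadings can be back-scaled and
   new samples projected with training constants.

## OPLS-DA

Two-class discriminant analysis with the ±1 mean-centered class
encoding.  Per orthogonal round on the current matrix: w ∝ Xᵀy
(unit norm), t = Xw, p = Xᵀt/(tᵀt), w⊥ ∝ p − (wᵀp)w (unit norm),
t⊥ = Xw⊥, p⊥ = Xᵀt⊥/(t⊥ᵀt⊥), deflate X ← X − t⊥p⊥ᵀ; the final
predictive component is computed on the filtered matrix.  With zero
orthogonal components this is exactly one-component NIPALS PLS1.
Exact consequences asserted in tests: t⊥ᵀy = 0 and tᵀt⊥ = 0.

Defaults: one orthogonal component (`n_ortho=1`).  S-plot and loading
coloring use corr(t, Xⱼ) (scale-free) and cov(t, Xⱼ) computed on
back-scaled (original-SD) columns so the covariance trace keeps
spectral magnitude; zero-variance bins report corr 0 with a degenerate
flag.  Prediction removes the orthogonal variation from new rows with
the stored weights/loadings before projecting.  Multi-group score
planes are produced by fitting the two contrast groups and passively
projecting the remaining samples (no multi-class algorithm is implied).

## Validation

* **Cross-validation** — repeated (default 50) stratified 2-fold.
  Centering/Pareto scaling and the response mean are refit inside each
  training fold and applied to the held-out fold, so no scaling
  information leaks; the natural input is therefore the normalized,
  unscaled matrix (a scaled one is accepted and simply rescaled per
  fold).  Q² = 1 − PRESS/SS(y); per-sample out-of-fold predictions are
  averaged over repeats.  Quality labels: Q² > 0.70 robust,
  Q² > 0.40 good, else poor.
* **Permutation test** — labels shuffled (protocol default n = 2000;
  the test suite and analysis scripts run 200 at desk scale), model
  refit with the same `n_ortho` for comparability, R²/Q² recorded with
  the |Pearson correlation| to the true labels; OLS lines through all
  points plus the unpermuted model at correlation 1 give the intercepts
  at 0.  Verdict "valid" requires Q²-intercept < 0.05 and every
  permuted Q² below the actual Q².  The empirical p-value is
  (1 + #{Q²perm ≥ Q²}) / (n_perm + 1).
* **ROC/AUROC** — pair counting via the rank formula (ties ½), which
  equals the trapezoidal area under the threshold-swept curve (asserted
  to 1e-10).  AUROC is computed from averaged **out-of-fold**
  predictions, not training scores: training scores of a
  high-dimensional fit are optimistically separable and would pin AUROC
  at 1.

## Univariate profiling

Levels are the normalized average integration of area: the mean of
PQN-normalized bin values whose centers fall in the metabolite's
windows (windows supplied as a TSV of closed intervals; intervals must
avoid the excluded water/urea region).  Group levels per collection
period are expressed against a reference group — relative level
mean_t/mean_ref and z = (mean_t − mean_ref)/SD_ref — under the study's
mapping: {HLD, TAA, BDL, THC, BHD} vs NC and {THC, BHD} vs HLD.

Significance is normality-gated: Shapiro–Wilk per group at α = 0.05;
both normal → Welch t-test (no variance-homogeneity assumption),
otherwise a rank test.  Because the compared groups contain different
animals, the default rank test is the unpaired rank-sum; a paired
signed-rank mode exists but is not the default.  Significance is
p < 0.05 uncorrected (an optional Benjamini–Hochberg adjustment is
provided).  Significance is assessed per period by default; pooling
periods is the powered choice when an effect is constant in time.
z-score tables are clipped to ±3 for color mapping only; exported
values keep the raw z.

Degenerate inputs: all-tied groups give p = 1 with a flag; zero
reference SD leaves z undefined with a flag; windows overlapping no
retained bin are flagged absent.

## STOCSY

Pearson correlation and covariance of the variable nearest the
requested driver ppm against all variables, on normalized unscaled
data (correlation is scale-free; covariance keeps spectral shape).
Default connectivity threshold |r| ≥ 0.8 — a declared default, strong
enough that independently varying metabolites essentially never
connect at n ≈ 48.  Zero-variance drivers are rejected.

## Orchestration and reproducibility

`AnalysisConfig` (YAML; JSON accepted) drives `run_pipeline`:
preprocess once, per-comparison OPLS-DA + validation with figures,
univariate tables under the reference mapping, optional STOCSY
drivers, a file manifest (every listed artifact is checked to exist)
and a fingerprinted run report.  All randomness is spawned from the
single global seed, so identical configs reproduce all numeric outputs
bit for bit.  ppm axes are stored ascending internally and written
descending (the NMR display convention); readers accept either.

## Problem sizes

The analysis scripts and test suite run a scaled design — 6 groups ×
6 subjects × 8 periods, grid steps 0.002–0.004 ppm, 200 permutations,
50 CV repeats — chosen as comfortable desk-scale sizes; all counts are
configurable, and the generator defaults (12-subject arms are simply
`n_subjects=12`) scale to the full design unchanged.

## Known limitations

* Two-class OPLS-DA only; no multi-class variant, O2-PLS or kernels.
* No phasing/baseline correction of real FIDs and no vendor raw-format
  ingestion; input is a tabular spectral matrix.
* Alignment uses integer-lag segment shifts; sub-grid shifts are not
  interpolated.
* The synthetic generator's variance parameters are plausible, not
  calibrated to any real study; absolute quantification (mM) is out of
  scope.
* Overlapping resonances (e.g. taurine/TMAO near 3.26 ppm) share
  integration windows by construction; separating them is an
  assignment problem outside the statistics implemented here.
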