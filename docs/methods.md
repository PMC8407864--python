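# Methods

## Scope

`ewasmeta` reproduces the statistical workflow of a coordinated
multi-cohort EWAS of parental BMI against offspring blood methylation:
cohort-level analysis under a shared plan, central pooling of summary
statistics, and the robustness analyses that surround the pooled result.
It also ships a generative model of such a consortium so that calibration
and recovery can be demonstrated end to end with known truth.

## Synthetic consortium generator

Per cohort, samples are drawn independently with:

- **Parental BMIs** from a bivariate Gaussian with per-cohort means/SDs
  (defaults follow the 13 birth-cohort study conditions: paternal means
  24.9–28.0 kg/m², SD 3.0–5.3; maternal 22.6–26.7, SD 3.3–6.1; pooled
  n 4894) and latent correlation 0.2, truncated to 15–60 kg/m². The
  Spearman correlation of the truncated Gaussian is ≈0.19 at ρ=0.2.
- **Covariates**: parental ages (Gaussian, clipped), maternal/paternal
  smoking (Bernoulli 0.15/0.25), parity (0.45), paternal SEP (0.30),
  child sex (48% female, the consortium's observed share).
- **Cell proportions** from a Dirichlet centred on typical cord-blood
  fractions (granulocytes 0.45 … nRBC 0.10; concentration 60). The
  reference panel draws bimodal baseline probe means (Beta mixtures) and
  gives a "discriminating" subset of probes (default 20%, ≥ one per cell
  type) independent per-cell-type means, which makes the panel full rank
  and is what deconvolution uses — mirroring the DMR panels of
  reference-based methods. Probes carrying injected effects are excluded
  from that panel, as real candidate CpGs are not deconvolution markers.

Methylation is built on the logistic scale and squashed to (0,1):

    s_ij = logit(m_ij) + (L F')_ij + sum_e a_e 1[sex] z_e(j) + eps_ij
    beta_ij = expit(s_ij)

where `m = R W'` is the linear cell mixture, L are sparse batch loadings
(20 factors by default, each hitting 30% of probes with loading SD 0.15,
factors standard normal), z_e is the within-cohort standardized BMI of the
injected effect's parent (masked by offspring sex when restricted), and
eps is Gaussian noise whose beta-scale SD (default 0.015, a typical
array-level residual) is converted to the logit scale per probe by
dividing by m0(1−m0) with m0 clipped to [0.05, 0.95] — the clip prevents
extreme-baseline probes from acquiring unrealistically heavy tails that a
Tukey fence would then truncate asymmetrically.

**Effect calibration.** `EffectSpec.effect_size` is a *linear-scale* slope
(percentage points per SD). Because the squash attenuates slopes in
proportion to the probe's total non-exposure variation, the logit
amplitude `a` is solved from the exact Gaussian-exposure relation (Stein's
lemma): `a · E[expit'(l0 + sqrt(sigma² + a²) U)] = delta`, with sigma² the
probe's mixture+batch+noise logit variance and the expectation computed by
Gauss–Hermite quadrature. Amplitudes above 1 logit unit per SD are
rejected: a linear slope that large at an extreme baseline only arises
through saturation, i.e. a grossly non-linear dose–response; callers
should inject at intermediate-baseline probes (`select_effect_probes`).

Missingness is completely at random; sub-seeding uses
`SeedSequence((master_seed, cohort_index))`, so each cohort is
independently reproducible and the whole consortium is bit-reproducible
for a fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: probe chemistry and normalization
artefacts, SNP-driven methylation structure, spatial/genomic correlation
between CpGs, informative missingness, cohort-specific covariate
distributions beyond BMI, and genetic relatedness. Null calibration and
recovery results transfer to real arrays only to the extent that the
linear-model assumptions hold there.

## Cohort-level EWAS

- Exposure Z-scores are internal to the analysis sample (n−1 SD); zero
  variance is an error.
- Tukey outliers: per probe, values outside [Q1 − 3·IQR, Q3 + 3·IQR]
  (linear-interpolation quartiles over non-missing values) become missing;
  probes with <4 values are skipped with a warning.
- Cell deconvolution: nonnegative least squares of each sample's betas on
  the reference's discriminating panel, renormalized to sum 1 (a `≤1`
  variant is a switch). Rank-deficient panels are an error.
- Surrogate variables: probes are mean-imputed (estimation only),
  residualized on the covariates-plus-cells design, and the top-k right
  singular vectors of the residual matrix are the SVs (k = 20 by default,
  the consortium's choice; computed via the sample-space Gram matrix,
  signs fixed by the first nonzero loading). The exposure is left out of
  the residualizing design. SVs estimated this way can in principle absorb
  a little exposure-driven signal; at array-like probe counts (≥10⁴ used
  throughout the validation) the absorption is negligible, while the SVs
  do capture batch variation that chance-correlates with the exposure
  in-sample — which is exactly what the adjustment is for. An
  exposure-"protected" variant was evaluated and rejected: it leaves those
  chance correlations unadjusted and measurably biases estimates.
- Per-CpG model: OLS of beta on exposure Z (+ other parent's Z under
  mutual adjustment) + the fixed covariates + estimated cell proportions
  (one column dropped against the sum constraint) + SVs, complete-case per
  probe; estimates ×100 (percentage points); p from the t distribution
  with residual df (small sex strata exist). Sex-stratified models require
  ≥30 samples per stratum (configurable), mirroring the consortium's
  exclusion of a 27-sample stratum.

## Meta-analysis and downstream statistics

Fixed-effects inverse-variance pooling with a normal reference for the
pooled z (the METAL convention); Cochran's Q on k−1 df and
I² = max(0,(Q−df)/Q)·100, zero for k=1; METAL-style direction strings with
`?` for missing cohorts. Probes present in a single cohort are retained
with k=1. BH-FDR is computed within each model/stratum analysis. The
genomic inflation factor uses the median 1-df chi-square. Leave-one-out
applies the three pre-specified criteria with the 20% change-in-estimate
read two-sided (an increase also fails). Meta-regression on cohort mean
age is inverse-variance weighted least squares with a normal reference.
Cell-proportion associations are pooled per cell type by the same fixed
effects engine (a random-effects switch is out of scope).

Pooled and cohort p-values are floored at the smallest positive normal
float so FDR and lambda preconditions (p > 0) hold when |z| is extreme.

## Probe harmonization and candidate sets

Probes are retained iff on both arrays, not control, not on a SNP, not
cross-hybridizing, autosomal; exclusion counts are reported in that
application order without double counting. Gene intervals use 1-based
closed coordinates (GeneCards convention); strand is ignored; a probe may
map to several overlapping genes; BED export converts to 0-based
half-open. The Chen cross-hybridizing list and vendor manifests enter
as boolean flags that users may populate out-of-band.

KS enrichment tests candidate p-values against Uniform(0,1), two-sided by
default with a one-sided `inflation` alternative (ECDF above the
diagonal); scipy's exact/asymptotic switching is used. Direction
concordance counts ties (beta = 0) as discordant and applies BH within
the candidate set at m = set size.

## Numerical and design choices

- Quantile convention everywhere: linear interpolation (numpy default) —
  fixed because Tukey fences must be reproducible across cohorts.
- Deconvolution renormalization divides by the NNLS solution sum; an
  all-zero solution falls back to uniform proportions.
- The percentage-difference denominator in model comparisons is the
  *unadjusted* model (the adjusted model is the intervention assessed);
  zero-baseline probes are excluded and counted.
- The attenuation criterion is |Δβ|/|β_full| > 0.20 in either direction.
- FDR is re-ranked within sensitivity subset analyses.
- Pipeline runs write every artefact as TSV with fixed float formatting
  plus a manifest (config hash, seed); reruns are byte-identical.
- Validation problem sizes: null calibration uses 5 cohorts × 500 samples
  × 10,000 probes; effect recovery 10,000 probes with 20 injected effects
  of 0.2–3 pp/SD; leave-one-out 5 × 300 × 500 probes; these sizes keep
  batch-absorption and boundary effects in the regime of real arrays
  while remaining desk-scale.

## Known limitations

- Plain OLS, not moderated (empirical-Bayes) variances: cohort SEs are
  slightly noisier than a limma-style analysis at small n.
- The BH step guarantees only expectation-level control: under a global
  null a run still produces ≥1 discovery with probability ≈ alpha, so
  occasional single false positives in a null consortium are expected
  behaviour, not miscalibration (lambda stays at 1 in those runs).
- The simplified SV estimator is a fixed-k residual SVD, not iterative
  surrogate variable analysis; with few probes (≲10³) and strong effects
  it can absorb part of an injected signal.
- Meta-regression on age is only meaningful for childhood-timepoint
  consortia; birth cohorts have no age spread and the stage is skipped.
- Cohort phenotype missingness is handled complete-case; no imputation.
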