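# Methods

This note documents the models implemented in `cnvclim`, the choices made
where the design was genuinely open, the synthetic-data generator the
tests rely on, and the limits of what those tests demonstrate.

## CNV quality control and CNVR construction

Calls are 1-based inclusive intervals with a copy-number class in
{0, 1, 3, 4} (homozygous deletion, hemizygous deletion, duplication,
biallelic triplication). Sample-level gates: LRR standard deviation
< 0.3, BAF drift < 0.01, waviness factor < 0.05 (all strict), and call
count ≤ 100 (only counts *above* 100 indicate poor DNA quality). Call
gates: more than 3 supporting SNPs (read literally as ≥ 4, configurable,
since array pipelines sometimes use ≥ 3) and length ≥ 1 kb.

CNVRs are the interval union of filtered calls per chromosome;
book-ended calls (gap 0 on the 1-based scale, i.e. `next.start ==
current.end + 1`) merge, mirroring the default semantics of the standard
interval-merging tool on the 0-based half-open transform. A region is
*loss* / *gain* when all supporting calls are deletion- /
duplication-class, *mixed* otherwise. Carrier frequency is reported both
as distinct carrier count and as call count, because the two differ
whenever a sample contributes several calls to one region.

Percentages in summaries are rounded half-up to 2 decimals. Call-set
concordance is direction-aware (deletion vs duplication classes),
computed per sample with a ≥ 1 bp overlap rule; the rule is configurable
because no canonical definition exists.

## Solar radiation from sunshine fraction

Daily extraterrestrial irradiation uses the standard solar-geometry
formulas (declination, sunset hour angle, Sun–Earth distance correction)
with the solar constant at 1361 W/m². The annual mean of H̄₀ is the mean
over 12 representative days (Klein's set: 17, 47, 75, 105, 135, 162,
198, 228, 258, 288, 318, 344); it agrees with the 365-day daily mean to
within 2 % for |Φ| ≤ 66°. The year is fixed at 365 days; the arccos
argument is clamped to [−1, 1] so polar night yields ω_s = 0 (H̄₀ = 0)
and polar day ω_s = π.

The clearness index is
K̄ = K̄_clear · (β + (1 − β) · S^γ), K̄_clear = 0.7191, β = 0.1930,
γ = 0.7283, with S the *annual* sunshine fraction. The multiplicative
form was chosen over an exponent reading (K̄_clear^β + (1 − β) S^γ)
because it yields a physically sensible overcast limit
(K̄(0) = 0.1388 rather than ≈ 0.94); both coincide at S = 1, where
K̄ = K̄_clear. The exponent variant stays available through
`SolarConstants(kbar_form="exponent")`. Computation runs in J/m²/day and
reports MJ/m²/day.

Note the annual H̄₀ is *not* exactly hemisphere-symmetric: perihelion
falls in southern summer, so southern latitudes receive up to ~3 % more
annual extraterrestrial irradiation through the distance factor.

## Genotype–environment association

CNV states are binary (present/absent per sample). Climate values are
site-level; every sample takes its site's value (a per-population mean
option would change nothing in the synthetic worlds, where sites are the
climate unit).

**Univariate logistic scan.** One logistic regression per
(locus, variable) pair, Newton/IRLS maximum likelihood, Wald statistic
(β/se)² against χ²(1), Bonferroni correction over the *full* model count
(loci × variables, including skipped models), selection at adjusted
p < 0.01 plus a configurable Wald-score floor (default 34, an operating
point rather than a derivation). Loci with fewer than 5 carriers or
non-carriers are skipped as numerically unstable. Quasi-complete
separation is detected (diverging estimates or optimizer failure) and
flagged instead of reported. Optional covariates carry population
structure.

**Latent factor mixed model.** Per locus the model is
g = μ + Xb + Uγ + ε with K latent factors U. The least-squares scan:
center G, standardize X, estimate U, refit each locus on [1, X, U],
convert the environment coefficients to z-scores, divide z² by the
genomic inflation factor λ = median(z²)/median(χ²₁) (χ²₁ median
0.454936…), and BH-adjust the calibrated p-values. Selection uses the
literal double rule |z| ≥ 10 and adjusted p < 10⁻⁶ (redundant at large
n; both applied). K = 0 reduces exactly to ordinary per-locus
regression.

Two factor estimators are exposed, and the choice matters:

* `factor_method="ridge"` (default) — the shrinkage estimator of the
  least-squares LFMM: damp the X directions of G by
  √(λ_r/(λ_r + s_j²)) (singular values s_j of X, penalty λ_r = 10⁻⁵ by
  default), SVD, re-inflate. The factors stay nearly orthogonal to X,
  preserving environment-aligned effects. Discovery-oriented: on planted
  synthetic worlds it recovers essentially all planted loci, but under
  strong structure–environment collinearity the corrected scan retains
  residual inflation (measured λ ≈ 1.4–1.9 on null worlds whose
  environment is a latitude composite), which the GIF division then
  absorbs.
* `factor_method="svd"` — factors are the top-K left singular vectors of
  centered G. They may absorb structure *collinear* with X, which keeps
  null z-scores calibrated (λ ≈ 0.9–1.1 on the same null worlds) at the
  cost of power for effects aligned with structure: with K = 4 on
  4-cluster data the fourth factor is free to capture a shared
  environment-response direction, and planted-locus recovery drops
  accordingly. Calibration-oriented.

The acceptance suite exercises each variant on the property it is
designed for: calibration on structured null worlds for `"svd"`,
planted-locus ranking for the default.

## Probe-based association with solar radiation

Occurrence matrices mark, per polarity, whether a call (deletion classes
0/1, duplication classes 3/4) spans a probe position (boundaries
inclusive). Balding–Nichols kinship standardizes each polymorphic probe
by √(p̂(1−p̂)) and averages the outer products; monomorphic probes are
excluded, and an indefinite matrix is repaired by the minimal diagonal
ridge (logged).

The mixed model is EMMAX-oriented: radiation is the response, each probe
the tested predictor, covariance σ_g²K + σ_e²I. The variance ratio
δ = σ_e²/σ_g² is REML-estimated once on the null model via the spectral
form of the restricted likelihood (eigenvalues of SKS), maximized over
ln δ ∈ [−10, 10] by a 100-point grid plus bounded refinement. Per probe
the scan is generalized least squares at that δ with the *residual scale
profiled per probe*; this makes K = I reduce exactly to OLS t-tests (the
strict EMMAX shortcut, variance fully fixed from the null model, would
not). Probes constant across samples are skipped. Suggestive threshold
p < 5 × 10⁻⁴; the logistic probe scan (occurrence on radiation + PCs)
uses 5 × 10⁻⁵; consensus probes are the intersection of the two
significant sets.

Structure covariates: kinship and stratification PCs are computed from
the **combined** deletion+duplication occurrence matrix (the genome-wide
marker set), and, when site labels are available, the PCs come from
site-mean occurrence frequencies broadcast back to samples
(`stratification_pcs`). Both choices are load-bearing: with
single-polarity, sample-level structure estimates on small cohorts the
max(T) family-wise error was measured at 0.25–0.58; combined-matrix
sample-level PCs brought it to ≈ 0.07–0.085, and site-level PCs to
≈ 0.02–0.06, consistent with nominal 0.05 control. The site-level choice
reflects that the phenotype (site-assigned radiation) varies only at the
site level, so the relevant confounding axes are site-frequency axes.

Regions are maximal runs of probes with p below a threshold, allowing
gaps up to 1 Mb between consecutive significant probes, with at least 3
probes; the region raw p is the peak (minimum) probe p. max(T)
adjustment permutes the radiation vector B times (default 10 000;
seeded), recomputes every probe statistic at the cached δ and
whitening (the standard fixed-δ shortcut), records the genome-wide
maximum |t|, and sets the region's adjusted p to
(1 + #{perm max ≥ observed region max})/(B + 1); significance at
adjusted p < 0.05. Requiring ≥ 3 probes per region makes the procedure
mildly conservative relative to probe-level max(T).

## Annotation

Intervals are 1-based inclusive internally; GFF3 (1-based) and BED
(0-based half-open) are normalized on read. Gene pairs are kept when the
overlap covers at least 10 % of the **region** length ("the entity being
annotated"; a gene-fraction option exists). QTLs with confidence
interval ≥ 5 Mb are excluded first (strict <), then pairs are kept at
≥ 50 % coverage of the region, with an optional reciprocal flag.

## Synthetic worlds

The generator emulates a worldwide survey: `n_sites` (default 47) on a
latitude gradient grouped into `n_clusters` (default 4) geographic
clusters, ~15 samples per site (705 by default). Climate has 9
parameters (SUN, DTR, REH, PR, TMP, PRCV, FRS, WND, RDO) × 12 monthly
+ 1 yearly column (117 variables) plus elevation; yearly values are the
monthly mean times a small relative noise (0.4 %); SUN is kept in
(0, 1]; each parameter has its own latitude slope, so some variables
(SUN, TMP) are strongly structure-aligned while others (WND) are nearly
structure-orthogonal. CNV loci get baseline frequencies in (0.05, 0.40),
cluster-specific logit offsets (s.d. 1.0 by default — the confounding
the corrected scans must absorb), and planted loci add
`effect_size` × standardized target variable to the logit. Copy-number
classes are drawn with weights 0.1207/0.5952/0.2815/0.0026
(CN0/1/3/4), matching the class balance reported for sheep array
cohorts. Call coordinates jitter by ±4 kb around the locus; 5 % junk
calls (too short or too few SNPs) and 5 % QC-violating samples exercise
the filters. Identical configuration and seed reproduce every table
bit-for-bit.

What the generator does **not** emulate: raw LRR/BAF signals and the HMM
calling step, linkage between loci beyond shared cluster offsets,
isolation-by-distance within clusters, genuine spatial autocorrelation
of climate beyond the latitude trend, and locus length/frequency
coupling. Passing tests therefore demonstrate the statistical machinery
under the stated generative model, not performance on real array data.

## Simulation sizes used by the acceptance suite

* Logistic-oracle agreement: 100 random instances, n = 12–60, tolerance
  1e-6 against an independent Newton solver.
* LFMM calibration: 50 null worlds, 400 samples, 500 loci, cluster
  offset s.d. 1.5 ("strong" structure), environment = first two climate
  PCs; median λ of the calibration-oriented scan in [0.8, 1.2],
  factor-free scan above 1.2.
* Mixed model: identity-kinship equality with OLS to 1e-8; REML δ vs a
  1001-point grid of the restricted likelihood.
* max(T): 200 null worlds (12 sites × 10 samples, 120 loci), B = 1000
  (scaled down from the 10 000 used for real analyses); family-wise
  error within the upper binomial bound of nominal 0.05.
* Recovery: 5 planted worlds (40 sites × 15 samples, 100 loci, 10
  planted, slope 1.5 on standardized wind speed — a structure-orthogonal
  variable, so recovery measures power rather than confounding);
  ≥ 80 % of planted loci in the top-10 of both scans, averaged over
  worlds.

## Known limitations

* The univariate scan is sequential statsmodels fits; at the real-data
  scale (4.6 M models) it would need hours — the model *count* is exact,
  but full-scale scans are out of desk scope.
* REML assumes a Gaussian phenotype; radiation is bounded and site-level,
  so its effective degrees of freedom are closer to the site count than
  the sample count. The site-level stratification PCs mitigate exactly
  this, and the permutation adjustment is the final arbiter.
* max(T) permutes samples freely; under residual structure the
  permutation null is only approximately exchangeable. Measured
  family-wise error stays at or below nominal with the default structure
  correction, but grossly mis-specified covariates void that guarantee.
* The latent-factor power/calibration tradeoff is inherent, not a bug:
  no single factor estimator maximizes both. The default favours
  discovery; switch to `"svd"` when the environment of interest is
  strongly collinear with structure and strict error control matters.
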