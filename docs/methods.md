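# Methods

This note documents the models implemented in `meshbag`, their
assumptions, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## NEXAFS deconvolution

**Model.** A normalized K-edge spectrum is modeled as one
Gaussian-broadened ionization step plus Gaussian resonances:

- π\* resonances at fixed literature energies — C1s: 284.3 (quinone-C),
  285.3 (substituted aromatic-C), 286.0 (aromatic-C), 286.6
  (phenolic-C), 287.4 (aliphatic-C), 288.4 (carboxyl-C), 289.3 eV
  (O-alkyl-C); N1s: 398.8 (heterocyclic-N), 400.0 (nitrilic/aromatic-N),
  401.4 (amidic-N), 402.7 (pyrrolic-N), 405.4 eV
  (nitrate-N/ammonium-N). All π\* Gaussians carry a fixed FWHM of
  1.2 eV (σ = FWHM / (2√(2 ln 2)); the conversion is stated because
  only the FWHM is conventionally quoted).
- two σ\* resonances above the edge (C: 294.3, 298.8 eV; N: 406,
  412.1 eV) with free widths, bounded σ ∈ [0.4, 8] eV.
- an error-function step at 289.9 eV (C) / 403.2 eV (N) with height ≥ 0
  and Gaussian broadening bounded [0.2, 2] eV. The step **center** is
  treated exactly like the π\* centers: a literature energy, fixed by
  default. This matters numerically — if the step center is allowed to
  float it can drift into the O-alkyl-C position (289.3 eV) and absorb
  that peak in a spurious local minimum.

Component classification (π\* vs σ\* vs step) is by declared kind, not
by position relative to the step: nitrate-N at 405.4 eV lies above the
403.2 eV step yet is a π\* transition and belongs in the π\*
denominator.

**Normalization.** Spectra are first reduced to a unit edge jump: the
mean over a pre-edge window is subtracted and the result divided by the
jump (post-edge mean − pre-edge mean). Default windows are C1s
275–282 / 310–320 eV and N1s 390–396 / 420–430 eV — inside the recorded
ranges (C 275–320, N 390–430 eV) and clear of all model components;
both are overridable. The transform is affine, hence idempotent and
invariant to detector gain and offset. A non-positive jump (post mean ≤
pre mean) is rejected as a non-absorbing or inverted spectrum.

**Fitting.** Bounded trust-region least squares through lmfit, in two
stages mirroring standard practice: the step is fitted first with all
Gaussian amplitudes pinned at zero, then amplitudes are released and
everything is refined jointly (cost tolerances 1e-12). On optimizer
failure the fit restarts up to 3 times from jittered amplitudes and the
lowest-cost solution is kept; a fit that still fails is returned with
`converged=False`, never silently. An optional `center_policy="bounded"`
lets π\* (and step) centers move ±0.2 eV for instruments with small
calibration offsets.

**Reported quantity.** Relative π\* abundances: each π\* area divided
by the sum of all π\* areas. These are invariant under global intensity
rescaling of the input (verified by property test). Recovery benchmarks
(50 seeded spectra, Dirichlet(2) compositions, noise 1 % of the edge
jump) give per-component abundance RMSE ≈ 0.003; noise-free round trips
recover abundances to ≈ 1e-7.

## Isotope and C/N mass balance

δ¹³C is the per-mil deviation of the molar ¹³C/¹²C ratio from VPDB.
The two-pool mixing model assumes exactly two carbon sources with fixed
end-members — maize compost at −13.36 ‰ and in-grown mycelial carbon at
−25.82 ‰ (defaults, both overridable) — and linear mixing of δ values
(adequate at natural-abundance contrasts). Fractions outside [0, 1] are
returned **unclamped with a flag** so end-member misspecification
surfaces in QC instead of being hidden.

The decay constant assumes a single well-mixed carbon pool,
C_t = C₀·e^(−kt); k < 0 (apparent gain) is allowed but flagged. The
default time base is t = 17/12 yr (placement to harvest); day-level
precision is not attempted.

**C/N partition convention.** The observed increase Δ = CN_final −
CN_initial is partitioned by counterfactual removal: the fungal pool
(`new_c_frac` of final C at C/N = `fungal_cn`, with the matching N) is
subtracted from final C and N to give CN_no-fungus, and the initially
present inorganic N (taken as leached early in the incubation) is added
back to final N to give CN_N-restored. Shares are
(CN_final − CN_counterfactual)/Δ · 100, with the remainder unexplained;
they sum to 100 by construction and the convention string is recorded
in every result. This is one declared, testable convention among
several defensible ones — the two counterfactuals are evaluated
one-at-a-time against the same baseline, so their shares are not
strictly additive decompositions of Δ, and interaction effects land in
the unexplained remainder.

## FTIR fingerprinting

Spectra are normalized to unit trapezoidal area over a configurable
range (default: full axis) before any comparison; band areas are
trapezoidal integrals with interpolated interval endpoints over six
regions: carbohydrates 970–1150, phenolics 1150–1250, nitrate/ammonium
1380–1400, aliphatics 1350–1450, aromatics 1500–1520 (a 20 cm⁻¹
interval realizing the 1510 cm⁻¹ point assignment), carbonyl
1620–1800 cm⁻¹. The nitrate band lies inside the aliphatic band;
overlapping bands are integrated independently and must never be summed.
No baseline correction, atmospheric compensation or Kubelka–Munk
transform is applied — spectra are treated as delivered.

PCA is covariance PCA (column centering, no variance scaling — the
area normalization already puts spectra on a common scale), computed by
full SVD. Signs are fixed deterministically (the largest-magnitude
loading of each component is made positive), explained variances match
a covariance eigendecomposition (oracle-tested), and
scores·loadingsᵀ + center reconstructs the input to 1e-8. A constant
matrix yields a flagged degenerate result rather than an error.

## Community processing

The canonical order is: rare-OTU filter on the raw counts → technical-
replicate averaging → rarefaction → relative abundance.

- **Rank assignment** from hit tables: ≥ 96 % identity with ≥ 80 %
  coverage → species; 94–95.99 % identity → genus; anything else
  unassigned. The coverage gate is applied to both tiers (the
  conservative reading of the protocol).
- **Rare-OTU filter:** default mode `either` removes an OTU with < 10
  total reads OR presence in < 2 columns; mode `both` implements the
  literal conjunction. The sentence describing this rule reads as a
  conjunction but the conventional intent is disjunctive, so `either`
  is the default and the mode plus removed ids are logged in the output
  metadata.
- **Averaging** is the arithmetic mean across a sample's technical
  replicates (replicates differ only by sampling depth and multinomial
  noise, which is exactly what a mean removes). Averaged counts are
  real-valued; **rarefaction rounds to nearest integers first**, since
  subsampling needs integer reads.
- **Rarefaction** subsamples each column without replacement
  (multivariate hypergeometric, seeded generator) to a common depth.
  The default depth is the **lower median** of the column sums — an
  always-achievable depth that guarantees at least half the samples
  need no drop policy. Columns below the depth raise an error naming
  the sample by default; `on_shallow="drop"` excludes them instead.
  Unbiasedness is benchmark-tested: the mean rarefied proportion of an
  OTU at true proportion 0.25 stays within [0.23, 0.27] over 200 seeds.
- **Guild profiles** sum OTU abundances per guild (ECM, saprotroph,
  pathogen, unknown) and normalize per sample; the display subset uses
  a strict > 50 total-read cutoff.
- **Bray–Curtis** dissimilarities come from scipy; two all-zero samples
  are rejected (the dissimilarity is undefined).
- **PERMANOVA** uses the distance-based pseudo-F
  (SS_total = Σd²/N, within-group analogues, F =
  (SS_A/(a−1))/(SS_W/(N−a)), R² = SS_A/SS_total) with free label
  permutation (no strata — an unblocked design) and
  p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm). Permutations are evaluated
  vectorized over membership matrices, which keeps a 500-simulation
  type-I study with 999 permutations each under a minute. The
  implementation is cross-checked in tests against brute-force
  enumeration on 4-sample toys and against scikit-bio's independent
  implementation; measured type-I error at α = 0.05 is ≈ 0.03–0.04.

## Synthetic data

The generators define the study conditions and return their ground
truth:

- **NEXAFS:** sum of the edge's canonical π\* Gaussians (total pre-edge
  area 2.0 intensity·eV, split by the true abundances), an edge jump of
  height 1, σ\* resonances (area 0.5 each, FWHM 4 eV — only their
  presence matters for π\* recovery) and additive i.i.d. Gaussian noise
  on intensity (the simplest model that exercises the fitter; real
  detector noise is partly multiplicative and correlated). Grid:
  0.05 eV steps over the recorded range.
- **FTIR:** broad Gaussians (FWHM = half the band width) centered in
  each weighted region on a 1 cm⁻¹ grid over 900–1850 cm⁻¹.
- **Chemistry tables:** per plot × horizon × treatment, C decays with
  per-horizon constants (defaults 0.11 humus / 0.29 mineral yr⁻¹), δ¹³C
  mixes −13.36/−25.82 ‰ end-members at 10 % new C, N is set so C/N
  rises by a factor 1.21 over the initial 12.1/1.02 material, pH ≈ 4.2;
  additive Gaussian between-plot noise (defaults roughly matching
  observed plot-level standard errors at n = 3; a scalar 0 disables all
  noise for closed-form tests). With zero noise the table reproduces
  the closed forms to 1e-9 relative.
- **OTU experiments:** 6 biological samples × 3 technical replicates,
  60 OTUs, guilds allocated by largest remainder (40 % ECM, 50 %
  saprotroph, 5 % pathogen, 5 % unknown), per-column depths uniform in
  12 000–25 000 reads. Each sample has one shared composition
  (Dirichlet(5) mixed with a uniform floor so no abundant OTU can fail
  the filter) that all of its replicates resample multinomially —
  replicates differ only by sampling noise, matching their later
  averaging. A planted 20 % of OTUs receive < 10 reads confined to a
  single column, so they fail the rare-OTU filter under both modes and
  `truth["filter_targets"]` is exact.

What the generators do **not** emulate: sequencing chimeras or
clustering artifacts, compositional correlations between OTUs,
beamline energy drift and self-absorption, baseline curvature in FTIR,
and replicate-level spectral variance (no published calibration exists;
the defaults are conventions). Passing round-trip tests therefore
demonstrates estimator correctness under the declared generative
model, not robustness to every field artifact.

## Numerical choices and degenerate inputs

- Optimizer tolerances 1e-12 (xtol/ftol/gtol) for spectral fits; up to
  3 restarts from jittered amplitudes on failure, best cost kept.
- All-zero spectra, zero-area normalization ranges, non-positive edge
  jumps, zero-sum samples, singleton PERMANOVA groups, degenerate
  mixing end-members (< 1 ‰ apart) and empty replicate groups are
  rejected with specific errors; constant PCA matrices and flat
  zero-weight FTIR spectra return flagged results.
- PCA sign ties (two equal-magnitude loadings) resolve to the first
  index by argmax; lower median is used wherever an even count needs a
  single achievable depth.
- Problem sizes in the benchmark studies (50 spectra for noisy
  recovery, 5 for noise-free, 500 × 999 for the PERMANOVA null, 200
  seeds for rarefaction) were chosen as the package's standard
  benchmark configuration; they complete in about a minute on one CPU.

## Known limitations

- Energy calibration against standards, multi-scan merging and
  fluorescence self-absorption correction are out of scope for the
  NEXAFS stage; spectra must arrive calibrated.
- The C/N partition reports shares under one declared convention;
  alternative conventions (sequential removal, Shapley-style averaging)
  would give different numbers.
- PERMANOVA assumes exchangeable samples under the null; the plot
  structure of a real blocked design would need restricted permutations.
- Rarefaction discards reads; for inference-grade abundance modeling a
  multinomial/negative-binomial model would be preferable. It is
  implemented because it is the field-standard preprocessing step.
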