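# Methods

## The model

`mr2s` implements two-sample summary-data Mendelian randomization. For each
of k instruments (independent SNPs robustly associated with the exposure),
two study samples supply

* γ̂ⱼ — the per-allele effect on the exposure (here: SD of BMI per
  BMI-increasing allele, from a continuous-trait GWAS), with SE σ_γⱼ;
* Γ̂ⱼ — the per-allele effect on the outcome (here: log-odds of multiple
  sclerosis, reconstructed from a case-control OR and its 95% CI), with SE
  σ_Γⱼ.

Under the instrumental-variable assumptions (relevance, no confounding of
the SNP–outcome relation, effect on the outcome only through the exposure),
each SNP gives a Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimating the same causal effect
β (log-odds of outcome per SD of exposure).

**Wald-ratio SE.** First-order delta method, σ_Γⱼ/|γ̂ⱼ|, ignoring
exposure-side uncertainty (the NOME approximation). This is the standard
choice for genome-wide-significant instruments, and the only SE
reconstructible from a published instrument table that prints no
exposure-side SEs. The neglected term contributes at relative order
(σ_γ/γ)², about 2% here.

**IVW (primary).** Fixed-effects inverse-variance pooling:
β̂ = Σwⱼβ̂ⱼ/Σwⱼ, SE = (Σwⱼ)^(−1/2), wⱼ = 1/SE(β̂ⱼ)². Algebraically
identical to the slope of a through-origin WLS of Γ̂ on γ̂ with weights
1/σ_Γ²; the test suite asserts that identity to 1e-10. A fixed-effects
model is the deliberate primary (one shared causal effect across valid
instruments); no random-effects variant is offered.

**Heterogeneity.** Cochran's Q = Σwⱼ(β̂ⱼ−β̂)², df = k−1, I² =
max(0, 100(Q−df)/Q). The I² confidence interval uses the test-based ln-H
construction: H = √(Q/df), SE(ln H) = ½(ln Q − ln df)/(√(2Q) − √(2df−1))
for Q > df (and the standard small-Q expression otherwise), the normal
interval for H back-transformed to I² and truncated to [0, 100]. On the
packaged data this reproduces the published interval (0–29) to within a
point.

**MR-Egger.** WLS of Γ̂ on γ̂ *with a free intercept*, weights 1/σ_Γ².
Instruments are first re-oriented so every γ̂ ≥ 0 (a joint sign flip of
(γ̂, Γ̂) is a relabeling of alleles; the intercept is only meaningful under
a consistent orientation). The intercept estimates the average directional
pleiotropic effect — zero under no directional pleiotropy — and the slope
is a pleiotropy-adjusted causal estimate, consistent under InSIDE
(pleiotropic effects independent of instrument strength). Parameter SEs use
the *unscaled* covariance (XᵀWX)⁻¹, i.e. the reported SEs are treated as
known rather than rescaled by residual dispersion; this known-variance
convention is what reproduces the published intercept CI half-width
(0.0115) exactly, and it makes the zero-intercept-constrained Egger
coincide with IVW.

**Weighted median.** Ratios sorted ascending, inverse-variance weights
normalized to sum 1, cumulative midpoints pⱼ = Sⱼ − wⱼ/2, and the estimate
is the linear interpolation of the ratio at p = ½ (the published method's
convention). A `interpolate=False` variant returns the step-CDF weighted
median — the exact minimizer of Σwⱼ|x−β̂ⱼ|; the two differ by at most the
local spacing between adjacent ratios. The estimator is consistent whenever
more than half the total weight comes from valid instruments. Its SE is a
parametric bootstrap: each replicate redraws every (γ̂ⱼ, Γ̂ⱼ) from normals
at the reported SEs and recomputes the estimate; default 5000 replicates,
seed 42, both configurable. The SE's own Monte-Carlo error at 5000
replicates is below 0.005, so reported SEs are stable to two decimals
across seeds.

**p-values** are two-sided normal throughout, floored at the smallest
positive normal double; the package never gates anything on a p-value and
applies no multiple-testing correction.

## Harmonization and instrument bookkeeping

* OR/CI → log scale: β = ln OR, SE = (ln CI_high − ln CI_low)/(2·z) with
  z = 1.959964 (more digits than the printed CIs, for reproducibility).
  Zero-width CIs are rejected rather than silently producing SE 0.
* Allele alignment (`alleles` mode): outcome effects reported on the other
  allele are negated and their frequency complemented; the strand
  complement is tried before declaring alleles irreconcilable. Palindromic
  SNPs (A/T, C/G) with EAF in [0.4, 0.6] are flagged
  `palindromic_unresolved`, never auto-dropped — the caller decides, which
  mirrors how this analysis handles frequency ambiguity through a
  sensitivity filter rather than a hard exclusion.
* `pre_oriented` mode serves published instrument tables that print only
  the exposure-increasing allele: effects are asserted aligned and copied
  through. Exposure SEs absent from such tables are reconstructed from the
  printed p-value as |β|/Φ⁻¹(1−p/2).
* LD pruning is greedy by ascending exposure p-value (ties lexicographic):
  a SNP is kept iff its r² with every kept SNP is ≤ 0.05 or unknown.
  Unknown pairs count as independent, because general inputs (unlike a
  fully measured reference panel) rarely cover all pairs. The output is
  invariant to input order.
* Proxy search honors outcome-source priority (e.g. Immunochip before the
  GWAS): a target genotyped in any source is its own proxy (r² = 1);
  otherwise sources are searched in order for the candidate with maximal
  known r² strictly above 0.8 (ties lexicographic, for determinism).
* The allele-frequency band flag marks *proxied* instruments with EAF in
  the closed interval [0.4, 0.6] (endpoint semantics pinned by the
  packaged table's 63/29 post-filter counts). Near-0.5 frequencies make
  allele matching across studies fragile, and proxies are where that
  fragility bites.

## The packaged dataset

`mr2s.summary_io.load_fixture()` returns the transcribed 70-SNP instrument
table of the BMI → multiple-sclerosis analysis: GIANT European
sex-combined exposure betas (SD of BMI per allele, 3 decimals) with
p-values, IMSGC Immunochip / IMSGC-WTCCC2 outcome ORs with 95% CIs
(2 decimals), and per-SNP proxy bookkeeping (36 proxies, mean UK10K
r² 0.937; 34 directly genotyped). Proxy status is carried by the proxy id,
not by r² < 1, because seven genuine proxies print r² = 1.00 at two
decimals. A SHA-256 of the TSV is pinned in the test suite so silent edits
fail loudly.

**Printed-precision limits.** The table's 2-decimal ORs quantize each
outcome log-odds in steps of ≈ 0.01, i.e. each Wald ratio in steps of up
to ≈ 0.5 for the weakest instruments. Averaging estimators damp this by
~1/√70, so IVW (1.408 vs published 1.41), the proxy-exclusion reruns
(1.651 vs 1.65; 1.485 vs 1.48), the Egger intercept/slope (0.0008/1.373 vs
0.0013/1.35) and I² (0%, CI 0–28.5 vs 0–29) all reproduce. The **weighted
median does not**: it is a single central order statistic and inherits the
full local quantization error, evaluating to 1.43 from the printed table
against the published 1.26 (computed by the original authors from
unrounded consortium data). Every interpolation/weighting variant tried
lands in 1.41–1.56. This is a fundamental limit of recomputing a median
from rounded inputs, not an implementation discrepancy; the corresponding
check is expected to fail and is left failing.

## Sensitivity suite and bidirectional mode

Analyses are declarative: a name plus an ordered filter list drawn from
`drop_proxies`, `drop_af_band_proxies`, `drop_height_ld`,
`restrict_source:<label>`. The canonical suite is the identity analysis
plus the two proxy checks; the three IVW ORs on the packaged data are
1.408 / 1.485 / 1.651 with 70 (36 proxies) / 63 (29) / 34 (0) instruments.
The height-LD filter (removing instruments with r² > 0.05 to any locus of
a supplied height-association list) and the source restriction are
implemented generically but exercised only on synthetic LD tables — the
published exclusion list and single-source effect table live in
unavailable supplements. A spec that filters below 3 instruments is marked
failed and the suite continues.

The bidirectional mode runs the identical estimator stack on instruments
harmonized with the roles swapped (disease log-odds as exposure, trait SD
as outcome). The published reverse-direction instrument set is likewise
unpublished, so this mode is validated on simulated panels: under a true
null the IVW CI covers zero at ≥ 93% over 500 replicates, and a reverse
effect of −0.003 SD per log-odds at realistic SEs has < 20% power at
α = 0.05 — a null finding in that direction is the expected outcome.

## The simulator

`mr2s.synthetic.generate` draws panels from the standard summary-data MR
data-generating process: true γⱼ ~ N(0.027, 0.012) truncated positive
(instruments oriented to the exposure-increasing allele), per-SNP SEs
uniform over the packaged table's empirical 10–90% bands (exposure side
[0.0031, 0.0047]; outcome side [0.0176, 0.0275] — the full min–max range
would overstate typical SEs, the empirical distributions being
concentrated with thin upper tails), γ̂ⱼ = γⱼ + N(0, σ_γⱼ), and
Γ̂ⱼ = β·γⱼ + αⱼ + N(0, σ_Γⱼ). Pleiotropy modes: `none`; `balanced`
(mean-zero αⱼ on invalid SNPs); `directional` (αⱼ ~ N(mean, sd) drawn
independently of γⱼ, so InSIDE holds by construction); and
`directional_correlated`, in which αⱼ additionally loads on γⱼ —
deliberately violating InSIDE to demonstrate where the Egger slope fails
(the test suite shows the slope collapsing onto the confounded value in
that mode). Binary-outcome noise is Gaussian on the log-odds scale — the
regime in which two-sample summary statistics live — with no
individual-level case/control sampling, no LD between instruments (they
model an already-pruned set) and no population-structure confounding.
Passing recovery tests therefore certify estimator correctness under the
stated model, not robustness to stratification, winner's curse or sample
overlap in real consortium data.

Calibration at the defaults (k = 70, β = ln 1.41, pinned seeds): IVW mean
bias −0.004 over 1000 replicates (the small attenuation is the expected
regression dilution from exposure-side noise), 95% CI coverage 95.8%,
Egger-intercept type-I error 5.05% at α = 0.05 over 2000 replicates.

**Weighted-median robustness scenario.** The demonstration that the median
resists directional pleiotropy uses αⱼ ~ N(0.15, 0.03) on 30% of SNPs.
The magnitude matters: the median's protection operates in the
*separation* regime, where invalid instruments' direct effects are
distinguishable from per-ratio sampling noise (≈ 0.8 here). In that regime
the contaminated weighted median converges to roughly the valid ratios'
71st percentile — a noise-sized offset that stays put while IVW bias grows
linearly with the pleiotropic mean (≈ prop_invalid · ᾱ · E[γ]/E[γ²], which
the tests verify). At ᾱ = 0.15 the median keeps under a third of the IVW
bias. At pleiotropy magnitudes small relative to the ratio noise
(ᾱ ≲ 0.05) the weighted median is nearly as biased as IVW — its robustness
is against gross outliers, not against diffuse small pleiotropy; this
limitation is inherent to the estimator, not to the implementation.

## Numerical conventions and degenerate inputs

* z quantile fixed at 1.959964 everywhere.
* γ̂ = 0 makes a Wald ratio undefined → a domain error naming the SNP
  (never a silent drop).
* Egger requires ≥ 3 instruments and nonzero spread in γ̂; the weighted
  median requires ≥ 3 instruments and a positive bootstrap spread.
* Proxy r² is validated on the closed interval [0.8, 1.0]: selection is
  strictly > 0.8, but published tables round, so a genuine 0.80x proxy
  prints as 0.80.
* Unparseable numeric cells in input tables become missing values, never
  zero; a row with no usable effect at all is a named validation error.
* All randomness flows through `numpy.random.default_rng(seed)`; suite
  results, simulated datasets and bootstrap SEs are bit-reproducible for a
  fixed seed.

## Problem sizes

The deterministic analyses run on the 70-SNP table in well under a second.
The stochastic calibration uses 1000 replicates (bias, coverage, median
robustness), 2000 (Egger type-I error) and 500 (bidirectional null
coverage and power), chosen so each check's Monte-Carlo error is several
times smaller than the band it asserts.
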