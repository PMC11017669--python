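# Methods

## The data model

The package operates on two-sample summary-data MR inputs: for each variant
j, an estimated effect γ̂_j on the exposure with standard error σ_Xj from one
GWAS, and an estimated effect Γ̂_j on the outcome with standard error σ_Yj
from an independent GWAS. All effects are assumed to be on standardized
(SD-unit) scales, so σ ≈ 1/√n. The structural model behind every estimator
is

    Γ_j = β γ_j + α_j ,

where β is the causal effect of interest and α_j a horizontal-pleiotropy
term: zero for valid instruments, zero-mean ("balanced") or mean-shifted
("directional") otherwise. MR-Egger is consistent when α is independent of
γ (the InSIDE condition).

## Instrument selection

Selection follows the standard cascade for metabolite exposures, with
defaults: association p < 1e-5 (strict inequality), greedy LD clumping —
repeatedly keep the most significant remaining SNP and discard same-
chromosome SNPs within ±500 kb (inclusive) with r² ≥ 0.1 against it — then
MAF ≥ 0.01 (records with missing frequency are kept and logged; frequency is
never used for inference), then removal of SNPs on a user-supplied
confounder blacklist. Ties on p-value break by smaller position, then
lexicographic variant ID. SNPs absent from the LD panel are removed and
logged. Instrument strength is summarized per SNP by F = β²/se² and variance
explained r² = t²/(t²+n−2); instruments with F ≤ 10 are flagged weak but not
dropped, since published screens report minimum F values near 18 without a
drop rule.

Harmonization aligns outcome effects to the exposure effect allele: flipped
codings negate the outcome beta, palindromic pairs (A/T, G/C) and
incompatible pairs are excluded unconditionally (no frequency-based rescue —
strand cannot be resolved from alleles alone, and allele frequency is kept
out of inference entirely). Duplicate variant IDs keep the smallest p-value,
first occurrence on ties. Multi-allelic records are rejected as invariant
violations.

## Estimators: conventions and numerical choices

- IVW fixed-effect: β̂ = Σ(γΓ/σ_Y²)/Σ(γ²/σ_Y²), SE = 1/√Σ(γ²/σ_Y²).
  Cochran's Q uses weights γ²/σ_Y² about the Wald ratios;
  I² = max(0, (Q−df)/Q)·100. Under the automatic model rule,
  multiplicative random effects (SE × max(1, √(Q/df))) apply when Q-p < 0.05
  and I² > 25%. p-values use the normal reference; the 95% multiplier is
  1.959964. k = 1 degrades to the single Wald ratio.
- MR-Egger orients every SNP to γ_j ≥ 0 before fitting (the intercept's sign
  is otherwise coding-dependent), fits the weighted regression with
  intercept by the normal equations, and scales SEs by multiplicative
  residual dispersion floored at 1, tested against t with k−2 df. The floor
  prevents anti-conservative SEs under underdispersion.
- Weighted median: weights γ²/σ_Y² normalized to 1; the estimate inverts the
  weighted empirical CDF using the standard percentile convention
  (cumulative weight minus half the step, linear interpolation at 0.5).
  A plain cumulative sum without the half-step offset fails the elementary
  check that equal weights reproduce the ordinary median, which is why the
  half-step form is used. SE by parametric bootstrap: γ*_j ~ N(γ̂_j, σ_Xj),
  Γ*_j ~ N(Γ̂_j, σ_Yj), weights held fixed, default 1000 resamples, seeded.
- Steiger: summed per-instrument variance explained on each side, compared
  on the Fisher-z scale with variance 1/(n_exp−3) + 1/(n_out−3).
- If the Egger intercept has p < 0.05 the fit is marked pleiotropy-suspect;
  IVW is still reported, alongside Egger, weighted-median and (when
  applicable) PRESSO-corrected estimates.

## MR-PRESSO

The global statistic is the 1/σ_Y²-weighted residual sum of squares about
per-SNP leave-one-out fixed-effect IVW predictions (closed form, so the
whole simulation is vectorized). The null distribution regenerates
γ* ~ N(γ̂, σ_X), Γ* ~ N(β̂_(−j)γ̂, σ_Y) and recomputes the statistic; default
1000 simulations. Empirical p-values use the add-one convention
(1+count)/(n_sim+1), so the attainable floor is 1/(n_sim+1) and is reported.
Per-SNP outlier p-values reuse the same simulated residuals (one seed, split
deterministically, governs the whole run) with Bonferroni adjustment over k.
The distortion test removes |outliers| random SNPs repeatedly and compares
the observed coefficient 100·(β_raw − β_corrected)/|β_corrected| to that
null, two-sided. The corrected estimate is exactly fixed-effect IVW on the
non-outliers.

## The synthetic generator

`ScenarioTruth` + `simulate_pair`/`simulate_harmonized` realize the data
model above with recorded ground truth. Defaults emulate a metabolite GWAS
of n_exp = 7,824 against a biobank outcome of n_out = 460,000, 30
independent instruments whose true effects (random signs, magnitudes spread
uniformly over ±30% of a common scale) are rescaled so total variance
explained is 8% — inside the 0.25–10% range typical of metabolite
instruments and high enough that per-SNP F statistics sit predominantly
above 10. Sampling noise is N(0, 1/√n) on each side; `noise_scale` (and the
per-side `noise_scale_x`/`noise_scale_y`) scales it, with 0 giving the
noiseless limit. Optional structure: equicorrelated LD blocks of companions
placed within 50 kb of index SNPs (shared effect and correlated noise, so
clumping has real work), palindromic allele pairs at a configurable
fraction, confounder-flagged SNPs for the blacklist, outlier instruments
with the outcome effect displaced by a stated multiple of σ_Y, and an
`inside_violated` pleiotropy mode correlating α with γ to document when
Egger fails. `simulate_screen` writes a complete file bundle (per-exposure
tables, one consistent outcome table, block-diagonal LD matrix, blacklist,
truth manifest), with per-exposure sub-seeds derived by fixed arithmetic
from the master seed.

What the generator does **not** emulate: realistic minor-allele-frequency
spectra, LD estimated from reference panels, sample overlap between the two
GWAS, selection-induced winner's curse, or non-normal effect distributions.
Passing tests therefore demonstrate correctness of the estimators and
pipeline logic under the stated model, not robustness to every property of
real GWAS data.

## Validation study designs

The test suite's simulation studies use these fixed designs (chosen once;
all seeded):

- **IVW coverage** (1000 replicates, k = 30, β = 0.2): instrument-exposure
  effects held at their true values (`noise_scale_x = 0`). IVW's sampling
  theory — like that of the originating method literature — treats γ as
  known (the NOME assumption). With the extreme sample-size asymmetry here
  (7.8k vs 460k), exposure-side noise induces regression dilution larger
  than the CI half-width, which is a violation of the estimator's
  assumptions rather than an error in the CI construction; the coverage
  study therefore evaluates the CI under its own model. The same convention
  applies to the Egger and weighted-median studies below.
- **Egger intercept type-I error** (1000 replicates): β = 0, balanced
  pleiotropy with SD 3σ_Y, k = 30. The intercept test's null holds by
  construction; rejection at α = 0.05 should be near 5%.
- **Weighted-median robustness** (500 replicates): 40% of 30 instruments
  carry directional pleiotropy of 3σ_Y, instruments oriented positive,
  total r² = 0.028. The regime is deliberately weak-instrument (per-SNP
  Wald-ratio noise ≈ 0.05) because that is where a 3σ_Y displacement breaks
  IVW (bias > 0.05) while the median, protected by the 60% valid weight,
  stays under 0.05.
- **PRESSO** (200 + 200 replicates, k = 20, n_sim = 1000): power against a
  single 8σ_Y outlier at β = 0 (a nonzero β feeds exposure-side variance
  into PRESSO's own null simulation, which is a property of that scenario,
  not of the detector); calibration as mean global p under no pleiotropy.
- **Steiger** (500 replicates, defaults, β = 0.2) and **screen recovery**
  (20 seeded screens of 10 exposures with 3 planted 0.3-SD effects,
  Bonferroni threshold 0.05/10).

## Screening and multiple testing

The Bonferroni denominator defaults to the number of exposures screened
(matching metabolome-wide practice of dividing by the metabolite count, not
metabolites × outcomes); it is configurable because that choice is a
judgment call. Tiers partition exhaustively: `bonferroni` (IVW p < α/m),
`suggestive` (α/m ≤ p < α), `null`. A pair is `sensitivity_consistent` when
every available sensitivity estimate (Egger, weighted median, and the
PRESSO-corrected IVW when outliers were found) shares the IVW sign with
nominal p < 0.05. Pairs that fail a stage are reported with a status, never
dropped. Identical config + seed reproduces byte-identical outputs.

## Pathway over-representation

ORA uses the upper-tail hypergeometric probability P(X ≥ k) for overlap k
between the query and a pathway of size K in a background of size N
(query size n); k = 0 reports p = 1. The background defaults to the union of
the library's sets and can be overridden (e.g., by a fixed metabolite
panel). Matching is case-insensitive with punctuation stripped, plus an
optional synonym table, because metabolite naming differs across libraries.
Published per-pathway p-values from web services are not comparison anchors
here: they depend on library versions that are not shipped.

## Known limitations

- No correction for sample overlap between exposure and outcome GWAS.
- Only multiplicative random-effects IVW; no additive variant, no
  multivariable MR, no mode-based estimator, no correlated-instrument IVW.
- Outcomes are treated as continuous summary statistics throughout.
- Weak-instrument (NOME-violation) bias is flagged via F statistics but not
  corrected; see the coverage discussion above.
- The LD interface consumes user-supplied correlation matrices; there is no
  reference-panel query or PLINK parsing.
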