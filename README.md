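# mrscreen

Two-sample Mendelian randomization (MR) screening of GWAS summary
statistics, built for metabolome-wide scans against complex traits such as
the components of sarcopenia (hand grip strength, walking pace, appendicular
lean mass).

MR uses genetic variants as instrumental variables to estimate the causal
effect of a modifiable exposure (here, a blood metabolite) on an outcome.
Given harmonized per-SNP effects — γ_j on the exposure (SE σ_Xj) and Γ_j on
the outcome (SE σ_Yj) — each variant supplies a Wald ratio Γ_j/γ_j, and the
suite combines them:

- **IVW**: the zero-intercept weighted regression slope of Γ on γ with
  weights 1/σ_Y², β̂ = Σ(γΓ/σ_Y²)/Σ(γ²/σ_Y²). Cochran's Q and I² quantify
  heterogeneity; when Q-p < 0.05 and I² > 25% the SE is inflated by
  √(Q/df) (multiplicative random effects).
- **MR-Egger**: the same regression with an intercept; a nonzero intercept
  flags directional horizontal pleiotropy (t test, k−2 df).
- **Weighted median**: the inverse-variance-weighted median of Wald ratios,
  consistent while valid instruments carry a majority of the weight;
  SE by parametric bootstrap.
- **MR-PRESSO**: simulation-based residual-sum-of-squares global test,
  per-SNP outlier test (Bonferroni over k) and distortion test, with an
  outlier-corrected IVW estimate.
- **Steiger directionality**: compares instrument variance explained in
  exposure versus outcome to confirm the causal orientation.
- **Leave-one-out**: IVW influence analysis per instrument.

Around the estimators sit the standard screening stages: summary-statistics
I/O with allele harmonization (palindromic A/T and G/C variants and
incompatible allele pairs excluded), instrument selection (p < 1e-5, greedy
LD clumping at r² < 0.1 within 500 kb, MAF ≥ 0.01, confounder blacklist,
F = β²/se² strength metrics), Bonferroni/suggestive tier classification, and
hypergeometric metabolite-set over-representation (ORA) on GMT libraries.
A synthetic GWAS generator with recorded ground truth exercises every stage.

## Worked example

Fit the estimator suite to a simulated metabolite→trait pair with a true
causal effect of 0.25 SD per SD (exposure GWAS n = 7,824, outcome
n = 460,000, 12 instruments):

```python
from mrscreen import MRModel, ScenarioTruth, simulate_harmonized

h, truth = simulate_harmonized(ScenarioTruth(causal_beta=0.25, k_snps=12, seed=42))
fit = MRModel(h).fit(seed=42)
print(fit.summary())
```

```
Two-sample MR: metabolite -> trait   (k=12, n_exp=7824, n_out=460000)
------------------------------------------------------------------------------
method                  beta        se                  95% CI           p
ivw_fixed             0.2478    0.0051      ( 0.2379,  0.2578)           0
egger                 0.2146    0.0318      ( 0.1523,  0.2769)    5.04e-05
weighted_median       0.2512    0.0138      ( 0.2242,  0.2782)    2.55e-74
------------------------------------------------------------------------------
Cochran Q = 9.423 (df=11, p=0.583), I2 = 0.0%
Egger intercept = 0.002826 (se 0.00267, p = 0.314)
Steiger: r2_exp = 0.08373, r2_out = 0.005199, direction exposure->outcome (p = 3.83e-87)
PRESSO: global p = 1 (floor 0.000999), outliers = 0
```

All three estimators agree near the true 0.25; there is no heterogeneity
(Q-p = 0.58, I² = 0), no directional pleiotropy (Egger intercept p = 0.31),
no PRESSO outliers, and Steiger confirms the exposure→outcome orientation
(the instruments explain 8.4% of the metabolite's variance but only 0.5% of
the outcome's).

The same works from files: `MRModel.from_tables(exposure, outcome)` reads
harmonized effects from `SummaryStatTable`s, and the `mrscreen` CLI wraps
the whole pipeline:

```bash
mrscreen simulate --out bundle/ --n-exposures 10 --n-true-effects 3 --seed 7
mrscreen screen --config config.yaml --out results/
mrscreen mr --exposure exp.tsv --outcome out.tsv
mrscreen ora --query hits.txt --gmt smpdb.gmt --out ora.tsv
```

`screen` writes `screen_results.tsv` (one row per exposure×outcome pair with
every estimate, heterogeneity/pleiotropy diagnostics, significance tier and
a sensitivity-consistency flag), `instruments.tsv` and `exclusions.tsv`.

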