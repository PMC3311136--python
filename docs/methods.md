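# Methods

## Data model

An analysis unit is one outcome at one time point of one trial: participant
values with an operating-surgeon label nested in a centre label and a trial
arm. Clustering is analysed at the centre or the surgeon level, one level at
a time; the operating surgeon defines the surgeon-level cluster whether or
not surgeons featured in the randomisation algorithm (when they did, the two
definitions coincide). Post-intervention values from the surgical arms are
pooled without treatment adjustment — the analysis assumes a common ICC
across the compared interventions, so any common treatment effect moves the
pooled mean but not the variance decomposition; under a differential effect
the pooled ICC is a pragmatic average.

Missing outcome values and missing cluster labels are handled complete-case
per outcome at load time, with the dropped count retained, so participant
numbers may differ legitimately between outcomes of the same trial.
Singleton clusters are retained: they carry between-cluster information even
though they contribute nothing to the within-cluster sum of squares. A
dataset must have at least two clusters and more participants than clusters
(otherwise the within-cluster variance is undefined).

## ANOVA ICC

The one-way random-effects method-of-moments estimator for unbalanced
clusters:

    MSB = Σ n_i (ȳ_i − ȳ)² / (k − 1)
    MSW = Σ Σ (y_ij − ȳ_i)² / (N − k)
    m0  = (N − Σ n_i²/N) / (k − 1)
    ρ̂raw = (MSB − MSW) / (MSB + (m0 − 1)·MSW)

It requires no distributional assumption and is applied unchanged to 0/1
outcomes; no latent-scale (logistic) ICC is offered. Negative intracluster
correlation is treated as implausible: the reported estimate is
`max(ρ̂raw, 0)` with a flag preserving whether censoring occurred, so
published zeros remain distinguishable from censored negatives. Totally
degenerate data (MSB = MSW = 0) define ρ̂ = 0 without the censoring flag.
The estimator is invariant to affine transformations of a continuous
outcome, and on balanced data coincides with the variance-components ratio
σ̂²_b/(σ̂²_b + σ̂²_w).

Under the simulation conditions used for validation (20 clusters of 30,
normal random intercepts), the mean estimate over 500 replicates is within
0.01 of the generating ρ for ρ ∈ {0.05, 0.2, 0.4}; the finite-k bias is
negative and grows slowly with ρ.

## Cluster bootstrap

Uncertainty comes from resampling k whole clusters with replacement at the
analysed level, copying every observation of a drawn cluster and giving each
draw a distinct synthetic label (so a resample again has k clusters and the
surgeon-in-centre nesting survives duplication). Replicate ICCs are censored
at zero exactly like the point estimate; interval bounds are additionally
clipped to [0, 1].

Intervals:

- **percentile** — empirical α/2 and 1−α/2 quantiles (linear-interpolation
  order statistics);
- **BC** — bias-corrected: `z0 = Φ⁻¹(#{ρ̂* < ρ̂}/B)`, quantiles at
  `Φ(2z0 ± z_{1−α/2})`;
- **BCa** — additionally accelerated with
  `a = Σd³ / (6 (Σd²)^{3/2})`, `d_i = mean(jack) − jack_i`, from a
  delete-one-**cluster** jackknife (consistent with the resampling unit).

A BC/BCa interval is *not calculable* when z0 is infinite (no or every
replicate below the estimate — typical when the estimate sits on the zero
boundary), when the jackknife has zero dispersion, or when the acceleration
denominator `1 − a(z0 ± z)` is non-positive; the percentile interval is then
substituted and the substitution recorded per result. The default is B =
1000 replicates at the 95% level, bounds reported to 3 dp.

With the default ANOVA estimator, replicate statistics are computed from
per-cluster sufficient statistics (size, sum, sum of squares) — algebraically
identical to estimating each materialised resample (a tested equivalence)
but orders of magnitude faster; a custom estimator switches to materialised
resamples. All resampling is driven by a single seedable generator;
seeded runs are bit-reproducible.

**Coverage.** At ρ = 0.2 with 20 clusters of 30 and B = 1000, the measured
coverage of the 95% BCa interval over 1000 independent simulations is
≈ 0.88 (the acceptance-level check at 200 simulations observed 174/200 =
0.87). This mild undercoverage at small k is a known property of the
standard cluster bootstrap for the ICC, not an implementation artefact: on a
shared replicate set the package's BCa bounds agree with an independent
implementation (`scipy.stats.bootstrap`, method `"BCa"`) to machine
precision, and that implementation shows the same coverage behaviour.
Intervals at k = 20 should therefore be read as slightly anti-conservative.

## Design effects

For a continuous outcome, an expertise-based design (each surgeon delivers
only one intervention, so treatment contrasts are between clusters) inflates
the independence-based sample size by `1 + (m − 1)ρ`; a stratified
within-surgeon design (each surgeon delivers both) deflates it by `1 − ρ`.
Cluster-size imbalance enters through the adjusted size `Σn_i²/Σn_i` (≥ the
arithmetic mean by Cauchy–Schwarz). Inflated sizes are rounded up to whole
participants; displayed multipliers are rounded half away from zero to 2 dp,
matching the convention of published tables. Binary-outcome design effects
and unequal-allocation corrections are out of scope.

## Three-level model

`y_ijk = μ + u_k + v_jk + e_ijk` with independent zero-mean normal
intercepts for centre (u) and surgeon-within-centre (v), fitted by REML via
`statsmodels.MixedLM` (random intercept for centre plus a surgeon variance
component). REML is preferred over ML for its small-sample behaviour of
variance components; the optimiser keeps components non-negative and
boundary estimates are reported as zeros. Derived ICCs: centre
`σ²_c/total`, surgeon `σ²_s/total`, and combined `(σ²_c + σ²_s)/total` (the
correlation of two patients under the same surgeon). The level-2 ICC is
*defined* here as the proportion of total variance at the surgeon level;
this definition is recorded on every result object because competing
definitions exist. When every centre has exactly one surgeon the two upper
components are confounded; the fit proceeds, flags the confounding, and only
their sum is interpretable — in that situation the combined ICC matches the
two-level ANOVA ICC (a tested consistency). Bootstrap CIs resample centres
(the top-level exchangeable units) with a delete-one-centre jackknife for
BCa and the same percentile fallback. Random treatment-effect (slope) models
are out of scope.

## Synthetic data

Generators exist so the pipeline is testable without confidential trial
data; their defaults describe the regimes the estimators are meant for.

- Continuous: `y = μ + b + e`, `b ~ N(0, ρσ²)`, `e ~ N(0, (1−ρ)σ²)`,
  σ² = 1 — the population ICC is exactly ρ.
- Binary: cluster probability `p_i ~ Beta(α, β)` with mean = prevalence and
  `ICC = 1/(α + β + 1)`; members Bernoulli(p_i); ρ = 0 degenerates to a
  common probability.
- Three-level: independent centre and surgeon normal intercepts with given
  variances; population ICCs follow the ratio formulas above.

Cluster-size inputs accept a fixed size, explicit sizes, or a shifted
(zero-truncated) negative binomial `1 + NB(r = 2, mean m − 1)` whose mean is
exactly m — defaults aimed at the observed median sizes (≈ 32 per centre,
≈ 6 per surgeon). The ten-trial suite reproduces the exact participant/
centre/surgeon counts of the emulated database using Dirichlet-multinomial
allocation (every cluster non-empty, realistically unbalanced) and assigns
centre-level ICCs from a palette spanning 0–0.47. One global seed spawns
per-trial streams, so the suite is reproducible item-wise.

What the generators do *not* emulate: treatment effects and arm-specific
ICCs, skewed or heavy-tailed outcomes (operation times are log-normal-ish in
practice), missingness mechanisms, and centre-size correlation with outcome
level. Passing recovery and coverage checks on these generators therefore
validates the estimators under their own model assumptions, not robustness
to such features of real trial data.

## Validation scale and numerics

The test suite runs estimator recovery at 500 replicates (k = 20, n_i = 30),
interval coverage at 200 simulations × B = 1000, and three-level REML
recovery at 100 replicates of 30 × 5 × 20 — sizes chosen to keep Monte-Carlo
error well inside the asserted tolerances while the whole suite stays
interactive (≈ 40 s). Exact-agreement checks (independent ANOVA oracle,
straight-line Efron formulas, scipy BCa) use 1e-12 tolerances. Rounding for
published views is half-away-from-zero (via `decimal`), applied only at the
display layer; full precision is preserved internally and in the database
CSV's shadow columns (`%.17g`, lossless for IEEE doubles).

## Known limitations

- BC/BCa calculability is operationalised as finite z0 and positive
  jackknife dispersion; other conventions exist and published "not
  calculable" flags may not correspond exactly.
- Zero-censoring of replicates slightly inflates interval bounds near
  ρ = 0 (boundary pile-up), which is why boundary estimates typically report
  percentile intervals of (0.000, 0.000).
- The beta-binomial ICC is a cluster-level (not latent-scale) correlation;
  it is the quantity the ANOVA estimator targets on 0/1 data.
- ICC estimates are unadjusted for covariates; covariate adjustment would
  typically shrink them.
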