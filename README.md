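# surgicc

Clustering effects in multicentre surgical trials: estimation of the
intracluster correlation coefficient (ICC) at centre and operating-surgeon
level, cluster-bootstrap confidence intervals, and the design-effect
arithmetic needed to size surgical randomised trials.

## The problem

Outcomes of patients treated by the same surgeon (or at the same centre)
tend to be more alike than outcomes of patients treated elsewhere — the
*clustering effect*. Trials of surgical interventions are nevertheless often
designed and analysed as if patient outcomes were independent, which
misstates the required sample size and overstates precision. The strength of
clustering is the intracluster correlation coefficient

ρ = σ²_b / (σ²_b + σ²_w),

the proportion of total outcome variance attributable to differences between
clusters. `surgicc` provides, for trialists and methodologists:

- **ANOVA ICC estimation** for unbalanced clusters: with cluster sizes `n_i`,
  `MSB` and `MSW` the between/within mean squares, and
  `m0 = (N − Σn_i²/N)/(k − 1)`,

  ρ̂ = (MSB − MSW) / (MSB + (m0 − 1)·MSW),

  censored at zero, applicable to continuous and 0/1 outcomes alike.
- **Cluster-bootstrap CIs**: whole clusters resampled with replacement;
  percentile, bias-corrected (BC) and BCa intervals (delete-one-cluster
  jackknife acceleration), with an automatic percentile fallback when the
  bias correction is incalculable.
- **Design effects**: `1 + (m − 1)ρ` for an expertise-based design (each
  surgeon delivers only one intervention) and `1 − ρ` for a stratified
  within-surgeon design, plus the adjusted cluster size `Σn_i²/Σn_i` and
  inflated sample sizes.
- **Three-level decomposition**: REML fit of patient-within-surgeon-
  within-centre random intercepts and the derived level-specific ICCs with
  centre-resampling bootstrap CIs.
- **Synthetic trial generators** with known ICC structure (normal
  random-intercept and beta-binomial models), including a ten-trial suite
  emulating the shapes of a published surgical-trial ICC database
  (138–1370 participants, 8–27 centres, 16–191 surgeons), whose published
  point estimates ship with the package.

## Worked example

Design effects for a patient-reported outcome with little clustering
(ρ = 0.01) and a surgical outcome with strong clustering (ρ = 0.27), at the
median surgeon (6.1) and centre (32.4) cluster sizes, for a base sample size
of 300:

```sh
$ icc design-effect --icc 0.01 --icc 0.27 --size 6.1 --size 32.4 --base-n 300
icc,cluster_size_label,cluster_size,expertise_design_effect,stratified_design_effect,expertise_n,stratified_n
0.01,m=6.1,6.1,1.05,0.99,316,297
0.01,m=32.4,32.4,1.31,0.99,395,297
0.27,m=6.1,6.1,2.38,0.73,714,219
0.27,m=32.4,32.4,9.48,0.73,2844,219
```

Reading the last row: with ρ = 0.27 and an average of 32.4 patients per
cluster, an expertise-based design needs 9.48× the independent-outcomes
sample size (2844 instead of 300), while a stratified within-surgeon design
needs only 0.73× (219).

The estimation pipeline on synthetic trials:

```python
from surgicc import run_full_analysis, simulate_trial_suite

suite = simulate_trial_suite(seed=7)
records = run_full_analysis(suite[:3], n_replicates=1000, seed=7)
for r in records:
    print(f"{r.trial:8s} {r.level:8s} N={r.n:4d} k={r.n_clusters:3d} "
          f"ICC={r.icc:.3f} 95% CI ({r.ci_lower:.3f}, {r.ci_upper:.3f}) "
          f"[{r.ci_method_used}]")
```

```
CLIVIT   centre   N= 491 k= 13 ICC=0.003 95% CI (0.000, 0.022) [bca]
CLIVIT   surgeon  N= 491 k=125 ICC=0.000 95% CI (0.000, 0.067) [percentile]
DISPACT  centre   N= 352 k= 21 ICC=0.051 95% CI (0.019, 0.143) [bca]
DISPACT  surgeon  N= 352 k=126 ICC=0.000 95% CI (0.000, 0.091) [percentile]
FILMS    centre   N= 138 k=  9 ICC=0.000 95% CI (0.000, 0.000) [percentile]
```

Each row is one outcome analysed at one cluster level: the ANOVA point
estimate (censored at zero), the 95% cluster-bootstrap interval, and which
interval method was actually used — where the bias-corrected intervals were
incalculable (here: estimates hard against the zero boundary) the percentile
interval is reported instead. FILMS carries no surgeon identifiers, so only
the centre level appears.

## Layout

- `surgicc.trial_data` — clustered dataset model, CSV I/O, arm selection,
  cluster summaries
- `surgicc.icc_anova` — ANOVA mean squares and ICC estimator
- `surgicc.cluster_bootstrap` — cluster resampling, percentile/BC/BCa
  intervals, fallback logic
- `surgicc.design_effects` — design-effect and sample-size calculators
- `surgicc.multilevel_variance` — three-level REML decomposition and
  derived ICCs
- `surgicc.synthetic_data` — generators with known clustering structure
- `surgicc.icc_database` — record schema, pipeline runner, summaries,
  bundled published estimates
- `surgicc.cli` — the `icc` command (`run`, `summarize`, `design-effect`,
  `simulate`, `three-level`)

See `docs/methods.md` for the statistical methodology, numerical choices and
known limitations.
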