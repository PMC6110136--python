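# Methods

This note records the statistical model, parameter conventions, numerical
choices and limitations behind `fepbench`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Units and conversion

All energies are kcal/mol; concentrations are nM. The change in binding
free energy caused by a mutation is obtained from potencies as

    ΔΔG = −RT · ln(IC₅₀,WT / IC₅₀,mut),

positive when the mutant binds the inhibitor more weakly. The pIC₅₀ route
ΔΔG = RT·ln10·(pIC₅₀,WT − pIC₅₀,mut) is algebraically identical and tested
as such. The gas constant is R = 1.9872×10⁻³ kcal/(mol·K).

**Temperature convention.** The default temperature is 298.15 K because the
operative fold-change cutoffs in common use (1.36 kcal/mol for 10-fold)
correspond to room temperature; `ThermoConstants(T=...)` makes any other
choice explicit. At 300 K the decade constant would be 1.37 kcal/mol.

**ATP competition.** `ki_from_ic50` implements the relation
IC₅₀ = Ki/(1 + S₀/K_M), i.e. Ki = IC₅₀·(1 + S₀/K_M), as used by the
benchmarking convention this package follows. Note this correction factor
is *inverted* relative to the textbook Cheng–Prusoff relation
(IC₅₀ = Ki·(1 + S₀/K_M)); both forms coincide in the K_M ≫ S₀ limit that
relative free-energy comparisons invoke, which is why the discrepancy has
no effect on ΔΔG values derived from ratios. Users applying the absolute
correction should check which form their assay conventions require.

**Reported cutoffs.** Internally, classification uses the full-precision
cutoff RT·ln f (1.3642 kcal/mol at 10-fold). Reports quote cutoffs at two
decimals following the convention of expressing larger cutoffs as
multiples of the rounded decade constant, 1.36·log₁₀ f: 10/20/100-fold
read 1.36/1.77/2.72. (Full precision would round 100-fold to 2.73; the
convention keeps the printed ladder self-consistent.) The difference is
three thousandths of a kcal/mol and never changes a classification in
practice; the full-precision value is always the one compared against.

## Classification and censoring

A mutation is *resistant* when ΔΔG > cutoff and *susceptible* when
ΔΔG ≤ cutoff (ties susceptible — the susceptible class is defined by the
≤ inequality). A censored experimental value — an assay that saturated its
dynamic range, e.g. IC₅₀ > 10,000 nM, leaving only a lower bound on ΔΔG —
is always classified resistant: the saturation itself demonstrates
resistance. Censored records are therefore *included* in truth tables and
classification metrics but *excluded* from MUE/RMSE, which need point
values. Predictions are never censored; predictors return point values,
so only experimental censoring triggers the forced-resistant rule.

Accuracy is strictly two-class ((tp+tn)/total); sensitivity and
specificity return a not-applicable marker (`None`) when their denominator
is zero (e.g. a drug with no resistant mutations in the panel), and NA
values are skipped — not coerced to zero — in bootstrap aggregation.

## Bootstrap

Confidence intervals are percentile bootstrap: the dataset's rows
((TKI, mutation) records) are resampled with replacement, 1000 resamples
by default, and the 2.5th/97.5th percentiles of the resample statistics
(linear interpolation between order statistics) bound the interval. The
resampling unit is the whole row, unstratified by default, which preserves
the pairing between experimental and predicted values; per-group
(e.g. per-TKI) stratification is available via `stratify_by`. BCa or
delta-method intervals are deliberately out of scope. All resampling uses
`numpy.random.default_rng` with an explicit integer seed that reports
record.

## Experimental variability

When two sources measure the same mutations, the RMSE of their paired
ΔΔG differences estimates √2 times the per-measurement noise: if each
measurement carries independent N(0, σ²) noise, the difference has
standard deviation σ√2. Hence σ_exp = RMSE_pairwise/√2 (0.81 → 0.57
kcal/mol; 0.45 → 0.32). The convergence of this rule is property-tested on
synthetic inter-lab pairs at M = 10⁵ within 2%.

## The hierarchical intrinsic-error model

### Structure

    ΔΔG_i^true     ~ N(μ_mut, σ_mut²)                 i = 1..M
    μ_mut          ~ U(−6, +6)
    σ_mut          ∝ 1 on (0, σ_cap]
    RMSE_method    ∝ 1 on (0, σ_cap]                  (the estimand)
    ΔΔG_i^method   ~ N(ΔΔG_i^true, RMSE_method²)      latent prediction
    ΔΔG_i^obs,calc ~ N(ΔΔG_i^method, σ_stat,i²)      stochastic predictors
    ΔΔG_i^obs,exp  ~ N(ΔΔG_i^true, σ_exp²)           σ_exp known

Deterministic predictors (single-structure rescoring) have no statistical
noise: the observed prediction *is* the latent prediction and the σ_stat
layer is skipped. For stochastic predictors whose record stores raw
replicate values, σ_stat,i is taken as the standard error of the reported
replicate mean (sample s.d./√n), since the observed value entering the
likelihood is that mean.

The flat priors on σ_mut and RMSE are truncated to (0, 10] kcal/mol to
make them proper; the benchmark's dynamic range is ≈ 5 kcal/mol, so the
bound is far from the likelihood's support and effectively non-informative.

### Sampling

Because every layer is normal, the M latent true values are marginalized
analytically: each record contributes a bivariate normal likelihood for
(ΔΔG_i^obs,exp, ΔΔG_i^obs,calc) with covariance

    [[σ_mut² + σ_exp²,  σ_mut²            ],
     [σ_mut²,            σ_mut² + RMSE² + σ_stat,i²]].

The resulting 3-parameter posterior is sampled with emcee's
affine-invariant ensemble sampler (20 walkers, vectorized log-posterior).
Defaults: 5000 retained draws pooled across walkers, 500 burn-in steps per
walker, thinning interval 10 (the ensemble autocorrelation time is ≈ 30
unthinned steps on typical benchmarks, so retained draws are nearly
independent). Initialization is method-of-moments: the covariance between
experimental and predicted values estimates σ_mut², and the excess
prediction variance estimates RMSE². Convergence requires split-R̂ < 1.05
and bulk ESS > 400 on all three parameters (computed with arviz); on
failure the fit retries with doubled burn-in and thinning up to twice
before raising a diagnostic error carrying the statistics. A fixed seed
makes the fit exactly reproducible.

Latent true values, when requested, are drawn exactly from their
conditional posterior: given (μ_mut, σ_mut, RMSE), ΔΔG_i^true is normal
with precision 1/σ_mut² + 1/σ_exp² + 1/(RMSE² + σ_stat,i²) and mean the
precision-weighted blend of the background mean and the two observations.
The marginal-plus-conditional scheme is mathematically identical to
sampling the full hierarchy, just better conditioned.

### Posterior-predictive metrics

For each posterior draw (optionally replicated), a synthetic benchmark of
M mutations is simulated at that draw's parameters and the *latent*
predictions are scored against the *true* values — MUE, RMSE and the
classification metrics at the chosen cutoff. This measures intrinsic
performance: what the predictor would achieve against noiseless truth.
Summaries are means and 2.5/97.5 percentiles over draws × replicates;
replicates with a missing class skip sensitivity/specificity. Under the
zero-bias normal error model MUE = √(2/π)·RMSE exactly, and the simulated
MUE summaries are tested for consistency with that closed form. The
predictive-simulation scheme (rather than plug-in evaluation) is a
declared design choice; one replicate per draw is the default since 5000
draws already give smooth summaries.

Pooling: one (μ_mut, σ_mut) background is shared across all TKIs by
default; fit per-TKI subsets separately where stratification is wanted.

## ROC and consensus

ROC curves follow the stepped-sweep definition: experimental labels are
fixed at the resistance cutoff; the prediction cutoff then sweeps
[min, max] of the predicted values inclusive, in 0.001 kcal/mol steps,
with predicted-resistant meaning prediction > cutoff (strict, matching the
classification rule). Corner anchors (0,0) and (1,1) are always appended
before trapezoidal integration — the sweep alone cannot reach the corners
when extreme predictions are tied, and anchoring makes the constant
(naive, all-zero) predictor score exactly 0.50. Against the Mann–Whitney
pairwise statistic (ties counted ½) the sweep agrees to within one step.

The consensus predictor first rescales each method by the slope minimizing
its RMSE to experiment (s* = Σ pred·exp / Σ pred², least squares through
the origin, fitted on non-censored records and applied to all), then
averages the two scaled predictions with inverse-variance weights
1/RMSE_scaled² — identical across records. A per-record variant weighting
by each record's scaled σ_i is available behind a flag. If both scaled
RMSEs are zero the weights are degenerate; the implementation falls back
to the unweighted mean with a warning.

## Synthetic benchmark generator

The generator draws exactly the hierarchy above: true ΔΔG from
N(μ_mut, σ_mut²); per method a latent prediction truth + N(0, RMSE²);
stochastic methods report the mean of 3 replicates (configurable),
each latent + N(0, σ_stat²), with the replicate sample s.d. stored as the
record's sigma; experimental observations truth + N(0, σ_exp²); optional
censoring truncates experimental values above an assay-ceiling energy and
flags them. Mutation labels are synthesized in the X###Z convention over a
kinase-domain-like numbering range; they are labels only. Reference
parameter scale for a realistic panel: M ≈ 131–150, σ_mut ≈ 1.2, σ_exp =
0.57, intrinsic RMSE ≈ 1.0 (good alchemical predictor) or ≈ 1.7 (fast
rescoring); placing μ_mut ≈ 0.05 yields the ≈ 13.7% resistant fraction
typical of clinical kinase mutation panels at the 10-fold cutoff.

What the generator does *not* emulate: fat-tailed or biased predictor
errors (real MM-GBSA errors are visibly non-Gaussian), correlation of
errors across mutations at the same site, TKI-specific backgrounds,
non-normal experimental noise, and censoring mechanisms other than a sharp
ceiling. Passing tests therefore demonstrate correctness of the statistics
under the model's own assumptions, not robustness to their violation; on
real data a heavy-tailed predictor will show an intrinsic MUE above
√(2/π)·RMSE·(apparent consistency), which is itself a useful diagnostic.

## Problem sizes used in the tests

Unit and property tests run on toy sets (≤ 10 records), law-of-large-number
checks at M = 10⁵, and the parameter-recovery study at M = 150 with 20
independent benchmarks at 5000 draws each — sizes chosen so the full suite
exercises every claim at meaningful precision while remaining quick to run
routinely.

## Known limitations

- Normality is assumed everywhere; there is no model-comparison machinery
  (WAIC/LOO) to check it.
- σ_exp is treated as exactly known, not estimated jointly.
- Censored records are excluded from the Bayesian fit rather than handled
  with a truncated likelihood.
- The Michaelis correction form follows the benchmarking convention noted
  above; absolute-Ki users should verify the direction.
- The bootstrap is percentile-only; narrow intervals on very small panels
  (N < 20 per TKI) should be read cautiously.
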