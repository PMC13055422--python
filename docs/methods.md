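# Methods

## The problem

Prognostic-factor evidence for early-stage glottic carcinoma treated with
definitive radiotherapy is scattered across small cohorts, each reporting
univariate odds ratios for local recurrence over a different subset of
candidate factors (anterior commissure involvement, T substage, smoking
status, treatment parameters, ...).  Pooling each factor separately
ignores two things: the factors are correlated (a tumour involving the
anterior commissure is more often T1b/T2), and each study's estimates for
different factors share sampling error because they come from the same
patients.  This package implements both the conventional univariate
pooling and a joint Bayesian multivariate meta-analysis of multiple
factors that models those correlations explicitly while tolerating the
pervasive missingness.

The data currency throughout is the `EffectTable`: an ordered studies x
factors grid of log odds ratios `y_ij` with within-study standard errors
`s_ij` and an implied missingness mask.  A blank cell is *missing*; a
printed `0.00` is an observed estimate.

## Univariate pooling

For one factor with estimates `(y_i, s_i)`, fixed-effect weights are
`W_i = 1/s_i^2`, Cochran's heterogeneity statistic is
`Q = sum W_i (y_i - mu_FE)^2` on `k-1` degrees of freedom, and the
DerSimonian-Laird moment estimator is

    tau^2 = max(0, (Q - (k-1)) / (sum W_i - sum W_i^2 / sum W_i)),

with random-effects weights `1/(s_i^2 + tau^2)`, Wald 95% CIs, a
two-sided normal test for the pooled effect, and
`I^2 = max(0, (Q - df)/Q) * 100` (0 when `Q = 0`).  DerSimonian-Laird is
the only random-effects estimator offered: it is what the mainstream
systematic-review tooling applies by default, so results are directly
comparable with the published literature in this area; REML is a
deliberate non-feature for now.  `tau^2` and `I^2` truncate at zero.
`z_from_or_ci` back-solves a Wald z from a published OR and CI; it is a
consistency check on printed summaries, not an estimator, and inherits
their rounding.

The implementation is cross-checked in the test suite against a
plain-float re-derivation of the same closed forms on a thousand random
tables (agreement to 1e-10) and against R's `metafor::rma(method="DL")`
on real data (agreement to 1e-8).

## The multivariate model

Let `mu` (length J) be the overall log ORs, `tau` the between-study SDs,
`R_B` the between-study correlation matrix, and `rho_W` a single shared
within-study correlation.  For study i with observed subset `O_i`:

    theta_i           ~ N_J(mu, D R_B D),    D = diag(tau)
    y_i(O_i) | theta_i ~ N(theta_i(O_i), S_i)

where `S_i` has diagonal `s_ij^2` and off-diagonals `rho_W s_ij s_ik`
under Model H, and is diagonal under Models M0 and U.  The three variants
differ only in which correlations they admit:

| variant | within-study (`rho_W`) | between-study (`R_B`) |
|---------|------------------------|------------------------|
| H       | shared scalar, sampled | sampled                |
| M0      | 0                      | sampled                |
| U       | 0                      | identity               |

Model U therefore *is* J independent univariate normal-normal
random-effects models; this structural identity is enforced by a test
comparing the joint engine against an independently coded per-factor
sampler.

**Missingness.**  `theta_i` is marginalized analytically: the likelihood
of study i is the normal density of its observed subvector with
covariance `S_i + (D R_B D)(O_i)`.  Nothing is imputed.  This is exact
for inference on `(mu, tau, R_B, rho_W)` under the multivariate normal
and keeps the state space small, which matters for mixing on a 9 x 14
table with 56 observed cells.  It assumes reporting is unrelated to the
unreported values (missing at random) — see limitations.

**Priors.**  The original analysis does not publish its priors, so the
defaults here are deliberately vague, standard choices, all configurable:
`mu_j ~ N(0, 10^2)` (log-OR scale; essentially flat over any plausible
odds ratio), `tau_j ~ U(0, 5)` (an upper bound of 5 on a log-OR SD is
far beyond any real between-study spread), `rho_W ~ U(-1, 1)` restricted
to values keeping every `S_i` positive definite, and a flat prior over
the set of positive-definite correlation matrices for `R_B` (the
LKJ-family prior with unit concentration).  Because the original priors
are unknown, Model H and M0 results should be read with a
prior-sensitivity band in mind; the acceptance checks use +/-0.35 on the
log-OR scale for those quantities and +/-0.15 for Model U, which is far
less prior-dependent.

**Shared versus pairwise `rho_W`.**  Whether the original fit used one
scalar within-study correlation or pairwise ones is not stated.  A single
shared scalar is the default here: with at most nine studies there is
essentially no information to identify `C(14,2)` separate within-study
correlations, and the shared scalar already spans the qualitative range
between Models M0 and H.

## MCMC

Sampling is by Metropolis-within-Gibbs, compiled with numba:

* `mu` — exact Gibbs draw: given the covariances, the full conditional is
  multivariate normal (precision = prior precision plus
  `sum_i X_i' V_i^{-1} X_i` over selection matrices `X_i`).
* each `tau_j` — random-walk Metropolis on the natural scale; proposals
  outside `(0, upper)` are rejected.
* each free element of `R_B` — single-site random-walk Metropolis with a
  positive-definiteness check by Cholesky; non-PD proposals are rejected,
  never projected, which together with the flat prior targets exactly the
  uniform distribution over PD correlation matrices.  Elements whose
  factor pair is co-reported by no study are still updated (their
  posterior is the prior conditional on PD).
* `rho_W` (Model H) — random-walk Metropolis over all studies observing
  two or more factors.

Proposal scales adapt in batches of 100 during burn-in only (targeting
acceptance roughly 0.2-0.5) and are frozen afterwards, so retained draws
come from fixed kernels.  Chains start overdispersed (`mu ~ N(0,1)`,
`tau ~ U(0.2, 1.5)`, `R_B = I`, `rho_W = 0`).  All randomness is
seeded; per-chain seeds derive from the configured seed, and identical
config + seed + package version reproduces summaries exactly.

The default protocol is 3 chains x 100 000 retained updates after
100 000 burn-in each — minutes on one CPU for the 9 x 14 table (the
Model U special case runs in ~20 s, Models H/M0 in ~1.5-2.5 min each).
`thin` controls storage only (default 10, i.e. 10 000 stored draws per
chain), which leaves quantile estimates with Monte Carlo error well
below the reporting precision.  Unit tests use a short 3 x 2000/2000
profile; the mid-scale checks in the acceptance tests use 3 x 20k/20k.
These sizes were chosen so the posterior-median Monte Carlo error
(~0.01-0.03 even for the sparsest factors) is negligible against the
tolerances being tested.

**Convergence.**  Beyond trace inspection (`trace_series` exports
per-parameter chains), every fit computes split-chain rank-normalized
R-hat and bulk effective sample size (via arviz) for every `mu_j`,
`tau_j` and `rho_W`; the gate is R-hat < 1.01 and ESS > 400.  A fit
failing the gate is returned *flagged* (`converged=False` plus a
warning), never silently.  At the full protocol all parameters pass on
the built-in dataset.

**Summaries.**  Posterior medians and central 95% credible intervals
(2.5th/97.5th percentiles) per factor on the log-OR scale; posterior
median `tau_j`; posterior mean `R_B` (accumulated online rather than
stored draw-by-draw).  Exponentiation to the OR scale maps quantiles
through the monotone transform, so the reported OR is
`exp(median log OR)` and interval ordering is preserved.  Display
rounding is 2 decimals; JSON artifacts keep full precision.

## Significance classification

A factor is "significant" under a model iff its 95% CrI excludes zero
strictly; an interval touching zero exactly counts as not significant
(conservative closed-boundary convention — the source analyses are
silent on the boundary case).  The pipeline also reports the factors
significant under *every* fitted model; on the built-in dataset that set
is exactly {T substage}.

## Synthetic data generator

`simulate_table` is the generative twin of the fitted model: it draws
`theta_i` from `N(mu, D R_B D)`, within-study SEs log-uniformly over a
configurable range (default emulating the real table's heavy 0.02-1.3
spread), adds sampling error with within-study correlation `rho_W`, and
masks cells independently with per-factor reporting probabilities.
`table1_like_params` calibrates those probabilities to the observed
reporting fractions of the built-in dataset and sets `mu`/`tau` to its
DerSimonian-Laird estimates, so simulated tables match the real one in
size, sparsity pattern and effect scale.

What it does **not** emulate: selective reporting driven by the results
themselves (a `value_dependent` mode exists for sensitivity studies but
is off by default, because the fitting model assumes missingness at
random), patient-level 2x2 event counts, and time-to-event structure.
Passing recovery tests therefore demonstrate calibration *under the
model's own assumptions*, not robustness to informative reporting.

`recovery_experiment` runs simulate-and-refit replicates and reports
per-factor bias, RMSE and 95% CrI coverage.  The acceptance-level check
(200 replicates of a 20-study x 4-factor design with 85% cell reporting)
tests coverage pooled over factors against a 3-sigma binomial band
around 95%: per-factor binomial checks at 200 replicates reject a
perfectly calibrated method too often once several factors are examined
jointly, while the pooled count is the direct test of the stated
hypothesis.  Per-factor bias is tested against its own Monte Carlo
error, with a gross-failure floor on each factor's coverage.

## The built-in dataset and its known quirks

The curated table holds nine radiotherapy cohorts (2000-2023, 2527
patients) by 14 factors, 56 observed cells, transcribed exactly from the
published data table; log ORs that originated from adjusted multivariate
regressions were already excluded upstream, and contrast orientations
are recorded as published without re-signing.  Two documented quirks:

* the printed grid is ragged, and one cell (Bignardi 2004, `0.00 (0.02)`)
  is bound to tumor grading rather than age — the curated reading, which
  also keeps the age column at seven studies, consistent with the
  published per-factor study counts;
* the published multivariate fit quotes one study fewer than the printed
  table holds for six factors (ACI 8 vs 9, T substage 6 vs 7, RT
  technique, gender, smoking status, tumor grading) without identifying
  the dropped cells.  The table is kept as printed;
  `EffectTable.without_cells` supports exclusion experiments, and the
  acceptance tests bracket the ACI / T substage ambiguity by fitting all
  leave-one-out subsets.

The published *univariate* headline (OR 1.61, 95% CI 1.15-2.26,
I^2 34%, Z 2.78) was computed from per-study 2x2 event counts that were
never printed.  It is **not** recomputable from the effect table — the
DL pool of the tabulated ACI log ORs gives OR 1.32 with I^2 57% — and
the package makes no claim to reproduce it; `z_from_or_ci` confirms the
printed triplet is internally consistent (implied z 2.76 vs printed
2.78).

## Known limitations

* Model H/M0 medians are prior-sensitive in this data regime (9 studies,
  91 free correlations); with the original priors unpublished, exact
  agreement with the published Model H column cannot be expected, only
  agreement within a sensitivity band.  Notably, this implementation
  does not reproduce the published strong attenuation of the ACI effect
  under Model H (published median 0.05; here ~0.3-0.4, i.e. close to the
  Model U value) — the published behaviour evidently depends on prior or
  structural choices that were not reported.
* Odds ratios, not hazard ratios: no time-to-event information enters.
* No publication-bias machinery (the source evidence base reports none
  with a named method) and no frequentist multivariate (REML) fit.
* Single shared `rho_W`; pairwise within-study correlations are out of
  scope.
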