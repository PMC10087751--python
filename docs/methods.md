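# Methods

## The estimation problem

Given a bipartite network of recorded host–parasite associations, two
questions are asked. First, how many parasite species would be recorded if
every potential host species were sampled — that is, total richness
including species not yet described? Second, what fraction of that total
fauna is lost if a given fraction of the host pool goes extinct?

Both answers rest on one assumption: parasite richness scales with host
richness as a power law, `P = b·H^z` with `b > 0` and `z` typically in
`(0, 1]`. The exponent is an aggregate measure of host specificity: a fauna
of strict specialists accumulates linearly (`z = 1`), a fauna dominated by
widespread generalists saturates almost immediately (`z → 0`). The power
law is preferred over asymptotic richness curves here because host sharing
by generalists produces exactly this scale-free accumulation shape, and
because it extrapolates to a host pool larger than the sampled one without
committing to an asymptote.

## Accumulation bootstrap and fitting

For each parasite group separately:

1. Take the hosts with at least one record for that group (hosts without
   records stay in the registry — they define the extrapolation target
   `H_total`, not the fitting domain).
2. Draw `n_boot` independent uniform random permutations of those hosts.
   For each permutation record the cumulative number of distinct parasite
   species at every prefix length `h = 1..H_obs`. The expected value of
   this curve is exactly `E[P(h)] = Σ_p (1 − C(H−r_p, h)/C(H, h))` with
   `r_p` the parasite's host range; the package exposes this closed form
   (`expected_accumulation`) and the test suite checks the bootstrap
   against a subset-enumeration oracle.
3. Fit `P(h) = b·h^z` to each replicate curve by bounded nonlinear least
   squares (`b > 0`, `z ∈ [0, 2]`), initialised from the log–log
   least-squares line, with parameter tolerance `1e-8` and at most 500
   function evaluations. A perfectly flat curve is represented exactly as
   `(b = P, z = 0)` without optimisation. More than 10% non-convergent
   replicates aborts the fit.
4. Summarise with coordinate-wise medians `(b̂, ẑ)`; carry the full set of
   replicate pairs forward.

The `z` upper bound of 2 exists only to stop runaway exponents on tiny,
noisy curves; fitted values on real-shaped data sit well inside it.
Regions (US/Europe) are pooled for fitting: per-host richness is
statistically indistinguishable between them, and the descriptive module
lets users verify that on their own data before pooling.

## Extrapolation and uncertainty

Total richness per group is the median over replicates of `b_i·H_total^z_i`,
with a 2.5/97.5 percentile interval (standard linear-interpolation
percentiles). Species counts are rounded half away from zero; the
undescribed fraction is `100·(predicted − observed)/predicted` rounded to a
whole percent, clamped at 0 (with a warning) if the curve underpredicts the
observed count. Totals across groups are sums of *unrounded* group values —
rounding first and summing later produces visibly inconsistent tables.

The percentile interval quantifies ordering-and-fit uncertainty, which on
realistic networks dominates the generative (assignment) noise. Coverage of
the true generating richness is therefore conservative (the recovery
experiment below observes ~98%).

## Coextinction

Substituting a surviving host pool `(1−p)·H` into the power law and
dividing by total richness gives the expected proportion of parasites lost,

    loss(p) = 1 − (1 − p)^z,

independent of `b`, equal to `p` at `z = 1`, and convex for `z < 1`: loss
starts slow while generalists persist on remaining hosts, then accelerates.
The mean curve uses `ẑ`; bands evaluate the loss at the replicate `z` draws
and take nearest-outside 2.5/97.5 order statistics (so with very few
replicates the band is the replicate envelope, never narrower). Scenario
proportions come from the threat registry: `p = EN/(assessed hosts)` or
`(EN+TH)/(assessed hosts)`, where assessed excludes data-deficient and
not-evaluated hosts. Excluding unassessed hosts from the denominator makes
the scenarios conservative whenever unassessed species are
disproportionately threatened; a config switch (`include_unassessed`)
divides by the full pool instead. Absolute species losses multiply the loss
proportion by the unrounded predicted richness; totals are
prediction-weighted means across groups.

An independent Monte-Carlo check removes `round(p·H)` hosts uniformly at
random (by default from the full registry, matching the extrapolated
interpretation) and declares a parasite extinct when all its recorded hosts
are gone. On networks generated in the power-law regime the analytic curve
and the simulation agree within Monte-Carlo error; the closed form is never
replaced by the simulation.

Host loss is random-order by design. Threat-ordered removal would require
assuming threatened and non-threatened hosts accumulate parasites at
different rates, which the specialist-richness comparison
(`specialist_richness_by_threat`) lets users test; under threat assigned
independently of parasite load the test is null-distributed.

## Descriptive statistics

Marginal counts conserve totals (Σ per-host richness = Σ per-parasite host
range = number of association pairs). Group and region comparisons use the
Kruskal–Wallis rank test (midranks, standard tie correction, chi-square
upper tail with `k−1` degrees of freedom; an all-tied pooled sample returns
`H = 0, p = 1` by convention). The chi-square tail is an approximation: at
pooled `n ≤ 8` its error against the exact permutation distribution is
substantial (mean ≈ 0.1 for mid-range p at `n = 6..8`, measured in the test
suite against a full enumeration oracle); at the sample sizes this package
is meant for (dozens of taxa per group) it is accurate. Means are reported
with standard errors using the `n−1` standard deviation.

The observation-effort diagnostic regresses `log10(host range)` on
`log10(total observations)` across parasites (OLS, pointwise 95% band of
the mean line). Because every association carries at least one observation,
total observations can never fall below host range; `above_isometry` is
true when the whole band is strictly separated from the 1:1 line on the
repeat-observation side, the signature that parasites are re-observed
within hosts and hence reliably absent from unoccupied ones. Base-10 logs;
observations as the explanatory variable.

## Synthetic data generator

The generator emulates the features of a compiled association dataset that
the estimator relies on, with defaults shaped like the motivating system:
295 hosts of which 128 are sampled; 96 parasites split 5/25/58/8 across
aspidogastreans (geometric host ranges, mean 30 — broad generalists),
digeneans and ciliates (truncated zeta, α = 2 — median range 1), and mites
(truncated zeta, α = 1.5 — median range 2); mean observation effort 3 per
association; 26% of hosts endangered and 7% threatened, assigned
independently of parasite load; ~95% of hosts in the US region. Parasites
attach uniformly at random to the sampled-host subset, so sampling gaps are
represented as hosts with no records.

Observation counts are `1 + Poisson(effort_mean − 1)` (a mean-parameterised
choice; no dispersion information is assumed). Detection thinning drops
each association independently with probability `1 − detection_prob`,
except that every parasite keeps at least one association — observed
richness equals true richness by construction, only host ranges shrink.
This deliberate deviation from pure binomial thinning isolates the
missing-links effect: thinning makes observed faunas look more specialist
and steepens the fitted exponent, which the test suite verifies as a paired
sign test.

Randomness is split into independent streams (host labels, sampled subset,
range draws and assignment, effort) spawned from the single config seed, so
each stage is reproducible on its own.

### The power-law regime

For recovery experiments a host-range *distribution* is designed so that
the expected accumulation curve equals `b·h^z` exactly for a requested
exponent: the per-range presence probabilities `1 − C(H−r, h)/C(H, h)` form
a linear system in the range counts, solved by nonnegative least squares
(residuals are numerically zero for `z ∈ (0, 1]`), rounded to integers by
largest remainder. Each simulation then draws parasite ranges i.i.d. from
this distribution, so realizations scatter around the generating law the
way real faunas scatter around a regime. Pool sizes in the recovery tests
(100 parasites for `z = 0.2, 0.5`; 280 for `z = 0.8`) are chosen so the
mean network degree keeps essentially every sampled host occupied, because
accumulation is defined over hosts with records.

What passing these tests shows — and does not show: the estimator recovers
the exponent and covers the generating richness *when the power law is the
true data-generating process and hosts are exchangeable*. Real compiled
datasets violate exchangeability (sampling effort is uneven, hosts are
phylogenetically structured) and the generator does not model phylogeny,
geography, nestedness beyond the generalism knobs, or multi-host life
cycles; conclusions about those failure modes cannot be drawn from green
tests here.

## Numerical and reporting conventions

- Species counts: round half away from zero. Percentages of richness:
  whole numbers; scenario percentages: one decimal.
- Problem sizes used by the test suite: 10,000 bootstrap replicates for the
  expectation oracle on a 4-host fixture; 50 simulations per exponent with
  200 bootstrap replicates each for recovery; 10,000 Monte-Carlo removals
  for oracle equivalence; 10 paired simulations for the thinning sign test.
  These sizes put Monte-Carlo error well below each test's tolerance.
- Pipeline default `n_boot = 1000`; a seed is mandatory and every table is
  byte-reproducible under it. Exit codes: 0 success, 2 validation, 3
  computation, 4 configuration.
- Degenerate inputs: empty groups after filtering are skipped with a
  warning (absent from tables); an empty record set after filtering, or a
  registry with no assessed hosts, aborts with a computation error.

## Known limitations

- The power law is an assumption, not an inference; no model selection
  against asymptotic estimators (Chao, jackknife) is performed.
- Estimates inherit compilation biases of the input data: missing links
  bias `z` upward (overestimating richness), unobserved-parasite
  undersampling biases it downward, and the two do not cancel.
- The coextinction projection ignores minimum-host-density thresholds and
  multi-host (heteroxenous) life cycles, both of which would raise true
  extinction risk; it is a lower-bound-style projection under random host
  loss.
- Bootstrap-over-orderings CIs do not capture uncertainty in the compiled
  network itself (they condition on the observed links).
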