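# Methods

## Model

A trial under a Simon two-stage design `(r1, n1, rt, nt)` observes i.i.d.
Bernoulli(π) responses. Stage 1 enrolls `n1`; the trial stops (futility)
iff `X1 ≤ r1`; otherwise stage 2 enrolls a further `n2* ` patients —
planned `n2 = nt − n1`, but possibly different in the realized trial —
and the null `H0: π ≤ π0` is rejected at the end when the total responder
count exceeds `rt`. There is no early stop for efficacy, so stage-1
counts above `rt` still proceed to stage 2.

All inference runs over the sample space of the pair (stopping stage M,
cumulative responders S_M), which is complete and sufficient for π. Its
pmf is

- `m = 1`: `C(n1, s) π^s (1−π)^(n1−s)` for `0 ≤ s ≤ r1`;
- `m = 2`: `[Σ_x C(n1, x) C(n2*, s−x)] π^s (1−π)^(n1+n2*−s)` for
  `r1+1 ≤ s ≤ n1+n2*`, the sum over stage-1 counts
  `x` from `max(r1+1, s−n2*)` to `min(s, n1)`.

When the stage-2 size change is unrelated to the responses (the
*non-informative* case: funding, accrual, administration), this is the
conditional likelihood given `n2*` and all planned-design formulas apply
with `n2*` substituted for `n2`. Informative (outcome-adaptive) size
changes are out of scope: they would require the joint likelihood of the
size-determination mechanism.

## Estimators

**MLE** `S_M / N_M` — simple but biased under sequential stopping.

**UMVUE** — the ratio of binomial-coefficient sums given in the README;
`x1/n1` after a stage-1 stop. Numerator and denominator are exact Python
integers, reduced as a `Fraction` before conversion, so no cancellation
occurs even for totals in the hundreds. Exact unbiasedness for every
fixed `n2*` is verified in the tests by full-support enumeration of
E[π̃] − π (tolerance 1e-10).

## Likelihood-ratio (LR) ordering, mid-p and interval

Paths are ordered by `T(m, s, π0) = L(π̂; m, s) / L(π0; m, s)` with
`π̂ = s/n` the path's own MLE; larger `T` is stronger evidence against
π0 (in either direction — the ordering is two-sided). The mid-p value is

p(π0) = Σ_{T(path) > T(obs)} f(path | π0) + ½ f(obs | π0),

which offsets the conservatism of a discrete sample space. Conventions:

- all `T` comparisons in log space; two paths tie when their log-ratios
  agree to a relative tolerance of 1e-12;
- non-observed paths tied with the observed one contribute nothing (the
  formula is applied literally); an optional `symmetric_ties` mode adds
  half their mass instead, off by default;
- a stage-1 stop is ranked within the support enumerated at the planned
  `n2` (no stage-2 size was realized); an override parameter exists for
  evaluating the ordering at a hypothetical size.

The confidence interval is the acceptance region `{π0 : p(π0) ≥ α}` with
`α = 1 − level`. The region is bracketed on a 2001-point uniform grid of
π0 (augmented with the observed MLE, where p is large, so the region is
never missed) and each edge is refined by bisection to 1e-9. If the
region is non-contiguous — possible but rare with discrete orderings —
its convex hull is returned and a warning attached. Totality holds: every
support path, including `x1 > rt` and `x2 = 0`, has a p-value in (0, 1)
and an interval.

## Conditional (Koyama–Chen) method

The planned conditional rejection rate is
`A(x, n2, π) = P_π[X2 > rt − x | n2]`, identically 1 when `x > rt`. With
a deviated `n2*`: (a) solve `A(x1, n2, π*) = P_{π0}[X2 ≥ x2 | n2*]` for
π\*; (b) p-value = `Σ_{x>r1} P_{π0}[X1 = x | n1] A(x, n2, π*)`. Step (a)
is solved in closed form through the incomplete-beta quantile
(`A(x1, n2, π) = I_π(k+1, n2−k)`, `k = rt − x1`), with a log-space
asymptotic fallback (`A ≈ C(n2, k+1) π^(k+1)`) where the quantile routine
underflows. Replacing π0 by a generic π in both roles gives the p-value
function g(π), nondecreasing from 0 to 1; a coarse-grid monotonicity
guard runs before every inversion. The point estimate solves
`g = 1/2` (median-unbiased), the `1−α` interval solves `g = α/2` and
`g = 1 − α/2`, all by bracketed root finding to 1e-9.

Failure modes, surfaced rather than papered over:

- `x1 > rt`: `A ≡ 1`, π\* does not exist — `KCUndefinedError`;
- `x2 = 0`: the observed tail is identically 1, π\* = 1, and the p-value
  collapses to `P_{π0}[X1 > r1]`, independent of both `x1` and `n2*` —
  returned with an explicit warning;
- after a stage-1 stop the method reduces to the exact binomial analysis
  of `x1/n1`: the stage-1 tail p-value `P_{π0}[X1 ≥ x1]`, and
  Clopper–Pearson limits (the tie-free limit of the same inversion; the
  literal g-inversion is degenerate at `x1 = 0`).

With `n2* = n2` the conditional *decision* (reject iff the observed tail
is at most `A(x1, n2, π0)`) is exactly the design's threshold rule
`s > rt`; the conditional *p-value*, however, does not reduce to the
planned-design path-ordering p-value, because π\* calibrates the
conditional tails only at the observed `x1`. Tests assert the calibration
identity rather than a reduction that does not hold.

## UMVUE-ordering interval

The UMVUE also orders the sample space. The limits solve
`Pr(π̃(M, S_M) ≥ π̃_obs | π_L) = α/2` and the same at `1 − α/2` for π_U;
the tail is nondecreasing in π, so each root is unique (bisection,
tolerance 1e-9 in π). Ties in π̃ across distinct paths are real (exact
`Fraction` comparison is used) and are included in the event, as the
defining equations state. Boundary conventions: the minimum-ordering path
takes lower = 0, the maximum takes upper = 1; for the minimum path the
tie-inclusive upper equation is degenerate (the event is the whole
space), so the strict-inequality event is used there — for a stage-1 zero
count this reproduces the Clopper–Pearson upper limit.

## Design operating characteristics and search

Exact rejection probability
`Σ_{x>r1} P_π[X1 = x | n1] P_π[X2 > rt − x | n2]`, probability of early
termination `P_π[X1 ≤ r1]`, expected size `n1 + (1 − PET) n2`. Binomial
tails go through scipy's stable survival/CDF routines, and the pmf
assembles coefficients in log space, so nothing underflows for totals of
several hundred. `search_design` enumerates all `(r1, n1, rt, nt)` with
`nt ≤ n_max` meeting the (α, β) constraints, vectorized over boundaries
for each size pair; *optimal* minimizes the null expected size, *minimax*
the maximum size; ties break deterministically by smaller `nt`, then
`n1`, then `r1`.

## Simulation study

The generator emulates the published study conditions: a design's trials
are simulated at each true rate; continuing trials draw `n2*` uniformly
on the integers from `ceil(n2/3)` to `floor(1.5 n2)` (the stated range,
with ceil/floor resolving the non-integer endpoints inward) and then
`X2 ~ Bin(n2*, π)`. Defaults: 5000 replicates, 90% intervals, test level
`alpha_test = 0.05`. Per (rate, method) cell the study reports:

- mean CI width over trials reaching stage 2 (missing if none did);
- coverage and bias over *all* trials, including stage-1 stops;
- rejection rate at π0 ("actual power"): LR rejects when the mid-p value
  is ≤ `alpha_test`; the conditional method uses its conditional decision
  rule by default (`kc_power_rule="conditional"`), with a p-value-based
  alternative (`"pvalue"`) available — the published table cells pin down
  neither rule unambiguously;
- counts of stage-2 trials and of conditional-method failures
  (`x1 > rt`), which are excluded from that method's coverage/bias/width
  denominators since it offers no answer for them.

One root seed drives everything; each rate gets a deterministic
substream, and all methods see identical trials, so reruns are
byte-identical. Per-outcome inference is cached by the sufficient
statistics, so cost scales with distinct outcomes, not replicates. For
small designs the exact CI coverage is also computable by enumerating
every (path, `n2*`) combination (`exact_lr_coverage`), and the Monte
Carlo estimate is tested against it.

What the generator does *not* emulate: informative size changes,
stage-1 size deviations, over-/under-dispersion relative to the binomial,
and any patient-level covariate structure. Passing tests therefore speak
to the correctness of the exact computations under the stated sampling
model, not to robustness against violations of it.

## Problem sizes and numerical choices

The test suite runs the full simulation cells it needs at 5000 replicates
for the two headline cells and 1000 replicates for the bias-trend
comparison across four designs — sizes chosen so the whole suite
completes in a few minutes while keeping Monte Carlo standard errors well
inside the tolerances being asserted. Root-finding tolerances are 1e-9
in π throughout; acceptance-region grids use 2001 points; reported values
are rounded to 2–3 decimals only at the presentation layer.

## Known limitations

- The acceptance-region interval returns a convex hull when the region is
  non-contiguous; the event is flagged but the reported interval is then
  conservative.
- The conditional method's simulated "power" depends on an unresolvable
  convention choice (decision rule vs p-value threshold); both are
  implemented and the choice is explicit in the configuration.
- Mean interval widths under deviation depend on fine conventions of the
  width averaging population; they are reported but should be compared
  across methods within a run, not against external tables digit by
  digit.
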