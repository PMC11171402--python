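# Methods

## Model

Behavior within an observation session is modelled as a time-homogeneous
first-order Markov chain over the N states of an ethogram: the state
variable X_n is the n-th scored behavior pattern, and

    p_ij = P(X_{n+1} = E_j | X_n = E_i)

is estimated by maximum likelihood as the row-normalized transition-count
table, pooling adjacent pairs over sessions. The model is event-indexed:
observation times order the records but inter-event durations are not
modelled (no dwell-time or continuous-time component).

Assumptions and conventions:

- **No self-transitions.** Consecutive identical records are collapsed by
  default, so only changes of behavior count. The built-in *L. vannamei*
  matrix has an empty diagonal, and the estimator treats the diagonal as
  structurally forbidden whenever no self-transition was observed (a flag
  overrides this for ethograms where self-transitions are meaningful).
- **Sessions are independent realizations.** Transitions never span
  session boundaries, and the bootstrap resamples whole sessions.
- **Canonical order.** States keep the order of the published
  next-behavior table so matrices can be compared cell-by-cell; internal
  values are proportions in [0, 1], and rendering to "table style"
  multiplies by 100 and rounds half-even to 2 decimals.
- **Undefined rows are explicit.** A source behavior never observed yields
  a NaN row rather than a silently uniform one; an optional pseudocount
  a ≥ 0 (added only to structurally allowed cells, so smoothing can never
  create self-transitions) produces a fully defined chain when needed.

Stage aggregation sums each row over the stage membership of the target
states. Because this is a fixed linear map of the rows, it commutes with
row normalization — aggregating counts and then normalizing equals
normalizing and then aggregating — which the test suite checks on random
count matrices.

## Built-in ethogram and matrix

The packaged ethogram has nine states in three fighting stages: encounter
(parade, demonstration), contact (attack, fight, chase, impact, feint),
withdrawal (temporary retreat, retreat). The packaged transition matrix is
stored as printed percents (two decimals, each row totalling 100.00; empty
cells are exact zeros, 20 nonzero cells) and divided by 100 on load. The
chain is irreducible and aperiodic (it contains cycles of length 2 and 5),
so the stationary distribution exists and is unique; its smallest entry is
temporary retreat at ≈ 0.7% long-run occupancy, which drives several
sample-size choices below.

## Markov dynamics

- **Simulation** draws X_0 from the initial distribution and each
  successor from the current row via inverse-CDF sampling on a
  `numpy.random.Generator`. `simulate(chain, n_steps, seed)` returns
  `n_steps` states (`n_steps − 1` transitions); the same seed gives the
  same sequence. Child streams (sessions, bootstrap replicates) are
  derived with `SeedSequence.spawn`, so results do not depend on execution
  order.
- **Stationary distribution** solves the balance equations πP = π with the
  normalization constraint by least squares, clips negative round-off and
  renormalizes, and reports the max-norm residual ‖πP − π‖∞ (required
  < 1e-8; in practice ~1e-16 for the built-in chain). Reducible chains are
  rejected with the offending communicating class named (strongly
  connected components of the support graph). Periodic chains are
  accepted; π is then long-run occupancy, not a limiting distribution. The
  test suite validates the solver against an independent power-iteration
  oracle.
- **Log-likelihood** is Σ log p(X_{n+1}|X_n), plus log initial(X_0) when an
  initial distribution is supplied; a structurally forbidden step yields
  −inf rather than an error.

## G-test of sequential dependence

The first-order model is compared against the zero-order null in which
each next state is an independent draw from the pooled next-state
frequencies. Expected counts are row margin × column frequency,
G = 2 Σ O log(O/E), and p comes from the χ² upper tail. Degrees of freedom
follow likelihood-ratio parameter accounting: Σ over supported rows of
(allowed, supported columns − 1), minus the (supported columns − 1)
parameters of the null; on a complete table this is the classical
(r−1)(c−1). With a structurally empty diagonal the χ² reference is an
approximation (the no-self null is not exactly of product form); the
nominal type-I error of the test is therefore validated by Monte Carlo
under an iid null *without* structural zeros (2,000 replicates of a
400-event, 3-state sequence; the rejection rate at α = 0.05 must fall
within 3 Monte-Carlo standard errors of 0.05). The G statistic was chosen
over Pearson χ² for its additivity over cells, and structural zeros are
simply never counted as parameters.

## Bootstrap

Percentile bootstrap over whole sessions: B resampled datasets, each the
same number of sessions drawn with replacement, re-estimated and reduced
to cell-wise percentile bounds. Cells whose source row is unobserved in a
replicate are skipped for that replicate. Coverage is validated on a
3-state chain with known truth (500 datasets, 150 sessions of 30 events,
B = 300): percentile intervals are asymptotic in the number of resampled
*units*, so the design uses many short sessions; with few sessions (tens)
the intervals visibly undercover (~0.92 at 40 sessions in our
experiments), which is inherent to the percentile method, not a defect of
the estimator.

## Synthetic data

The generator emulates a scored-video study: `n_sessions` independent
sequences from a configured chain, fixed or uniformly ranged lengths,
strictly increasing times from unit-exponential gaps (an arbitrary,
documented choice — only ordering matters downstream), and optional
per-record dropout applied after simulation. What it does **not** emulate:
dyadic structure (who fights whom), body-size/RHP asymmetries,
winner–loser effects, time-of-day rhythms, or scorer disagreement beyond
record dropout. Passing recovery tests therefore show the estimator is
correct for the assumed generating process, not that real shrimp scoring
meets those assumptions. Dropout deliberately violates the model: deleting
a record can splice unrelated neighbors into a spurious transition (or
merge a run), so recovery reports flag dropout runs as having inflated
error instead of asserting recovery.

## Problem sizes and numerical choices

- Matrix-recovery checks simulate ~1,000,000 transitions so that the 0.02
  max-abs-error tolerance exceeds three binomial standard errors even for
  the temporary-retreat row (≈ 0.7% occupancy → ≈ 7,000 visits); at
  50,000 transitions that row alone has SE ≈ 0.026 and a fixed tolerance
  of 0.02 would fail by chance alone.
- The headline simulation (impact→retreat) runs the chain in chunks until
  the impact state has been exited ≥ 100,000 times; the conditional exit
  distribution is independent of the restart distribution, so chunked
  restarts introduce no bias.
- Row-stochasticity is enforced within 1e-9; matrix powers are
  renormalized after `matrix_power` to absorb float drift; printed-percent
  inputs whose rows total 100.00 are renormalized exactly on load.
- Diagram edge thickness uses penwidth = 0.5 + 4·p (p = 1 → 4.5), stated
  here so renders are reproducible; self-loops are structurally absent and
  never drawn.

## ΔΔCt

Livak's method with arithmetic-mean ΔCt aggregation within groups:
ΔCt = Ct(target) − Ct(reference) per sample, ΔΔCt = mean ΔCt(treated) −
mean ΔCt(control), fold change = 2^−ΔΔCt. Per-replicate fold changes
reference each treated sample to the control-group mean, so their
geometric mean equals the summary exactly. Fold change is invariant to
adding a constant to all Ct values of a sample, and log2 fold change is
antisymmetric under swapping the groups. Primer-efficiency correction is
out of scope, and real Ct tables for the motivating study are not
published, so tests use synthetic tables with a documented layout (one
target + one reference Ct per biological replicate, both groups).

## Known limitations

- First-order and time-homogeneous only; no higher-order, variable-order,
  hidden-state, or duration modelling.
- The transition-count totals behind the built-in matrix are not public,
  so cell-level uncertainty for the published chain cannot be
  reconstructed; bootstrap output on synthetic data is illustrative.
- The event-log schema carries an optional `subject_id`, but whether the
  original scoring unit was an individual or an arena-level bout is
  unknown; the analysis treats the session as the independent unit either
  way.
- The χ² reference for the order test is approximate under structural
  zeros (see above).
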