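# Methods

## The problem

A growing data repository — a mouse-knockout phenotyping database, a
chemical–genetic screening collection — accumulates hypothesis tests over
time. Each upload produces p-values that must be judged immediately, without
knowing the future p-values or even how many tests will ever be run, and a
decision, once published, must not change. Classical FDR procedures
(Benjamini–Hochberg) need the whole p-value family at once, so they either
cannot be applied or force past decisions to be revised on every re-analysis.
Online FDR procedures solve this: the adjusted significance threshold
`alpha_i` for test `i` is a function of past decisions only, and
`H_i` is rejected when `p_i <= alpha_i`. The FDR — the expected fraction of
rejections that are false — is controlled over the whole (unbounded) family.

## Procedures

All rules consume a *spending sequence* `gamma_1, gamma_2, ...`: non-negative
weights with `sum <= 1` that meter how the error budget is spread over future
tests. Writing `tau_1 < tau_2 < ...` for discovery times, `D(i)` for the
discovery count among the first `i` tests, `w0` for the initial alpha-wealth
and `b0 = alpha - w0` for the payout per discovery:

| rule | threshold `alpha_i` | validity |
|---|---|---|
| alpha-spending | `alpha * gamma_i` | any dependence (controls FWER) |
| LOND | `alpha * gamma_i * (D(i-1) + 1)` | independent p-values |
| LOND (dependent) | same, with `gamma_j / H(j)` | any dependence |
| LORD 1 | `gamma_i * w0`, then `gamma_{i-tau(i)} * b0` | independent |
| LORD 2 | `gamma_i * w0 + b0 * sum_j gamma_{i-tau_j}` | independent |
| LORD++ | LORD 2 with payout `alpha` from the 2nd discovery on | independent |
| LORD 3 | `gamma_{i-tau(i)} * W(tau(i))`, `W(t) = W(t-1) - alpha_t + b0*R_t` | empirical only |
| LORD (dependent) | LORD 2 recursion with the `dependent_default` sequence | see caveat |

`H(j)` is the j-th harmonic number and `tau(i)` the most recent discovery
before `i` (0 if none). Gap indices are 1-based in test counts: the test
immediately after a discovery reads `gamma_1`.

LORD 3's FDR control has only been demonstrated empirically; the
implementation carries this warning in its docstring but no code difference.
The dependent LORD variant implemented here is the LORD 2 recursion run with
the heavier-tailed `dependent_default` sequence; this follows the convention
of existing implementations rather than a derivation, and is flagged as such.
Which real-world dependence structures actually inflate the FDR of the
independence-based rules is an open research question.

Rejection is non-strict (`p <= alpha_i`). p-values exactly 0 or 1 are legal;
missing values are an error, never dropped — online FDR control assumes
*all* p-values of the family are analysed. The fixed-threshold benchmark
alone uses strict `p < threshold`, matching the database convention it
emulates.

## Spending-sequence defaults

- `lord_default`: `gamma_j = c * log(max(j,2)) / (j * exp(sqrt(log j)))`.
- `dependent_default`: `gamma_j = c~ / (j * log(max(j,2))^3)`.

The constants normalize the infinite series to exactly 1. They are computed
at first use, not hard-coded: a direct partial sum of 4,000,000 terms (numpy
pairwise summation) plus the closed-form integral of the term function from
`N + 1/2` to infinity — the midpoint Euler–Maclaurin remainder. Both series
decay too slowly for naive truncation (over a third of the `lord_default`
mass lies beyond 10^7 terms), but the remainder integral is exact, leaving a
truncation error below 1e-12. The computed values,
`c = 0.079081966722115` and `c~ = 0.197290520655319`, are stable to 12+
digits when `N` is varied over 1e5–2e7 and are cross-checked in the test
suite against an independent `math.fsum` + adaptive-quadrature oracle to six
significant figures. The computed constant is logged at first use for
auditability. (Some published implementations hard-code `c = 0.07720838`,
under which the series sums to about 0.976 rather than 1; both choices keep
the budget `sum(gamma) <= 1` and thus the FDR guarantee — ours spends the
budget exactly.)

User sequences longer than the stream are truncated at use time; shorter
ones are an error rather than being zero-padded, because silent zero
thresholds would kill power with no warning.

## Streaming engine

`step(state, p, config)` advances a `WealthState` (tests seen, current
wealth, discovery times) one test at a time; the batch functions fold the
same threshold formula over the stream, so streaming and batch outputs are
bit-identical — this is asserted, per variant, in the tests. Thresholds are
computed from the state *before* the p-value is examined, which is what
makes the rules online and prefix-invariant: running on `p_1..k` and on
`p_1..n` gives identical outputs for `i <= k`.

LORD 2/LORD++ thresholds are computed by direct summation over past
discovery gaps — O(n·D) worst case. Correctness and auditability were
preferred over micro-optimization; at the problem sizes of the simulation
harness (streams of 1000, ~10^2 discoveries) a full 2000-replicate
experiment over six procedures runs in seconds.

Dominance invariants (LORD++ >= LORD2 >= LORD1, LOND >= alpha-spending,
pointwise on a common stream) are asserted with tolerance 1e-12 to absorb
summation-order noise; wealth is required to stay above -1e-12.

## Repository wrapper

`order_stream` sorts records by calendar date (day granularity; finer ties
are one batch) and randomizes within each date batch, because the
independence-based rules require within-batch order to be random or fixed by
independent information. The permutation for a batch is drawn from an RNG
keyed by `(seed, batch date)` **only**. This per-batch seeding is the one
design under which "previous results remain the same" survives appends: a
single global RNG would reshuffle history whenever the record count grows.
Records carrying an explicit `order` value bypass randomization (the
independent-information alternative); a batch must use one mechanism or the
other for all its records.

`update_repository` enforces finality: previously analysed records must
reappear unchanged (same date, same p-value), and new records must be dated
strictly after the last analysed batch — a same-date append would reopen a
finalized batch, so it is rejected rather than silently merged. The update
recomputes the whole stream from scratch and verifies the prefix
bit-for-bit against the stored results instead of trusting stored state;
results are written with 17-significant-digit floats and re-read with
round-trip parsing precisely so this equality is exact across save/load.

## Simulation harness

`simulate_stream` draws the standard two-groups model: each hypothesis is
non-null independently with probability `pi1`; the statistic is `N(0,1)`
under the null and `N(mu,1)` under the alternative; the one-sided p-value is
`1 - Phi(Z)`. Defaults `n = 1000`, `pi1 = 0.1`, `mu = 3` give alternatives
that are detectable but not trivial (a z-shift of 3 is ~85% marginal power
at p < 0.05), a realistic regime for screening repositories. Replicates use
RNG substreams spawned deterministically from the model seed, so results are
bit-reproducible and independent of evaluation order.

The false discovery proportion of a replicate is
`(# rejected nulls) / max(# rejections, 1)` — zero when nothing is rejected,
the convention under which FDR is the FDP's expectation. The headline
experiment (2000 replicates, six procedures at nominal level 5%) confirms
every procedure's Monte-Carlo FDR stays below `0.05 + 3·SE`; with
`track_time=True` the harness also returns the FDR of every time prefix,
showing control holds over time, not just at the stream's end.

What the generator does **not** emulate: dependent p-values (no
autocorrelation or factor structure), composite or conservative nulls,
heterogeneous effect sizes, and batch-correlated uploads. Passing the
simulation suite therefore certifies the implementation of the rules and
their guarantees under independence — it does not certify FDR control of
the independence-based rules on arbitrarily dependent real data, which is
exactly why the dependence-safe variants exist.

## Numerical and design choices

- Non-strict rejection (`p <= alpha_i`) throughout the online rules; strict
  `<` only in the fixed-threshold benchmark. The asymmetry is deliberate and
  documented where it occurs.
- Default `w0 = alpha / 10`, exposed in `ProcedureConfig`.
- Thresholds are reported at full precision; no rounding anywhere in outputs.
- BH/BY use non-strict step-up comparison on a stable sort; tied p-values
  share a fate by construction. BY is BH at level `alpha / H(m)`.
- Degenerate inputs: empty record lists yield empty results with metadata;
  a one-element spending sequence `(1.0)` spends everything on the first
  test and errors (sequence too short) on the second.
- The simulation's generative settings are exposed as configuration, not
  constants, so any published setting can be reproduced by passing it in.

## Known limitations

- No FDX (false-discovery-exceedance) control, no adaptive/decaying-memory
  rules beyond LORD++, no asynchronous-decision procedures.
- The repository wrapper is files-in/files-out; no service mode, no
  database backends.
- Dependent-stream simulation is out of scope; only the dependence-safe
  procedure variants are provided, not a verification of their power.
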