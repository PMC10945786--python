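# Methods

## Model summary

`bondsim` simulates the evolution of helping mediated by dyadic social
bonds. The population is partitioned into fixed-size groups of `N`
individuals; a group has `K` subgroups ("places") with expected occupancy
`G = N/K`. A day runs: subgroup choice → association update → foraging →
help requests and donations → subgroup-estimate update → mortality →
(every `T` days) replacement of the dead. All state advances through a
single `numpy` random generator, so a run is a pure function of
`(config, seed)`.

The behavioural core is the effective bond strength `y_ij = ρ_ij · x_ij`:
a learned bond `x` (Rescorla–Wagner-style saturating update, both
directions of a pair updating after every donation with their own
learning rates) discounted by an exponentially tracked co-roosting
frequency `ρ`. `y` enters three places: soft-max partner choice
(`P ∝ exp(y)`), soft-max subgroup choice (`P ∝ exp(β ŷ_k)`, mixed with an
`ε_p` uniform exploration term), and the steep logistic donation gate
`H_y`. Donations are scaled by `H_w`, which carries the heritable
asymptote `h_a`, the quality factor `g_0 + (1−g_0)q`, and a logistic in
`h_s w + b z + c ζ` — the pairwise balance `w` (reciprocity enforcement),
the donor's foraging success `z`, and its current resource balance `ζ`.
Mortality is a declining logistic in `a + b z + c ζ` with floor `μ_0`.

## Parameters

Printed model constants (defaults): `x_s = 1.25`, `d = 8`, `y_0 = 1.5`,
`g_0 = 0.75`, `a = 2`, `b = 4.5`, `c = 3`, `μ_0 = 0.002`, `ε_p = 0.05`,
`T = 20` days, two asks per needy individual per day.

Calibrated constants (not printed anywhere; declared here once and
config-overridable):

* `x_a = 2.5` — places the gate midpoint `y_0 = 1.5` strictly inside the
  reachable range of `y ∈ [0, x_a]`, so bonds can both open and shut the
  gate.
* `λ_ρ = 0.1`/day — association reaches ~0.9 after three weeks of daily
  co-roosting; also reused as the EMA rate for the subgroup estimates `ŷ`
  (one fewer free constant).
* `p_d = 0.9` — detection of foraging success; failures are never
  mistaken for successes (no false positives, which would introduce an
  extra unprinted parameter).
* quality `q ~ Beta(4, 4)`: symmetric on [0, 1] with mean 1/2.
* `p_s(q) = 0.8 + 0.2 q` — the mean-quality individual fails one night in
  ten.
* `ζ_0(q) = 0.6 q` — fixed by requiring the marginal benefit–cost ratios
  of a transfer between average-quality individuals to be ≈80 as `u → 0`
  and ≈8 at `u = 0.4`. Verified against the closed-form
  `∂μ/∂ζ = −(1−μ_0) c e^s/(1+e^s)²` before the engine was wired: the
  slope 0.6 gives 80.97 and 7.93.
* trait bounds `α ∈ [0,5]`, `β ∈ [−20,20]`, `Δy_new ∈ [−5,5]`,
  `h_a ∈ [0,1]`, `h_s ∈ [−20,20]`; mutation probability `m = 0.02` per
  locus with Laplace scale 2% of each bound width; founders start
  helping-naive (`α = 0.5`, `h_a = 0.2`, others 0) with one
  mutation-scale Laplace jitter.

## Numerical and scheduling choices

* Eq.-style bond updates are clamped at `x_a` (a large `α·u` would
  overshoot the asymptote).
* `ρ` starts at 0 for fresh pairs; new-partner generosity is carried
  entirely by the heritable increment `Δy_new`, applied on a donor's
  first donation to a recipient and, on the asker side, toward candidates
  the asker has never received from.
* Requesters are processed in a freshly randomised order each day;
  donations use the donor's *current* (mid-day) `ζ`, so a generous donor
  automatically throttles later gifts the same day.
* Both asks happen unconditionally; a donor may serve several requesters.
* Deaths are drawn after all transfers from end-of-day state; memories of
  a dead partner are discarded (lifetime summaries are folded into the
  dissolving pair's records first); newborns fill the vacated slots at
  the next `T`-day replacement, with parents drawn uniformly from the
  global living population.
* Soft-max draws subtract the maximum value before exponentiating; the
  subgroup rule's exploration term bounds every choice probability inside
  `[ε_p/K, 1 − ε_p(K−1)/K]`.
* An optional crowding penalty `exp(−κ·max(0, n_k − G)/G)` on subgroup
  weights (computed from the previous day's occupancy) exists as a hook;
  `κ = 0` by default, so the printed two-subgroup choice formula holds
  exactly.
* The generalized-reciprocity variant pools each individual's bond and
  balance over "anyone in the group" (`ρ ≡ 1`) and makes partner choice
  uniform over perceived successes; per-pair machinery is bypassed.

## What the statistics mean

* **Reciprocity correlation**: partnerships are aggregated from the
  transfer log; over pairs with helping at least once in each direction,
  the Spearman correlation between totals donated and received is
  computed from both members' perspectives (the statistic is symmetric in
  pair orientation). Both the all-pairs value and a 1,000-partnership
  subsample value are reported.
* **Lifetime summaries** use 20 equal-width lifespan bins (binned means in
  place of kernel smoothing); only monotonicity/proportionality is
  asserted, not curve shape.
* **Association distributions** compare `ρ` for random same-subgroup
  pairs (periodic survey), pairs at helping moments, and helping moments
  between established (bidirectional-history) partners.
* **Return probability** is the per-individual fraction of consecutive
  day-pairs spent in the same subgroup.

## Problem sizes used by the tests and acceptance script

Desk-scale runs stand in for the full-scale study (population 4,000–4,200
for tens of thousands of days):

* ecological reciprocity run: 25 groups of 24 (`K = 6`), 2,000 recorded
  days after a 500-day warm-up, evolution frozen at evolved trait values
  (`α = 1.2`, `β = 7.9`, `Δy_new = 2`, `h_a = 0.49`, `h_s = 4.5`).
* directional-evolution checks: 10–240 groups for 12,000–60,000 days.
  From the helping-naive founders the helping transition does not occur
  on desk-scale budgets when `G < N` (with `β ≈ 0` the association
  `ρ ≈ 1/K` keeps the `H_y` gate effectively shut, so `h_a` is nearly
  neutral and the co-evolutionary bootstrap of `β`, `Δy_new` and `h_a` is
  far slower than any run we can afford); the checks therefore probe the
  *direction of selection* at the relevant neighborhood sizes. From the
  evolved trait state, `N = 24, K = 6` (20 groups, 12k days) holds
  helping in place while `N = 24, K = 1` (10 groups, 60k days) erodes it
  steadily (≈0.002 of `h_a` per thousand days); the generalized-
  reciprocity runs evolve from naive founders for 40k days (10 groups of
  24 vs 24 groups of 8); the pair-group reciprocity contrast uses 240
  groups of 2 for 60k days. Selection differentials here are small, so
  the *equilibrium endpoints* of the slow-collapse cases lie beyond
  these run lengths; the corresponding endpoint assertions document that
  gap rather than hide it.

## Limitations

* The unprinted calibrations above shape quantitative outcomes; the
  reciprocity correlation of the scaled ecological run lands around
  0.6–0.65 rather than the high-0.7s, which we attribute to these
  calibrations rather than the bond mechanism itself (the qualitative
  loose-reciprocity pattern is robust).
* The synthetic world omits: sexes and kin structure (by design — parents
  are drawn globally), seasonality, spatial structure beyond subgroups,
  partner death awareness beyond memory discard, and any begging/signal
  layer. Passing tests demonstrate the mechanism's internal logic and its
  selection-direction consequences, not fidelity to any particular field
  system.
* The between-group "visitor" variant is not implemented; the variant
  enumeration leaves room for it.
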