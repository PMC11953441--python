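# Methods

## Scope and data model

The package operates on undirected weighted contact graphs *G(V, E, W)*
whose weights are either total contact durations in seconds (derived from
timestamped proximity records) or 4-level ordinal durations. Proximity
records follow the badge-deployment convention: one record `t i j` means
the pair was in contact during the 20-second window ending at `t`.

## Sessionization and edge weighting

Records of one pair are merged into sessions wherever consecutive
timestamps differ by at most `max_gap` (default = the sampling interval
Δ = 20 s; exposed because real deployments drop pings). A session over
ticks *t₁ < … < tₙ* is taken to span *(t₁ − Δ, tₙ]*, duration
*tₙ − t₁ + Δ*: each record attests contact during the *preceding* window,
so an isolated record contributes Δ seconds rather than zero. The
alternative convention (*st = t₁*, singleton sessions vanish) is available
via `isolated_zero=True`; which of the two a given upstream pipeline used
is rarely documented, so both are first-class. The edge weight is the sum
of session durations; pairs with zero total weight produce no edge.

Column order is never auto-detected — `tij` vs `ijt` must be stated —
because the two layouts are not reliably distinguishable on small files.
Timestamps must be integers; non-integer timestamps are rejected rather
than silently rounded. Ordinal thresholds (300/900/3600 s) are left-closed
on the upper category: exactly 5 minutes maps to level 2. The category
boundaries overlap in their usual verbal statement, so the tie direction is
a documented convention, tested at the boundaries.

## The RWInf score

`RWInf(v) = ld(v) · smlI(v)` combines a clustering-aware local size with a
distance-discounted global influence sum. Two numerical decisions:

- **Contact distance is the unweighted hop count.** The defining sum
  divides neighborhood influence by the number of contact "levels"
  separating two individuals; integer hop counts are the reading consistent
  with the published worked computation (all denominators are 1–4), and a
  duration-weighted path length would perversely penalize strong ties. A
  `distance="weighted-inverse"` mode (Dijkstra on lengths 1/W) is provided
  for sensitivity analysis.
- **Unreachable nodes contribute zero** to smlI (1/∞); contact networks
  are typically connected, so this only matters for fragmentary inputs.

Degree and triangle counts use the unweighted skeleton. The `+1` in
`ld = (tri + 1)·k` keeps triangle-free nodes ranked by degree instead of
collapsing to zero. Isolated nodes score 0 on every quantity.

Ranking uses competition ("1224") ranking with ties broken by node
identifier, so rankings are deterministic even when scores tie.

## Baseline indices

Eight comparison indices are implemented behind one dispatch surface.
Structural tunables default to 0.5 (ksd^w's α₁/μ₁, ngsc's t₁/t₂): their
originating studies tuned them per-network against the giant component by
procedures not stated precisely enough to reproduce, and 0.5 is the
midpoint of their admissible range. W_k-shell uses α₁ = β₁ = 1 as in its
source. Since the weighted degree k′ is real-valued, it is rounded to the
nearest integer before shell peeling (configurable rounding).

The HIC edge weight needs a "k-shell iteration factor" whose defining
formula is not published in the primary description; we adopt
`I(v) = ks(v) · (1 + n(v)/m)` from the HIC literature, with `n(v)` the
pruning round at which `v` was removed and `m` the total number of rounds.
It is isolated in one function so an alternative definition is a one-line
swap. A pruning round removes every node whose current degree is at or
below the running shell threshold; the threshold never decreases.

Weighted betweenness and closeness interpret durations as tie strengths:
edge length 1/W (strong ties are short). A `raw_weight` mode treats
weights as costs instead. Closeness is the plain reciprocal of summed
distances (no (n−1) normalization), computed per component on disconnected
graphs; isolated nodes score 0.

## SIR ground truth

Synchronous discrete-time SIR: at each step every infected node infects
each susceptible neighbor independently with probability β, then recovers
with probability λ (default 1, so nodes transmit for exactly one step); a
node infected at step *t* first transmits at *t* + 1. A node's spreading
capability is the mean count of ever-infected individuals over `runs`
independent realizations (default 1000) seeded at that node.

Transmission ignores edge weights by default: the SIR score serves as a
method-agnostic ground truth, and the threshold heuristic β_th ≈ ⟨k⟩/⟨k²⟩
is an unweighted-network result. A weighted mode with per-contact
probability 1 − (1 − β)^(W/Δ) is available for sensitivity studies.

Randomness: one root seed; each seed node draws from a substream derived
from (seed, node index), so per-node scores are independent of evaluation
order and bitwise reproducible.

## Evaluation

Kendall's τ uses the tie-corrected τ-b variant (both SIR means and index
scores carry ties); it is computed on raw scores, which is equivalent to
computing it on ranks. A fully tied vector carries no rank information and
is scored τ = 0. The β grid is β_th + 0.01·i for i = 1..iter (default 15),
values above 1 clamped out with a warning; an `absolute` grid mode
(0.01..0.01·iter) covers the alternative fixed-range protocol seen in
summary tables. σ(τ) is the plain mean of the per-β τ values.
Monotonicity M(I) = [1 − Σ Vᵢ(Vᵢ−1)/(V(V−1))]², with Vᵢ the tie-group
sizes. The improvement percentage η divides the τ difference by |τ| of the
comparator, signed so that positive η always means the reference index is
closer to the SIR ranking, and is defined as 0 when the comparator's τ is 0.

Graph summaries (diameter, mean path length) are computed on the largest
connected component with a warning when the graph is disconnected.

## Synthetic data generator

The stream generator emulates the *structure* of badge data — per-pair
sessions arriving as a Poisson process (default 0.2 sessions/pair/hour over
an 8-hour horizon, 20-person default), geometric session lengths (mean 3
ticks = 60 s), one record per Δ-tick per active session — with session
starts snapped to the tick grid and a minimum 2-tick gap between a pair's
sessions. The snapping makes sessionization *exactly* invertible, so
pipeline tests assert equality with the generator's recorded ground truth
rather than approximate agreement. Random weighted graphs use
Erdős–Rényi/Barabási–Albert/ring topologies with lognormal(μ=4, σ=1)
weights (seconds), a heavy-tailed shape typical of contact durations.

What the generator does **not** emulate: empirical degree and duration
distributions of real deployments, circadian/schedule structure, repeated
daily contacts, or sensor noise (missed and spurious pings beyond the gap
tolerance). Passing tests therefore demonstrate correctness of the
computations, not predictive performance on real contact data.

## Problem sizes and tolerances

Tests compare against brute-force oracles exactly (or at absolute
tolerance 1e−9 for floating accumulations); the published toy-network
values are asserted at their printed 3-decimal rounding (±0.001 on smlI,
±0.05 on the product). Monte-Carlo assertions use 3 standard errors at
10,000 runs for closed-form comparisons and smaller run counts (30–200)
where only determinism or ranges are asserted. Oracle sweeps use ≥200
random graphs of ≤8 nodes — small enough for exhaustive path enumeration,
large enough in number to exercise disconnected, tied and degenerate
cases. Evaluation examples in the test suite use 12–30-node graphs so the
full 9-index pipeline runs in seconds.

## Known limitations

- Session-boundary conventions in upstream deployments vary; only the two
  conventions above are supported.
- The HIC iteration factor and the structural baselines' tunables are
  literature-informed assumptions, not reproductions of any one study's
  settings.
- No continuous-time (Gillespie) dynamics, no SEIR/SIS variants, no
  intervention simulation.
- No incremental recomputation: every score is computed from scratch per
  graph.
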