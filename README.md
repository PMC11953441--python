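# rwinf

Identifying superspreading individuals in human contact networks from the
*duration* of their contacts.

Proximity-sensor deployments (conference badges, school and workplace
studies) record a line `t i j` whenever individuals `i` and `j` were
face-to-face during the 20-second sampling window ending at `t`. Most
spreader-ranking indices either ignore edge weights entirely or derive them
from topology (degree, k-shell) — discarding the one quantity that most
directly drives transmission risk: how long two people were actually
together. This package builds contact-duration edge weights from raw
proximity streams, computes the **RWInf** (Real Weighted Influence) score on
the resulting weighted graph, and evaluates it — against eight baseline
weighted-network indices — using SIR epidemic simulations as ground truth.

It is aimed at epidemiological modellers and network scientists working
with SocioPatterns-style contact data.

## The method

**Edge weights.** Consecutive contact records of a pair with gaps of at
most *g* seconds (default one sampling interval, Δ = 20 s) are merged into
sessions; a session over ticks *t₁ < … < tₙ* spans *(t₁ − Δ, tₙ]*. The edge
weight is the pair's total session time,

    W_uv = Σ_sessions (et − st)   [seconds].

**The RWInf score.** For a weighted graph *G(V, E, W)*:

- *neighborhood weighted influence* — `nwI(v) = Σ_{u∈N(v)} W_vu`
  (single-level, local);
- *contact distance* — `cd(v,u)`, the shortest-path hop count, i.e. the
  number of contact "levels" separating two individuals;
- *single-and-multiple-level influence* —
  `smlI(v) = Σ_{u≠v} nwI(u) / cd(v,u)` (global, distance-discounted);
- *local density* — `ld(v) = (triangles(v) + 1) · k(v)`;
- the score — `RWInf(v) = ld(v) · smlI(v)`. Rank 1 = most influential.

**Ground truth and evaluation.** A node's true spreading capability is its
mean final epidemic size over repeated discrete-time SIR runs seeded at
that node (infection probability β per contact per step, recovery
probability λ = 1). Index rankings are compared to SIR rankings with
Kendall's τ-b on a grid β = β_th + 0.01·i (i = 1..15) above the epidemic
threshold β_th ≈ ⟨k⟩/⟨k²⟩, and summarized by the grid average σ(τ),
monotonicity M(I) (rank uniqueness), and the improvement percentage η.

Baselines implemented: weighted k-shell (W_k-shell), degree-sum weighted
k-shell (Wks), weighted k-shell degree neighborhood (ksd^w), network global
structure centrality (ngsc), H-index/k-shell/clustering hybrid (HIC), and
weighted degree, betweenness and closeness centrality.

## Worked example

Generate a synthetic 8-person contact stream, weigh it, rank by RWInf, and
evaluate against SIR ground truth:

```sh
rwinf synth stream --n 8 --hours 2 --rate 0.6 --seed 11 --out demo.tij
# wrote 89 records, 28 sessions
rwinf weigh --input demo.tij --dialect tij --out demo_graph.tsv
# wrote 8 nodes, 17 edges to demo_graph.tsv
rwinf rank --graph demo_graph.tsv --index rwinf --out demo_scores.tsv
head -6 demo_scores.tsv
```

```
# rwinf v0.1.0 cmd=rank index=rwinf
node    score   rank
p2      166860  1
p4      144180  2
p5      70800   3
p0      51600   4
```

Person `p2` accumulated the most contact time in the best-connected
neighborhood, so it is the predicted top spreader (score = local density ×
distance-discounted neighborhood influence, in units of seconds × degree).

```sh
rwinf evaluate --graph demo_graph.tsv --indices rwinf,wkshell,wdeg \
    --runs 200 --iter 5 --seed 7 --out demo_report.json
```

yields σ(τ) = 0.786 for RWInf vs 0.575 (weighted degree) and 0.388
(weighted k-shell): on this stream the duration-aware score tracks the
simulated epidemic sizes markedly better than the structural baselines.

The same operations are available as a library:

```python
from rwinf import (parse_contact_events, build_weighted_graph,
                   rwinf_scores, rank_nodes)
events = parse_contact_events("demo.tij", dialect="tij")
G = build_weighted_graph(events, interval=20)
ranking = rank_nodes(rwinf_scores(G))
```

Real SocioPatterns datasets are not redistributed here; download them from
sociopatterns.org and feed them to `rwinf weigh` (`--dialect tij`) or, for
pre-weighted edge lists, directly to `rwinf rank` / `rwinf evaluate`.

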