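# Methods

This note documents the models, estimators and numerical choices behind
`osdis`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and
where the genuinely open design decisions were made.

## Network model

A network is an undirected simple graph `G = (V, E, θ)` with contiguous
0-based integer node ids and a strictly positive propagation delay
`θ_uv` (time units) on every edge.  Delays are drawn i.i.d. from a
Gaussian `N(μ, σ²)` with defaults `μ = 4`, `σ = 1`; only the ratio
`μ/σ = 4` is pinned by the evaluation protocol, the absolute scale is a
unit choice.  Non-positive draws are redrawn; at `μ/σ = 4` this touches
less than 10⁻⁴ of the mass and keeps path delays monotone in path
length.  One delay realization per run constitutes the weighted graph,
and the locator sees these realized delays by default; a
`delay_mode="mean"` locator setting restricts its knowledge to `μ`
(hop depth × μ replaces the realized path sums).

Two synthetic families reproduce the benchmark recipes:

* **Scale-free growth** (`generate_ba`): start from one node; each new
  node attaches `m` edges to distinct existing nodes chosen without
  replacement with probability ∝ `degree^power + 1`.  The additive
  zero-appeal term makes the isolated seed attachable and matches the
  semantics of the igraph generator named in the benchmark recipes;
  with `n = 200, m = 2` the construction forces `|E| = 1 + 2(n−2) = 397`
  regardless of the exponent.
* **Small-world rewiring** (`generate_ws`): ring lattice with radius-2
  neighborhoods (degree 4), each edge rewired with probability `p`,
  skipping rewires that would create self-loops or duplicates, so
  `|E| = 2n = 400` at `n = 200` for every `p`.  Implemented via
  `networkx.watts_strogatz_graph`, whose rewiring rule is exactly this.

## Diffusion model

Discrete SI: nodes are susceptible or infectious, infection is
permanent, and the process starts from a single source `s*` at time
`t*` (default 0 — the locator never sees it and re-estimates it).  When
`v` is infected at `t_v` it attempts to infect each susceptible
neighbor `u` with per-attempt success probability β.  The retry
schedule is not fully pinned down by the verbal model, so two readings
are implemented (`DiffusionConfig.semantics`):

* `"geometric"` (default): attempts are unit-time retries; transmission
  succeeds on the W-th attempt, `W ~ Geometric(β)` on {1, 2, …}, and the
  infection lands at `t_v + (W − 1) + θ_vu`.  At β = 1 this reduces
  exactly to the pure delay model (infection time = `t*` + delay-weighted
  shortest-path distance), and it introduces growing model mismatch as β
  falls, which is what makes low-β localization hard.
* `"thinning"`: failed attempts cost no time, so the first-arrival
  process is β-independent and degenerates to the pure delay model;
  kept as the documented alternative reading.

The simulator is event-driven (a priority queue of tentative arrivals
processed in nondecreasing time; later arrivals at an infected node are
discarded), so a node's infector is well defined and the infector edges
form the actual diffusion tree.  Exact arrival ties — measure zero
under continuous delays — are broken uniformly at random from the run
seed.  The geometric waits are driven by one uniform variate per
directed edge, pre-drawn from the seed (common random numbers); a
consequence used by the property tests is that lowering β can never
make any node's infection earlier for a fixed seed.

Observers are drawn uniformly without replacement (⌈fraction·|V|⌉ of
the nodes, default 5%), optionally excluding the source, and report
their infector and infection time.

## Relaxed direction-induced search

For a candidate root `s`, the DIS traversal grows a tree breadth-first
under one constraint: an observer may only be attached via the edge
from its recorded direction neighbor; non-observers attach to the first
frontier node that reaches them.  If all `|V|` nodes join, the tree is
returned; otherwise the root is *infeasible* — a normal value the
locator interprets as "candidate excluded", not an error.  Records from
a real diffusion are always satisfied by the actual diffusion tree, so
the true source is never excluded.

The DIS tree for a root need not be unique in principle; determinism is
imposed by a FIFO frontier with neighbors explored in ascending node
id, so each root maps to exactly one tree.  An observer whose direction
neighbor has not yet joined is picked up automatically when that
neighbor is dequeued, keeping the traversal `O(|V| + |E|)` per root.
When the root is itself an observer, its own direction record is
ignored for rooting (a root has no parent).

## Scoring and the estimator

With tree delays `d_k` (root-to-observer path sums) and observed times
`t_{o_k}`, the start time is estimated by least squares over
`t* ∈ [0, z]`:
`t̂* = clip(mean_k(t_{o_k} − d_k), 0, z)` — the exact minimizer of the
convex quadratic objective, with `z` defaulting to the sum of the
tree's edge delays (an upper bound on any root-to-node delay).  A
unit-step grid scan is provided and agrees with the closed form to grid
resolution; the closed form is used throughout because it is exact and
O(K).

* Time similarity: `1 / (1 + ‖t̂* + d − t_obs‖₂)`; equals 1 iff the tree
  reproduces the observations exactly.
* Order similarity: `(1 + τ)/2` with τ the Kendall correlation of the
  two time vectors (equivalent to comparing the two ascending observer
  orders).  The tie-adjusted τ (tau-b, via `scipy.stats.kendalltau`) is
  used; with continuous delays ties have measure zero and tau-b equals
  the classical `(C − D) / (K(K−1)/2)`.  Degenerate cases: a single
  observer imposes no ordering constraint (τ := 1, similarity neutral
  high); a constant time vector carries no ordering information
  (τ := 0, similarity 0.5).

The OSDIS estimate maximizes the product of the two similarities over
feasible candidates; OSBFS runs the identical scoring pipeline on plain
BFS trees (every candidate feasible, directions unused).  Ties are
broken by smallest node id (deterministic; a seeded random-among-ties
mode exists for bias studies).

### Candidate admissibility

Infeasible candidates are excluded from the argmax rather than scored
zero: tree existence is a precondition of the measuring-time model, and
a feasible low-score candidate should always beat an unsatisfiable one.
In addition, under the DIS heuristic an observer candidate whose record
names an infecting neighbor is marked infeasible outright: its own
direction information contradicts it being the origin.  Without this,
the estimator is not identifiable in an otherwise exactly identified
regime — on a tree network with β = 1 and full observation, the
observer adjacent to a leaf source reproduces the observed times
exactly (the unknown start time absorbs the one-edge offset) and would
win the smallest-id tie-break.  The BFS ablation ignores direction
information by design and is unaffected.  This never interacts with
the benchmark protocol, where sources are never observers and the
harness restricts candidates to non-observers anyway.

## Evaluation harness

One experiment fixes a topology (recipe or file) and runs `runs`
independent rounds (default 100): redraw delays, draw observers, draw
the source uniformly outside the observer set, simulate, observe, and
run each configured locator on the non-observer candidate set.  Metrics
per algorithm: precision (fraction of runs with error hop exactly 0),
mean/median/Q1/Q3 of the error hop (unweighted shortest-path distance
between estimate and truth) and mean error delay (delay-weighted
distance).  Runs without an estimate are counted separately and
excluded from the error means.  All randomness descends from one master
seed through per-run child seeds, so experiments are bit-reproducible.

Switches cover the genuinely unspecified protocol details: delays can
be realized once for the whole experiment instead of per run
(`refresh_delays=False`), and an `every-node` source policy visits each
node in turn (the natural reading for small networks where the run
count equals `|V|`).

## What the synthetic generators do and do not emulate

The generators reproduce the degree structure of the benchmark families
(scale-free hubs with tunable attachment exponent; small-world rings
with tunable disorder) and the i.i.d. Gaussian delay weights.  They do
not emulate features of real contact networks — community structure,
degree–degree correlations, weight–topology coupling, temporal edges —
so passing results bound the method's behavior under the stated model
only; on real networks with correlated delays or assortative mixing the
accuracy ordering of DIS versus BFS need not transfer.

## Problem sizes and numerical notes

The package's own validation uses 200-node synthetic networks with 100
Monte-Carlo runs (the benchmark scale for synthetic families), and
smaller graphs (8–50 nodes) where an exhaustive oracle — simple-path
enumeration, permutation enumeration, grid scans — is the comparison.
A full 100-run, 200-node experiment with both locators takes tens of
seconds on one CPU; the locator itself is `O(|V|·(|V| + |E|) + |V|·K²)`
per call.

Known limitations: single-source localization only; connected networks
(diffusion restricted to the source's component, disconnected
estimate/truth pairs are flagged, not repaired); the geometric-waiting
reading of β is one consistent formalization of a verbally specified
discrete process, and measured error rates at low β depend on that
choice.
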