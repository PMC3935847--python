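# Methods

## Model and procedure

The package couples two standard formalisms on a simple directed graph
(no self-loops, no duplicate edges; nodes `0..N-1`).

**Driver-node count.** A matching is a set of directed edges no two of which
share a source or share a target; on the bipartite representation (out-copy
`i+` to in-copy `j-` for each edge `i -> j`) this is an ordinary bipartite
matching, computed with Hopcroft–Karp. The driver count is
`N_D = max(N - |M*|, 1)`: unmatched nodes need one independent input each,
and a perfectly matched network (matched edges then form disjoint cycles)
still needs a single input, attached by convention to the lowest-id node.
`N_D` is invariant across maximum matchings; the reported driver *set* is
one deterministic representative and is never asserted in tests.

Edge roles: an edge is *critical* iff removing it shrinks the maximum
matching (equivalently, it lies in every maximum matching), *redundant* iff
it lies in no maximum matching — tested by forcing the edge into a matching:
`e = (u, v)` is in some maximum matching iff
`1 + |M*(G - u+ - v-)| = |M*(G)|` — and *ordinary* otherwise.

**Exact controllability cross-check.** For a concrete weighted adjacency
matrix the minimum input count is `max over eigenvalues λ of
N - rank(λI - A)`. Weights are either identical (all 1) or i.i.d. uniform on
(0, 1]; with random weights the count coincides with the structural one on
almost every graph, which the acceptance suite verifies on ER and SF samples.

**Cascade dynamics.** The load of an edge is the *raw count* of shortest
directed paths through it, summed over all ordered reachable pairs — when a
pair has several equal-length shortest paths, each contributes 1 to every
edge it uses. Capacities are fixed once on the intact graph,
`C_e = (1 + α)·L_e(0)`. After the attack removes its batch of edges, stages
iterate synchronously: recompute all loads on the residual graph, fail every
edge with `L > C` (strict — at `α = 0` an edge whose load merely stays put
survives), remove the failures simultaneously, record `N_D` and the SCC edge
count. Each stage removes at least one edge, so at most `M` stages occur.
Stage 0 is the post-attack, pre-overload state. `total_failed` counts
overload failures only; the attacked edges are tracked separately.

Attacks: RA draws `round(f·M)` edges uniformly without replacement
(half-away-from-zero rounding, at least one edge when `f > 0`); IA takes the
same number in descending order of *initial* load in one batch (no
re-ranking between removals), breaking ties at the load cutoff uniformly at
random under the attack seed. The single-trigger experiment is IA with one
edge.

## Tunable parameters

| parameter | meaning | default | rationale |
| --- | --- | --- | --- |
| `α` | capacity tolerance (fractional headroom) | 0.3 | moderate tolerance: cascades propagate but terminate well before total collapse |
| `N` | network size | 500 | desk-scale; matches the regime of the emulated real networks (hundreds of nodes) |
| `⟨k⟩` | mean degree `M/N` | 1.5 / 3 / 6 / 10 | small / moderate-trigger / moderate-sweep / large regimes |
| `γ` | SF tail exponent | 2.2–3.0 | the empirical range of heterogeneous directed networks |
| `f` grid | removal fractions | 0–1.0 step 0.05 | the cascade-free region sits above 0.8 at `α = 0.3`, so the grid extends to full removal |
| realizations | Monte Carlo repeats | 50 | standard errors small enough for one-sided ordering tests at the 0.05 level |

All experiment randomness descends from one master seed through
`SeedSequence` spawning (graph seed, trigger tie-break seed and per-cell
attack seeds are independent streams), making every output table
byte-reproducible.

## Synthetic generators

`generate_er` draws each ordered pair independently with
`p = ⟨k⟩/(N-1)` (so `E[M/N] = ⟨k⟩`). `generate_sf` uses the static model:
node `i` has weight `(i+1)^(-1/(γ-1))` and `M = round(N·⟨k⟩)` distinct
edges are drawn with both endpoints sampled proportionally to the weights,
rejecting self-loops and duplicates. This yields in- and out-degree tails
with exponent `γ` and independent control of `γ` and `⟨k⟩`, at the price of
(i) uncorrelated in/out degrees within a node beyond what common weights
induce, (ii) no degree-degree correlations, and (iii) a possibly
disconnected graph at small `⟨k⟩` (intentional: the small-degree regime
relies on it). These are idealisations — real networks carry correlations,
communities and weights that the ensembles do not emulate, so passing the
qualitative suite shows the mechanism, not quantitative predictions for any
particular real system.

## Experiment design choices

- **SCC statistic**: edges inside *all* SCCs of size ≥ 2 by default (stable
  under the largest-component ties that appear after heavy damage);
  largest-only available via a flag.
- **Census baseline**: failed-edge categories are always taken from the
  intact pre-attack classification — the census asks what roles the
  destroyed edges played in the original network.
- **Trace averaging**: traces of different lengths are aligned by stage
  index and shorter ones padded with their terminal value (a finished
  cascade stays in its final state).
- **Load convention**: the raw path count is primary; the
  Brandes-fractional variant (each pair contributes 1 split across its
  shortest paths) is available behind `fractional=True` for sensitivity
  analysis.
- **Degree regimes**: the single-trigger comparison uses ⟨k⟩ = 3 as the
  moderate (most damaging) ER degree against 1.5 and 10; the RA/IA sweep
  uses ⟨k⟩ = 6, where the attacked networks retain enough connectivity for
  the three-region structure of the driver-count curves; the SF γ-comparison
  runs at ⟨k⟩ = 1.5, the small-degree regime where damage scale and driver
  increment decouple (at ⟨k⟩ = 3 both exponents already saturate the
  cascade).
- **Directional reading of the decoupling claim**: the γ = 2.2 ensemble
  fails significantly more edges than γ = 3.0 while the *same* one-sided
  test on the driver increment is far from significant — i.e. a larger
  cascade does not imply more driver nodes. (The increments are in fact
  slightly larger for γ = 3.0, opposing the damage ordering.)
- **Large-f census regime**: the RA/IA census comparison pools the f-cells
  of the detected IA-above-RA large-f region, excluding `f = 1.0` where both
  strategies remove every edge and the censuses coincide identically. At
  `α = 0.3` the strictly cascade-free region only begins at `f ≈ 0.9`,
  where a random and an intentional 90% sample share most edges and the
  (real, everywhere-else significant) redundant-density ordering dilutes.

## Numerical choices

- Loads and path counts are exact in double precision (integer-valued until
  ~2^53; shortest-path counts on these ensembles stay far below).
- Bipartite matchings: `scipy.sparse.csgraph.maximum_bipartite_matching`
  (deterministic); SCCs: `scipy.sparse.csgraph.connected_components`.
- Exact controllability: eigenvalues within 1e-8 are grouped as one
  candidate; rank uses numpy's default singular-value cutoff
  (`N·eps·s_max`). λ = 0 is always evaluated explicitly because a defective
  zero eigenvalue (nilpotent Jordan blocks of size b) scatters numerically
  over a radius ~ eps^(1/b) that no fixed clustering tolerance absorbs; a
  dense-algebra guard rejects N > 5000.
- Load computation is an O(N·(N+M)) per-source BFS with forward path
  counting and reverse DAG accumulation, JIT-compiled with numba.
- IA cutoff ties and maximal-load trigger ties are broken uniformly at
  random under the given seed, never by input order.

## Problem sizes

Oracle-equivalence checks run exhaustive enumeration on hundreds of random
graphs with N ≤ 8. The qualitative reproduction suite runs the full study
conditions (N = 500, α = 0.3, 50 realizations); `scripts/acceptance.py`
uses the same conditions with 25 sweep realizations, which keeps the whole
reproduction in a few minutes on one core while the ordering margins remain
several standard errors wide.

## Known limitations

- The SF construction is one of several reasonable choices; growth models
  (preferential attachment) or configuration-model graphs with prescribed
  in/out sequences would give different micro-structure at equal γ and ⟨k⟩.
- The exact-controllability routine can in principle miss a *defective
  non-zero* eigenvalue of high geometric multiplicity (only λ = 0 gets the
  explicit treatment); with identical weights on adversarial structured
  graphs the reported count is then a lower bound. Random-weight use — the
  mode the cross-check relies on — is unaffected in practice.
- Cascades are synchronous; asynchronous single-edge failure order is out
  of scope, as are node-capacity variants and flow-based (non-shortest-path)
  load models.
- The qualitative assertions are ensemble statements at the documented
  conditions; single realizations can and do deviate.
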