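# Methods

`ancestate` reconstructs the history of one discrete character (geographic
origin, host, resistance status, ...) on a rooted phylogeny, and summarizes
that history as a set of state transitions read from the root toward the
tips. This note documents the models, the numerical choices, and the
limits of what the test suite demonstrates.

## Ancestral reconstruction

### Parsimony (ACCTRAN / DELTRAN)

The minimum-change criterion is evaluated with unit-cost dynamic
programming over per-state subtree change counts. For every node `v` and
state `s`, `c_v(s)` is the minimum number of changes in `v`'s subtree when
`v` carries `s`; at a leaf `c` is 0 for the observed state and effectively
infinite otherwise (a leaf with no annotation costs 0 in every state,
i.e. it is fully ambiguous). The per-node argmin sets of these tables
coincide with the classical Fitch downpass sets on binary trees and with
Hartigan's majority sets on multifurcations, so polytomies — common in
imported Bayesian summary trees — are handled exactly, and branch lengths
are ignored by construction.

A single labeling is then chosen in preorder. Given the parent's assigned
state `a`, the choice at `v` is forced except when `c_v(a) = min c_v + 1`:
there, keeping `a` (pushing the change into the subtree) and switching to
an argmin state (spending the change on this edge) complete equally
parsimonious labelings. ACCTRAN switches — the change happens as close to
the root as possible; DELTRAN keeps the parent's state — the change is
delayed toward the tips. Every resolution therefore realizes exactly the
minimum change count; the suite verifies this against exhaustive
enumeration on trees small enough to enumerate. Remaining ties (including
the root's choice among its argmin states) are broken by lexicographic
state order so results are reproducible. One consequence of a shared root
tie-break worth knowing: on perfectly symmetric instances such as
`((A:red,B:blue),(C:red,D:blue))` the two resolutions coincide, because
the only freedom is the joint choice of the root state.

### F81 maximum likelihood

The probabilistic model is the multi-state Felsenstein 1981 process: from
any state the character jumps at rate `mu` to a state drawn from the
stationary distribution `pi`, giving the closed form

    P(i -> j | t) = pi_j (1 - e^{-mu sigma t}) + [i = j] e^{-mu sigma t},

with `mu = 1 / (1 - sum_s pi_s^2)` so one unit of scaled branch length is
one expected substitution at stationarity. With equal frequencies over
four states this reduces to Jukes–Cantor, which the tests use as a
closed-form cross-check. Whether to apply the `mu` normalization at all
is a modeling convention; we adopt the normalized form, and since `sigma`
is refitted multiplicatively the choice only relabels the scale of
`sigma`, not the fitted likelihood.

Input branch lengths are usually in expected substitutions per sequence
site, which is the wrong clock for an arbitrary character. A single
global scaling factor `sigma > 0` multiplies all branch lengths and is
fitted by maximizing the Felsenstein-pruning log-likelihood with bounded
Brent search on `log sigma` in `[log 1e-3, log 1e3]` (tolerance 1e-6 in
log space). The likelihood of a rescaled-length problem is exactly
invariant under `lengths * c, sigma / c`, which the tests assert; hitting
a search bound triggers a warning rather than an error. With fewer than
two observed states the factor is unidentifiable and `sigma = 1` is
returned with a warning. Trees without branch lengths get unit lengths
(the factor then absorbs the unit).

State priors default to observed leaf frequencies with add-one smoothing
over the alphabet — the model requires strictly positive `pi`, including
for states that are in the alphabet but absent from the sampled tips.
Uniform or user-supplied priors are accepted everywhere. Priors are
estimated first and held fixed while `sigma` is fitted; they are not
optimized jointly.

Three read-outs are provided:

* **Marginal posteriors / MAP** — one up-pass (inside likelihoods) and
  one down-pass (outside likelihoods); the per-node posterior is their
  normalized product. MAP takes the per-node argmax.
* **Joint reconstruction** — the single most probable full assignment via
  max-product dynamic programming with traceback, in log space.
* **Total log-likelihood** — root partial weighted by `pi`.

MAP maximizes each node's marginal independently and may disagree with
the joint scenario; the suite keeps a frozen three-state instance where
the two provably differ. Underflow is handled by per-node vector
renormalization with the discarded magnitude accumulated in log space, so
likelihoods are exact up to floating point; zero-probability data (e.g.
conflicting states across zero-length branches) yield `-inf` rather than
an exception, and zero-length branches use an exact identity matrix with
no epsilon inflation. Argmax tie-breaks are lexicographic and flagged.

## Transition analysis

A transition is a parent/child pair with different states, attributed to
the child node; its distance is the root-to-node path length in input
units (absent lengths contribute zero, with a warning). Probabilistic
reconstructions are reduced to their per-node majority state first.

The three map types form a collapse hierarchy:

1. **Type 1** is the annotated tree contracted along state-constant
   edges: the map root carries the root state and every event is one map
   node under its nearest ancestral event.
2. **Type 2** merges sibling map nodes representing the same transition
   (same father in the type-1 map), top-down, summing counts.
3. **Type 3** additionally merges equal transitions `i -> j` anywhere in
   the map whose parents carry the same state `i`. The one-line rule
   does not by itself define a tree, so the merge is implemented as a
   preorder fixpoint: the first `i -> j` node encountered is canonical,
   later ones fold into it and their children are re-attached and
   re-merged. Counts are conserved by construction at every stage.

Merged nodes store the minimum member distance plus the full member set,
so any other summary (mean, range) remains recoverable. Transition
matrices count events per ordered state pair; the relative-rate variant
divides each count share `n_ij / N` by the *target* state's prior
`pi_j`. The normalization convention is genuinely ambiguous (source,
target, or both priors are all defensible); the choice is isolated in one
function and selectable by flag.

Path queries compress every root-to-leaf state sequence (consecutive
duplicates dropped) and match a whitespace-separated token pattern
against any contiguous subsequence; `*` matches a run of zero or more
states, and optional `^`/`$` anchors pin the match to the path ends.
The matcher is a direct recursion over token lists; the tests compare it
exhaustively against an independent regular-expression oracle.

The ambiguity filter flags nodes where at least two states have posterior
at or above `(1 - f)` times the MAP probability (default `f = 0.4`); the
Sz criterion counts, for each node, descendant leaves sharing its
annotation.

## Method comparison

Reconstructions are compared on per-node majority states so parsimony,
MAP, joint, and imported (e.g. Bayesian) annotations are commensurable.
Discrepant nodes are internal nodes where at least two methods disagree;
leaves are excluded since every method pins observed leaves. Transition
maps are compared by full root-to-node state sequences: a map node is
shared when the other map contains the identical sequence, which marks
path-consistent structure rather than mere local agreement (a local-key
mode is available behind a flag).

## Synthetic data

The generator emulates the study conditions end to end: ultrametric
pure-birth (Yule) trees — forward-simulated with exponential waits at
rate `k * lambda` for `k` open lineages, closed just before the next
birth so terminal branches are never zero — and characters evolved down
the tree under the scaled F81 process from a root state drawn from `pi`.
Defaults: birth rate 1, uniform priors, `sigma = 1`, 100 leaves. Every
generator is seed-deterministic.

What it deliberately does not emulate: non-ultrametric sampling through
time, lineage-specific or time-varying rates, rate heterogeneity across
characters, sampling bias among locations, and phylogenetic error (the
tree is known without error). Passing parameter-recovery tests therefore
show correctness of the estimators under the model's own assumptions,
not robustness to their violation on real data.

The worked example used throughout docs and tests is a six-leaf,
three-state tree whose transition multiset is exactly two gray→red
events (independent clades), one gray→gold, and one red→gold, with both
gray→red events hanging off the map root — so the type-2 collapse shows
a count of 2 on the merged node.

## Problem sizes used in the checks

Exhaustive oracles (parsimony minima, likelihood sums, marginal
conditionals, joint argmax) run on a seeded grid of trees up to 10 nodes
with alphabets up to 4 states — the largest sizes where enumeration is
exact and fast. Conservation laws run on 500 random annotated trees of
5–29 leaves; query semantics on 200 trees against the regex oracle.
Scaling-factor recovery uses 20 replicates of 200-leaf trees at true
`sigma = 2`; the accuracy-versus-rate trend uses 50 replicates per
`sigma` in {0.1, 1, 10} on 50-leaf trees.

## Known limitations

* One character per run; multi-character analyses loop at the CLI level.
* No Sankoff cost matrices or Dollo/Camin–Sokal parsimony variants.
* No rate heterogeneity and no substitution models beyond F81 (equal-`pi`
  F81 is Jukes–Cantor; GTR-class models are out of scope).
* NEXUS support covers trees with BEAST-style bracket comments, not the
  full standard (no CHARACTERS/DATA blocks).
* Rendering is static SVG; there is no interactivity or animation of
  maps by root distance (distances are exported for downstream use).
* Comparisons require identical tree topologies; consensus transition
  maps across methods are not built.
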