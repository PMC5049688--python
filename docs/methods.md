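# Methods

## Model

`bacsim` simulates the ancestry of `n` sampled bacterial genomes backward
in time under the standard coalescent with gene conversion, then evolves
sequences tip-ward through the resulting ancestral recombination graph
(ARG).  Time is measured in units of `N_e` generations and all rates are
scaled accordingly.

With `k` active lineages the process competes three exponential clocks:

* **Coalescence** at rate `k(k−1)/2`; two uniformly chosen lineages merge,
  their ancestral material unions, and a lineage on the clonal frame stays
  on it.
* **Within-species gene conversion.**  Every site of every lineage initiates
  a conversion tract at rate `R/2`; tract lengths are geometric with mean
  `δ`, `P(ℓ) = (1/δ)(1 − 1/δ)^{ℓ−1}`.  Backward in time the recipient
  lineage splits: the continuing (recipient) branch keeps the material
  outside the tract and inherits clonal-frame membership, a new donor
  branch carries the material inside the tract and is never clonal.
* **Between-species gene conversion** at rate `R_e/2` per site with mean
  tract length `δ_e`.  The donor lies outside the population, so the tract
  is removed from backward-time tracking; each event draws a divergence
  `d ~ Uniform(D_1, D_2)` which later parameterises the imported sequence.

The *clonal frame* — the genealogy obtained by following the recipient
branch through every split — is tracked directly during simulation.
Recombination cannot remove a lineage from the clonal frame, so the clonal
genealogy remains an exact `n`-coalescent for every `R` (a property the
test suite checks distributionally).

### Effective events only

An event is *effective* when it alters the ancestry of sampled material:
a within-species tract must split a lineage's ancestral material into two
non-empty parts; a between-species tract need only touch ancestral
material.  For a tract starting at site `s`, effectiveness is monotone in
the tract length at both ends, so the effective lengths form one contiguous
range `[ℓ_min(s), ℓ_cov(s) − 1]`: too-short tracts miss the material,
too-long tracts (on a circular genome) engulf it.  With the geometric tail
`P(ℓ ≥ m) = q^{m−1}`, `q = 1 − 1/δ`, the per-start effectiveness
probability is `q^{ℓ_min−1} − q^{ℓ_cov−1}`.  Within a run of starts between
two material boundaries both exponents shift by one per site, so each run
sums to a geometric series, and the total effective rate is evaluated
exactly in `O(#material intervals)`.  Sampling inverts the same structure:
choose a run by its closed-form weight, a start within the run by truncated
geometric inversion, then a length from the geometric law conditioned on
the effective range.  The closed forms are asserted *equal* (to 1e-10
relative) to brute-force enumeration over all `(s, ℓ)` pairs on small
genomes, and the samplers are chi-square-tested against the enumerated
tract law.

### Pruning at local MRCAs

A per-site carrier count is maintained over the genome.  Whenever a site's
count drops to one — after a coalescence of its last two carriers, or after
an external import removes one of two carriers — the site is pruned from
the remaining lineage's material and its local MRCA is recorded at that
lineage's current node.  Pruned regions contribute no recombination rate:
an event confined to fully resolved material would shift all samples
identically and is unobservable.  Without this pruning the effective rate
stays proportional to the full genome for the whole history and high-rate
simulation is infeasible.  For the external-import prune case the MRCA
anchor sits at the remaining carrier's *last event node* rather than the
exact prune time; because the root sequence assigned there is drawn from
the Jukes–Cantor stationary distribution, the two choices are equal in law.

### Rate convention

The published description fixes only "the same per-site initiation rate
R"; whether that is `R` or `R/2` per lineage per unit time is a convention.
`bacsim` uses `R/2` (and `R_e/2`), matching the `ρ/2`-per-lineage
convention of standard coalescent simulators.  The convention is testable:
in the rejection-sampling oracle the raw candidate count over a history is
Poisson with mean `(R/2)·G·∫k dt`, and the suite asserts exactly that.

## Sequence simulation

The root sequence is i.i.d. uniform on {A,C,G,T} (the JC stationary law).
Nodes are processed in decreasing time order; each node assembles its
sequence from its parents — splicing tract columns from the donor-side
parent at splits, overwriting tract columns at external imports with
`apply_external_import(root, tract, d)` (each site differs from the root
homolog independently with probability `d`), overwriting freshly resolved
sites with the root sequence at their recorded MRCA node — and then evolves
a copy down each child edge with per-site Poisson(θ/2 × branch length)
substitution counts.  Substitutions are uniform shifts in Z/4, which
compose exactly like successive JC substitutions, so batching and multiple
hits are handled without approximation.

Two deliberate modelling choices:

* **Divergence `d` is an observed per-site difference probability**, not a
  branch length.  This keeps `D_1, D_2` directly interpretable (a donor at
  `d = 0.3` differs from the root homolog at 30 % of sites).  Only the
  Newick *display* of import edges converts to a length, using `2d/θ` —
  the coalescent-unit length whose expected substitution load at rate
  `θ/2` equals `d` (total over both directions of the pair path); with
  `θ = 0` the exported length is 0 and the annotation alone marks the edge.
  Sequence simulation always uses `d` itself.
* **Every local MRCA receives the same single root sequence.**  Under JC
  stationarity this is marginally exact per segment; what it omits is
  correlation between the roots of segments that resolved on different
  nodes.  Single-segment statistics are unaffected.

## Local trees and breakpoints

The local tree of a site follows each sample root-ward, taking the donor
parent at a split when the site lies in the tract, stopping at an external
import that covers the site or at the site's recorded MRCA.  Paths merge at
coalescences; import-terminated clades are grafted onto the coalescent root
with the `2d/θ` display length and an explicit `[&import,d=…]` comment.  In
the degenerate case where every clade of a segment is import-terminated the
graft point is anchored at the latest import and `tmrca` refuses the tree.
Breakpoints are computed by building the local tree once per candidate
segment (candidates: recorded tract endpoints plus fragment boundaries) and
merging adjacent segments with identical topology, node times and import
annotations; on small genomes the suite verifies the partition equals the
exhaustive per-site equivalence classes.

## Genome geometry

Coordinates are 0-based half-open; a circular tract wrapping the origin is
canonicalised to two intervals at construction.  Fragmented genomes declare
`(fragment_length, trailing_gap)` pairs; gap sites are real coordinates
that can initiate and carry conversion tracts (preserving long-range
correlation across fragments) but bear no sequence and never enter
ancestral-material bookkeeping.  Whether real conversion tracts span
inter-fragment gaps is not documented for this model family; spanning is
the default here because confining tracts would artificially decorrelate
fragments.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `n` | sample size | genomes | required |
| `G` | genome length (fragments + gaps) | sites | required |
| `theta` | scaled mutation rate (2 `N_e` µ) | per site | 0.01 |
| `rho_int` (R) | within-species initiation rate | per site | 0 |
| `delta_int` (δ) | mean within-species tract length | sites | 500 |
| `rho_ext` (R_e) | between-species initiation rate | per site | 0 |
| `delta_ext` (δ_e) | mean between-species tract length | sites | 500 |
| `div_min`, `div_max` (D_1, D_2) | external-donor divergence bounds | probability | 0, 0 |
| `seed` | RNG seed | — | entropy |

Defaults put the simulator in the pure within-species mode with
recombination off until rates are supplied.  The tract-length default of
500 sites is an order-of-magnitude choice for bacterial conversion tracts
(typical estimates run from a few hundred bases to a few kilobases); it is
a convenience default, not a fitted value.  Divergence is capped at 0.75,
the JC saturation point.

## Numerical choices

* Geometric sampling is by inverse-CDF (`⌊log1p(−u(1−q^span))/log q⌋`),
  exact up to floating point; `δ = 1` (q = 0) short-circuits to length 1.
* Per-lineage rates are maintained as running totals updated on material
  change; totals are re-summed every 4096 events to bound float drift, and
  a drift-created phantom sliver of rate triggers a re-sum and redraw
  instead of an invalid event.
* Event times are strictly increasing almost surely; simultaneous-time ties
  are broken by creation order.  A fixed seed reproduces the identical ARG
  and outputs byte-for-byte on one platform.
* A configurable event cap (default 5·10⁶) turns runaway parameter sets
  into an error naming the parameters rather than a hang.
* Degenerate inputs are errors, not silent defaults: empty material in the
  rate operations, gap coordinates in `local_tree`, `d` outside
  `[0, 0.75]`, negative branch lengths, `n < 2`.

## Implementation and verification strategy

The event loop, interval algebra, closed-form rates, samplers and the
sequence pass are compiled (numba); the surrounding API materialises ARG
nodes and event records lazily from the flat array output.  Verification
deliberately rests on independently written slow paths: a pure-Python
rejection-sampling simulator (candidates at the raw initiation rate,
ineffective candidates discarded) shares no event-loop code with the
compiled simulator and is compared to it distributionally (two-sample KS
at α = 0.001 on event counts and clonal TMRCA); a pure-Python sequence
pass is likewise compared to the compiled one; rates and samplers are
checked against brute-force enumeration.  All statistical tests use fixed
seeds, stated replicate counts and α = 0.001 so that suite flake rates are
negligible.

## Problem sizes used by the suite

Unit and distributional tests run on genomes of 10–5000 sites where
enumeration and rejection sampling are exact references.  The clonal-frame
recovery study runs at a scaled-down operating point — 50 kb circular
genomes, `n = 15`, `θ = 0.01`, `δ = 500`, 50 replicates, NJ inference —
which preserves the qualitative pattern (accuracy degrades with `R`; old,
root-proximal branches degrade most) while keeping the suite quick.  At
this scale absolute accuracies are far below the ~91 % reported for ML on
1 Mbp genomes, since twenty times less sequence signal supports the same
tree; `scripts/clonal_accuracy_experiment.py --full` runs the 1 Mbp
version (hours, and the original sample size behind the published figure
is not on record — it is a knob).

## What the generator does and does not emulate

Simulated data are exchangeable coalescent samples from a single unstructured,
constant-size population with homogeneous recombination and mutation rates
along the genome and a strict JC substitution model.  Passing tests
therefore demonstrate correctness of the model as specified, not realism of
any particular organism: there is no demography, population structure,
selection, rate heterogeneity, distributive conjugal transfer, or indel
process.  Non-JC substitution models are intentionally delegated to
external tools via the per-segment local-tree output.  The between-species
donor model draws each event's divergence independently and uniformly;
real donors are phylogenetically correlated across events.
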