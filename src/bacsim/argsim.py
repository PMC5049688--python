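"""Coalescent simulation of the ancestral recombination graph (ARG) with
gene conversion, for bacterial samples.

The sample's history is generated backward in time under the standard
coalescent.  With ``k`` active lineages, coalescence occurs at rate
``k(k-1)/2`` in units of ``N_e`` generations.  Gene-conversion recombination
initiates at every genome site of every lineage at scaled rate ``R/2``
(within-species) and ``R_e/2`` (between-species) per site per unit time,
with tract lengths geometric, ``P(l) = (1/delta)(1 - 1/delta)**(l-1)``,
mean exactly ``delta``.

Only *effective* events are ever sampled:

* a within-species event is effective iff the tract bipartitions the
  lineage's ancestral material into two non-empty parts (the recipient keeps
  the complement, a new donor lineage takes the intersection);
* a between-species event is effective iff the tract touches ancestral
  material at all; the donor is outside the population, so the tract is
  removed from backward-time tracking and annotated with a divergence
  ``d ~ Uniform(D1, D2)``.

For a tract starting at ``s`` the effective lengths form a contiguous range,
so the per-start effectiveness probability is a difference of two geometric
tails ``q**k`` with ``q = 1 - 1/delta``; summing the closed form over runs of
starts gives the total rate in O(#intervals) and an exact, rejection-free
sampler for ``(s, l)``.  Sites whose material is carried by a single lineage
are pruned from tracking (their local MRCA recorded); clonal-frame lineages
persist even with empty material so the clonal genealogy is always emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .genealogies import LocalTree, TreeNode
from . import _kernels as _k
from .genome import GenomeMap, IntervalSet, wrap_interval

_EMPTY_IV = IntervalSet()

__all__ = [
    "Parameters", "EventRecord", "ArgNode", "Arg",
    "effective_within_rate", "effective_external_rate",
    "sample_within_event", "sample_external_event",
    "simulate_arg", "clonal_frame",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class Parameters:
    """Scaled simulation parameters.

    Rates are per site, scaled by the effective population size; ``delta``
    values are mean tract lengths in sites; ``div_min``/``div_max`` bound the
    per-site divergence of between-species donors (Jukes-Cantor saturates at
    0.75).
    """

    n: int
    genome: GenomeMap
    theta: float = 0.01
    rho_int: float = 0.0
    delta_int: float = 500.0
    rho_ext: float = 0.0
    delta_ext: float = 500.0
    div_min: float = 0.0
    div_max: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        for name in ("theta", "rho_int", "rho_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta_int < 1 or self.delta_ext < 1:
            raise ValueError("mean tract lengths delta must be >= 1")
        if not (0.0 <= self.div_min <= self.div_max <= 0.75):
            raise ValueError("require 0 <= div_min <= div_max <= 0.75")


@dataclass
class EventRecord:
    """One recombination event, as written to the events TSV."""

    kind: str                 # 'within' | 'external'
    time: float
    lineage: int              # id of the recipient lineage's node at event time
    tract: IntervalSet        # genomic footprint (wrapped/truncated)
    raw_length: int           # sampled geometric length before truncation
    divergence: Optional[float] = None


class ArgNode:
    """Node of the ARG: a leaf, coalescence, recombination split,
    between-species import, or the grand root.

    ``material`` snapshots the lineage's ancestral material: after the event
    for coalescences and imports, and *before* the split for recombination
    nodes (the two parent-side materials derive from it and the tract).
    """

    __slots__ = ("id", "kind", "time", "children", "clonal", "material",
                 "tract", "divergence", "mrca")

    def __init__(self, id: int, kind: str, time: float, children, clonal: bool,
                 material: Optional[IntervalSet] = None,
                 tract: Optional[IntervalSet] = None,
                 divergence: Optional[float] = None):
        self.id = id
        self.kind = kind
        self.time = time
        self.children = list(children)   # (child_id, role) pairs
        self.clonal = clonal
        self.material = material
        self.tract = tract
        self.divergence = divergence
        self.mrca = _EMPTY_IV           # sites whose local MRCA is this node

    @property
    def donor_material(self) -> Optional[IntervalSet]:
        """Material taken by the donor-side parent of a split."""
        if self.material is None or self.tract is None:
            return None
        return self.material & self.tract

    @property
    def recipient_material(self) -> Optional[IntervalSet]:
        """Material kept by the recipient-side parent of a split."""
        if self.material is None or self.tract is None:
            return None
        return self.material - self.tract


_KIND_CODES = {0: "leaf", 1: "coalescence", 2: "recomb_split",
               3: "external_import"}
_ROLE_CODES = {0: None, 1: "donor", 2: "recipient"}


class Arg:
    """Node/edge graph of the sample's recombination-and-coalescence history.

    Instances produced by the compiled simulator carry the raw array form
    and materialise :class:`ArgNode` objects lazily on first access.
    """

    def __init__(self, genome: GenomeMap, n: int):
        self.genome = genome
        self.n = n
        self._nodes: List[ArgNode] = []
        self._raw = None
        self.root_id: Optional[int] = None
        self._parent_of: Optional[dict] = None

    # -- python-built path (rejection oracle, hand-built fixtures) ---------

    def add_node(self, kind: str, time: float, children, clonal: bool,
                 **kw) -> int:
        nid = len(self._nodes)
        self._nodes.append(ArgNode(nid, kind, time, children, clonal, **kw))
        return nid

    def finalize(self, root_id: int) -> None:
        self.root_id = root_id
        self._parent_of = None

    # -- raw-array path -----------------------------------------------------

    @classmethod
    def _from_raw(cls, genome: GenomeMap, n: int, raw: dict) -> "Arg":
        obj = cls(genome, n)
        obj._raw = raw
        obj.root_id = int(raw["root_node"])
        return obj

    def _materialize(self) -> None:
        raw = self._raw
        kinds = raw["kind"]
        times = raw["time"]
        clonal = raw["clonal"]
        c1, r1 = raw["c1"], raw["r1"]
        c2, r2 = raw["c2"], raw["r2"]
        div = raw["div"]
        toff, tlen, tpool = raw["toff"], raw["tlen"], raw["tpool"]
        moff, mlen, mpool = raw["moff"], raw["mlen"], raw["mpool"]
        nodes = []
        for nid in range(kinds.size):
            children = []
            if c1[nid] >= 0:
                children.append((int(c1[nid]), _ROLE_CODES[int(r1[nid])]))
            if c2[nid] >= 0:
                children.append((int(c2[nid]), _ROLE_CODES[int(r2[nid])]))
            tract = None
            if toff[nid] >= 0:
                tract = IntervalSet._from_bounds(
                    tpool[toff[nid]:toff[nid] + tlen[nid]])
            material = None
            if moff[nid] >= 0:
                material = IntervalSet._from_bounds(
                    mpool[moff[nid]:moff[nid] + mlen[nid]])
            d = float(div[nid]) if div[nid] == div[nid] else None
            nodes.append(ArgNode(nid, _KIND_CODES[int(kinds[nid])],
                                 float(times[nid]), children,
                                 bool(clonal[nid]), material=material,
                                 tract=tract, divergence=d))
        by_node: dict[int, list] = {}
        for nid, s, e in zip(raw["mr_node"], raw["mr_s"], raw["mr_e"]):
            by_node.setdefault(int(nid), []).append((int(s), int(e)))
        for nid, pairs in by_node.items():
            nodes[nid].mrca = IntervalSet(pairs)
        if nodes and nodes[self.root_id].kind == "coalescence":
            nodes[self.root_id].kind = "root"
        self._nodes = nodes

    @property
    def nodes(self) -> List[ArgNode]:
        if self._raw is not None and not self._nodes:
            self._materialize()
        return self._nodes

    @property
    def parent_of(self) -> dict:
        if self._parent_of is None:
            mapping = {}
            for node in self.nodes:
                for child_id, role in node.children:
                    mapping[(child_id, role)] = node.id
            self._parent_of = mapping
        return self._parent_of

    @property
    def leaves(self) -> range:
        return range(self.n)


# ---------------------------------------------------------------------------
# analytical effective-event rates and sampling
#
# Closed forms and exact samplers live in the compiled kernels: for a tract
# starting at s the effective lengths form one contiguous range, so the
# per-start probability is a difference of two geometric tails and runs of
# starts sum to geometric series in O(#intervals).
# ---------------------------------------------------------------------------

def effective_within_rate(material: IntervalSet, genome: GenomeMap,
                          delta_int: float, *, rho_int: float = 1.0) -> float:
    """Total rate of within-species events that bipartition ``material``.

    Equals ``(R/2) * sum_s P_{l ~ Geom(delta)}(both material&tract and
    material-tract non-empty)`` evaluated in closed form; exact against
    brute-force enumeration.
    """
    if material.is_empty:
        raise ValueError("effective rate undefined for empty material")
    if rho_int == 0.0:
        return 0.0
    q = 1.0 - 1.0 / delta_int
    return 0.5 * rho_int * _k.weight_within(material.bounds,
                                            genome.total_length,
                                            genome.circular, q)


def effective_external_rate(material: IntervalSet, genome: GenomeMap,
                            delta_ext: float, *, rho_ext: float = 1.0) -> float:
    """Total rate of between-species events whose tract touches
    ``material`` (no bipartition requirement; the donor is outside the
    ARG)."""
    if material.is_empty:
        raise ValueError("effective rate undefined for empty material")
    if rho_ext == 0.0:
        return 0.0
    q = 1.0 - 1.0 / delta_ext
    return 0.5 * rho_ext * _k.weight_external(material.bounds,
                                              genome.total_length,
                                              genome.circular, q)


def _sample_within(material: IntervalSet, genome: GenomeMap, delta: float,
                   rng) -> Tuple[int, int, IntervalSet]:
    q = 1.0 - 1.0 / delta
    u = rng.random(3)
    s, l = _k.sample_within_k(material.bounds, genome.total_length,
                              genome.circular, q, u[0], u[1], u[2])
    return int(s), int(l), wrap_interval(int(s), int(l), genome)


def sample_within_event(material: IntervalSet, genome: GenomeMap,
                        delta_int: float, rng) -> IntervalSet:
    """Draw the tract of an effective within-species event.

    The joint law of (start, length) conditioned on effectiveness matches
    the enumeration distribution; the returned footprint intersects the
    material and leaves part of it untouched.
    """
    if effective_within_rate(material, genome, delta_int) <= 0.0:
        raise ValueError("no effective within-species event exists")
    return _sample_within(material, genome, delta_int, rng)[2]


def _sample_external(material: IntervalSet, genome: GenomeMap, delta: float,
                     rng) -> Tuple[int, int, IntervalSet]:
    q = 1.0 - 1.0 / delta
    u = rng.random(3)
    s, l = _k.sample_external_k(material.bounds, genome.total_length,
                                genome.circular, q, u[0], u[1], u[2])
    s, l = int(s), int(l)
    l_fp = min(l, genome.total_length) if genome.circular else l
    return s, l, wrap_interval(s, l_fp, genome)


def sample_external_event(material: IntervalSet, genome: GenomeMap,
                          delta_ext: float, rng) -> IntervalSet:
    """Draw the tract of an effective between-species event (touches
    material; no bipartition requirement)."""
    if effective_external_rate(material, genome, delta_ext) <= 0.0:
        raise ValueError("no effective between-species event exists")
    return _sample_external(material, genome, delta_ext, rng)[2]


# ---------------------------------------------------------------------------
# backward-in-time simulation core
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node_id", "role", "material", "clonal", "w_in", "w_ext",
                 "cf")

    def __init__(self, node_id, role, material, clonal, cf):
        self.node_id = node_id
        self.role = role
        self.material = material
        self.clonal = clonal
        self.cf = cf
        self.w_in = 0.0
        self.w_ext = 0.0


class _SimCore:
    """Shared event semantics for the analytical simulator and the
    rejection-sampling oracle: lineage state, carrier counts, pruning at
    local MRCAs, clonal-frame tracking."""

    def __init__(self, params: Parameters, rng):
        self.params = params
        self.rng = rng
        self.genome = params.genome
        G = self.genome.total_length
        self.arg = Arg(self.genome, params.n)
        self.counts = np.zeros(G, dtype=np.int32)
        material0 = self.genome.seq_intervals()
        for s, e in material0:
            self.counts[s:e] = params.n
        self.sum_w = 0.0        # running totals of per-lineage rates
        self.sum_e = 0.0
        self.lineages: List[_Lineage] = []
        for i in range(params.n):
            nid = self.arg.add_node("leaf", 0.0, [], True, material=material0)
            lin = _Lineage(nid, None, material0, True,
                           TreeNode(time=0.0, label=f"sample_{i + 1}"))
            self._refresh(lin)
            self.lineages.append(lin)
        self.events: List[EventRecord] = []
        self.t = 0.0

    # -- rate bookkeeping --------------------------------------------------

    def _refresh(self, lin: _Lineage) -> None:
        p = self.params
        mat = lin.material
        G = self.genome.total_length
        circ = self.genome.circular
        if p.rho_int > 0.0 and mat:
            w = 0.5 * p.rho_int * _k.weight_within(
                mat.bounds, G, circ, 1.0 - 1.0 / p.delta_int)
        else:
            w = 0.0
        self.sum_w += w - lin.w_in
        lin.w_in = w
        if p.rho_ext > 0.0 and mat:
            w = 0.5 * p.rho_ext * _k.weight_external(
                mat.bounds, G, circ, 1.0 - 1.0 / p.delta_ext)
        else:
            w = 0.0
        self.sum_e += w - lin.w_ext
        lin.w_ext = w

    def _drop(self, lin: "_Lineage") -> None:
        self.sum_w -= lin.w_in
        self.sum_e -= lin.w_ext
        self.lineages.remove(lin)

    def _resum(self) -> None:
        """Re-derive the running totals (guards float drift)."""
        self.sum_w = math.fsum(l.w_in for l in self.lineages)
        self.sum_e = math.fsum(l.w_ext for l in self.lineages)

    # -- carrier counts and pruning ---------------------------------------

    def _decrement_and_singles(self, region: IntervalSet) -> IntervalSet:
        """Drop one carrier over ``region``; return freshly resolved runs."""
        return IntervalSet._from_bounds(
            _k.counts_decrement_singles(self.counts, region.bounds))

    def _counts_zero(self, region: IntervalSet) -> None:
        _k.counts_zero(self.counts, region.bounds)

    def _prune_from_others(self, prune: IntervalSet) -> None:
        """Remove freshly resolved sites from their (single) remaining
        carrier and anchor their MRCA record at that lineage's node."""
        doomed = []
        for lin in self.lineages:
            inter = lin.material & prune
            if inter:
                node = self.arg.nodes[lin.node_id]
                node.mrca = node.mrca | inter
                lin.material = lin.material - inter
                self._refresh(lin)
                if lin.material.is_empty and not lin.clonal:
                    doomed.append(lin)
        self._counts_zero(prune)
        for lin in doomed:
            self._drop(lin)

    # -- event semantics ---------------------------------------------------

    def do_coalescence(self, i: int, j: int) -> None:
        if i > j:
            i, j = j, i
        y = self.lineages.pop(j)
        x = self.lineages.pop(i)
        self.sum_w -= x.w_in + y.w_in
        self.sum_e -= x.w_ext + y.w_ext
        inter = x.material & y.material
        mat = x.material | y.material
        clonal = x.clonal or y.clonal
        nid = self.arg.add_node("coalescence", self.t,
                                [(x.node_id, x.role), (y.node_id, y.role)],
                                clonal)
        node = self.arg.nodes[nid]
        if inter:
            prune = self._decrement_and_singles(inter)
            if prune:
                node.mrca = prune
                mat = mat - prune
                self._counts_zero(prune)
        node.material = mat
        if x.clonal and y.clonal:
            cf = TreeNode(time=self.t, children=[x.cf, y.cf])
        else:
            cf = x.cf if x.clonal else y.cf
        if clonal or mat:
            lin = _Lineage(nid, None, mat, clonal, cf)
            self._refresh(lin)
            self.lineages.append(lin)

    def do_within(self, idx: int, s: int, raw_length: int,
                  tract: IntervalSet) -> None:
        lin = self.lineages[idx]
        donor_mat = lin.material & tract
        recip_mat = lin.material - tract
        nid = self.arg.add_node("recomb_split", self.t,
                                [(lin.node_id, lin.role)], lin.clonal,
                                tract=tract, material=lin.material)
        self.events.append(EventRecord("within", self.t, lin.node_id,
                                       tract, raw_length))
        lin.node_id = nid
        lin.role = "recipient"
        lin.material = recip_mat
        self._refresh(lin)
        donor = _Lineage(nid, "donor", donor_mat, False, None)
        self._refresh(donor)
        self.lineages.append(donor)

    def do_external(self, idx: int, s: int, raw_length: int,
                    tract: IntervalSet) -> None:
        lin = self.lineages[idx]
        removed = lin.material & tract
        d = self.rng.uniform(self.params.div_min, self.params.div_max)
        nid = self.arg.add_node("external_import", self.t,
                                [(lin.node_id, lin.role)], lin.clonal,
                                tract=tract, divergence=d,
                                material=lin.material - removed)
        self.events.append(EventRecord("external", self.t, lin.node_id,
                                       tract, raw_length, d))
        lin.node_id = nid
        lin.role = None
        lin.material = lin.material - removed
        self._refresh(lin)
        prune = self._decrement_and_singles(removed)
        if prune:
            self._prune_from_others(prune)
        if lin.material.is_empty and not lin.clonal:
            self._drop(lin)

    # -- finish -------------------------------------------------------------

    def finish(self) -> Tuple[Arg, LocalTree, List[EventRecord]]:
        assert len(self.lineages) == 1
        top = self.lineages[0]
        node = self.arg.nodes[top.node_id]
        if node.kind == "coalescence":
            node.kind = "root"
        self.arg.finalize(top.node_id)
        frame = LocalTree(root=top.cf, n=self.params.n)
        return self.arg, frame, self.events


def simulate_arg(params: Parameters, rng=None, *,
                 max_events: int = 5_000_000, record_materials: bool = True
                 ) -> Tuple[Arg, LocalTree, List[EventRecord]]:
    """Generate an ARG, its clonal frame and the chronological event list.

    Competing exponentials: coalescence at ``k(k-1)/2``, within-species
    recombination at the summed per-lineage effective rates, between-species
    likewise; the whole event loop runs compiled.  A fixed seed reproduces
    the identical ARG on one platform.

    ``record_materials=False`` skips per-node ancestral-material snapshots
    (needed only for the material-mode ARG rendering), which trims memory
    for large runs.

    Raises ``RuntimeError`` when more than ``max_events`` events accumulate
    (non-termination guard; the offending parameter set is reported).
    """
    from ._simkernel import sim_loop

    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params
    genome = p.genome
    seed = int(rng.integers(0, 2 ** 31 - 1))
    out = sim_loop(genome.total_length, genome.circular,
                   genome.seq_intervals().bounds, p.n,
                   float(p.rho_int), float(p.delta_int),
                   float(p.rho_ext), float(p.delta_ext),
                   float(p.div_min), float(p.div_max),
                   seed, max_events, record_materials)
    (nd_kind, nd_time, nd_clonal, nd_c1, nd_r1, nd_c2, nd_r2, nd_div,
     nd_toff, nd_tlen, tpool, nd_moff, nd_mlen, mpool,
     mr_node, mr_s, mr_e, ev_node, ev_rawlen,
     cf_t, cf_a, cf_b, root_node, root_cf, ok) = out
    if not ok:
        raise RuntimeError(
            f"event cap {max_events} exceeded; parameters: {p}")
    raw = {"kind": nd_kind, "time": nd_time, "clonal": nd_clonal,
           "c1": nd_c1, "r1": nd_r1, "c2": nd_c2, "r2": nd_r2,
           "div": nd_div, "toff": nd_toff, "tlen": nd_tlen, "tpool": tpool,
           "moff": nd_moff, "mlen": nd_mlen, "mpool": mpool,
           "mr_node": mr_node, "mr_s": mr_s, "mr_e": mr_e,
           "ev_node": ev_node, "ev_rawlen": ev_rawlen,
           "root_node": root_node}
    arg = Arg._from_raw(genome, p.n, raw)
    # clonal frame straight from the recorded clonal joins
    cfs = [TreeNode(time=0.0, label=f"sample_{i + 1}") for i in range(p.n)]
    for tt, a, b in zip(cf_t, cf_a, cf_b):
        cfs.append(TreeNode(time=float(tt),
                            children=[cfs[int(a)], cfs[int(b)]]))
    frame = LocalTree(root=cfs[int(root_cf)], n=p.n)
    events = _LazyEvents(raw)
    return arg, frame, events


class _LazyEvents:
    """Chronological event list, materialised on first element access."""

    def __init__(self, raw: dict):
        self._raw = raw
        self._list: Optional[List[EventRecord]] = None

    def _materialize(self) -> List[EventRecord]:
        if self._list is None:
            raw = self._raw
            out = []
            for nid, rawlen in zip(raw["ev_node"], raw["ev_rawlen"]):
                nid = int(nid)
                kind = "within" if raw["kind"][nid] == 2 else "external"
                d = float(raw["div"][nid])
                tract = IntervalSet._from_bounds(
                    raw["tpool"][raw["toff"][nid]:
                                 raw["toff"][nid] + raw["tlen"][nid]])
                out.append(EventRecord(kind, float(raw["time"][nid]),
                                       int(raw["c1"][nid]), tract,
                                       int(rawlen),
                                       None if d != d else d))
            self._list = out
        return self._list

    def __len__(self) -> int:
        return int(self._raw["ev_node"].size)

    def __iter__(self):
        return iter(self._materialize())

    def __getitem__(self, i):
        return self._materialize()[i]

    def __repr__(self) -> str:
        return f"<EventList n={len(self)}>"


def clonal_frame(arg: Arg) -> LocalTree:
    """Clonal genealogy of a completed ARG: follow, through every
    recombination split, the recipient branch.

    Reconstructed from the graph by tracing clonal paths; equals the tree
    returned alongside :func:`simulate_arg`.
    """
    n = arg.n
    paths = {}
    for leaf in range(n):
        path = [leaf]
        cur = leaf
        while True:
            node = arg.nodes[cur]
            role = "recipient" if node.kind == "recomb_split" else None
            nxt = arg.parent_of.get((cur, role))
            if nxt is None:
                break
            path.append(nxt)
            cur = nxt
        paths[leaf] = path

    clade = {leaf: TreeNode(time=0.0, label=f"sample_{leaf + 1}")
             for leaf in range(n)}
    rep = {leaf: leaf for leaf in range(n)}

    def find(x):
        while rep[x] != x:
            rep[x] = rep[rep[x]]
            x = rep[x]
        return x

    visits: dict[int, list[int]] = {}
    for leaf, path in paths.items():
        for nid in path[1:]:
            visits.setdefault(nid, []).append(leaf)
    for nid in sorted(visits, key=lambda i: (arg.nodes[i].time, i)):
        node = arg.nodes[nid]
        groups = sorted({find(l) for l in visits[nid]})
        if len(groups) > 1 and node.kind in ("coalescence", "root"):
            new = TreeNode(time=node.time,
                           children=[clade[g] for g in groups])
            for g in groups[1:]:
                rep[g] = groups[0]
            clade[groups[0]] = new
    roots = sorted({find(l) for l in range(n)})
    assert len(roots) == 1, "clonal paths failed to merge"
    return LocalTree(root=clade[roots[0]], n=n)
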