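"""Independent oracles and the clonal-frame recovery experiment harness.

Brute-force enumeration of effective-event rates and tract distributions,
a rejection-sampling ARG simulator (candidate events at the raw initiation
rate, ineffective candidates discarded), standard coalescent closed forms,
JC distance-based tree inference (neighbour joining and UPGMA) and
Robinson-Foulds branch accuracy.  These re-derive, by slower independent
routes, the quantities the analytical simulator computes in closed form.
"""

from __future__ import annotations

import io
import logging
import math
import shutil
import subprocess
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import dendropy

from .argsim import (Arg, EventRecord, Parameters, _SimCore,
                     effective_external_rate, effective_within_rate)
from .genealogies import LocalTree, TreeNode
from .genome import GenomeMap, IntervalSet, wrap_interval
from .seqevolve import Alignment, simulate_alignment

__all__ = [
    "brute_force_within_rate", "brute_force_external_rate",
    "brute_force_within_tract_probs", "brute_force_external_tract_probs",
    "rejection_simulate_arg", "RejectionStats", "forced_import_arg",
    "coalescent_expectations", "jc_distance", "jc_distance_matrix",
    "nj_tree", "upgma_tree", "fasttree_ml_adapter",
    "branch_accuracy", "branch_accuracy_by_age",
    "ExperimentConfig", "run_clonal_recovery_experiment",
]

logger = logging.getLogger("bacsim")


# ---------------------------------------------------------------------------
# brute-force enumeration of effective rates and tract laws
# ---------------------------------------------------------------------------

def _geom_pmf(l: int, delta: float) -> float:
    p = 1.0 / delta
    return p * (1.0 - p) ** (l - 1)


def _geom_tail(l: int, delta: float) -> float:
    """P(length >= l)."""
    return (1.0 - 1.0 / delta) ** (l - 1)


def brute_force_within_rate(material: IntervalSet, genome: GenomeMap,
                            delta: float, *, rho: float = 1.0) -> float:
    """Direct enumeration of (R/2) * sum_{s,l} P(l) [tract bipartitions
    material], with the geometric tail beyond tract saturation summed
    analytically.  Small genomes only."""
    G = genome.total_length
    total = 0.0
    for s in range(G):
        if genome.circular:
            # l >= G covers the whole genome: never a bipartition
            for l in range(1, G):
                tract = wrap_interval(s, l, genome)
                if (material & tract) and (material - tract):
                    total += _geom_pmf(l, delta)
        else:
            sat = G - s           # tract footprint saturates at [s, G)
            for l in range(1, sat):
                tract = wrap_interval(s, l, genome)
                if (material & tract) and (material - tract):
                    total += _geom_pmf(l, delta)
            tract = wrap_interval(s, sat, genome)
            if (material & tract) and (material - tract):
                total += _geom_tail(sat, delta)
    return 0.5 * rho * total


def brute_force_external_rate(material: IntervalSet, genome: GenomeMap,
                              delta: float, *, rho: float = 1.0) -> float:
    """Direct enumeration of (R_e/2) * sum_{s,l} P(l) [tract touches
    material]."""
    G = genome.total_length
    total = 0.0
    for s in range(G):
        sat = G if genome.circular else G - s
        for l in range(1, sat):
            tract = wrap_interval(s, l, genome)
            if material & tract:
                total += _geom_pmf(l, delta)
        tract = wrap_interval(s, sat, genome)
        if material & tract:
            total += _geom_tail(sat, delta)
    return 0.5 * rho * total


def brute_force_within_tract_probs(material: IntervalSet, genome: GenomeMap,
                                   delta: float) -> Dict[IntervalSet, float]:
    """Probability of each effective tract footprint, by enumeration,
    normalised to 1 (the law sampled by ``sample_within_event``)."""
    G = genome.total_length
    probs: Dict[IntervalSet, float] = {}
    for s in range(G):
        sat = G if genome.circular else G - s
        for l in range(1, sat):
            tract = wrap_interval(s, l, genome)
            if (material & tract) and (material - tract):
                probs[tract] = probs.get(tract, 0.0) + _geom_pmf(l, delta)
        tract = wrap_interval(s, sat, genome)
        if (material & tract) and (material - tract):
            probs[tract] = probs.get(tract, 0.0) + _geom_tail(sat, delta)
    z = sum(probs.values())
    return {t: p / z for t, p in probs.items()}


def brute_force_external_tract_probs(material: IntervalSet, genome: GenomeMap,
                                     delta: float) -> Dict[IntervalSet, float]:
    G = genome.total_length
    probs: Dict[IntervalSet, float] = {}
    for s in range(G):
        sat = G if genome.circular else G - s
        for l in range(1, sat):
            tract = wrap_interval(s, l, genome)
            if material & tract:
                probs[tract] = probs.get(tract, 0.0) + _geom_pmf(l, delta)
        tract = wrap_interval(s, sat, genome)
        if material & tract:
            probs[tract] = probs.get(tract, 0.0) + _geom_tail(sat, delta)
    z = sum(probs.values())
    return {t: p / z for t, p in probs.items()}


# ---------------------------------------------------------------------------
# rejection-sampling simulator (the discarded baseline, kept as oracle)
# ---------------------------------------------------------------------------

@dataclass
class RejectionStats:
    """Raw-candidate bookkeeping of one rejection-sampling run."""

    raw_within: int = 0
    accepted_within: int = 0
    raw_external: int = 0
    accepted_external: int = 0
    #: realized integral of the active-lineage count over time; candidate
    #: counts are Poisson with mean (rate/2) * G * lineage_time
    lineage_time: float = 0.0
    #: realized integrals of the summed per-lineage effective rates;
    #: accepted-candidate counts are Poisson with these means
    effective_within_exposure: float = 0.0
    effective_external_exposure: float = 0.0


def rejection_simulate_arg(params: Parameters, rng=None, *,
                           max_candidates: int = 20_000_000
                           ) -> Tuple[Arg, LocalTree, List[EventRecord],
                                      RejectionStats]:
    """ARG simulation with naive rejection sampling of recombination.

    Candidate events are proposed at the unconditioned initiation rate
    ``(R/2) G`` per lineage with ``(s, l)`` from the raw product law
    (uniform start, geometric length); candidates that do not alter
    ancestral material are discarded without advancing lineage state.
    Distributionally equivalent to :func:`bacsim.argsim.simulate_arg`, and
    practical only for small genomes and modest rates.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    core = _SimCore(params, rng)
    p = params
    G = p.genome.total_length
    stats = RejectionStats()
    n_cand = 0
    while len(core.lineages) > 1:
        n_cand += 1
        if n_cand > max_candidates:
            raise RuntimeError(
                f"candidate cap {max_candidates} exceeded; parameters: {p}")
        k = len(core.lineages)
        c_rate = k * (k - 1) / 2.0
        w_rate = 0.5 * p.rho_int * G * k
        e_rate = 0.5 * p.rho_ext * G * k
        total = c_rate + w_rate + e_rate
        wait = rng.exponential(1.0 / total)
        core.t += wait
        stats.lineage_time += k * wait
        if p.rho_int > 0.0:
            stats.effective_within_exposure += wait * sum(
                effective_within_rate(lin.material, p.genome, p.delta_int,
                                      rho_int=p.rho_int)
                for lin in core.lineages if lin.material)
        if p.rho_ext > 0.0:
            stats.effective_external_exposure += wait * sum(
                effective_external_rate(lin.material, p.genome, p.delta_ext,
                                        rho_ext=p.rho_ext)
                for lin in core.lineages if lin.material)
        u = rng.random() * total
        if u < c_rate:
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            core.do_coalescence(i, j)
        elif u < c_rate + w_rate:
            stats.raw_within += 1
            idx = int(rng.integers(k))
            lin = core.lineages[idx]
            s = int(rng.integers(G))
            l = int(rng.geometric(1.0 / p.delta_int))
            tract = wrap_interval(s, min(l, G) if p.genome.circular else l,
                                  p.genome)
            if (lin.material & tract) and (lin.material - tract):
                stats.accepted_within += 1
                core.do_within(idx, s, l, tract)
        else:
            stats.raw_external += 1
            idx = int(rng.integers(k))
            lin = core.lineages[idx]
            s = int(rng.integers(G))
            l = int(rng.geometric(1.0 / p.delta_ext))
            tract = wrap_interval(s, min(l, G) if p.genome.circular else l,
                                  p.genome)
            if lin.material & tract:
                stats.accepted_external += 1
                core.do_external(idx, s, l, tract)
    arg, frame, events = core.finish()
    return arg, frame, events, stats


def forced_import_arg(genome: GenomeMap, tract: IntervalSet, d: float,
                      theta: float = 0.0):
    """Deterministic four-sample ARG with exactly one between-species
    import, driven by hand through the pure-Python event core.

    Samples 3 and 4 coalesce first; their lineage receives an import over
    ``tract`` with divergence ``d`` before joining the rest, so alignment
    differences must be confined to that clade and tract.  Returns
    ``(arg, clonal_frame, events, params)``.
    """
    params = Parameters(n=4, genome=genome, theta=theta,
                        rho_ext=1e-9, delta_ext=10.0,
                        div_min=d, div_max=d)
    core = _SimCore(params, np.random.default_rng(0))
    core.t = 0.3
    core.do_coalescence(2, 3)         # clade {sample_3, sample_4}
    core.t = 0.5
    idx = next(i for i, lin in enumerate(core.lineages)
               if lin.cf is not None and lin.cf.time == 0.3)
    core.do_external(idx, tract.first, tract.total_sites, tract)
    core.t = 0.7
    core.do_coalescence(0, 1)         # clade {sample_1, sample_2}
    core.t = 1.1
    core.do_coalescence(0, 1)
    arg, frame, events = core.finish()
    return arg, frame, events, params


# ---------------------------------------------------------------------------
# coalescent closed forms
# ---------------------------------------------------------------------------

def coalescent_expectations(n: int) -> Tuple[float, float]:
    """(E[TMRCA], E[total branch length]) for an n-sample coalescent,
    in units of N_e generations: 2(1 - 1/n) and 2 * sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("n must be >= 2")
    e_tmrca = 2.0 * (1.0 - 1.0 / n)
    e_total = 2.0 * sum(1.0 / i for i in range(1, n))
    return e_tmrca, e_total


# ---------------------------------------------------------------------------
# distance-based tree inference
# ---------------------------------------------------------------------------

def jc_distance(p_hat: float) -> float:
    """JC-corrected distance (expected substitutions per site) from an
    observed proportion of differing sites; saturates near p = 0.75."""
    if p_hat < 0:
        raise ValueError("proportion must be >= 0")
    x = 1.0 - 4.0 * p_hat / 3.0
    if x <= 0:
        return 25.0  # saturated; effectively infinite
    return -0.75 * math.log(x)


def jc_distance_matrix(aln: Alignment) -> np.ndarray:
    n = aln.matrix.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_distance(aln.pairwise_diff(i, j))
            dm[i, j] = dm[j, i] = d
    return dm


def _pdm(dm: np.ndarray, ids: Sequence[str]) -> dendropy.PhylogeneticDistanceMatrix:
    buf = io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for i, name in enumerate(ids):
        buf.write(name + "," + ",".join(f"{x:.10g}" for x in dm[i]) + "\n")
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, delimiter=",")


def nj_tree(aln: Alignment) -> dendropy.Tree:
    """Neighbour-joining tree from pairwise JC distances."""
    return _pdm(jc_distance_matrix(aln), aln.ids).nj_tree()


def upgma_tree(aln: Alignment) -> dendropy.Tree:
    """UPGMA tree from pairwise JC distances."""
    return _pdm(jc_distance_matrix(aln), aln.ids).upgma_tree()


def fasttree_ml_adapter(aln: Alignment) -> Optional[dendropy.Tree]:
    """Maximum-likelihood inference through an external ``fasttree``
    binary, if one is on PATH; returns None otherwise."""
    exe = shutil.which("fasttree") or shutil.which("FastTree")
    if exe is None:
        return None
    fasta = []
    for i, name in enumerate(aln.ids):
        fasta.append(f">{name}\n{aln.sequence(i)}\n")
    proc = subprocess.run([exe, "-nt", "-gtr", "-nosupport", "-quiet"],
                          input="".join(fasta).encode(),
                          capture_output=True, check=True)
    return dendropy.Tree.get(data=proc.stdout.decode(), schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# Robinson-Foulds branch accuracy
# ---------------------------------------------------------------------------

def _bipartitions_of_localtree(tree: LocalTree) -> Tuple[list, frozenset]:
    """Non-trivial bipartitions of a LocalTree as frozensets of leaf labels
    (the side not containing the reference taxon), plus the full leaf set."""
    all_leaves = tree.leaf_labels()
    ref = min(all_leaves)
    bips = []

    def walk(node: TreeNode) -> frozenset:
        if not node.children:
            return frozenset([node.label])
        below = frozenset()
        for c in node.children:
            below |= walk(c)
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            bips.append(side)
        return below

    walk(tree.root)
    return bips, all_leaves


def _bipartitions_of_dendropy(tree: dendropy.Tree,
                              all_leaves: frozenset) -> set:
    ref = min(all_leaves)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            bips.add(side)
    return bips


def branch_accuracy(true_tree: LocalTree, inferred_tree) -> float:
    """Fraction of the true tree's internal branches (non-trivial
    bipartitions) whose bipartition appears in the inferred tree."""
    true_bips, leaves = _bipartitions_of_localtree(true_tree)
    if isinstance(inferred_tree, LocalTree):
        inf_list, inf_leaves = _bipartitions_of_localtree(inferred_tree)
        inferred = set(inf_list)
    else:
        inf_leaves = frozenset(l.taxon.label
                               for l in inferred_tree.leaf_node_iter())
        inferred = _bipartitions_of_dendropy(inferred_tree, inf_leaves)
    if inf_leaves != leaves:
        raise ValueError("leaf sets differ between true and inferred trees")
    if not true_bips:
        return 1.0
    hits = sum(1 for b in true_bips if b in inferred)
    return hits / len(true_bips)


def branch_accuracy_by_age(true_tree: LocalTree, inferred_tree,
                           thresholds: Tuple[float, float] = (1.32, 2.09)
                           ) -> Dict[str, Tuple[int, int]]:
    """Per-age-class (hits, total) over the true tree's internal branches.

    A branch is classified by the distance from the root to its mid-point:
    'old' below the first threshold, 'middle' between the two, 'young'
    beyond the second (all in N_e generations).
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be increasing")
    true_bips, leaves = _bipartitions_of_localtree(true_tree)
    if isinstance(inferred_tree, LocalTree):
        inf_list, inf_leaves = _bipartitions_of_localtree(inferred_tree)
        inferred = set(inf_list)
    else:
        inf_leaves = frozenset(l.taxon.label
                               for l in inferred_tree.leaf_node_iter())
        inferred = _bipartitions_of_dendropy(inferred_tree, inf_leaves)
    if inf_leaves != leaves:
        raise ValueError("leaf sets differ between true and inferred trees")
    root_t = true_tree.root.time
    ref = min(leaves)
    out = {"old": [0, 0], "middle": [0, 0], "young": [0, 0]}

    def walk(node: TreeNode, parent_time: Optional[float]):
        below = frozenset()
        if not node.children:
            return frozenset([node.label])
        for c in node.children:
            below |= walk(c, node.time)
        if parent_time is not None and 1 < len(below) < len(leaves) - 1:
            mid = 0.5 * (parent_time + node.time)
            dist = root_t - mid
            cls = "old" if dist < lo else ("middle" if dist < hi else "young")
            side = below if ref not in below else leaves - below
            out[cls][1] += 1
            if side in inferred:
                out[cls][0] += 1
        return below

    walk(true_tree.root, None)
    return {k: (v[0], v[1]) for k, v in out.items()}


# ---------------------------------------------------------------------------
# clonal-frame recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Grid for the clonal-frame recovery experiment.

    Defaults are the scaled-down study conditions used by the test suite
    (50 kb genomes, 15 samples); the full-scale script raises genome length
    to 1 Mbp.  ``age_thresholds`` split branches into old / middle / young
    by root-to-midpoint distance at 1.32 and 2.09 N_e generations.
    """

    r_grid: Tuple[float, ...] = (0.0, 0.1)
    n_reps: int = 50
    n: int = 15
    genome_length: int = 50_000
    theta: float = 0.01
    delta: float = 500.0
    methods: Tuple[str, ...] = ("nj", "upgma")
    age_thresholds: Tuple[float, float] = (1.32, 2.09)
    ml_adapter: Optional[Callable[[Alignment], Optional[dendropy.Tree]]] = None

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("need at least one replicate")


_INFERRERS = {"nj": nj_tree, "upgma": upgma_tree}


def run_clonal_recovery_experiment(config: ExperimentConfig, rng
                                   ) -> List[dict]:
    """Simulate, infer and score clonal-frame recovery over a rate grid.

    Per replicate: simulate an alignment, infer a tree per method, score
    Robinson-Foulds branch accuracy against the true clonal frame, overall
    and per branch-age class.  Returns tidy rows
    ``{R, method, age_class, mean_accuracy, sd, n_reps}`` ('all' rows give
    the overall accuracy).  Replicates are paired across R values through
    per-replicate child seeds.
    """
    from .argsim import simulate_arg  # local import avoids cycle at startup

    methods = list(config.methods)
    if "ml" in methods:
        adapter = config.ml_adapter or fasttree_ml_adapter
    else:
        adapter = None
    genome = GenomeMap.whole(config.genome_length, circular=True)
    seeds = rng.integers(0, 2 ** 31 - 1, size=config.n_reps)
    acc: Dict[tuple, list] = {}
    ml_warned = False
    for r_val in config.r_grid:
        for rep, seed in enumerate(seeds):
            params = Parameters(n=config.n, genome=genome,
                                theta=config.theta, rho_int=float(r_val),
                                delta_int=config.delta)
            rep_rng = np.random.default_rng(int(seed))
            arg, frame, _events = simulate_arg(params, rep_rng)
            aln = simulate_alignment(arg, params, rep_rng)
            for method in methods:
                if method == "ml":
                    inferred = adapter(aln) if adapter else None
                    if inferred is None:
                        if not ml_warned:
                            logger.warning(
                                "no ML adapter available; reporting NJ/UPGMA only")
                            ml_warned = True
                        continue
                else:
                    inferred = _INFERRERS[method](aln)
                overall = branch_accuracy(frame, inferred)
                acc.setdefault((r_val, method, "all"), []).append(overall)
                by_age = branch_accuracy_by_age(frame, inferred,
                                                config.age_thresholds)
                for cls, (hits, tot) in by_age.items():
                    if tot:
                        acc.setdefault((r_val, method, cls),
                                       []).append(hits / tot)
    rows = []
    for (r_val, method, cls), vals in sorted(acc.items()):
        rows.append({
            "R": r_val, "method": method, "age_class": cls,
            "mean_accuracy": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_reps": len(vals),
        })
    return rows
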