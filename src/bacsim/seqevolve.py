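"""Jukes-Cantor sequence simulation down the ARG.

The root sequence is i.i.d. uniform over {A,C,G,T} (the JC stationary
distribution).  Along every edge each site accumulates substitutions as a
Poisson process of rate theta/2 per unit coalescent time, each substitution
replacing the base by one of the other three uniformly.  At recombination
splits the tract content is spliced from the donor-side parent; at
between-species imports the tract is rewritten from the root-homologous
sequence with per-site probability ``d`` of differing from it (the
divergence drawn at event time); sites are handed the root sequence at their
recorded local MRCA.

Sequences are kept as uint8 arrays with bases encoded 0..3 = A,C,G,T over
alignment columns (sequence-bearing sites only); a substitution is an
additive shift in Z/4, so independently drawn shifts compose exactly like
successive JC substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .argsim import Arg, Parameters
from .genome import GenomeMap, IntervalSet

__all__ = ["Alignment", "draw_root_sequence", "evolve_edge",
           "apply_external_import", "simulate_alignment", "BASES"]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Alignment:
    """n sequences over alignment columns; rows match ARG leaves in order."""

    ids: list
    matrix: np.ndarray  # (n, seq_length) uint8 codes 0..3
    genome: GenomeMap

    def sequence(self, i: int) -> str:
        return BASES[self.matrix[i]].tobytes().decode()

    def segregating_sites(self) -> int:
        return int(np.count_nonzero(
            (self.matrix != self.matrix[0]).any(axis=0)))

    def pairwise_diff(self, i: int, j: int) -> float:
        """Proportion of differing sites between rows i and j."""
        return float(np.mean(self.matrix[i] != self.matrix[j]))


def draw_root_sequence(genome: GenomeMap, rng) -> np.ndarray:
    """Uniform random sequence over the sequence-bearing sites."""
    return rng.integers(0, 4, size=genome.seq_length, dtype=np.uint8)


def evolve_edge(seq: np.ndarray, branch_length: float, theta: float,
                rng) -> np.ndarray:
    """Evolve a copy of ``seq`` for ``branch_length`` coalescent units.

    Substitution counts are Poisson(theta/2 * branch_length) per site;
    multiple hits compose correctly because uniform shifts in Z/4 are closed
    under addition.
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    out = seq.copy()
    mean = 0.5 * theta * branch_length * seq.size
    if mean == 0.0:
        return out
    n_mut = int(rng.poisson(mean))
    if n_mut:
        sites = rng.integers(0, seq.size, size=n_mut)
        shifts = rng.integers(1, 4, size=n_mut).astype(np.uint8)
        np.add.at(out, sites, shifts)
        out &= 3  # uint8 wrap-around is mod 256, a multiple of 4
    return out


def apply_external_import(root_seq: np.ndarray, tract: IntervalSet,
                          d: float, rng,
                          genome: Optional[GenomeMap] = None) -> np.ndarray:
    """Donor content for a between-species import.

    Copies the root-homologous sequence over the tract's sequence-bearing
    columns and, independently per site with probability ``d``, replaces the
    base by one of the other three.  Returns the concatenated fragment in
    column order.  If ``genome`` is omitted the tract is taken to be in
    column coordinates already.
    """
    if not (0.0 <= d <= 0.75):
        raise ValueError(f"divergence {d} outside [0, 0.75]")
    if genome is not None:
        cols = genome.to_columns(tract)
    else:
        cols = list(tract)
    pieces = [root_seq[s:e] for s, e in cols]
    frag = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    frag = frag.copy()
    if frag.size:
        hit = rng.random(frag.size) < d
        n_hit = int(hit.sum())
        if n_hit:
            shifts = rng.integers(1, 4, size=n_hit).astype(np.uint8)
            frag[hit] = (frag[hit] + shifts) & 3
    return frag


def _col_slices(genome: GenomeMap, tract: IntervalSet) -> list:
    return genome.to_columns(tract)


def simulate_alignment(arg: Arg, params: Parameters, rng) -> Alignment:
    """Evolve sequences tip-ward through a completed ARG.

    Nodes are processed root-ward-first (decreasing time).  Each node
    assembles its sequence from its parent(s) -- splicing the tract from the
    donor side at splits, injecting root-derived donor content at
    between-species imports -- then overwrites sites whose local MRCA it is
    with the root sequence, and finally evolves a copy down each child edge.
    """
    if arg.n != params.n or arg.genome is not params.genome \
            and arg.genome.fragments != params.genome.fragments:
        raise ValueError("ARG and parameters describe different problems")
    genome = arg.genome
    root_seq = draw_root_sequence(genome, rng)
    theta = params.theta

    if getattr(arg, "_raw", None) is not None:
        return _simulate_alignment_raw(arg, params, root_seq, rng)

    order = sorted(arg.nodes, key=lambda nd: (-nd.time, -nd.id))
    # per-edge substitution counts in one batched Poisson draw; edges are
    # consumed in the same deterministic order below
    L = genome.seq_length
    edge_lens = []
    for node in order:
        for child_id, _role in node.children:
            edge_lens.append(node.time - arg.nodes[child_id].time)
    if edge_lens:
        n_muts = rng.poisson(0.5 * theta * L * np.asarray(edge_lens))
    else:
        n_muts = np.empty(0, dtype=np.int64)

    slots: dict = {}
    leaf_rows: dict[int, np.ndarray] = {}
    edge_i = 0
    for node in order:
        # assemble this node's sequence from its parent deliveries;
        # delivered arrays are owned here and may be mutated in place
        mine = slots.pop(node.id, {})
        if node.kind == "recomb_split":
            recip = mine.get("recipient")
            donor = mine.get("donor")
            seq = recip if recip is not None else root_seq.copy()
            src = donor if donor is not None else root_seq
            for s, e in _col_slices(genome, node.tract):
                seq[s:e] = src[s:e]
        else:
            got = mine.get(None)
            seq = got if got is not None else root_seq.copy()
            if node.kind == "external_import":
                frag = apply_external_import(root_seq, node.tract,
                                             node.divergence, rng, genome)
                pos = 0
                for s, e in _col_slices(genome, node.tract):
                    seq[s:e] = frag[pos:pos + (e - s)]
                    pos += e - s
        if node.mrca:
            for s, e in _col_slices(genome, node.mrca):
                seq[s:e] = root_seq[s:e]
        if node.kind == "leaf":
            leaf_rows[node.id] = seq
            continue
        last = len(node.children) - 1
        for ci, (child_id, role) in enumerate(node.children):
            out = seq if ci == last else seq.copy()
            nm = int(n_muts[edge_i])
            edge_i += 1
            if nm:
                sites = rng.integers(0, L, size=nm)
                shifts = rng.integers(1, 4, size=nm).astype(np.uint8)
                np.add.at(out, sites, shifts)
                out &= 3
            slots.setdefault(child_id, {})[role] = out
    matrix = np.vstack([leaf_rows[i] for i in range(arg.n)])
    ids = [f"sample_{i + 1}" for i in range(arg.n)]
    return Alignment(ids=ids, matrix=matrix, genome=genome)


def _col_map(genome: GenomeMap) -> np.ndarray:
    """site -> alignment column (-1 for gap sites), cached per genome."""
    cm = getattr(genome, "_col_map_cache", None)
    if cm is None:
        cm = np.full(genome.total_length, -1, dtype=np.int64)
        col = 0
        for fs, fe in genome.fragment_spans:
            cm[fs:fe] = np.arange(col, col + fe - fs)
            col += fe - fs
        object.__setattr__(genome, "_col_map_cache", cm)
    return cm


def _simulate_alignment_raw(arg: Arg, params: Parameters,
                            root_seq: np.ndarray, rng) -> Alignment:
    """Compiled tip-ward pass over the simulator's flat array form."""
    from ._simkernel import align_loop, count_buffers

    raw = arg._raw
    genome = arg.genome
    n_nodes = raw["kind"].size
    # CSR layout of per-node MRCA runs
    mr_node = raw["mr_node"]
    order = np.argsort(mr_node, kind="stable")
    counts = np.bincount(mr_node, minlength=n_nodes) if mr_node.size \
        else np.zeros(n_nodes, dtype=np.int64)
    mr_off = np.zeros(n_nodes + 1, dtype=np.int64)
    np.cumsum(counts, out=mr_off[1:])
    mr_bounds = np.empty(2 * mr_node.size, dtype=np.int64)
    mr_bounds[0::2] = raw["mr_s"][order]
    mr_bounds[1::2] = raw["mr_e"][order]
    # 64-bit-aliased buffers for fast whole-row copies
    L = genome.seq_length
    L8 = (L + 7) // 8
    n_buf = int(count_buffers(n_nodes, raw["kind"], raw["c1"], raw["r1"],
                              raw["c2"], raw["r2"])) + 2
    pool8 = np.zeros((n_buf, L8 * 8), dtype=np.uint8)
    pool64 = pool8.view(np.uint64)
    root8 = np.zeros(L8 * 8, dtype=np.uint8)
    root8[:L] = root_seq
    root64 = root8.view(np.uint64)
    out8 = np.zeros((arg.n, L8 * 8), dtype=np.uint8)
    out64 = out8.view(np.uint64)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    align_loop(arg.n, L, _col_map(genome),
               raw["kind"], raw["time"], raw["c1"], raw["r1"],
               raw["c2"], raw["r2"], raw["div"],
               raw["toff"], raw["tlen"], raw["tpool"],
               mr_off, mr_bounds,
               pool8, pool64, root8, root64, out8, out64,
               float(params.theta), seed)
    matrix = np.ascontiguousarray(out8[:, :L])
    ids = [f"sample_{i + 1}" for i in range(arg.n)]
    return Alignment(ids=ids, matrix=matrix, genome=genome)
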