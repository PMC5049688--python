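"""Marginal genealogies: local trees, breakpoints and the clonal frame container.

Every genomic site of an ancestral recombination graph (ARG) marginalises to
a single rooted genealogy, the *local tree*.  Following a site from each leaf
root-ward -- taking the donor parent at a recombination split when the site
lies inside the imported tract, the recipient parent otherwise -- yields the
per-site ancestry; paths merge at coalescences and may terminate early at a
between-species import, in which case the terminated clade is grafted onto
the local-tree root with a divergence annotation.

Trees are stored in a minimal ultrametric representation (:class:`TreeNode` /
:class:`LocalTree`) with node times in coalescent units of ``N_e``
generations; Newick export converts times to branch lengths, optionally
rescaled to expected substitutions per site (multiply by theta/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome import IntervalSet

__all__ = ["TreeNode", "LocalTree", "local_tree", "breakpoints", "tmrca",
           "segment_trees"]


@dataclass
class TreeNode:
    """Node of a sample genealogy; ``time`` is measured back from the leaves."""

    time: float
    children: list = field(default_factory=list)
    label: Optional[str] = None
    #: divergence of a between-species import terminating this clade's
    #: ancestry; None for ordinary coalescent edges
    import_div: Optional[float] = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset:
        return frozenset(l.label for l in self.leaves())

    def signature(self) -> tuple:
        """Canonical hashable form: topology, times and import annotations."""
        if not self.children:
            return ("leaf", self.label, self.time, self.import_div)
        kids = tuple(sorted(c.signature() for c in self.children))
        return ("node", kids, self.time, self.import_div)

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class LocalTree:
    """Rooted genealogy of the n samples for one genomic segment.

    Branch lengths are in coalescent units.  Clades whose ancestry for this
    segment terminates at a between-species import carry ``import_div`` on
    their root; on Newick export such clades hang off the root with branch
    length ``2 d / theta`` (the coalescent-unit length whose expected
    substitution load at mutation rate theta/2 equals the observed divergence
    d) and a ``[&import ...]`` comment so consumers can tell them apart.
    Internally ``d`` itself is kept and sequence simulation uses it directly.
    """

    root: TreeNode
    n: int

    @property
    def tmrca(self) -> float:
        return self.root.time

    def leaf_labels(self) -> frozenset:
        return self.root.leaf_labels()

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """All leaf-to-root path lengths along coalescent edges agree."""
        ok = True

        def depth(node: TreeNode) -> None:
            nonlocal ok
            for leaf in node.leaves():
                if abs(leaf.time) > tol:
                    ok = False

        depth(self.root)
        # path length leaf->root is root.time - leaf.time for coalescent
        # edges; leaves at time 0 suffice for ultrametricity here
        return ok

    def signature(self) -> tuple:
        return self.root.signature()

    def newick(self, theta: Optional[float] = None,
               substitution_units: bool = False) -> str:
        """Newick string; import clades are grafted with length 2d/theta."""
        scale = (theta / 2.0) if substitution_units else 1.0
        if substitution_units and theta is None:
            raise ValueError("substitution units require theta")

        def fmt(node: TreeNode, parent_time: float) -> str:
            if node.import_div is not None:
                if theta and theta > 0:
                    blen = 2.0 * node.import_div / theta * scale
                else:
                    blen = 0.0
                tag = f"[&import,d={node.import_div:.6g}]"
            else:
                blen = (parent_time - node.time) * scale
                tag = ""
            if node.children:
                body = ",".join(fmt(c, node.time) for c in node.children)
                return f"({body}){tag}:{blen:.10g}"
            return f"{node.label}{tag}:{blen:.10g}"

        r = self.root
        if r.children:
            body = ",".join(fmt(c, r.time) for c in r.children)
            return f"({body});"
        return f"{r.label};"


def tmrca(tree: LocalTree) -> float:
    """Root time of a local tree, in coalescent units.

    The degenerate case of a tree whose every clade terminates at an
    external import has no coalescent root and is rejected.
    """
    root = tree.root
    if root.import_div is not None:
        raise ValueError("tree has no coalescent root (import-only ancestry)")
    return root.time


# ---------------------------------------------------------------------------
# per-site extraction from a completed ARG
# ---------------------------------------------------------------------------

def _trace_leaf(arg, leaf_id: int, site: int):
    """Follow one sample's ancestry for ``site`` root-ward.

    Returns ``(path, termination)`` where path is the list of visited node
    ids in ascending time and termination is ``("mrca", node_id)``,
    ``("import", node_id)`` or ``("top", node_id)``.
    """
    path = [leaf_id]
    cur = leaf_id
    while True:
        node = arg.nodes[cur]
        if node.mrca.contains(site):
            return path, ("mrca", cur)
        if node.kind == "external_import" and cur != leaf_id \
                and node.tract.contains(site):
            return path, ("import", cur)
        if node.kind == "recomb_split" and cur != leaf_id:
            role = "donor" if node.tract.contains(site) else "recipient"
        else:
            role = None
        nxt = arg.parent_of.get((cur, role))
        if nxt is None:
            return path, ("top", cur)
        path.append(nxt)
        cur = nxt


def _cluster(arg, members: dict, site: int) -> TreeNode:
    """Agglomerate leaf paths into a subtree by shared-node visits.

    ``members`` maps leaf id -> (path, leaf TreeNode).  Paths that share a
    node merge there at the node's time.  Returns the subtree root.
    """
    # node -> leaves visiting it, in ascending time order
    visits: dict[int, list[int]] = {}
    for leaf, (path, _) in members.items():
        for nid in path[1:]:
            visits.setdefault(nid, []).append(leaf)
    clade: dict[int, TreeNode] = {leaf: tn for leaf, (_, tn) in members.items()}
    rep: dict[int, int] = {leaf: leaf for leaf in members}  # leaf -> cluster rep

    def find(x: int) -> int:
        while rep[x] != x:
            rep[x] = rep[rep[x]]
            x = rep[x]
        return x

    for nid in sorted(visits, key=lambda i: (arg.nodes[i].time, i)):
        leaves_here = visits[nid]
        groups = sorted({find(l) for l in leaves_here})
        if len(groups) > 1:
            new = TreeNode(time=arg.nodes[nid].time,
                           children=[clade[g] for g in groups])
            tgt = groups[0]
            for g in groups[1:]:
                rep[g] = tgt
            clade[tgt] = new
    roots = sorted({find(l) for l in members})
    if len(roots) != 1:  # pragma: no cover - defensive
        t = max(clade[r].time for r in roots)
        return TreeNode(time=t, children=[clade[r] for r in roots])
    return clade[roots[0]]


def local_tree(arg, site: int) -> LocalTree:
    """Marginal genealogy of one sequence-bearing genomic site."""
    if not arg.genome.is_seq_site(site):
        raise ValueError(f"site {site} is a gap coordinate")
    n = arg.n
    traces = {}
    for leaf in range(n):
        path, term = _trace_leaf(arg, leaf, site)
        traces[leaf] = (path, term)

    # group leaves by termination: survivors (coalescent) vs import node
    survivors = {}
    import_groups: dict[int, dict] = {}
    resolve_time = 0.0
    for leaf, (path, term) in traces.items():
        tn = TreeNode(time=0.0, label=f"sample_{leaf + 1}")
        kind, nid = term
        if kind == "import":
            import_groups.setdefault(nid, {})[leaf] = (path, tn)
        else:
            survivors[leaf] = (path, tn)
            resolve_time = max(resolve_time, arg.nodes[nid].time)

    import_clades = []
    for nid, members in sorted(import_groups.items()):
        sub = _cluster(arg, members, site)
        sub.import_div = arg.nodes[nid].divergence
        import_clades.append(sub)

    if survivors:
        root = _cluster(arg, survivors, site)
        if import_clades:
            if not root.children or root.time < resolve_time:
                root = TreeNode(time=resolve_time, children=[root])
            root.children.extend(import_clades)
    else:
        # every clade imported; anchor the graft point at the last import
        t = max(arg.nodes[nid].time for nid in import_groups)
        if len(import_clades) == 1:
            root = import_clades[0]
        else:
            root = TreeNode(time=t, children=import_clades)
    return LocalTree(root=root, n=n)


def breakpoints(arg) -> list[int]:
    """Minimal segment boundaries between which the local tree is constant.

    Boundaries are genome coordinates drawn from recorded tract endpoints
    (and fragment boundaries); adjacent segments with identical local trees
    (topology, times and import annotations) are merged.
    """
    segs = segment_trees(arg)
    bounds = []
    for (start, _end), _tree in segs[1:]:
        bounds.append(start)
    return bounds


def _candidate_boundaries(arg) -> list[int]:
    cand = set()
    for fs, fe in arg.genome.fragment_spans:
        cand.add(fs)
        cand.add(fe)
    for node in arg.nodes:
        if node.tract is not None:
            for s, e in node.tract:
                cand.add(s)
                cand.add(e)
    G = arg.genome.total_length
    return sorted(c for c in cand if 0 <= c <= G)


def segment_trees(arg) -> list[tuple[tuple[int, int], LocalTree]]:
    """Partition sequence-bearing sites into runs sharing one genealogy.

    Returns ``[((start, end), tree), ...]`` covering the fragment spans in
    order; a segment may span a gap when the flanking trees coincide.
    """
    cand = _candidate_boundaries(arg)
    seq = arg.genome.seq_intervals()
    raw: list[tuple[tuple[int, int], LocalTree]] = []
    for lo, hi in zip(cand[:-1], cand[1:]):
        piece = IntervalSet([(lo, hi)]) & seq
        if piece.is_empty:
            continue
        tree = local_tree(arg, piece.first)
        raw.append(((lo, hi), tree))
    merged: list[tuple[tuple[int, int], LocalTree]] = []
    for (span, tree) in raw:
        if merged and merged[-1][1].signature() == tree.signature():
            prev_span, prev_tree = merged[-1]
            merged[-1] = ((prev_span[0], span[1]), prev_tree)
        else:
            merged.append((span, tree))
    return merged
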