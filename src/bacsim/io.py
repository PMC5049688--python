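"""Writers for the simulator's outputs.

All outputs are UTF-8 text with LF line endings and begin with a comment
header recording the full parameter set and seed, so any file can be
regenerated from its own header: FASTA alignments (';' comment line),
Newick clonal frames and per-segment local trees ('[...]' comments), DOT
renderings of the ARG ('//' comments) and the TSV event list ('#' comments).
Leaf labels ("sample_1" ... "sample_n") agree across all formats.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .argsim import Arg, EventRecord, Parameters
from .genealogies import LocalTree, segment_trees
from .genome import IntervalSet
from .seqevolve import Alignment

__all__ = ["params_line", "write_alignment_fasta", "write_clonal_newick",
           "write_local_trees", "write_events_tsv", "write_arg_dot",
           "render_arg_dot"]


def params_line(params: Parameters) -> str:
    g = params.genome
    frags = ",".join(f"{l}:{gap}" for l, gap in g.fragments)
    return (f"bacsim n={params.n} fragments={frags} "
            f"topology={'circular' if g.circular else 'linear'} "
            f"theta={params.theta} rho_int={params.rho_int} "
            f"delta_int={params.delta_int} rho_ext={params.rho_ext} "
            f"delta_ext={params.delta_ext} div_min={params.div_min} "
            f"div_max={params.div_max} seed={params.seed}")


def write_alignment_fasta(path, aln: Alignment, params: Parameters) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"; {params_line(params)}\n")
        for i, name in enumerate(aln.ids):
            fh.write(f">{name}\n{aln.sequence(i)}\n")


def write_clonal_newick(path, frame: LocalTree, params: Parameters,
                        substitution_units: bool = False) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"[{params_line(params)}]\n")
        fh.write(frame.newick(theta=params.theta,
                              substitution_units=substitution_units) + "\n")


def write_local_trees(path, arg: Arg, params: Parameters,
                      substitution_units: bool = False) -> int:
    """Multi-tree Newick, one line per segment, each preceded by a comment
    giving the segment's half-open genomic span.  Returns segment count."""
    segs = segment_trees(arg)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"[{params_line(params)}]\n")
        for (start, end), tree in segs:
            fh.write(f"[segment {start} {end}]\n")
            fh.write(tree.newick(theta=params.theta,
                                 substitution_units=substitution_units) + "\n")
    return len(segs)


def _tract_columns(tract: IntervalSet) -> tuple[str, str]:
    starts = ";".join(str(s) for s, _ in tract)
    ends = ";".join(str(e) for _, e in tract)
    return starts, ends


def write_events_tsv(path, events: Iterable[EventRecord],
                     params: Parameters) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# {params_line(params)}\n")
        fh.write("kind\ttime\trecipient_id\ttract_start\ttract_end"
                 "\tdivergence\n")
        for ev in events:
            starts, ends = _tract_columns(ev.tract)
            div = "" if ev.divergence is None else f"{ev.divergence:.8g}"
            fh.write(f"{ev.kind}\t{ev.time:.10g}\t{ev.lineage}\t"
                     f"{starts}\t{ends}\t{div}\n")


# ---------------------------------------------------------------------------
# DOT rendering of the ARG
# ---------------------------------------------------------------------------

_MAX_GLYPHS = 60


def _material_glyphs(arg: Arg, material: Optional[IntervalSet],
                     imported: Optional[IntervalSet] = None) -> str:
    """Fixed-width per-segment string: '#' ancestral, '.' absent,
    'x' imported from an external species."""
    G = arg.genome.total_length
    width = min(_MAX_GLYPHS, G)
    out = []
    for b in range(width):
        lo = b * G // width
        hi = max(lo + 1, (b + 1) * G // width)
        bin_iv = IntervalSet([(lo, hi)])
        if imported is not None and (imported & bin_iv):
            out.append("x")
        elif material is not None and (material & bin_iv):
            out.append("#")
        else:
            out.append(".")
    return "".join(out)


def render_arg_dot(arg: Arg, mode: str = "lineage") -> str:
    """DOT text of the ARG, time flowing bottom-to-top.

    mode 'lineage': clonal-frame lineages black, non-clonal grey,
    between-species imports red.  mode 'material': each node labelled with
    its ancestral-material glyph string (imported segments marked).
    """
    if mode not in ("lineage", "material"):
        raise ValueError(f"unknown DOT mode: {mode}")
    lines = ["digraph arg {", "  rankdir=BT;",
             '  node [fontname="Helvetica"];']
    for node in arg.nodes:
        color = "black" if node.clonal else "grey"
        if node.kind == "external_import":
            color = "red"
        if mode == "lineage":
            if node.kind == "leaf":
                label = f"sample_{node.id + 1}"
                shape = "box"
            else:
                label = f"t={node.time:.3g}"
                shape = "ellipse"
            lines.append(f'  n{node.id} [label="{label}", shape={shape}, '
                         f"color={color}];")
        else:
            if node.kind == "recomb_split":
                gl_r = _material_glyphs(arg, node.recipient_material)
                gl_d = _material_glyphs(arg, node.donor_material)
                label = f"R {gl_r}\\nD {gl_d}"
            elif node.kind == "external_import":
                label = _material_glyphs(arg, node.material, node.tract)
            else:
                label = _material_glyphs(arg, node.material)
            if node.kind == "leaf":
                label = f"sample_{node.id + 1} {label}"
            lines.append(f'  n{node.id} [label="{label}", shape=box, '
                         f'fontname="Courier", color={color}];')
    for node in arg.nodes:
        for child_id, role in node.children:
            child = arg.nodes[child_id]
            if node.kind == "external_import":
                ecolor = "red"
            elif role == "donor":
                ecolor = "grey"
            else:
                # the edge belongs to the lineage rooted at the child node
                ecolor = "black" if child.clonal else "grey"
            attrs = f"color={ecolor}"
            if role is not None:
                attrs += f', label="{role[0].upper()}"'
            lines.append(f"  n{child_id} -> n{node.id} [{attrs}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_arg_dot(path, arg: Arg, params: Parameters,
                  mode: str = "lineage") -> None:
    text = render_arg_dot(arg, mode)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"// {params_line(params)}\n")
        fh.write(text)
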