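"""Genome coordinate system and interval algebra for ancestral material.

A bacterial replicon is described by a :class:`GenomeMap`: a total length
``G``, a topology (circular chromosome or linear), and an ordered layout of
sequence-bearing fragments separated by gaps.  Gap sites are first-class
coordinates -- a recombination tract may start in or span a gap, which
preserves the long-range correlation structure of local genealogies across
fragments -- but they carry no sequence and are excluded from
ancestral-material bookkeeping.

Ancestral material (the set of sites on a backward-time lineage that are
ancestral to the sample) is represented as an :class:`IntervalSet`: a sorted,
disjoint, non-adjacent list of half-open ``[start, end)`` intervals.  On a
circular genome a tract wrapping the origin is canonicalised at construction
into two intervals ``[s, G)`` and ``[0, e)``; no operation ever sees a wrapped
raw pair.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Tuple

import numpy as np

from . import _kernels as _k

__all__ = ["GenomeMap", "IntervalSet", "wrap_interval"]


Pair = Tuple[int, int]


@dataclass(frozen=True)
class GenomeMap:
    """Layout of a single replicon: fragments, gaps and topology.

    Parameters
    ----------
    fragments:
        Ordered ``(fragment_length, trailing_gap)`` pairs in sites.  A whole
        genome is the degenerate case of one fragment with trailing gap 0.
        For a circular genome the trailing gap of the last fragment closes
        the circle back to the first; for a linear genome it must be 0.
    circular:
        Topology flag; bacterial chromosomes are circular by default.
    """

    fragments: Tuple[Pair, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("genome needs at least one fragment")
        frags = tuple((int(l), int(g)) for l, g in self.fragments)
        object.__setattr__(self, "fragments", frags)
        for length, gap in frags:
            if length < 1:
                raise ValueError(f"fragment length must be >= 1, got {length}")
            if gap < 0:
                raise ValueError(f"trailing gap must be >= 0, got {gap}")
        if not self.circular and frags[-1][1] != 0:
            raise ValueError("a linear genome must end with trailing gap 0")
        object.__setattr__(self, "_total", sum(l + g for l, g in frags))
        object.__setattr__(self, "_seq_len", sum(l for l, _ in frags))
        spans = []
        pos = 0
        for length, gap in frags:
            spans.append((pos, pos + length))
            pos += length + gap
        object.__setattr__(self, "_spans", tuple(spans))
        object.__setattr__(self, "_seq_ivs", IntervalSet(spans))
        if self.total_length < 1:
            raise ValueError("total genome length must be >= 1")

    @classmethod
    def whole(cls, length: int, circular: bool = True) -> "GenomeMap":
        """A single unfragmented replicon of ``length`` sites."""
        return cls(((int(length), 0),), circular=circular)

    @property
    def total_length(self) -> int:
        """G: fragment sites plus gap sites."""
        return self._total

    @property
    def seq_length(self) -> int:
        """Number of sequence-bearing sites (alignment columns)."""
        return self._seq_len

    @property
    def fragment_spans(self) -> Tuple[Pair, ...]:
        """Genome-coordinate span ``[start, end)`` of each fragment."""
        return self._spans

    def seq_intervals(self) -> "IntervalSet":
        """The union of fragment spans as an IntervalSet."""
        return self._seq_ivs

    def is_seq_site(self, site: int) -> bool:
        return self.seq_intervals().contains(site)

    def to_columns(self, intervals: "IntervalSet") -> list[Pair]:
        """Map genome-coordinate intervals to alignment-column slices.

        Gap portions are dropped; the result is a list of half-open column
        ranges in ascending order.
        """
        cols: list[Pair] = []
        col_start = 0
        spans = self.fragment_spans
        it = iter(intervals)
        pending = list(intervals)
        for (fs, fe) in spans:
            for (s, e) in pending:
                lo, hi = max(s, fs), min(e, fe)
                if lo < hi:
                    cols.append((col_start + lo - fs, col_start + hi - fs))
            col_start += fe - fs
        # merge adjacent column ranges produced by gap-spanning tracts
        merged: list[Pair] = []
        for s, e in sorted(cols):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def column_to_site(self, col: int) -> int:
        """Inverse of :meth:`to_columns` for a single column."""
        if col < 0 or col >= self.seq_length:
            raise ValueError(f"column {col} outside alignment")
        acc = 0
        for (fs, fe) in self.fragment_spans:
            width = fe - fs
            if col < acc + width:
                return fs + (col - acc)
            acc += width
        raise AssertionError("unreachable")


class IntervalSet:
    """Canonical set of disjoint, non-adjacent half-open intervals.

    Construction canonicalises: intervals are sorted, overlapping or abutting
    pairs are merged, empty intervals dropped.  Instances are immutable and
    hashable; set algebra is exact on sites.  Internally the set is a flat
    int64 boundary array ``[s1, e1, s2, e2, ...]`` shared with the compiled
    kernels.
    """

    __slots__ = ("_b",)

    def __init__(self, intervals: Iterable[Pair] = ()):
        ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
        merged: list[int] = []
        for s, e in ivs:
            if s < 0:
                raise ValueError(f"negative coordinate in interval ({s}, {e})")
            if merged and s <= merged[-1]:
                if e > merged[-1]:
                    merged[-1] = e
            else:
                merged.append(s)
                merged.append(e)
        self._b = np.asarray(merged, dtype=np.int64)

    @classmethod
    def _from_bounds(cls, bounds: np.ndarray) -> "IntervalSet":
        """Wrap an already-canonical boundary array (no checks)."""
        obj = object.__new__(cls)
        obj._b = bounds
        return obj

    @property
    def bounds(self) -> np.ndarray:
        """Canonical boundary array (treat as read-only)."""
        return self._b

    # -- basic protocol ----------------------------------------------------

    @property
    def intervals(self) -> Tuple[Pair, ...]:
        b = self._b.tolist()
        return tuple(zip(b[0::2], b[1::2]))

    def __iter__(self) -> Iterator[Pair]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return self._b.size // 2

    def __bool__(self) -> bool:
        return self._b.size > 0

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and \
            np.array_equal(self._b, other._b)

    def __hash__(self) -> int:
        return hash(self._b.tobytes())

    def __repr__(self) -> str:
        body = ", ".join(f"[{s},{e})" for s, e in self.intervals)
        return f"IntervalSet({{{body}}})"

    @property
    def total_sites(self) -> int:
        return int(np.sum(self._b[1::2] - self._b[0::2]))

    @property
    def is_empty(self) -> bool:
        return self._b.size == 0

    def contains(self, site: int) -> bool:
        # boundaries alternate start/end; falling after an odd number of
        # boundaries means inside an interval
        return int(np.searchsorted(self._b, site, side="right")) % 2 == 1

    @property
    def first(self) -> int:
        """Smallest member site."""
        if self.is_empty:
            raise ValueError("empty interval set")
        return int(self._b[0])

    @property
    def last(self) -> int:
        """Largest member site."""
        if self.is_empty:
            raise ValueError("empty interval set")
        return int(self._b[-1]) - 1

    def sites(self) -> Iterator[int]:
        """Iterate member sites (small sets only; used by oracles/tests)."""
        for s, e in self.intervals:
            yield from range(s, e)

    # -- set algebra -------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet._from_bounds(_k.iv_union(self._b, other._b))

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet._from_bounds(_k.iv_intersect(self._b, other._b))

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet._from_bounds(_k.iv_difference(self._b, other._b))

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    def overlaps(self, other: "IntervalSet") -> bool:
        return bool(self.intersection(other))


def wrap_interval(start: int, length: int, genome: GenomeMap) -> IntervalSet:
    """Genomic footprint of a conversion tract beginning at ``start``.

    On a circular genome the tract wraps around the origin and a length of
    ``G`` or more covers the whole genome; on a linear genome the tract is
    truncated at ``G``.
    """
    G = genome.total_length
    if not 0 <= start < G:
        raise ValueError(f"tract start {start} outside [0, {G})")
    if length < 1:
        raise ValueError(f"tract length must be >= 1, got {length}")
    if genome.circular:
        if length >= G:
            return IntervalSet._from_bounds(np.array([0, G], dtype=np.int64))
        end = start + length
        if end <= G:
            return IntervalSet._from_bounds(
                np.array([start, end], dtype=np.int64))
        return IntervalSet._from_bounds(
            np.array([0, end - G, start, G], dtype=np.int64))
    return IntervalSet._from_bounds(
        np.array([start, min(start + length, G)], dtype=np.int64))
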