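"""Genome layout, genomic intervals and interval arithmetic.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Two intervals *overlap* only if they share at least one
base, so touching intervals ``[a,b)`` and ``[b,c)`` do not overlap — but they
are coalesced by :func:`merge_intervals`, which is the semantics expected of
a merged peak or repeat annotation.  Strand never affects overlap or
coverage computations.

Unknown chromosomes in input files raise :class:`~satarray.errors.DataError`
rather than being dropped: a silently shrunk interval set corrupts the
denominator of every downstream enrichment statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import BedFormatError, DataError

_STRANDS = ("+", "-", ".")


class GenomeLayout:
    """Named chromosomes with lengths; the universe for placement and coverage.

    Parameters
    ----------
    entries:
        Iterable of ``(name, length)`` pairs.  Names must be unique and
        non-empty, lengths strictly positive.
    """

    def __init__(self, entries: Iterable[Tuple[str, int]]):
        pairs = []
        seen = set()
        for name, length in entries:
            name = str(name)
            length = int(length)
            if not name:
                raise DataError("chromosome name must be non-empty")
            if name in seen:
                raise DataError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise DataError(f"chromosome {name!r} has non-positive length {length}")
            seen.add(name)
            pairs.append((name, length))
        if not pairs:
            raise DataError("genome layout must contain at least one chromosome")
        self.entries: Tuple[Tuple[str, int], ...] = tuple(pairs)
        self._sizes: Dict[str, int] = dict(pairs)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def total_size(self) -> int:
        """G, the summed chromosome length."""
        return sum(l for _, l in self.entries)

    def size_of(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise DataError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self.entries == other.entries

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self.entries)} chromosomes, G={self.total_size})"

    @classmethod
    def read_chrom_sizes(cls, path) -> "GenomeLayout":
        """Read a two-column ``chrom.sizes`` file (name, length)."""
        entries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise BedFormatError(path, lineno, "expected two columns: name, length")
                try:
                    length = int(fields[1])
                except ValueError:
                    raise BedFormatError(path, lineno, f"non-integer length {fields[1]!r}") from None
                entries.append((fields[0], length))
        return cls(entries)

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.entries:
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand, name and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` under one layout.

    May contain overlapping members; :func:`merge_intervals` produces the
    sorted disjoint union.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], layout: GenomeLayout,
                 validate: bool = True):
        self.intervals: Tuple[GenomicInterval, ...] = tuple(intervals)
        self.layout = layout
        if validate:
            for iv in self.intervals:
                if iv.chrom not in layout:
                    raise DataError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > layout.size_of(iv.chrom):
                    raise DataError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {layout.size_of(iv.chrom)}"
                    )
        self._merged_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, idx):
        return self.intervals[idx]

    def sorted(self) -> "IntervalSet":
        order = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(order, self.layout, validate=False)

    def total_bp(self) -> int:
        """Summed interval length, double-counting overlaps."""
        return sum(iv.length for iv in self.intervals)

    # ---- merged representation, cached per set -------------------------
    def _merged_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per chromosome: (starts, ends, cum) of the merged disjoint runs.

        ``cum[i]`` is the covered bp in runs ``0..i-1``; ``cum[-1]`` the total.
        """
        if self._merged_cache is None:
            by_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            out = {}
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                starts: List[int] = []
                ends: List[int] = []
                for s, e in pairs:
                    if ends and s <= ends[-1]:
                        if e > ends[-1]:
                            ends[-1] = e
                    else:
                        starts.append(s)
                        ends.append(e)
                sa = np.asarray(starts, dtype=np.int64)
                ea = np.asarray(ends, dtype=np.int64)
                cum = np.concatenate(([0], np.cumsum(ea - sa)))
                out[chrom] = (sa, ea, cum)
            self._merged_cache = out
        return self._merged_cache


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Sorted disjoint union; abutting intervals are coalesced.

    The covered base set is preserved exactly.  Name/score/strand metadata is
    dropped, as merged regions no longer correspond to single input records.
    """
    merged = []
    for chrom in sorted(s._merged_arrays()):
        starts, ends, _ = s._merged_arrays()[chrom]
        for st, en in zip(starts.tolist(), ends.tolist()):
            merged.append(GenomicInterval(chrom, st, en))
    return IntervalSet(merged, s.layout, validate=False)


def overlap_bp_per_interval(query: IntervalSet, reference: IntervalSet) -> np.ndarray:
    """For each query interval, the number of bases shared with the merged
    reference union (overlaps within the reference are not double-counted)."""
    ref = reference._merged_arrays()
    out = np.zeros(len(query), dtype=np.int64)
    for idx, iv in enumerate(query):
        if iv.chrom not in ref:
            continue
        starts, ends, cum = ref[iv.chrom]
        i0 = int(np.searchsorted(ends, iv.start, side="right"))
        i1 = int(np.searchsorted(starts, iv.end, side="left"))
        if i1 <= i0:
            continue
        total = int(cum[i1] - cum[i0])
        total -= max(0, iv.start - int(starts[i0]))
        total -= max(0, int(ends[i1 - 1]) - iv.end)
        out[idx] = total
    return out


def count_overlapping(query: IntervalSet, reference: IntervalSet,
                      min_overlap: int = 1) -> int:
    """Number of query intervals sharing >= ``min_overlap`` bases with the
    reference union; each query member counted at most once."""
    if min_overlap < 1:
        raise DataError(f"min_overlap must be >= 1, got {min_overlap}")
    return int(np.count_nonzero(overlap_bp_per_interval(query, reference) >= min_overlap))


def coverage_fraction(s: IntervalSet, layout: Optional[GenomeLayout] = None) -> float:
    """Merged covered bases divided by the total genome size G."""
    layout = layout if layout is not None else s.layout
    covered = sum(int(cum[-1]) for _, _, cum in s._merged_arrays().values())
    return covered / layout.total_size


# ---- boolean set operations on merged interval sets ----------------------

def _runs_to_intervals(runs_by_chrom: Dict[str, List[Tuple[int, int]]],
                       layout: GenomeLayout) -> IntervalSet:
    ivs = []
    for chrom in sorted(runs_by_chrom):
        for s, e in runs_by_chrom[chrom]:
            if e > s:
                ivs.append(GenomicInterval(chrom, s, e))
    return IntervalSet(ivs, layout, validate=False)


def _boolean_op(a: IntervalSet, b: IntervalSet, keep) -> IntervalSet:
    """Sweep the merged runs of ``a`` and ``b``; keep segments where
    ``keep(in_a, in_b)`` is true."""
    am, bm = a._merged_arrays(), b._merged_arrays()
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in set(am) | set(bm):
        events: List[Tuple[int, int, int]] = []  # (pos, delta_a, delta_b)
        if chrom in am:
            sa, ea, _ = am[chrom]
            for s, e in zip(sa.tolist(), ea.tolist()):
                events.append((s, 1, 0))
                events.append((e, -1, 0))
        if chrom in bm:
            sb, eb, _ = bm[chrom]
            for s, e in zip(sb.tolist(), eb.tolist()):
                events.append((s, 0, 1))
                events.append((e, 0, -1))
        events.sort()
        in_a = in_b = 0
        prev = None
        runs: List[Tuple[int, int]] = []
        i = 0
        while i < len(events):
            pos = events[i][0]
            if prev is not None and pos > prev and keep(in_a > 0, in_b > 0):
                if runs and runs[-1][1] == prev:
                    runs[-1] = (runs[-1][0], pos)
                else:
                    runs.append((prev, pos))
            while i < len(events) and events[i][0] == pos:
                in_a += events[i][1]
                in_b += events[i][2]
                i += 1
            prev = pos
        if runs:
            out[chrom] = runs
    return _runs_to_intervals(out, a.layout)


def intersect_sets(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return _boolean_op(a, b, lambda x, y: x and y)


def subtract_sets(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return _boolean_op(a, b, lambda x, y: x and not y)


def support_regions(replicates: Sequence[IntervalSet], min_support: int) -> IntervalSet:
    """Regions covered by at least ``min_support`` of the given interval sets.

    Each replicate is merged first, so one replicate contributes at most one
    unit of support per base.
    """
    if not replicates:
        raise DataError("support_regions requires at least one replicate")
    if not (1 <= min_support <= len(replicates)):
        raise DataError(
            f"min_support must be in [1, {len(replicates)}], got {min_support}"
        )
    layout = replicates[0].layout
    events: Dict[str, List[Tuple[int, int]]] = {}
    for rep in replicates:
        for chrom, (sa, ea, _) in rep._merged_arrays().items():
            lst = events.setdefault(chrom, [])
            for s, e in zip(sa.tolist(), ea.tolist()):
                lst.append((s, 1))
                lst.append((e, -1))
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        prev = None
        runs: List[Tuple[int, int]] = []
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            if prev is not None and pos > prev and depth >= min_support:
                if runs and runs[-1][1] == prev:
                    runs[-1] = (runs[-1][0], pos)
                else:
                    runs.append((prev, pos))
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            prev = pos
        if runs:
            out[chrom] = runs
    return _runs_to_intervals(out, layout)


# ---- BED I/O --------------------------------------------------------------

def read_bed(path, layout: GenomeLayout) -> IntervalSet:
    """Read BED3-BED6.  ``track``/``browser``/``#`` lines are skipped; columns
    4/5/6 map to name/score/strand when present ('.' means absent).

    Malformed coordinates, ``start >= end`` or unknown chromosomes raise
    :class:`BedFormatError` naming the offending line.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(path, lineno, "fewer than 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    path, lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            if start < 0 or start >= end:
                raise BedFormatError(path, lineno, f"invalid coordinates start={start} end={end}")
            if chrom not in layout:
                raise BedFormatError(path, lineno, f"unknown chromosome {chrom!r}")
            if end > layout.size_of(chrom):
                raise BedFormatError(
                    path, lineno,
                    f"end {end} exceeds chromosome length {layout.size_of(chrom)}",
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedFormatError(path, lineno, f"non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in _STRANDS:
                raise BedFormatError(path, lineno, f"invalid strand {strand!r}")
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return IntervalSet(intervals, layout, validate=False)


def _format_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return format(score, ".6g")


def write_bed(s: IntervalSet, path) -> None:
    """Write sorted BED; BED6 if any interval carries name/score/strand,
    BED3 otherwise."""
    ivs = s.sorted().intervals
    six = any(iv.name is not None or iv.score is not None or iv.strand != "."
              for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name if iv.name is not None else '.'}\t"
                    f"{_format_score(iv.score)}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
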