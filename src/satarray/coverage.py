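"""Coverage tracks and signal aggregation.

A :class:`CoverageTrack` is a per-chromosome step function stored as sorted,
non-overlapping ``(start, end, value)`` runs; positions not covered by any
run read as 0, so a bedGraph that omits zero runs loses nothing.  This is
the canonical in-memory form of a sequencing coverage track here (bedGraph
on disk), and everything downstream — fold-enrichment normalization against
an IgG control, features-by-bins signal matrices, trimmed-mean profile
curves, per-feature mean statistics — consumes it.

The aggregation pipeline mirrors standard ChIP/CUT&RUN practice: coverage is
retrieved in fixed-width windows (default 100 bp) over the flanks of each
feature, the feature body is rescaled to a common number of bins, and the
per-bin summary across features is either a trimmed mean (profile plots) or
a per-feature mean over body bins (boxplot-style distributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import BedFormatError, ConfigError, DataError
from .intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    intersect_sets,
    merge_intervals,
    subtract_sets,
    support_regions,
)


class CoverageTrack:
    """Non-negative step function over a genome layout.

    Parameters
    ----------
    runs_by_chrom:
        Mapping chromosome -> (starts, ends, values) arrays of sorted,
        non-overlapping runs.  Zero-valued runs are permitted but not
        required.
    layout:
        Governing genome layout; runs must fit their chromosome.
    """

    def __init__(self, runs_by_chrom: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
                 layout: GenomeLayout, validate: bool = True):
        self.layout = layout
        self.runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs_by_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if validate:
                if chrom not in layout:
                    raise DataError(f"track run on unknown chromosome {chrom!r}")
                if len(starts) != len(ends) or len(starts) != len(values):
                    raise DataError("run arrays must have equal length")
                if len(starts):
                    if np.any(starts >= ends):
                        raise DataError(f"empty or inverted run on {chrom}")
                    if np.any(starts[1:] < ends[:-1]):
                        raise DataError(f"overlapping or unsorted runs on {chrom}")
                    if starts[0] < 0 or ends[-1] > layout.size_of(chrom):
                        raise DataError(f"run outside chromosome bounds on {chrom}")
                    if np.any(values < 0):
                        raise DataError(f"negative coverage value on {chrom}")
            self.runs[chrom] = (starts, ends, values)
        self._cum: Dict[str, np.ndarray] = {}

    # ---- construction ---------------------------------------------------
    @classmethod
    def from_run_list(cls, runs: Sequence[Tuple[str, int, int, float]],
                      layout: GenomeLayout) -> "CoverageTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, s, e, v in runs:
            by_chrom.setdefault(chrom, []).append((s, e, v))
        out = {}
        for chrom, lst in by_chrom.items():
            lst.sort()
            out[chrom] = (np.array([r[0] for r in lst]),
                          np.array([r[1] for r in lst]),
                          np.array([r[2] for r in lst]))
        return cls(out, layout)

    @classmethod
    def from_dense(cls, arrays: Mapping[str, np.ndarray],
                   layout: GenomeLayout) -> "CoverageTrack":
        """Run-length encode per-base arrays, dropping zero runs."""
        out = {}
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            if len(arr) != layout.size_of(chrom):
                raise DataError(f"dense array length mismatch on {chrom}")
            if len(arr) == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            values = arr[starts]
            keep = values != 0
            out[chrom] = (starts[keep], ends[keep], values[keep])
        return cls(out, layout, validate=False)

    @classmethod
    def read_bedgraph(cls, path, layout: GenomeLayout,
                      scale_to_library: bool = False) -> "CoverageTrack":
        """Read a bedGraph.  With ``scale_to_library`` the track is multiplied
        by ``1e6 / total signal`` at load (library-size scaling)."""
        runs: List[Tuple[str, int, int, float]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise BedFormatError(path, lineno, "expected 4 bedGraph columns")
                chrom = fields[0]
                if chrom not in layout:
                    raise BedFormatError(path, lineno, f"unknown chromosome {chrom!r}")
                try:
                    s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError:
                    raise BedFormatError(path, lineno, "malformed bedGraph line") from None
                if s < 0 or s >= e or e > layout.size_of(chrom):
                    raise BedFormatError(path, lineno, f"invalid run {s}-{e}")
                runs.append((chrom, s, e, v))
        track = cls.from_run_list(runs, layout)
        if scale_to_library:
            total = track.total_signal()
            if total <= 0:
                raise DataError("cannot library-scale a track with zero total signal")
            track = track.scaled(1e6 / total)
        return track

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.runs):
                starts, ends, values = self.runs[chrom]
                for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
                    if v == 0:
                        continue
                    sv = str(int(v)) if float(v).is_integer() else format(v, ".6g")
                    fh.write(f"{chrom}\t{s}\t{e}\t{sv}\n")

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.runs.items()},
            self.layout, validate=False)

    # ---- queries ---------------------------------------------------------
    def total_signal(self) -> float:
        return float(sum(np.sum((e - s) * v) for s, e, v in self.runs.values()))

    def mean_nonzero(self) -> float:
        num = den = 0.0
        for s, e, v in self.runs.values():
            nz = v != 0
            num += float(np.sum((e[nz] - s[nz]) * v[nz]))
            den += float(np.sum(e[nz] - s[nz]))
        return num / den if den else 0.0

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            s, e, v = self.runs.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum((e - s) * v)))
        return self._cum[chrom]

    def _integral_to(self, chrom: str, xs: np.ndarray) -> np.ndarray:
        """Integral of the step function from 0 to each x (x may be
        fractional; positions outside any run contribute 0)."""
        starts, ends, values = self.runs.get(
            chrom, (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)))
        cum = self._cumulative(chrom)
        xs = np.asarray(xs, dtype=np.float64)
        j = np.searchsorted(starts, xs, side="right")
        out = np.zeros_like(xs)
        has = j > 0
        jj = j[has] - 1
        partial = np.clip(xs[has] - starts[jj], 0.0, (ends[jj] - starts[jj]).astype(float))
        out[has] = cum[jj] + values[jj] * partial
        return out

    def mean_over(self, chrom: str, a: float, b: float) -> float:
        """Per-base mean value over the real interval [a, b); positions
        beyond the chromosome (or any run) read as 0."""
        if b <= a:
            raise DataError("mean_over requires b > a")
        ints = self._integral_to(chrom, np.array([a, b]))
        return float(ints[1] - ints[0]) / (b - a)

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        ints = self._integral_to(chrom, np.asarray(edges, dtype=np.float64))
        widths = np.diff(edges)
        return np.diff(ints) / widths


def fold_enrichment_track(signal: CoverageTrack, control: CoverageTrack,
                          pseudocount: Optional[float] = None) -> CoverageTrack:
    """Per-base ``(signal + c) / (control + c)`` on the union of breakpoints.

    This is the IgG-normalized fold-enrichment track used to compare
    chromatin-mark coverage across conditions.  ``pseudocount`` defaults to
    half the control track's mean nonzero value: a scale-aware guard
    against division blow-ups at zero-control bases.  With integer-count
    tracks a much smaller pseudocount lets those bases dominate the mean
    ratio (a tenfold inflation of true enrichment is easy to produce), so
    the default trades a mild compression of high ratios for boundedness.
    """
    if signal.layout != control.layout:
        raise DataError("signal and control tracks must share a genome layout")
    sig_chroms, ctl_chroms = set(signal.runs), set(control.runs)
    if sig_chroms != ctl_chroms:
        missing = sig_chroms ^ ctl_chroms
        raise DataError(f"mismatched chromosome sets between tracks: {sorted(missing)}")
    if pseudocount is None:
        base = control.mean_nonzero()
        pseudocount = 0.5 * base if base > 0 else 1.0
    if pseudocount <= 0:
        raise ConfigError(f"pseudocount must be > 0, got {pseudocount}")

    out: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in sig_chroms:
        L = signal.layout.size_of(chrom)
        bps = {0, L}
        for track in (signal, control):
            s, e, _ = track.runs[chrom]
            bps.update(s.tolist())
            bps.update(e.tolist())
        edges = np.array(sorted(p for p in bps if 0 <= p <= L), dtype=np.int64)
        seg_starts, seg_ends = edges[:-1], edges[1:]

        def seg_values(track: CoverageTrack) -> np.ndarray:
            st, en, va = track.runs[chrom]
            j = np.searchsorted(st, seg_starts, side="right") - 1
            vals = np.zeros(len(seg_starts))
            ok = (j >= 0)
            ok[ok] &= seg_starts[ok] < en[j[ok]]
            vals[ok] = va[j[ok]]
            return vals

        ratio = (seg_values(signal) + pseudocount) / (seg_values(control) + pseudocount)
        # coalesce adjacent equal-valued segments
        keep = np.concatenate(([True], ratio[1:] != ratio[:-1]))
        rs = seg_starts[keep]
        re = np.concatenate((rs[1:], [seg_ends[-1]])) if len(rs) else seg_ends[:0]
        out[chrom] = (rs, re, ratio[keep])
    return CoverageTrack(out, signal.layout, validate=False)


@dataclass
class SignalMatrix:
    """Features x bins matrix of per-base mean track values.

    Columns are ``flank/bin_size`` fixed-width upstream bins, ``body_bins``
    equal-width body segments (fractional bp widths allowed), then the
    downstream flank bins.  Minus-strand rows are reversed when
    ``strand_oriented`` so that columns read 5'->3' along the feature.
    """

    values: np.ndarray
    features: Tuple[GenomicInterval, ...]
    bin_size: int
    flank: int
    body_bins: int
    strand_oriented: bool

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.bin_size

    @property
    def n_columns(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins

    @property
    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.body_bins)

    def column_labels(self) -> List[str]:
        nf = self.n_flank_bins
        labels = [f"up_{-self.flank + i * self.bin_size}" for i in range(nf)]
        labels += [f"body_{i}" for i in range(self.body_bins)]
        labels += [f"down_{i * self.bin_size}" for i in range(nf)]
        return labels

    def row_order_by_mean(self) -> np.ndarray:
        """Row indices in descending mean-signal order (heatmap ordering)."""
        means = self.values.mean(axis=1)
        return np.lexsort((np.arange(len(means)), -means))


def extract_signal_matrix(track: CoverageTrack, features: IntervalSet,
                          flank: int, bin_size: int = 100, body_bins: int = 10,
                          strand_oriented: bool = True) -> SignalMatrix:
    """Binned per-base mean coverage around and across each feature.

    Flank bins are fixed ``bin_size`` windows; the body is rescaled to
    ``body_bins`` equal-width segments so features of different lengths
    share columns.  Flank positions falling outside the chromosome read 0.
    """
    if bin_size < 1:
        raise ConfigError("bin_size must be >= 1")
    if body_bins < 1:
        raise ConfigError("body_bins must be >= 1")
    if flank % bin_size != 0:
        raise ConfigError(f"flank {flank} must be a multiple of bin_size {bin_size}")
    nf = flank // bin_size
    rows = []
    for iv in features:
        if iv.chrom not in track.layout:
            raise DataError(f"feature chromosome {iv.chrom!r} missing from layout")
        up_edges = iv.start - flank + bin_size * np.arange(nf + 1, dtype=np.float64)
        body_edges = iv.start + (iv.end - iv.start) * np.arange(body_bins + 1) / body_bins
        down_edges = iv.end + bin_size * np.arange(nf + 1, dtype=np.float64)
        row = np.concatenate([
            track.binned_means(iv.chrom, up_edges) if nf else np.empty(0),
            track.binned_means(iv.chrom, body_edges),
            track.binned_means(iv.chrom, down_edges) if nf else np.empty(0),
        ])
        if strand_oriented and iv.strand == "-":
            row = row[::-1]
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, 2 * nf + body_bins))
    return SignalMatrix(values, tuple(features), bin_size, flank, body_bins,
                        strand_oriented)


@dataclass
class ProfileCurve:
    """Per-column trimmed mean of a signal matrix."""

    values: np.ndarray
    trim_fraction: float


def _trimmed_mean(column: np.ndarray, trim_fraction: float) -> float:
    n = len(column)
    if trim_fraction == 0:
        return float(np.mean(column))
    k = int(math.ceil(n * trim_fraction / 100.0))
    if 2 * k >= n:
        raise DataError(
            f"trim of {trim_fraction}% removes all {n} values; reduce the trim"
        )
    srt = np.sort(column)
    return float(np.mean(srt[k:n - k]))


def trimmed_mean_profile(m: SignalMatrix, trim_fraction: float = 0.5) -> ProfileCurve:
    """Column-wise symmetric trimmed mean: the ``ceil(n * f/100)`` smallest
    and largest values of each bin are excluded before averaging (nearest-rank
    trimming of the top and bottom ``f`` percentiles).  ``trim_fraction = 0``
    reduces to the plain column mean."""
    if not (0 <= trim_fraction < 50):
        raise ConfigError(f"trim_fraction must be in [0, 50), got {trim_fraction}")
    if m.values.shape[0] == 0:
        raise DataError("cannot profile an empty signal matrix")
    vals = np.array([_trimmed_mean(m.values[:, j], trim_fraction)
                     for j in range(m.values.shape[1])])
    return ProfileCurve(vals, trim_fraction)


def per_feature_mean(m: SignalMatrix) -> np.ndarray:
    """Row-wise mean over body bins only (flanks are display context)."""
    if m.values.shape[0] == 0:
        raise DataError("cannot summarize an empty signal matrix")
    return m.values[:, m.body_slice].mean(axis=1)


def top_k_peaks(peaks: IntervalSet, k: int) -> IntervalSet:
    """The ``k`` highest-scoring peaks; score ties broken by (chrom, start)
    ascending.  ``k >= n`` returns all peaks."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    for iv in peaks:
        if iv.score is None:
            raise DataError(f"peak {iv.chrom}:{iv.start}-{iv.end} has no score")
    ranked = sorted(peaks, key=lambda iv: (-iv.score, iv.chrom, iv.start))
    return IntervalSet(ranked[:k], peaks.layout, validate=False)


@dataclass
class OccupancySubsets:
    """Disjoint partition of supported peak space into condition-exclusive
    and shared regions."""

    a_only: IntervalSet
    b_only: IntervalSet
    shared: IntervalSet
    min_replicate_support: int

    def as_dict(self) -> Dict[str, IntervalSet]:
        return {"a_only": self.a_only, "b_only": self.b_only, "shared": self.shared}


def occupancy_subsets(condition_a_replicates: Sequence[IntervalSet],
                      condition_b_replicates: Sequence[IntervalSet],
                      min_replicate_support: Optional[int] = None) -> OccupancySubsets:
    """Occupancy comparison of two peak-set conditions.

    A base is *present* in a condition when covered by at least
    ``min_replicate_support`` of its (individually merged) replicates; the
    supported space of the two conditions is then split into ``a_only``,
    ``b_only`` and ``shared`` disjoint interval sets.  With support 1 the
    union of the subsets equals the merged input peak space.  The default
    support is ``min(2, replicate count)`` per condition.
    """
    if not condition_a_replicates or not condition_b_replicates:
        raise DataError("each condition requires at least one replicate peak set")
    if min_replicate_support is None:
        k = min(2, len(condition_a_replicates), len(condition_b_replicates))
    else:
        k = min_replicate_support
        if k > min(len(condition_a_replicates), len(condition_b_replicates)):
            raise ConfigError(
                f"min_replicate_support {k} exceeds a condition's replicate count"
            )
        if k < 1:
            raise ConfigError("min_replicate_support must be >= 1")
    present_a = support_regions(condition_a_replicates, k)
    present_b = support_regions(condition_b_replicates, k)
    return OccupancySubsets(
        a_only=subtract_sets(present_a, present_b),
        b_only=subtract_sets(present_b, present_a),
        shared=intersect_sets(present_a, present_b),
        min_replicate_support=k,
    )


def repeat_fraction_of_subsets(subsets: OccupancySubsets,
                               repeat_annotation: IntervalSet) -> Dict[str, Dict[str, float]]:
    """Per subset: fraction of its total length overlapping each repeat
    class, plus an ``unannotated`` remainder completing the unit sum.

    The repeat class is the annotation interval's ``name``.  Where annotation
    intervals of different classes overlap, each base is assigned to the
    longest covering interval (ties: class name, then start) so the
    fractions partition the subset length.
    """
    ann_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in repeat_annotation:
        if iv.name is None:
            raise DataError(
                f"repeat annotation interval {iv.chrom}:{iv.start}-{iv.end} lacks a class label"
            )
        ann_by_chrom.setdefault(iv.chrom, []).append(iv)
    for lst in ann_by_chrom.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))

    out: Dict[str, Dict[str, float]] = {}
    for subset_name, subset in subsets.as_dict().items():
        merged = merge_intervals(subset)
        total = merged.total_bp()
        class_bp: Dict[str, int] = {}
        for seg in merged:
            anns = [a for a in ann_by_chrom.get(seg.chrom, ())
                    if a.start < seg.end and a.end > seg.start]
            if not anns:
                continue
            bps = sorted({seg.start, seg.end}
                         | {max(seg.start, a.start) for a in anns}
                         | {min(seg.end, a.end) for a in anns})
            for lo, hi in zip(bps[:-1], bps[1:]):
                covering = [a for a in anns if a.start <= lo and a.end >= hi]
                if not covering:
                    continue
                winner = min(covering, key=lambda a: (-a.length, a.name, a.start))
                class_bp[winner.name] = class_bp.get(winner.name, 0) + (hi - lo)
        fractions = ({cls: bp / total for cls, bp in sorted(class_bp.items())}
                     if total else {})
        if total:
            fractions["unannotated"] = (total - sum(class_bp.values())) / total
        out[subset_name] = fractions
    return out
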