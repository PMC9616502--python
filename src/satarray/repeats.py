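"""Satellite repeat copy profiling.

A satellite family is a set of tandemly repeated copies of a short
consensus unit.  This module classifies annotated copies as factor-bound or
unbound by overlap with a ChIP/CUT&RUN peak set, rebuilds the family
consensus by iterative star alignment with majority voting, measures each
copy's percent divergence from the consensus over aligned non-gap columns,
and compares the bound and unbound groups (length and divergence) with a
pooled-variance two-sample t-test.

Divergence here is the substitution proportion of the pairwise global
alignment: ``100 * mismatches / (matches + mismatches)``, gap columns
excluded and with no multiple-hit (Kimura-style) correction.  Copies
annotated on the minus strand are reverse-complemented before alignment by
default — mixing orientations corrupts both the consensus and the
divergence estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy import stats as _stats

from .errors import ConfigError, DataError
from .intervals import GenomicInterval, IntervalSet, overlap_bp_per_interval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatCopy:
    """One satellite instance: interval, sequence in annotated orientation,
    optional bound label and percent divergence."""

    interval: GenomicInterval
    sequence: str
    bound: Optional[bool] = None
    divergence: Optional[float] = None

    def __post_init__(self):
        if len(self.sequence) != self.interval.length:
            raise DataError(
                f"sequence length {len(self.sequence)} does not match interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.divergence is not None and not (0 <= self.divergence <= 100):
            raise DataError(f"divergence must be in [0, 100], got {self.divergence}")

    @property
    def length(self) -> int:
        return self.interval.length


def copies_from_annotation(annotation: IntervalSet, genome: Mapping[str, str],
                           orient: bool = True) -> List[RepeatCopy]:
    """Extract copy sequences from a genome given a repeat annotation.

    With ``orient`` (default) minus-strand copies are reverse-complemented so
    every sequence reads in the repeat's own orientation.
    """
    copies = []
    for iv in annotation:
        if iv.chrom not in genome:
            raise DataError(f"chromosome {iv.chrom!r} missing from genome sequences")
        seq = genome[iv.chrom][iv.start:iv.end].upper()
        if orient and iv.strand == "-":
            seq = reverse_complement(seq)
        copies.append(RepeatCopy(iv, seq))
    return copies


def classify_copies(copies: Sequence[RepeatCopy], peaks: IntervalSet,
                    min_overlap: int = 1) -> List[RepeatCopy]:
    """Label each copy bound iff it shares >= ``min_overlap`` bases with the
    merged peak set.  Returns new copies; n_bound + n_unbound = len(copies).
    """
    if min_overlap < 1:
        raise ConfigError(f"min_overlap must be >= 1, got {min_overlap}")
    if not copies:
        return []
    layout = peaks.layout
    query = IntervalSet([c.interval for c in copies], layout, validate=False)
    ov = overlap_bp_per_interval(query, peaks)
    return [replace(c, bound=bool(o >= min_overlap)) for c, o in zip(copies, ov)]


# ---- pairwise global alignment -------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    mismatches: int
    gap_columns: int

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise DataError("aligned strings must have equal length")


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, gap):  # pragma: no cover - jit-compiled
    n, m = a.shape[0], b.shape[0]
    H = np.empty((n + 1, m + 1), np.float64)
    P = np.empty((n + 1, m + 1), np.uint8)  # 0 diag, 1 up (gap in b), 2 left
    H[0, 0] = 0.0
    P[0, 0] = 0
    for i in range(1, n + 1):
        H[i, 0] = i * gap
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = j * gap
        P[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            best = H[i - 1, j - 1] + s
            ptr = 0
            up = H[i - 1, j] + gap
            if up > best:
                best = up
                ptr = 1
            left = H[i, j - 1] + gap
            if left > best:
                best = left
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    return H, P


def needleman_wunsch(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                     gap: float = -2.0) -> PairwiseAlignment:
    """Global alignment with linear gap penalty, maximizing the additive
    score.  Ties are broken deterministically: diagonal, then up (gap in
    ``b``), then left (gap in ``a``)."""
    if not a or not b:
        raise DataError("cannot align an empty sequence")
    ab = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    H, P = _nw_fill(ab, bb, float(match), float(mismatch), float(gap))
    i, j = len(a), len(b)
    ra: List[str] = []
    rb: List[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and P[i, j] == 0:
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and (j == 0 or P[i, j] == 1):
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    matches = mismatches = gaps = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            gaps += 1
        elif ca == cb:
            matches += 1
        else:
            mismatches += 1
    return PairwiseAlignment(aligned_a, aligned_b, float(H[len(a), len(b)]),
                             matches, mismatches, gaps)


def percent_divergence(aln: PairwiseAlignment) -> float:
    """``100 * mismatches / (matches + mismatches)``; gap columns excluded."""
    denom = aln.matches + aln.mismatches
    if denom == 0:
        raise DataError("alignment has no non-gap columns; divergence undefined")
    return 100.0 * aln.mismatches / denom


# ---- iterative majority consensus ----------------------------------------

@dataclass
class ConsensusModel:
    """Majority consensus plus per-column base counts from the final
    profiling round (counts over contributing, non-gap sequences)."""

    consensus: str
    column_frequencies: List[Dict[str, int]]
    rounds: int


def _majority_base(counts: Dict[str, int]) -> str:
    best = max(counts.values())
    return min(b for b, c in counts.items() if c == best)


def _profile_against(consensus: str, sequences: Sequence[str],
                     match: float, mismatch: float, gap: float):
    """Align every sequence to the consensus; tally per-column bases and
    insertion slots keyed by (consensus position, offset)."""
    n_cols = len(consensus)
    col_counts: List[Dict[str, int]] = [dict() for _ in range(n_cols)]
    col_gaps = [0] * n_cols
    ins_counts: Dict[Tuple[int, int], Dict[str, int]] = {}
    for seq in sequences:
        aln = needleman_wunsch(consensus, seq, match, mismatch, gap)
        c = 0
        offset = 0
        for cc, cs in zip(aln.aligned_a, aln.aligned_b):
            if cc == "-":
                key = (c, offset)
                ins_counts.setdefault(key, {})[cs] = ins_counts.get(key, {}).get(cs, 0) + 1
                offset += 1
            else:
                if cs == "-":
                    col_gaps[c] += 1
                else:
                    col_counts[c][cs] = col_counts[c].get(cs, 0) + 1
                c += 1
                offset = 0
    return col_counts, col_gaps, ins_counts


def build_consensus(sequences: Sequence[str], max_rounds: int = 5,
                    match: float = 1.0, mismatch: float = -1.0,
                    gap: float = -2.0) -> ConsensusModel:
    """Iterative star consensus.

    The seed is the sequence whose length is closest to the group median
    (earliest index on ties).  Each round aligns every sequence to the
    current consensus, stacks alignment columns in consensus coordinates,
    drops columns whose gap fraction is >= 0.5, emits the per-column
    majority base (lexicographic tie-break) and inserts a column wherever
    more than half of the sequences carry an insertion at the same slot.
    Iteration stops at a fixed point or after ``max_rounds``.
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise DataError("consensus building requires at least 2 sequences")
    if any(not s for s in seqs):
        raise DataError("consensus building requires non-empty sequences")
    if max_rounds < 1:
        raise ConfigError("max_rounds must be >= 1")
    n = len(seqs)
    lengths = sorted(len(s) for s in seqs)
    median = lengths[len(lengths) // 2]
    consensus = min(seqs, key=lambda s: (abs(len(s) - median), seqs.index(s)))
    rounds_done = 0
    for _ in range(max_rounds):
        col_counts, col_gaps, ins_counts = _profile_against(
            consensus, seqs, match, mismatch, gap)
        pieces: List[str] = []
        for c in range(len(consensus) + 1):
            # insertion slots before consensus position c, in offset order
            for offset in range(n):
                key = (c, offset)
                if key not in ins_counts:
                    break
                counts = ins_counts[key]
                if sum(counts.values()) * 2 > n:
                    pieces.append(_majority_base(counts))
            if c < len(consensus):
                contributing = sum(col_counts[c].values())
                if col_gaps[c] * 2 >= col_gaps[c] + contributing and col_gaps[c] > 0:
                    continue  # gap fraction >= 0.5: drop the column
                if contributing:
                    pieces.append(_majority_base(col_counts[c]))
        new_consensus = "".join(pieces)
        rounds_done += 1
        if not new_consensus:
            raise DataError("consensus collapsed to an empty sequence")
        if new_consensus == consensus:
            consensus = new_consensus
            break
        consensus = new_consensus
    # final profiling pass for the reported column frequencies
    col_counts, _, _ = _profile_against(consensus, seqs, match, mismatch, gap)
    return ConsensusModel(consensus, col_counts, rounds_done)


def copy_divergence(sequence: str, consensus: str, match: float = 1.0,
                    mismatch: float = -1.0, gap: float = -2.0) -> float:
    """Percent divergence of one (possibly tandem) copy from the consensus
    unit.

    The copy is treated as an in-phase tandem array of the unit: it is
    chopped into consecutive unit-length windows (a trailing remainder
    shorter than half a unit is merged into the previous window), each
    window is globally aligned to the unit, and match/mismatch counts are
    pooled before applying the divergence formula.  Pooling avoids the
    optimistic bias of one global alignment of a short unit against a long
    array, where the unavoidable gap columns make it free for the aligner
    to hop between repeat units and dodge substitutions.
    """
    if not sequence:
        raise DataError("cannot compute divergence of an empty sequence")
    L = len(consensus)
    windows = [sequence[p:p + L] for p in range(0, len(sequence), L)]
    if len(windows) > 1 and len(windows[-1]) < L / 2:
        windows[-2] += windows[-1]
        windows.pop()
    matches = mismatches = 0
    for w in windows:
        aln = needleman_wunsch(consensus, w, match, mismatch, gap)
        matches += aln.matches
        mismatches += aln.mismatches
    if matches + mismatches == 0:
        raise DataError("no non-gap columns; divergence undefined")
    return 100.0 * mismatches / (matches + mismatches)


def divergence_from_consensus(copies: Sequence[RepeatCopy], consensus: str,
                              match: float = 1.0, mismatch: float = -1.0,
                              gap: float = -2.0) -> List[RepeatCopy]:
    """Attach :func:`copy_divergence` against the family consensus unit to
    each copy."""
    return [replace(c, divergence=copy_divergence(c.sequence, consensus,
                                                  match, mismatch, gap))
            for c in copies]


# ---- two-sample statistics ------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t_test(x: Sequence[float], y: Sequence[float],
                      welch: bool = False) -> TTestResult:
    """Two-sided unpaired t-test.

    Default is the classical Student form: pooled variance,
    ``df = nx + ny - 2``.  ``welch=True`` uses Welch's unequal-variance
    statistic with Satterthwaite degrees of freedom.  When both groups have
    zero variance and equal means the test is degenerate and p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise DataError(f"each group needs >= 2 observations (got {nx}, {ny})")
    mx, my = float(np.mean(x)), float(np.mean(y))
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if welch:
        sem2 = vx / nx + vy / ny
        if sem2 == 0:
            return TTestResult(0.0, float(nx + ny - 2), 1.0) if mx == my else \
                TTestResult(math.copysign(math.inf, mx - my), float(nx + ny - 2), 0.0)
        df = sem2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        t = (mx - my) / math.sqrt(sem2)
    else:
        df = float(nx + ny - 2)
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        if sp2 == 0:
            if mx == my:
                return TTestResult(0.0, df, 1.0)
            return TTestResult(math.copysign(math.inf, mx - my), df, 0.0)
        t = (mx - my) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), min(p, 1.0))


@dataclass
class GroupStats:
    n: int
    mean_length: float
    sd_length: float
    mean_divergence: Optional[float]
    sd_divergence: Optional[float]


@dataclass
class GroupSummary:
    """Bound-vs-unbound comparison of copy length and percent divergence."""

    bound: GroupStats
    unbound: GroupStats
    length_test: TTestResult
    divergence_test: Optional[TTestResult]
    length_histogram: Dict[str, np.ndarray]
    divergence_histogram: Optional[Dict[str, np.ndarray]]


def _group_stats(values: np.ndarray) -> Tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1))


def group_summary(copies: Sequence[RepeatCopy], length_bin_width: float = 100.0,
                  divergence_bin_width: float = 1.0) -> GroupSummary:
    """Per-group n/mean/SD, histogram counts at the configured bin widths
    and the two-sample t-tests comparing the groups on L and on d.

    Requires both groups non-empty — an empty group usually signals an
    upstream classification problem (empty peak set, wrong min_overlap).
    """
    labeled = [c for c in copies if c.bound is not None]
    if len(labeled) != len(copies):
        raise DataError("all copies must carry a bound label; run classify_copies first")
    bound = [c for c in labeled if c.bound]
    unbound = [c for c in labeled if not c.bound]
    if not bound or not unbound:
        raise DataError(
            "one of the groups is empty; inspect the peak set and min_overlap "
            "used for classification"
        )
    lb = np.array([c.length for c in bound], dtype=float)
    lu = np.array([c.length for c in unbound], dtype=float)

    def _hist(xb: np.ndarray, xu: np.ndarray, width: float) -> Dict[str, np.ndarray]:
        lo = math.floor(min(xb.min(), xu.min()) / width) * width
        hi = math.ceil(max(xb.max(), xu.max()) / width) * width
        if hi <= lo:
            hi = lo + width
        edges = np.arange(lo, hi + width / 2, width)
        cb, _ = np.histogram(xb, bins=edges)
        cu, _ = np.histogram(xu, bins=edges)
        return {"edges": edges, "bound": cb, "unbound": cu}

    have_div = all(c.divergence is not None for c in labeled)
    db = np.array([c.divergence for c in bound], dtype=float) if have_div else None
    du = np.array([c.divergence for c in unbound], dtype=float) if have_div else None

    mb, sb = _group_stats(lb)
    mu, su = _group_stats(lu)
    return GroupSummary(
        bound=GroupStats(len(bound), mb, sb,
                         *( _group_stats(db) if have_div else (None, None))),
        unbound=GroupStats(len(unbound), mu, su,
                           *( _group_stats(du) if have_div else (None, None))),
        length_test=two_sample_t_test(lb, lu),
        divergence_test=two_sample_t_test(db, du) if have_div else None,
        length_histogram=_hist(lb, lu, length_bin_width),
        divergence_histogram=_hist(db, du, divergence_bin_width) if have_div else None,
    )
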