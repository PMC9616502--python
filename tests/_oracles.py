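"""Independent naive reference implementations used only by the tests.

Everything here works on explicit per-base boolean/float arrays or by
exhaustive enumeration, deliberately sharing no code with the package's
interval/run-length implementations.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np


def cover_array(chrom_len: int, intervals: Sequence[Tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(chrom_len, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def per_base_masks(layout_entries, interval_set) -> Dict[str, np.ndarray]:
    masks = {chrom: np.zeros(size, dtype=bool) for chrom, size in layout_entries}
    for iv in interval_set:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def oracle_merge(layout_entries, interval_set) -> List[Tuple[str, int, int]]:
    """Merged runs from a per-base boolean array."""
    out = []
    for chrom, mask in sorted(per_base_masks(layout_entries, interval_set).items()):
        padded = np.concatenate(([False], mask, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def oracle_count_overlapping(layout_entries, query, reference, min_overlap=1) -> int:
    masks = per_base_masks(layout_entries, reference)
    n = 0
    for iv in query:
        if int(masks[iv.chrom][iv.start:iv.end].sum()) >= min_overlap:
            n += 1
    return n


def oracle_overlap_bp(layout_entries, query, reference) -> List[int]:
    masks = per_base_masks(layout_entries, reference)
    return [int(masks[iv.chrom][iv.start:iv.end].sum()) for iv in query]


def oracle_coverage_fraction(layout_entries, interval_set) -> float:
    masks = per_base_masks(layout_entries, interval_set)
    total = sum(size for _, size in layout_entries)
    return sum(int(m.sum()) for m in masks.values()) / total


# ---- coverage tracks ------------------------------------------------------

def dense_track(layout_entries, runs: Sequence[Tuple[str, int, int, float]]
                ) -> Dict[str, np.ndarray]:
    arrays = {chrom: np.zeros(size) for chrom, size in layout_entries}
    for chrom, s, e, v in runs:
        arrays[chrom][s:e] = v
    return arrays


def oracle_mean(dense: np.ndarray, a: float, b: float) -> float:
    """Mean of a per-base array over the real interval [a, b); positions
    outside the array read 0.  Computed base by base with partial-base
    weights."""
    total = 0.0
    lo = int(np.floor(a))
    hi = int(np.ceil(b))
    for i in range(lo, hi):
        if i < 0 or i >= len(dense):
            continue
        w = min(b, i + 1) - max(a, i)
        if w > 0:
            total += float(dense[i]) * w
    return total / (b - a)


def oracle_trimmed_mean(column: Sequence[float], trim_fraction: float) -> float:
    vals = sorted(column)
    n = len(vals)
    if trim_fraction == 0:
        return float(np.mean(vals))
    k = int(np.ceil(n * trim_fraction / 100.0))
    return float(np.mean(vals[k:n - k]))


# ---- alignment ------------------------------------------------------------

def oracle_nw_score(a: str, b: str, match: float, mismatch: float,
                    gap: float) -> float:
    """Maximum global-alignment score by plain recursion over all gapped
    alignments (exponential; only for tiny sequences)."""

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


# ---- occupancy ------------------------------------------------------------

def oracle_occupancy(layout_entries, a_reps, b_reps, min_support: int
                     ) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-base three-way classification into a_only/b_only/shared."""

    def support(reps):
        masks = {chrom: np.zeros(size, dtype=np.int32)
                 for chrom, size in layout_entries}
        for rep in reps:
            seen = per_base_masks(layout_entries, rep)
            for chrom in masks:
                masks[chrom] += seen[chrom].astype(np.int32)
        return {chrom: m >= min_support for chrom, m in masks.items()}

    pa, pb = support(a_reps), support(b_reps)
    return {
        "a_only": {c: pa[c] & ~pb[c] for c, _ in layout_entries},
        "b_only": {c: pb[c] & ~pa[c] for c, _ in layout_entries},
        "shared": {c: pa[c] & pb[c] for c, _ in layout_entries},
    }


def oracle_repeat_fractions(layout_entries, subset_masks: Dict[str, np.ndarray],
                            annotation) -> Dict[str, float]:
    """Per-class length fractions of one subset under longest-interval
    precedence per base (ties: class name, then start)."""
    # per-base winning class
    winner: Dict[str, np.ndarray] = {}
    best_key: Dict[str, list] = {}
    for chrom, size in layout_entries:
        winner[chrom] = np.full(size, None, dtype=object)
        best_key[chrom] = [None] * size
    for iv in annotation:
        key = (-(iv.end - iv.start), iv.name, iv.start)
        for pos in range(iv.start, iv.end):
            cur = best_key[iv.chrom][pos]
            if cur is None or key < cur:
                best_key[iv.chrom][pos] = key
                winner[iv.chrom][pos] = iv.name
    total = sum(int(m.sum()) for m in subset_masks.values())
    out: Dict[str, float] = {}
    if total == 0:
        return out
    annotated = 0
    for chrom, mask in subset_masks.items():
        for pos in np.flatnonzero(mask):
            cls = winner[chrom][pos]
            if cls is not None:
                out[cls] = out.get(cls, 0) + 1
                annotated += 1
    out = {cls: cnt / total for cls, cnt in out.items()}
    out["unannotated"] = (total - annotated) / total
    return out
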