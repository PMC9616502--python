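"""Synthetic genome generator.

Emulates the data layout of a KZFP/satellite study at desk scale so every
downstream stage is testable without external downloads: a small multi-
chromosome genome carrying one satellite family whose factor-*bound* copies
are longer and less diverged from the family consensus than unbound copies,
with the bound copies clustered into arrays on two designated chromosomes
(named ``chr5`` and ``chr7`` by default, after the arrangement the analysis
is modeled on) while unbound copies are scattered genome-wide.  Peaks cover
bound copies (tunable recall and false-positive rate), and Poisson coverage
tracks carry configurable fold-enrichment over a feature class — a strong
"control" condition and a weaker "depleted" condition over the bound
copies, plus an IgG-like flat noisy control and an RNA-like track over all
repeat loci.

A single integer seed fans out to fixed per-component substreams (genome,
copies, placement, peaks, then one per track), so adding a track never
perturbs copy placement, and a fixed seed yields byte-identical output
files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .errors import ConfigError, DataError
from .intervals import GenomeLayout, GenomicInterval, IntervalSet, merge_intervals
from .repeats import RepeatCopy, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class TrackSpec(NamedTuple):
    """One coverage track: condition name, enriched feature class
    (``bound`` / ``unbound`` / ``all``), fold enrichment over background."""

    condition: str
    feature_class: str
    enrichment: float


DEFAULT_CHROMOSOMES: Tuple[Tuple[str, int], ...] = (
    ("chr1", 1_000_000),
    ("chr2", 1_000_000),
    ("chr3", 1_000_000),
    ("chr5", 1_000_000),
    ("chr7", 1_000_000),
)

DEFAULT_TRACK_SPECS: Tuple[TrackSpec, ...] = (
    TrackSpec("control", "bound", 8.0),
    TrackSpec("depleted", "bound", 3.0),
    TrackSpec("rna", "all", 5.0),
)


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic dataset.

    The defaults encode the study conditions the package is exercised
    under: ~100 bound copies (mean 2500 bp, SD 200, 5% divergence) in
    arrays on 2 of 5 chromosomes versus ~300 scattered unbound copies
    (mean 800 bp, SD 200, 15% divergence), perfect peak recall with no
    false positives, and Poisson tracks at 8x (control) / 3x (depleted)
    enrichment over bound copies against a background rate of 2.
    """

    seed: int = 0
    chromosomes: Tuple[Tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    consensus: Optional[str] = None
    consensus_length: int = 300
    n_bound: int = 100
    n_unbound: int = 300
    array_chromosomes: Tuple[str, ...] = ("chr5", "chr7")
    bound_length_mean: float = 2500.0
    bound_length_sd: float = 200.0
    unbound_length_mean: float = 800.0
    unbound_length_sd: float = 200.0
    bound_divergence: float = 0.05
    unbound_divergence: float = 0.15
    indel_rate: float = 0.002
    peak_recall: float = 1.0
    peak_fpr: float = 0.0
    peak_padding: int = 50
    n_peak_replicates: int = 2
    depleted_peak_dropout: float = 0.3
    track_specs: Tuple[TrackSpec, ...] = DEFAULT_TRACK_SPECS
    background_rate: float = 2.0
    library_size: float = 1.0
    min_copy_length: int = 60
    array_gap_min: int = 200
    array_gap_max: int = 800

    def validate(self) -> None:
        problems = []
        for name, p in (("bound_divergence", self.bound_divergence),
                        ("unbound_divergence", self.unbound_divergence),
                        ("indel_rate", self.indel_rate),
                        ("peak_recall", self.peak_recall),
                        ("peak_fpr", self.peak_fpr),
                        ("depleted_peak_dropout", self.depleted_peak_dropout)):
            if not (0.0 <= p <= 1.0):
                problems.append(f"{name} must be in [0, 1], got {p}")
        for name, v in (("consensus_length", self.consensus_length),
                        ("n_bound", self.n_bound), ("n_unbound", self.n_unbound),
                        ("bound_length_mean", self.bound_length_mean),
                        ("unbound_length_mean", self.unbound_length_mean),
                        ("background_rate", self.background_rate),
                        ("library_size", self.library_size),
                        ("n_peak_replicates", self.n_peak_replicates)):
            if v <= 0:
                problems.append(f"{name} must be > 0, got {v}")
        names = [n for n, _ in self.chromosomes]
        for c in self.array_chromosomes:
            if c not in names:
                problems.append(f"array chromosome {c!r} not in the genome")
        if self.consensus is not None and not self.consensus:
            problems.append("consensus must be a non-empty DNA string")
        for spec in self.track_specs:
            if spec.enrichment < 0:
                problems.append(f"track {spec.condition!r}: enrichment must be >= 0")
            if spec.feature_class not in ("bound", "unbound", "all"):
                problems.append(
                    f"track {spec.condition!r}: unknown feature class "
                    f"{spec.feature_class!r}")
        if problems:
            raise ConfigError("; ".join(problems))

    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chromosomes)


@dataclass
class SyntheticDataset:
    """Everything one generated study comprises, plus the ground truth."""

    config: SyntheticConfig
    layout: GenomeLayout
    genome: Dict[str, str]
    consensus: str
    repeats: List[RepeatCopy]           # truth labels in .bound, truth divergence in .divergence
    repeat_annotation: IntervalSet      # name = truth label, score = true % divergence
    peaks: Dict[str, IntervalSet]       # keyed '<condition>_rep<i>'
    tracks: Dict[str, CoverageTrack]    # track_specs conditions plus 'igg'
    counts: pd.DataFrame                # per-locus expression-like counts
    truth: pd.DataFrame


@dataclass
class MutatedCopy:
    sequence: str
    n_substitutions: int
    n_insertions: int
    n_deletions: int
    template_length: int

    @property
    def true_divergence_pct(self) -> float:
        return 100.0 * self.n_substitutions / self.template_length


def random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate_from_consensus(consensus: str, substitution_p: float, indel_rate: float,
                          target_length: int, rng: np.random.Generator) -> MutatedCopy:
    """Build a copy by tandem repetition of the consensus truncated to
    ``target_length``, then apply i.i.d. substitutions (to a uniformly
    chosen *different* base) and single-base indels (insertion/deletion
    equally likely at ``indel_rate`` per base)."""
    if not consensus:
        raise DataError("consensus must be non-empty")
    if target_length < 1:
        raise DataError(f"target_length must be >= 1, got {target_length}")
    if not (0 <= substitution_p <= 1) or not (0 <= indel_rate <= 1):
        raise ConfigError("substitution_p and indel_rate must be in [0, 1]")
    reps = math.ceil(target_length / len(consensus))
    template = (consensus * reps)[:target_length]
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
    # substitutions: map base -> index, shift by 1..3 (mod 4) to force a change
    idx = np.searchsorted(_BASES, arr)
    sub_mask = rng.random(target_length) < substitution_p
    n_sub = int(sub_mask.sum())
    if n_sub:
        shifts = rng.integers(1, 4, size=n_sub)
        idx[sub_mask] = (idx[sub_mask] + shifts) % 4
        arr = _BASES[idx]
    # single-base indels, insertion and deletion equally likely
    r = rng.random(target_length)
    del_mask = r < indel_rate / 2.0
    ins_mask = r > 1.0 - indel_rate / 2.0
    n_ins = int(ins_mask.sum())
    ins_bases = rng.choice(_BASES, size=n_ins) if n_ins else np.empty(0, np.uint8)
    pieces: List[np.ndarray] = []
    last = 0
    ins_positions = np.flatnonzero(ins_mask)
    for k, pos in enumerate(ins_positions.tolist()):
        pieces.append(arr[last:pos + 1])
        pieces.append(ins_bases[k:k + 1])
        last = pos + 1
    pieces.append(arr[last:])
    arr = np.concatenate(pieces) if len(pieces) > 1 else arr
    if del_mask.any():
        # deletion positions shift once insertions are spliced in; re-derive
        keep = np.ones(target_length, dtype=bool)
        keep[del_mask] = False
        expanded = np.ones(len(arr), dtype=bool)
        # positions of original bases within the expanded array
        orig_pos = np.arange(target_length) + np.cumsum(
            np.concatenate(([0], ins_mask[:-1].astype(np.int64))))
        expanded[orig_pos[~keep]] = False
        arr = arr[expanded]
    seq = arr.tobytes().decode("ascii")
    if not seq:
        raise DataError("mutation deleted the entire copy; lower indel_rate")
    return MutatedCopy(seq, n_sub, n_ins, int(del_mask.sum()), target_length)


def simulate_coverage_track(features: IntervalSet, enrichment: float,
                            background_rate: float, library_size: float,
                            rng: np.random.Generator,
                            layout: Optional[GenomeLayout] = None) -> CoverageTrack:
    """Per-base Poisson counts with mean ``background_rate`` outside the
    (merged) features and ``background_rate * enrichment`` inside, scaled by
    ``library_size`` and run-length encoded."""
    if enrichment < 0:
        raise ConfigError(f"enrichment must be >= 0, got {enrichment}")
    if background_rate <= 0:
        raise ConfigError(f"background_rate must be > 0, got {background_rate}")
    layout = layout if layout is not None else features.layout
    merged = features._merged_arrays()
    dense: Dict[str, np.ndarray] = {}
    for chrom, size in layout.entries:
        lam = np.full(size, background_rate, dtype=np.float64)
        if chrom in merged:
            starts, ends, _ = merged[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                lam[s:e] *= enrichment
        dense[chrom] = rng.poisson(lam).astype(np.float64) * library_size
    return CoverageTrack.from_dense(dense, layout)


def _place_copies(cfg: SyntheticConfig, layout: GenomeLayout,
                  bound_lengths: Sequence[int], unbound_lengths: Sequence[int],
                  rng: np.random.Generator):
    """Bound copies go into clustered arrays on the array chromosomes;
    unbound copies are scattered genome-wide by rejection sampling."""
    placements: List[Tuple[str, int, int, bool]] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in layout.names}

    n_arr = len(cfg.array_chromosomes)
    per_chrom = [len(bound_lengths) // n_arr] * n_arr
    for i in range(len(bound_lengths) % n_arr):
        per_chrom[i] += 1
    pos = 0
    for chrom, k in zip(cfg.array_chromosomes, per_chrom):
        if k == 0:
            continue
        lens = list(bound_lengths[pos:pos + k])
        pos += k
        gaps = rng.integers(cfg.array_gap_min, cfg.array_gap_max + 1,
                            size=max(k - 1, 0))
        span = int(sum(lens) + gaps.sum())
        size = layout.size_of(chrom)
        if span >= size:
            raise DataError(
                f"bound array needs {span} bp but chromosome {chrom} has only "
                f"{size} bp available")
        start = int(rng.integers(0, size - span + 1))
        cur = start
        for j, L in enumerate(lens):
            placements.append((chrom, cur, cur + L, True))
            occupied[chrom].append((cur, cur + L))
            cur += L
            if j < len(gaps):
                cur += int(gaps[j])

    sizes = np.array([layout.size_of(c) for c in layout.names], dtype=np.float64)
    weights = sizes / sizes.sum()
    total_needed = int(sum(unbound_lengths))
    # unbound copies keep a peak_padding margin from every placed copy, so
    # padded peaks over bound copies can never touch an unbound copy
    margin = cfg.peak_padding
    for L in unbound_lengths:
        placed = False
        for _ in range(1000):
            ci = int(rng.choice(len(sizes), p=weights))
            chrom = layout.names[ci]
            size = layout.size_of(chrom)
            if size < L:
                continue
            s = int(rng.integers(0, size - L + 1))
            e = s + L
            if any(s < oe + margin and e > os_ - margin
                   for os_, oe in occupied[chrom]):
                continue
            placements.append((chrom, s, e, False))
            occupied[chrom].append((s, e))
            placed = True
            break
        if not placed:
            raise DataError(
                f"could not place a {L}-bp copy after 1000 attempts; "
                f"~{total_needed} bp of copies requested in a "
                f"{layout.total_size}-bp genome")
    return placements


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic study: genome, satellite annotation with
    truth labels, peak replicates for two conditions, coverage tracks and
    per-locus counts."""
    cfg.validate()
    layout = cfg.layout()
    ss = np.random.SeedSequence(cfg.seed)
    s_genome, s_consensus, s_copies, s_place, s_peaks, s_tracks = ss.spawn(6)

    rng_cons = np.random.default_rng(s_consensus)
    consensus = cfg.consensus if cfg.consensus is not None else \
        random_dna(cfg.consensus_length, rng_cons)

    # per-copy lengths, divergences and mutated sequences
    rng_copies = np.random.default_rng(s_copies)
    n_total = cfg.n_bound + cfg.n_unbound
    means = np.concatenate([np.full(cfg.n_bound, cfg.bound_length_mean),
                            np.full(cfg.n_unbound, cfg.unbound_length_mean)])
    sds = np.concatenate([np.full(cfg.n_bound, cfg.bound_length_sd),
                          np.full(cfg.n_unbound, cfg.unbound_length_sd)])
    lengths = np.maximum(
        np.round(rng_copies.normal(means, sds)).astype(np.int64),
        cfg.min_copy_length)
    divs = np.concatenate([np.full(cfg.n_bound, cfg.bound_divergence),
                           np.full(cfg.n_unbound, cfg.unbound_divergence)])
    mutated = [mutate_from_consensus(consensus, float(divs[i]), cfg.indel_rate,
                                     int(lengths[i]), rng_copies)
               for i in range(n_total)]
    realized_lengths = [len(m.sequence) for m in mutated]

    rng_place = np.random.default_rng(s_place)
    placements = _place_copies(
        cfg, layout, realized_lengths[:cfg.n_bound], realized_lengths[cfg.n_bound:],
        rng_place)
    strands = np.where(rng_place.random(n_total) < 0.5, "+", "-")

    # genome background, copies embedded in annotated orientation
    rng_genome = np.random.default_rng(s_genome)
    genome_arrays: Dict[str, np.ndarray] = {
        chrom: rng_genome.choice(_BASES, size=size)
        for chrom, size in layout.entries}

    copies: List[RepeatCopy] = []
    ann: List[GenomicInterval] = []
    truth_rows = []
    for i, ((chrom, s, e, bound), m) in enumerate(zip(placements, mutated)):
        strand = str(strands[i])
        iv = GenomicInterval(chrom, s, e, strand,
                             name=("bound" if bound else "unbound"),
                             score=round(m.true_divergence_pct, 4))
        embedded = m.sequence if strand == "+" else reverse_complement(m.sequence)
        genome_arrays[chrom][s:e] = np.frombuffer(embedded.encode("ascii"),
                                                  dtype=np.uint8)
        copies.append(RepeatCopy(iv, m.sequence, bound=bound,
                                 divergence=None))
        ann.append(iv)
        truth_rows.append({
            "copy_id": f"copy_{i:05d}", "chrom": chrom, "start": s, "end": e,
            "strand": strand, "bound": bound, "length": e - s,
            "true_divergence_pct": round(m.true_divergence_pct, 4),
            "n_substitutions": m.n_substitutions,
            "n_insertions": m.n_insertions, "n_deletions": m.n_deletions,
        })
    genome = {c: a.tobytes().decode("ascii") for c, a in genome_arrays.items()}
    repeat_annotation = IntervalSet(ann, layout, validate=False).sorted()
    truth = pd.DataFrame(truth_rows)

    # peaks: per condition and replicate; 'depleted' replicates lose a
    # fraction of bound peaks (heterochromatin-loss analogue)
    rng_peaks = np.random.default_rng(s_peaks)
    peaks: Dict[str, IntervalSet] = {}
    for cond in ("control", "depleted"):
        for rep in range(1, cfg.n_peak_replicates + 1):
            ivs = []
            for c in copies:
                if c.bound:
                    keep = rng_peaks.random() < cfg.peak_recall
                    if cond == "depleted" and keep:
                        keep = rng_peaks.random() >= cfg.depleted_peak_dropout
                else:
                    keep = rng_peaks.random() < cfg.peak_fpr
                if keep:
                    s0 = max(0, c.interval.start - cfg.peak_padding)
                    e0 = min(layout.size_of(c.interval.chrom),
                             c.interval.end + cfg.peak_padding)
                    ivs.append(GenomicInterval(
                        c.interval.chrom, s0, e0, ".",
                        name=f"peak_{len(ivs):05d}",
                        score=float(np.round(rng_peaks.uniform(5, 50), 3))))
            peaks[f"{cond}_rep{rep}"] = IntervalSet(ivs, layout,
                                                    validate=False).sorted()

    # coverage tracks: igg first so adding specs never perturbs it
    feature_sets = {
        "bound": IntervalSet([c.interval for c in copies if c.bound], layout,
                             validate=False),
        "unbound": IntervalSet([c.interval for c in copies if not c.bound],
                               layout, validate=False),
        "all": repeat_annotation,
    }
    track_children = s_tracks.spawn(1 + len(cfg.track_specs))
    tracks: Dict[str, CoverageTrack] = {}
    tracks["igg"] = simulate_coverage_track(
        feature_sets["all"], 1.0, cfg.background_rate, cfg.library_size,
        np.random.default_rng(track_children[0]), layout)
    for k, spec in enumerate(cfg.track_specs):
        tracks[spec.condition] = simulate_coverage_track(
            feature_sets[spec.feature_class], spec.enrichment,
            cfg.background_rate, cfg.library_size,
            np.random.default_rng(track_children[1 + k]), layout)

    # per-locus counts from the RNA-like track (if configured)
    count_rows = []
    rna = tracks.get("rna")
    for i, c in enumerate(copies):
        if rna is not None:
            total = rna.mean_over(c.interval.chrom, c.interval.start,
                                  c.interval.end) * c.length
        else:
            total = 0.0
        count_rows.append({"copy_id": f"copy_{i:05d}", "length": c.length,
                           "count": int(round(total))})
    counts = pd.DataFrame(count_rows)

    return SyntheticDataset(cfg, layout, genome, consensus, copies,
                            repeat_annotation, peaks, tracks, counts, truth)


def write_dataset(ds: SyntheticDataset, out_dir) -> Dict[str, str]:
    """Write the dataset as plain-text files (FASTA, BED, bedGraph, TSV)
    plus the generating config; returns the path of every file written."""
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    def p(name: str) -> str:
        full = os.path.join(out_dir, name)
        paths[name] = full
        return full

    ds.layout.write_chrom_sizes(p("genome.chrom.sizes"))
    with open(p("genome.fa"), "w") as fh:
        for chrom, seq in ds.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(p("consensus.fa"), "w") as fh:
        fh.write(">consensus\n")
        for i in range(0, len(ds.consensus), 80):
            fh.write(ds.consensus[i:i + 80] + "\n")
    # repeats: BED6 + truth label + true divergence
    with open(p("repeats.bed"), "w") as fh:
        for iv in ds.repeat_annotation:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tsat\t0\t{iv.strand}\t"
                     f"{iv.name}\t{iv.score}\n")
    from .intervals import write_bed
    for key, pk in ds.peaks.items():
        write_bed(pk, p(f"peaks_{key}.bed"))
    for name, track in ds.tracks.items():
        track.write_bedgraph(p(f"track_{name}.bedGraph"))
    ds.counts.to_csv(p("counts.tsv"), sep="\t", index=False)
    ds.truth.to_csv(p("truth.tsv"), sep="\t", index=False)
    cfg_dict = dataclasses.asdict(ds.config)
    cfg_dict["track_specs"] = [list(t) for t in ds.config.track_specs]
    with open(p("config.json"), "w") as fh:
        json.dump(cfg_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
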