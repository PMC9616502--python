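# Methods

## Scope and model

`satarray` analyses a satellite repeat family under factor surveillance.
The objects are: a genome layout (named chromosomes with lengths, total
size *G*); interval sets on 0-based half-open coordinates; repeat copies
(interval + sequence + length *L* + percent divergence *d* + bound label);
coverage tracks (non-negative step functions, bedGraph on disk); and
enrichment results (*O*, *E*, *O/E*, *b*, *N*, *p*).

Two intervals overlap only if they share ≥ 1 base; touching intervals
(`[a,b)`, `[b,c)`) do not overlap but are coalesced by merging. Strand
never affects overlap or coverage. Unknown chromosomes in any input are
errors, never silent drops — a silently shrunk set corrupts the
denominator of every enrichment statistic downstream.

## Binding classification

A copy is *bound* iff it shares at least `min_overlap` bases with the
merged peak set. The loosest criterion (1 bp) is the default because it is
the most reproducible choice when the underlying overlap rule of an
upstream study is unstated; it is a flag, not a constant. Labels always
partition the copies: `n_bound + n_unbound = n`.

## Alignment, consensus and divergence

Global alignment is Needleman–Wunsch with linear gap penalty; defaults
match +1, mismatch −1, gap −2, ties broken diagonal → up → left so the
traceback is deterministic across platforms. The matrix fill is
numba-compiled; the test suite checks scores against brute-force
enumeration over all gapped alignments for short sequences.

The family consensus is rebuilt by iterative star alignment: the seed is
the sequence whose length is closest to the group median; each round
aligns every sequence to the current consensus, stacks columns in
consensus coordinates, drops columns with gap fraction ≥ 0.5, emits the
per-column majority base (lexicographic tie-break) and inserts a column
where more than half the sequences insert at the same slot; iteration
stops at a fixed point or `max_rounds` (default 5). This is an
instance-level consensus: applied to mixed-length tandem instances it
reconstructs a typical instance, not the repeat monomer.

Percent divergence is the substitution proportion over aligned non-gap
columns, `100 · mismatches / (matches + mismatches)`, with no
multiple-hit (Kimura) correction — the closest self-contained counterpart
of the "% divergence" column of a RepeatMasker-style annotation, and
exactly what the generator's truth measures. For a tandem copy much longer
than the consensus unit, a *single* global alignment is badly biased: the
unavoidable gap columns are sunk cost, so the aligner can hop between
repeat units and dodge nearly every substitution (measured: a 5%-diverged
2.5-kb copy reads back ~0%). `copy_divergence` therefore chops the copy
into consecutive unit-length windows (assumed in phase, as satellite
annotations laid down by a repeat model are), aligns each window globally
and pools match/mismatch counts. Unit-length copies reduce to the plain
pairwise definition. A small residual bias remains because each window may
slide its register at the ends (~2% relative at the default conditions);
it is visible in the tests' tolerances and does not affect any group
contrast.

Because the rebuilt instance consensus generally has a length that is not
a multiple of the repeat unit, it cannot phase the window decomposition;
the pipeline therefore measures divergence against the family's reference
unit that ships with a dataset (the analogue of a RepeatMasker repeat
model) and reports the rebuilt instance consensus alongside.

Minus-strand copies are reverse-complemented before consensus building and
divergence (on by default): mixing orientations corrupts both.

Group comparisons of *L* and *d* use the classical pooled-variance Student
t-test (df = nₓ + n_y − 2, two-sided p from the t distribution); Welch's
form is available behind a flag. When both groups are constant and equal,
p = 1 by convention.

## Randomization enrichment test

The observed statistic is the number of query intervals with
≥ `min_overlap` bases shared with the merged reference (a shared-bp
statistic is available behind a flag). Each of *N* randomizations
re-places every query interval independently, start uniform over valid
positions, length preserved exactly; randomized intervals may overlap each
other. Two placement modes: `same_chromosome` (default — preserves
chromosome composition, conservative for clustered satellites) and
`genome_wide` (uniform over all valid placements). Exceedances are
strictly greater (`Oᵢ > O`; ties do not count against the query) and

  p = (1 + b) / (1 + N),

so p is never 0 and its floor is 1/(1+N) — 0.000999 at the customary
N = 1000. The expectation *E* = |query| · coverage_fraction(reference)
treats query intervals as points; for wide intervals it understates the
hit probability slightly. This bias is documented, not corrected, because
*O/E* is interpreted relative to the same convention. Randomization *i*
draws from an independent substream keyed by (seed, *i*), so results do
not depend on execution order.

## Coverage aggregation

Tracks are sorted non-overlapping runs; uncovered bases read 0. Optional
library-size scaling multiplies a track by 1e6/total-signal at load.

Fold enrichment is per-base `(signal + c)/(control + c)` on the union of
breakpoints. The pseudocount default is **half the control's mean nonzero
value**: with per-base Poisson counts (background rate ~2) a much smaller
pseudocount lets zero-control bases dominate the mean ratio (an 8×
enrichment measured as ~116× with a 1% pseudocount, ~7.3× with this
default, flanks ~1.3). The compression of high ratios this trades for is
uniform across conditions, so condition contrasts are unaffected; the
value is overridable.

Signal matrices take fixed `bin_size` (default 100 bp) windows over each
flank and rescale the feature body to `body_bins` equal-width segments
(fractional base-pair widths are averaged exactly); flank positions beyond
the chromosome read 0; minus-strand rows are reversed when strand-oriented.
Profile curves use a symmetric trimmed mean per bin: the ⌈n·f/100⌉ smallest
and largest values are excluded (default f = 0.5, the top/bottom 0.5
percentile in nearest-rank form — this is the convention that leaves the
mean of 1…1000 at 500.5 under a symmetric trim). Per-feature means average
body bins only; flanks are display context. Occupancy subsets call a base
"present" in a condition when ≥ `min_replicate_support` merged replicates
cover it (default min(2, replicate count)) and partition the supported
space into exclusive and shared subsets; repeat-class fractions resolve
nested annotations by longest-interval precedence per base so the
fractions (plus an `unannotated` remainder) sum to 1.

## Synthetic data generator

The generator emulates the study conditions every test and example runs
under: five 1-Mb chromosomes (chr1/chr2/chr3/chr5/chr7); one satellite
family with a random 300-bp consensus unit; 100 bound copies
(length ~N(2500, 200²) bp, 5% substitution divergence) packed into
clustered arrays with 200–800-bp gaps on chr5 and chr7; 300 unbound copies
(~N(800, 200²) bp, 15% divergence) scattered genome-wide without overlap;
single-base indels at 0.2% per base (insertion/deletion equally likely);
peaks covering bound copies (recall 1.0, false-positive rate 0.0, ±50 bp
padding) in two replicates for a "control" and a "depleted" condition,
the latter dropping 30% of its peaks; per-base Poisson coverage at
background rate 2 with 8× (control) and 3× (depleted) enrichment over
bound copies, an IgG-like flat track, and an RNA-like 5× track over all
loci from which per-locus counts are integrated. Copies are built by
tandem repetition of the unit truncated to the target length, so every
instance starts in phase.

One integer seed fans out through fixed-order substreams (genome,
consensus, copies, placement, peaks, then IgG and one stream per track),
so adding a track never moves a copy and a fixed seed reproduces every
output file byte for byte. Unbound copies keep a peak-padding margin from
all other copies, which makes truth-label recovery by classification exact
by construction at recall 1 / FPR 0.

What the generator does **not** model: read-level noise and mappability
(coverage is sampled per base, not from alignments), GC or accessibility
bias, diploid genomes, transposition dynamics, and repeat families other
than the one satellite. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not performance on real
sequencing artifacts.

## Problem sizes and numerics

Tests and examples run at desk scale — genomes of 3–5 Mb, hundreds of
copies, N = 200–1000 randomizations, ≥ 100 random instances per oracle
check on ≤ 50-kb genomes — chosen as the smallest sizes at which every
directional and calibration property is decisively measurable. Exact
per-base oracle comparisons use tolerance 1e-9. Deterministic tie-breaks:
alignment traceback diagonal → up → left; top-K peaks by (−score, chrom,
start); majority base lexicographic; repeat-class precedence by
(−length, class, start). Degenerate inputs raise typed errors
(`ConfigError`/`DataError`, CLI exit codes 2/3) rather than warnings.

## Known limitations

- Window-based divergence assumes in-phase instances; out-of-phase
  truncation (common in real annotations) would inflate divergence for the
  first window until absorbed by end gaps.
- The instance-level consensus is not a monomer inference; recovering the
  repeat unit from mixed-length arrays is out of scope.
- *E* ignores finite query width and chromosome-end effects; for queries
  comparable in size to chromosomes the O/E ratio drifts from 1 under the
  null.
- Empirical p-values are bounded below by 1/(1+N); claims beyond that
  resolution require more randomizations, not extrapolation.
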