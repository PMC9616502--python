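# satarray

Analysis toolkit for satellite DNA arrays under KRAB-zinc-finger-protein
(KZFP) surveillance. Satellite families form megabase tandem arrays; when a
sequence-specific factor binds a subset of copies (read out as ChIP or
CUT&RUN peaks), the bound copies tend to be longer and less diverged from
the family consensus than unbound ones, and the chromatin over them shifts
between conditions. `satarray` implements the computational half of such a
study as a reusable library:

- **Interval core** — genome layouts (`chrom.sizes`), BED I/O, merge /
  overlap-count / coverage-fraction on 0-based half-open coordinates.
- **Binding classification** — a repeat copy is *bound* iff it shares
  ≥ `min_overlap` bases (default 1) with the merged peak set.
- **Consensus & divergence** — iterative star (majority-vote) consensus via
  Needleman–Wunsch global alignment (match +1, mismatch −1, gap −2); percent
  divergence of a copy is `100 · mismatches / (matches + mismatches)` over
  aligned non-gap columns against the family consensus unit, pooled across
  the copy's in-phase unit windows. Group contrasts (length *L*, divergence
  *d*) use the pooled-variance Student t-test.
- **Randomization enrichment** — observed overlap count *O*, *N*
  length-preserving uniform re-placements, exceedances
  *b* = #{*O*ᵢ > *O*}, one-sided add-one empirical p-value
  **p = (1 + b)/(1 + N)** (floor 1/(1+N), i.e. 0.000999 at N = 1000), and
  the observed/expected ratio *O/E* with
  *E* = |query| · coverage_fraction(reference).
- **Signal aggregation** — bedGraph coverage tracks, per-base
  fold-enrichment against an IgG control, features × bins signal matrices
  (fixed 100-bp flank bins + body rescaled to equal bins), trimmed-mean
  profiles (top/bottom 0.5 percentile per bin excluded), per-feature body
  means, top-K peak selection, replicate-supported occupancy subsets and
  repeat-class length fractions, plus TPM and −ΔΔCt utilities.
- **Synthetic generator** — a fully self-contained desk-scale study
  (genome FASTA, truth-labeled repeat annotation, peak replicates, Poisson
  coverage tracks, count tables) with the statistical structure above, so
  every stage is testable without downloads.

## Worked example

```bash
python examples/03_enrichment_test.py
```

```
maximal overlap: O = 10, E = 1.00, O/E = 10.0, b = 0, p = 0.000999
null-ish query:  O = 1, E = 1.00, O/E = 1.0, b = 297, p = 0.2977
```

The first query is engineered so every interval lies inside a reference
interval: no randomization can strictly exceed the observed count, *b* = 0
is forced, and the p-value sits exactly at the attainable floor
1/1001 = 0.000999. The second, independently placed query is unremarkable:
*O/E* ≈ 1 and a mid-range p.

```bash
python examples/02_classify_and_divergence.py
```

```
classified 60 bound + 150 unbound = 210 copies
bound:   n= 60  L =   2491 bp  d = 4.95%
unbound: n=150  L =    750 bp  d = 14.35%
length t-test    p = 5.15e-121
divergence t-test p = 6.68e-124
```

Classification recovers the generator's truth labels, and the group
summaries read back the configured contrast: bound copies longer and less
diverged, both at astronomically small p.

The other examples cover dataset generation (`01`), IgG-normalized
profiles and the control-vs-depleted condition contrast (`04`), and
occupancy subsets plus expression utilities (`05`). A thin CLI wraps the
same functions (`satarray simulate|classify|consensus|enrich|aggregate|
occupancy|run`); `satarray run --out dir/ --seed 1` executes the whole
pipeline on a synthetic dataset and writes a machine-readable
`report.json`.

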