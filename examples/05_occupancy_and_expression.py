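"""Occupancy subsets between peak-set conditions, repeat-class length
fractions, and the small expression utilities (TPM, -ddCt).

A peak region is present in a condition when enough replicates support it;
the supported space splits into condition-exclusive and shared subsets,
and each subset is decomposed into repeat-class length fractions.
"""

from satarray import (
    SyntheticConfig,
    ddct_fold_change,
    generate_dataset,
    merge_intervals,
    occupancy_subsets,
    repeat_fraction_of_subsets,
    tpm_normalize,
)

ds = generate_dataset(SyntheticConfig(seed=3, depleted_peak_dropout=0.4))
a = [ds.peaks[k] for k in sorted(ds.peaks) if k.startswith("control")]
b = [ds.peaks[k] for k in sorted(ds.peaks) if k.startswith("depleted")]
subs = occupancy_subsets(a, b)  # default: >= 2 replicates per condition
for name, sub in subs.as_dict().items():
    print(f"{name:8s} {merge_intervals(sub).total_bp():8,} bp")

fractions = repeat_fraction_of_subsets(subs, ds.repeat_annotation)
for name, classes in fractions.items():
    parts = ", ".join(f"{cls} {frac:.2f}" for cls, frac in classes.items())
    print(f"  {name}: {parts}")
# control-exclusive peak space should be dominated by the 'bound' repeat
# class: those are the peaks lost in the depleted condition.

tpm = tpm_normalize(ds.counts["count"], ds.counts["length"])
print(f"TPM over {len(tpm)} loci sums to {tpm.sum():,.0f} "
      f"(top locus {tpm.max():,.0f})")
fold = ddct_fold_change(ct_target_treated=20.0, ct_ref_treated=15.0,
                        ct_target_control=22.0, ct_ref_control=15.0)
print(f"-ddCt example: Ct (20,15) vs (22,15) -> fold change {fold:.1f}")
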