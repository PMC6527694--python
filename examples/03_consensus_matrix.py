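"""From per-replicate peak calls to the consensus count/RPM matrix.

Keeps peaks reproducible between technical replicates, merges all tissues
into the standard peak list, counts fragments per peak and normalizes to
reads per million (RPM).
"""

import atacatlas as aa

atlas = aa.simulate_atlas(aa.SimulationConfig(
    n_tissues=4, n_chromosomes=2, chromosome_length=2_000_000,
    n_shared_peaks=60, n_restricted_peaks=20, n_tss=60,
    fragments_per_sample=30_000, seed=7,
))

by_tissue = {}
for tissue in atlas.config.tissues:
    kept = aa.reproducible_peaks(
        atlas.peak_calls[f"{tissue}_r1"], atlas.peak_calls[f"{tissue}_r2"],
        min_overlap_fraction=0.5,
    )
    by_tissue[tissue] = kept
    print(f"{tissue}: {len(atlas.peak_calls[f'{tissue}_r1'])} rep1 calls -> "
          f"{len(kept)} reproducible (supported by rep2)")

consensus, contributors = aa.merge_standard_peaks(by_tissue)
shared_by_all = sum(1 for c in contributors if len(c) == len(by_tissue))
print(f"standard peak list: {len(consensus)} consensus peaks, "
      f"{shared_by_all} contributed by every tissue")

cm = aa.build_counts_matrix(
    atlas.fragments, consensus,
    library_sizes={r.sample_id: r.usable_reads for r in atlas.records},
)
pid = cm.raw.index[0]
sid = cm.samples[0]
print(f"{pid} in {sid}: {cm.raw.loc[pid, sid]} fragments -> "
      f"{cm.rpm.loc[pid, sid]:.2f} RPM -> "
      f"{cm.log_rpm.loc[pid, sid]:.3f} log10(RPM+1)")
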