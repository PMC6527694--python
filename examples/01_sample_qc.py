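"""Sample accounting and the QC exclusion rule on the bundled atlas sheet.

Loads the 66-library mouse tissue atlas metadata table, recomputes the
usable-read percentages, and applies the exclusion rule (TSS enrichment
< 10.0 or < 10,000 reproducible peaks drops a library).
"""

import atacatlas as aa

records = aa.load_atlas_records()
print(f"{len(records)} libraries across {len({r.tissue for r in records})} tissues")

by_id = {r.sample_id: r for r in records}
for sid in ("ATAC-1", "ATAC-3"):
    rec = by_id[sid]
    pct = aa.percentage_usable(rec)
    print(f"{sid}: {rec.usable_reads:,} of {rec.total_reads:,} reads usable "
          f"({pct}%) — the fraction surviving mapping-quality, duplicate "
          f"and mitochondrial filtering")

passing, failing = aa.apply_qc_filter(records)
print(f"QC: {len(passing)} pass, {len(failing)} excluded")
for rec, reasons in failing[:3]:
    print(f"  e.g. {rec.sample_id} fails: {'; '.join(reasons)}")

mean_usable = sum(r.usable_reads for r in records) / len(records)
mean_peaks = sum(r.reproducible_peaks for r in records) / len(records)
print(f"mean usable reads {mean_usable / 1e6:.1f} M; "
      f"mean reproducible peaks {mean_peaks:,.0f} per library")
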