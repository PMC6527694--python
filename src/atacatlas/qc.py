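"""Per-sample quality metrics and the sample-exclusion rule.

Three standard ATAC-seq library diagnostics: usable-read accounting, the
TSS enrichment score (fold-enrichment of aggregate fragment coverage at
transcription start sites over distal background), and the fragment-size
distribution with its nucleosomal periodicity. Samples failing the
thresholds (TSS enrichment < 10.0 or fewer than 10,000 reproducible peaks
by default) are excluded from matrix construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .fragments import Fragments, as_fragment_set
from .io import GenomicInterval, SampleRecord, ValidationError


def percentage_usable(record: SampleRecord) -> float:
    """Usable reads as a percentage of total reads, rounded to 2 decimals."""
    if record.total_reads <= 0:
        raise ValidationError(f"{record.sample_id}: total_reads must be positive")
    return round(100.0 * record.usable_reads / record.total_reads, 2)


@dataclass
class TssEnrichmentProfile:
    """Aggregate fragment coverage around TSSs, offsets ``-w .. +w``."""

    window_half_width: int
    positions: np.ndarray          # offsets relative to the TSS
    aggregate_signal: np.ndarray   # mean per-base coverage across TSS windows
    background: float              # mean aggregate over the outer flanks
    score: float                   # max of smoothed, background-normalized signal

    def normalized(self) -> np.ndarray:
        return self.aggregate_signal / self.background


def tss_enrichment_score(
    fragments: Fragments,
    tss: Sequence[GenomicInterval],
    window_half_width: int = 1000,
    flank: int = 100,
    smooth: int = 25,
) -> tuple[float, TssEnrichmentProfile]:
    """ENCODE-style TSS enrichment score.

    Per-base fragment coverage is aggregated over all TSS-centered windows
    (orientation-flipped for minus-strand TSSs), normalized by the mean
    signal in the outermost ``flank`` bp of both window edges, smoothed
    with a ``smooth``-bp moving average, and the maximum taken. A flat
    (TSS-independent) fragment distribution scores ~1.

    Returns ``(score, profile)``. If no fragment touches any window the
    score is undefined and reported as NaN with a warning.
    """
    if not tss:
        raise ValidationError("need at least one TSS")
    frags = as_fragment_set(fragments)
    if len(frags) == 0:
        raise ValidationError("need at least one fragment")
    w = int(window_half_width)
    width = 2 * w + 1
    delta = np.zeros(width + 1)
    n_windows = 0

    by_chrom = {name: (s, e) for name, s, e in frags.sorted().per_chrom()}
    for point in tss:
        n_windows += 1
        if point.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[point.chrom]
        max_len = int((ends - starts).max())
        win_start, win_end = point.start - w, point.start + w + 1
        i0 = np.searchsorted(starts, win_start - max_len, side="left")
        i1 = np.searchsorted(starts, win_end, side="left")
        a = np.clip(starts[i0:i1], win_start, win_end) - win_start
        b = np.clip(ends[i0:i1], win_start, win_end) - win_start
        keep = b > a
        a, b = a[keep], b[keep]
        if point.strand == "-":
            a, b = width - b, width - a
        np.add.at(delta, a, 1.0)
        np.add.at(delta, b, -1.0)

    aggregate = np.cumsum(delta)[:width] / max(n_windows, 1)
    positions = np.arange(-w, w + 1)
    background = float(
        np.mean(np.concatenate((aggregate[:flank], aggregate[-flank:])))
    )
    profile = TssEnrichmentProfile(w, positions, aggregate, background, np.nan)
    if background <= 0:
        warnings.warn(
            "no fragment coverage in TSS flanks; enrichment score undefined",
            stacklevel=2,
        )
        return float("nan"), profile
    kernel = np.ones(max(int(smooth), 1)) / max(int(smooth), 1)
    smoothed = np.convolve(aggregate, kernel, mode="same")
    score = float(np.max(smoothed) / background)
    profile.score = score
    return score, profile


@dataclass
class FragmentSizeProfile:
    """Fragment-length histogram with detected modes and their spacing."""

    histogram: np.ndarray      # counts for lengths 1..max_length
    lengths: np.ndarray        # 1..max_length
    modes: np.ndarray          # detected local maxima (bp), ascending
    period_estimate: float | None  # median spacing of consecutive modes


def fragment_size_profile(
    fragments: Fragments,
    max_length: int = 1000,
    smooth_width: int = 5,
    prominence_fraction: float = 0.05,
) -> FragmentSizeProfile:
    """Histogram of fragment lengths with nucleosomal mode detection.

    Lengths beyond ``max_length`` accumulate in the last bin so the
    histogram total always equals the number of fragments. Modes are local
    maxima of a ``smooth_width``-bp moving-average of the histogram with
    prominence at least ``prominence_fraction`` of the smoothed maximum;
    the period estimate is the median spacing of consecutive modes (None
    with fewer than two modes).
    """
    frags = as_fragment_set(fragments)
    if len(frags) == 0:
        raise ValidationError("need at least one fragment")
    lengths = np.clip(frags.lengths(), 1, max_length)
    hist = np.bincount(lengths, minlength=max_length + 1)[1:].astype(float)
    k = max(int(smooth_width), 1)
    smoothed = np.convolve(hist, np.ones(k) / k, mode="same")
    peaks_idx, _ = find_peaks(smoothed, prominence=prominence_fraction * smoothed.max())
    modes = np.sort(peaks_idx + 1)  # bin i holds length i+1
    period = float(np.median(np.diff(modes))) if len(modes) >= 2 else None
    return FragmentSizeProfile(
        histogram=hist, lengths=np.arange(1, max_length + 1),
        modes=modes, period_estimate=period,
    )


def apply_qc_filter(
    records: Sequence[SampleRecord],
    min_tss: float = 10.0,
    min_peaks: int = 10000,
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, list[str]]]]:
    """Partition samples into passing and failing sets.

    A sample fails if its TSS enrichment is strictly below ``min_tss`` or
    its reproducible-peak count strictly below ``min_peaks``; each failure
    lists the criteria that fired. Records lacking either metric raise.
    """
    passing: list[SampleRecord] = []
    failing: list[tuple[SampleRecord, list[str]]] = []
    for rec in records:
        if rec.tss_enrichment is None or rec.reproducible_peaks is None:
            raise ValidationError(
                f"{rec.sample_id}: QC metrics not populated"
            )
        reasons = []
        if rec.tss_enrichment < min_tss:
            reasons.append(f"tss_enrichment {rec.tss_enrichment} < {min_tss}")
        if rec.reproducible_peaks < min_peaks:
            reasons.append(f"reproducible_peaks {rec.reproducible_peaks} < {min_peaks}")
        if reasons:
            failing.append((rec, reasons))
        else:
            passing.append(rec)
    return passing, failing


def qc_report(
    records: Sequence[SampleRecord],
    min_tss: float = 10.0,
    min_peaks: int = 10000,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """One row per sample: accounting, metrics, pass/fail and reasons."""
    passing, failing = apply_qc_filter(records, min_tss, min_peaks)
    reasons = {rec.sample_id: "; ".join(why) for rec, why in failing}
    rows = []
    for rec in records:
        rows.append({
            "sample_id": rec.sample_id, "tissue": rec.tissue,
            "gender": rec.gender, "replicate": rec.replicate,
            "total_reads": rec.total_reads, "mapped_reads": rec.mapped_reads,
            "chrm_reads": rec.chrm_reads, "usable_reads": rec.usable_reads,
            "pct_usable": percentage_usable(rec),
            "tss_enrichment": rec.tss_enrichment,
            "reproducible_peaks": rec.reproducible_peaks,
            "qc_pass": rec.sample_id not in reasons,
            "qc_fail_reasons": reasons.get(rec.sample_id, ""),
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
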