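"""Consensus peak construction and the count/RPM matrix backbone.

Stages: keep peaks reproducible between the two technical replicates of a
tissue (reciprocal-overlap filter standing in for IDR), merge all tissues'
reproducible peaks into a non-redundant standard peak list, count each
sample's fragments per consensus peak, and normalize to reads-per-million
(RPM) and log10 RPM layers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import Fragments, as_fragment_set
from .io import GenomicInterval, ValidationError, sort_intervals, write_bed, write_matrix


def reproducible_peaks(
    rep1_peaks: Sequence[GenomicInterval],
    rep2_peaks: Sequence[GenomicInterval],
    min_overlap_fraction: float = 0.5,
    use_intersection: bool = False,
) -> list[GenomicInterval]:
    """Peaks of replicate 1 supported by replicate 2.

    A rep1 peak is retained when some rep2 peak overlaps it by at least
    ``min_overlap_fraction`` of the *shorter* of the two peaks. Retained
    peaks keep rep1 coordinates by default; with ``use_intersection`` the
    overlap region with the best-supporting rep2 peak is returned instead.
    Output is sorted by (chrom, start).
    """
    if not 0 < min_overlap_fraction <= 1:
        raise ValidationError("min_overlap_fraction must be in (0, 1]")
    rep2_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in rep2_peaks}:
        arr = sorted(
            (p for p in rep2_peaks if p.chrom == chrom), key=lambda p: p.start
        )
        rep2_by_chrom[chrom] = (
            np.array([p.start for p in arr], dtype=np.int64),
            np.array([p.end for p in arr], dtype=np.int64),
        )

    kept: list[GenomicInterval] = []
    for peak in rep1_peaks:
        if peak.chrom not in rep2_by_chrom:
            continue
        s2, e2 = rep2_by_chrom[peak.chrom]
        max_len = int((e2 - s2).max())
        lo = np.searchsorted(s2, peak.start - max_len, side="left")
        hi = np.searchsorted(s2, peak.end, side="left")
        if hi <= lo:
            continue
        ov = np.minimum(peak.end, e2[lo:hi]) - np.maximum(peak.start, s2[lo:hi])
        shorter = np.minimum(len(peak), e2[lo:hi] - s2[lo:hi])
        frac = ov / shorter
        frac[ov <= 0] = 0.0
        best = int(np.argmax(frac))
        if frac[best] >= min_overlap_fraction:
            if use_intersection:
                kept.append(replace(
                    peak,
                    start=int(max(peak.start, s2[lo + best])),
                    end=int(min(peak.end, e2[lo + best])),
                ))
            else:
                kept.append(peak)
    return sort_intervals(kept)


def merge_standard_peaks(
    per_tissue_peak_sets: Mapping[str, Sequence[GenomicInterval]]
    | Sequence[Sequence[GenomicInterval]],
) -> tuple[list[GenomicInterval], list[tuple[str, ...]]]:
    """Merge all tissues' peaks into the non-redundant standard peak list.

    Overlapping or bookended (end == start) intervals collapse into maximal
    intervals. Returns the sorted consensus peaks — named ``cons_00001``…
    with score = number of contributing tissues — and, aligned with them,
    the tuple of contributing tissue labels per consensus peak.
    """
    if isinstance(per_tissue_peak_sets, Mapping):
        labelled = list(per_tissue_peak_sets.items())
    else:
        labelled = [
            (f"set_{i + 1}", peaks) for i, peaks in enumerate(per_tissue_peak_sets)
        ]
    tagged = [
        (p.chrom, p.start, p.end, label)
        for label, peaks in labelled
        for p in peaks
    ]
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[GenomicInterval] = []
    contributors: list[tuple[str, ...]] = []
    cur: list | None = None
    cur_labels: set[str] = set()
    for chrom, start, end, label in tagged:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur_labels.add(label)
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
                contributors.append(tuple(sorted(cur_labels)))
            cur = [chrom, start, end]
            cur_labels = {label}
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
        contributors.append(tuple(sorted(cur_labels)))
    merged = [
        replace(p, name=f"cons_{i + 1:05d}", score=float(len(contributors[i])))
        for i, p in enumerate(merged)
    ]
    return merged, contributors


def _chrom_arrays(
    peaks: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Split a sorted, non-overlapping consensus list per chromosome,
    validating the contract. The third array maps back to global indices."""
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    out = {}
    for chrom, idx in by_chrom.items():
        starts = np.array([peaks[i].start for i in idx], dtype=np.int64)
        ends = np.array([peaks[i].end for i in idx], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        if (starts[1:] < ends[:-1]).any():
            raise ValidationError(
                f"peaks on {chrom} overlap; counting requires a consensus list"
            )
        out[chrom] = (starts, ends, np.array(idx, dtype=np.int64)[order])
    return out


def count_fragments_in_peaks(
    fragments: Fragments, peaks: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-peak fragment counts with any-overlap (>= 1 bp) semantics.

    Peaks must be non-overlapping (a consensus list); a fragment spanning
    two bookended peaks increments both. Returns counts aligned with the
    input peak order.
    """
    frags = as_fragment_set(fragments)
    arrays = _chrom_arrays(peaks)
    counts = np.zeros(len(peaks), dtype=np.int64)
    for chrom, fs, fe in frags.per_chrom():
        if chrom not in arrays:
            continue
        ps, pe, idx = arrays[chrom]
        lo = np.searchsorted(pe, fs, side="right")
        hi = np.searchsorted(ps, fe, side="left")
        delta = np.zeros(len(ps) + 1, dtype=np.int64)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        counts[idx] += np.cumsum(delta)[: len(ps)]
    return counts


def normalize_rpm(
    raw: pd.DataFrame, library_sizes: pd.Series | Mapping[str, int]
) -> pd.DataFrame:
    """Reads-per-million: ``raw * 1e6 / library_size`` column-wise."""
    sizes = pd.Series(library_sizes).reindex(raw.columns)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()])
        raise ValidationError(f"missing library sizes for {missing}")
    if (sizes <= 0).any():
        raise ValidationError("library sizes must be positive")
    return raw * 1e6 / sizes


def log_transform(rpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(RPM + pseudocount); the default pseudocount of 1 maps zeros to 0."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return np.log10(rpm + pseudocount)


@dataclass
class CountsMatrix:
    """Consensus-peak x sample matrix with raw, RPM and log10 RPM layers."""

    peaks: list[GenomicInterval]
    samples: list[str]
    raw: pd.DataFrame
    library_sizes: pd.Series
    rpm: pd.DataFrame
    log_rpm: pd.DataFrame

    def write(self, outdir: str | Path, prefix: str = "counts") -> None:
        outdir = Path(outdir)
        write_bed(self.peaks, outdir / "consensus_peaks.bed")
        write_matrix(self.raw, outdir / f"{prefix}_raw.tsv")
        write_matrix(self.rpm, outdir / f"{prefix}_rpm.tsv")
        write_matrix(self.log_rpm, outdir / f"{prefix}_log10rpm.tsv")


def build_counts_matrix(
    fragments_by_sample: Mapping[str, Fragments],
    peaks: Sequence[GenomicInterval],
    library_sizes: Mapping[str, int] | None = None,
    pseudocount: float = 1.0,
) -> CountsMatrix:
    """Count every sample's fragments over the consensus peaks and attach
    RPM / log10 RPM layers.

    ``library_sizes`` defaults to each sample's total fragment count (the
    synthetic analogue of usable mapped reads); pass the usable-read totals
    from the sample sheet to reproduce the published normalization.
    """
    if not peaks:
        raise ValidationError("consensus peak list is empty")
    samples = list(fragments_by_sample)
    names = [p.name or f"cons_{i + 1:05d}" for i, p in enumerate(peaks)]
    if len(set(names)) != len(names):
        raise ValidationError("consensus peak names must be unique")
    raw = pd.DataFrame(index=names, columns=samples, dtype=np.int64)
    sizes = {}
    for sid, frags in fragments_by_sample.items():
        fset = as_fragment_set(frags)
        raw[sid] = count_fragments_in_peaks(fset, peaks)
        sizes[sid] = len(fset)
    lib = pd.Series(library_sizes if library_sizes is not None else sizes,
                    dtype=float).reindex(samples)
    rpm = normalize_rpm(raw, lib)
    return CountsMatrix(
        peaks=list(peaks), samples=samples, raw=raw,
        library_sizes=lib, rpm=rpm, log_rpm=log_transform(rpm, pseudocount),
    )
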