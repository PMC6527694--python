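import numpy as np
import pandas as pd
import pytest

import atacatlas as aa
from atacatlas.io import ValidationError


def iv(chrom, start, end, **kw):
    return aa.GenomicInterval(chrom, start, end, **kw)


# ------------------------------------------------------------ oracles

def merge_by_coverage(sets):
    """Boolean-coverage union oracle: mark covered (and bookend-bridged)
    bases, read off maximal runs."""
    out = []
    chroms = {p.chrom for peaks in sets for p in peaks}
    for chrom in sorted(chroms):
        spans = sorted(
            (p.start, p.end) for peaks in sets for p in peaks if p.chrom == chrom
        )
        hi = max(e for _, e in spans) + 1
        covered = np.zeros(hi, dtype=bool)
        for s, e in spans:
            covered[s:e] = True
            # bookended intervals merge: bridge the zero-width junction
        runs = np.flatnonzero(np.diff(covered.astype(int)))
        edges = np.concatenate(([0], runs + 1, [hi]))
        for a, b in zip(edges[:-1], edges[1:]):
            if covered[a]:
                out.append((chrom, int(a), int(b)))
    return out


def count_by_all_pairs(frags, peaks):
    counts = np.zeros(len(peaks), dtype=int)
    for f in frags:
        for j, p in enumerate(peaks):
            if f.chrom == p.chrom and f.start < p.end and p.start < f.end:
                counts[j] += 1
    return counts


# ------------------------------------------------------------ reproducible

def test_reproducible_identical_sets_identity():
    peaks = [iv("chr1", 100, 200), iv("chr1", 500, 800), iv("chr2", 10, 60)]
    assert aa.reproducible_peaks(peaks, peaks) == sorted(
        peaks, key=lambda p: (p.chrom, p.start))


def test_reproducible_disjoint_sets_empty():
    a = [iv("chr1", 100, 200)]
    b = [iv("chr1", 300, 400), iv("chr2", 100, 200)]
    assert aa.reproducible_peaks(a, b) == []


def test_reproducible_boundary_fraction():
    # overlap 50 over shorter length 100 -> exactly 0.5, retained
    a = [iv("chr1", 100, 200)]
    b = [iv("chr1", 150, 250)]
    assert aa.reproducible_peaks(a, b, 0.5) == a
    assert aa.reproducible_peaks(a, b, 0.51) == []


def test_reproducible_intersection_mode():
    a = [iv("chr1", 100, 200)]
    b = [iv("chr1", 150, 250)]
    (kept,) = aa.reproducible_peaks(a, b, 0.5, use_intersection=True)
    assert (kept.start, kept.end) == (150, 200)


def test_reproducible_antimonotone_in_threshold():
    rng = np.random.default_rng(2)
    a = [iv("chr1", int(s), int(s) + int(w))
         for s, w in zip(rng.integers(0, 10_000, 60), rng.integers(50, 400, 60))]
    b = [iv("chr1", int(s), int(s) + int(w))
         for s, w in zip(rng.integers(0, 10_000, 60), rng.integers(50, 400, 60))]
    prev = None
    for frac in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
        kept = {(p.start, p.end) for p in aa.reproducible_peaks(a, b, frac)}
        if prev is not None:
            assert kept <= prev
        prev = kept


# ------------------------------------------------------------ merge

def test_merge_hand_examples():
    merged, contrib = aa.merge_standard_peaks(
        {"liver": [iv("chr1", 100, 200)], "lung": [iv("chr1", 150, 250)]}
    )
    assert [(p.chrom, p.start, p.end) for p in merged] == [("chr1", 100, 250)]
    assert contrib == [("liver", "lung")]
    assert merged[0].score == 2.0


def test_merge_idempotent_on_disjoint_set():
    peaks = [iv("chr1", 0, 50), iv("chr1", 100, 150), iv("chr2", 0, 10)]
    merged, _ = aa.merge_standard_peaks([peaks])
    assert [(p.chrom, p.start, p.end) for p in merged] == [
        (p.chrom, p.start, p.end) for p in peaks
    ]


def test_merge_no_cross_chromosome():
    merged, _ = aa.merge_standard_peaks(
        [[iv("chr1", 100, 200)], [iv("chr2", 100, 200)]]
    )
    assert len(merged) == 2


def test_merge_bookended_intervals():
    merged, _ = aa.merge_standard_peaks([[iv("chr1", 0, 100), iv("chr1", 100, 200)]])
    assert [(p.start, p.end) for p in merged] == [(0, 200)]


def test_merge_matches_coverage_oracle_random():
    rng = np.random.default_rng(0)
    for _ in range(120):
        n_sets = int(rng.integers(1, 4))
        sets = []
        for _ in range(n_sets):
            n = int(rng.integers(1, 15))
            starts = rng.integers(0, 500, n)
            widths = rng.integers(1, 80, n)
            chroms = rng.choice(["chr1", "chr2"], n)
            sets.append([iv(c, int(s), int(s + w))
                         for c, s, w in zip(chroms, starts, widths)])
        merged, _ = aa.merge_standard_peaks(sets)
        got = [(p.chrom, p.start, p.end) for p in merged]
        assert got == merge_by_coverage(sets)


# ------------------------------------------------------------ counting

def test_count_containment_and_half_open():
    peaks = [iv("chr1", 100, 200, name="p1")]
    inside = [iv("chr1", 150, 160)]
    bookended = [iv("chr1", 200, 300)]
    assert aa.count_fragments_in_peaks(inside, peaks).tolist() == [1]
    assert aa.count_fragments_in_peaks(bookended, peaks).tolist() == [0]


def test_count_spanning_fragment_hits_both_peaks():
    peaks = [iv("chr1", 100, 200, name="p1"), iv("chr1", 250, 350, name="p2")]
    spanner = [iv("chr1", 190, 260)]
    assert aa.count_fragments_in_peaks(spanner, peaks).tolist() == [1, 1]


def test_count_rejects_overlapping_peaks():
    with pytest.raises(ValidationError, match="overlap"):
        aa.count_fragments_in_peaks(
            [iv("chr1", 0, 10)], [iv("chr1", 100, 200), iv("chr1", 150, 300)]
        )


def test_count_matches_quadratic_oracle_random():
    rng = np.random.default_rng(1)
    for _ in range(30):
        # non-overlapping random peaks on two chromosomes
        peaks = []
        for chrom in ("chr1", "chr2"):
            pos = 0
            for _ in range(int(rng.integers(3, 30))):
                pos += int(rng.integers(1, 300))
                width = int(rng.integers(1, 150))
                peaks.append(iv(chrom, pos, pos + width))
                pos += width
        n = int(rng.integers(1, 2_000))
        starts = rng.integers(0, 6_000, n)
        widths = rng.integers(1, 400, n)
        chroms = rng.choice(["chr1", "chr2", "chr3"], n)
        frags = [iv(c, int(s), int(s + w)) for c, s, w in zip(chroms, starts, widths)]
        got = aa.count_fragments_in_peaks(frags, peaks)
        assert got.tolist() == count_by_all_pairs(frags, peaks).tolist()


# ------------------------------------------------------------ normalization

def test_rpm_definition():
    raw = pd.DataFrame({"s1": [5], "s2": [250]}, index=["p1"])
    rpm = aa.normalize_rpm(raw, {"s1": 1_000_000, "s2": 50_000_000})
    assert rpm.loc["p1", "s1"] == pytest.approx(5.0)
    assert rpm.loc["p1", "s2"] == pytest.approx(5.0)


def test_rpm_doubling_library_halves_values():
    raw = pd.DataFrame({"s1": [3, 7], "s2": [1, 9]}, index=["p1", "p2"])
    sizes = {"s1": 2_000_000, "s2": 5_000_000}
    doubled = {k: 2 * v for k, v in sizes.items()}
    a = aa.normalize_rpm(raw, sizes)
    b = aa.normalize_rpm(raw, doubled)
    assert np.allclose(a.to_numpy(), 2 * b.to_numpy())


def test_rpm_zero_library_rejected():
    raw = pd.DataFrame({"s1": [3]}, index=["p1"])
    with pytest.raises(ValidationError):
        aa.normalize_rpm(raw, {"s1": 0})


def test_log_transform_zero_maps_to_zero():
    rpm = pd.DataFrame({"s1": [0.0, 99.0]}, index=["p1", "p2"])
    log = aa.log_transform(rpm)
    assert log.loc["p1", "s1"] == 0.0
    assert log.loc["p2", "s1"] == pytest.approx(2.0)


def test_counts_matrix_layers_consistent(small_atlas):
    cm = aa.build_counts_matrix(
        small_atlas.fragments, small_atlas.truth.peaks,
        library_sizes={r.sample_id: r.usable_reads for r in small_atlas.records},
    )
    assert cm.raw.shape == (len(small_atlas.truth.peaks), len(small_atlas.records))
    assert (cm.raw.to_numpy() >= 0).all()
    recomputed = cm.raw * 1e6 / cm.library_sizes
    assert np.allclose(cm.rpm.to_numpy(), recomputed.to_numpy())
    assert np.allclose(cm.log_rpm.to_numpy(), np.log10(cm.rpm.to_numpy() + 1))
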