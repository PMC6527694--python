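import numpy as np
import pandas as pd
import pytest

import atacatlas as aa
from atacatlas.io import ValidationError
from atacatlas.simulate import PlacementError


def test_config_validation():
    with pytest.raises(ValidationError, match="sum to 1"):
        aa.SimulationConfig(fragment_length_modes=((200, 20, 0.4), (400, 30, 0.4)))
    with pytest.raises(ValidationError, match="restricted_fold"):
        aa.SimulationConfig(restricted_fold=1.0)
    with pytest.raises(ValidationError, match="background_fraction"):
        aa.SimulationConfig(background_fraction=1.0)


def test_conservation_every_sample_has_exact_fragment_count(small_atlas, small_config):
    for frags in small_atlas.fragments.values():
        assert len(frags) == small_config.fragments_per_sample


def test_determinism_same_seed_identical_output(small_config):
    a = aa.simulate_atlas(small_config)
    b = aa.simulate_atlas(small_config)
    for sid in a.fragments:
        fa, fb = a.fragments[sid], b.fragments[sid]
        assert (fa.starts == fb.starts).all()
        assert (fa.ends == fb.ends).all()
        assert (fa.chrom_codes == fb.chrom_codes).all()
    assert a.truth.labels == b.truth.labels
    assert [len(v) for v in a.peak_calls.values()] == [
        len(v) for v in b.peak_calls.values()
    ]


def test_different_seed_differs(small_config):
    from dataclasses import replace
    a = aa.simulate_atlas(small_config)
    b = aa.simulate_atlas(replace(small_config, seed=small_config.seed + 1))
    sid = next(iter(a.fragments))
    assert not np.array_equal(a.fragments[sid].starts, b.fragments[sid].starts)


def test_truth_peaks_nonoverlapping_and_named(small_atlas):
    peaks = small_atlas.truth.peaks
    by_chrom = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: p.start)
        for a, b in zip(plist, plist[1:]):
            assert a.end <= b.start
    assert len({p.name for p in peaks}) == len(peaks)


def test_restricted_peaks_have_single_home_tissue(small_atlas):
    truth = small_atlas.truth
    assert set(truth.home_tissue) == set(truth.restricted_peaks)
    tissues = set(small_atlas.config.tissues)
    assert set(truth.home_tissue.values()) <= tissues


def test_no_restricted_config_concentrates_entropy():
    cfg = aa.SimulationConfig(
        n_tissues=4, n_chromosomes=2, chromosome_length=2_000_000,
        n_shared_peaks=50, n_restricted_peaks=0, n_tss=40,
        fragments_per_sample=40_000, seed=3,
    )
    atlas = aa.simulate_atlas(cfg)
    assert atlas.truth.restricted_peaks == []
    cm = aa.build_counts_matrix(atlas.fragments, atlas.truth.peaks)
    tm = aa.aggregate_by_tissue(cm.rpm, atlas.records)
    _, h = aa.entropy_scores_matrix(tm)
    assert (h > 0.95 * np.log2(cfg.n_tissues)).mean() > 0.95


def test_placement_error_when_peaks_do_not_fit():
    with pytest.raises(PlacementError, match="longer chromosomes"):
        aa.simulate_atlas(aa.SimulationConfig(
            n_tissues=2, n_chromosomes=1, chromosome_length=50_000,
            n_shared_peaks=200, n_restricted_peaks=0, n_tss=5,
            fragments_per_sample=100, seed=0,
        ))


def test_fragment_length_mixture_modes_recovered():
    cfg = aa.SimulationConfig(
        n_tissues=2, n_chromosomes=1, chromosome_length=4_000_000,
        n_shared_peaks=40, n_restricted_peaks=0, n_tss=30,
        fragments_per_sample=60_000,
        fragment_length_modes=((200, 15, 0.5), (400, 20, 0.5)),
        seed=11,
    )
    atlas = aa.simulate_atlas(cfg)
    frags = next(iter(atlas.fragments.values()))
    profile = aa.fragment_size_profile(frags)
    for target in (200, 400):
        assert np.min(np.abs(profile.modes - target)) <= 10


# ------------------------------------------------------------ expected_counts

def test_expected_counts_symmetry_and_fold(small_atlas):
    truth = small_atlas.truth
    exp = {t: aa.expected_counts(truth, f"{t}_r1", include_background=False)
           for t in small_atlas.config.tissues}
    shared = truth.shared_peaks[0]
    t1, t2 = small_atlas.config.tissues[:2]
    assert exp[t1][shared] == pytest.approx(exp[t2][shared])

    fold = small_atlas.config.restricted_fold
    pid = truth.restricted_peaks[0]
    home = truth.home_tissue[pid]
    other = next(t for t in small_atlas.config.tissues if t != home)
    # every tissue owns the same number of restricted peaks, so total
    # weights match across tissues and the expectation ratio is the fold
    assert exp[home].sum() == pytest.approx(exp[other].sum())
    assert exp[home][pid] / exp[other][pid] == pytest.approx(fold)


def test_expected_counts_conservation(small_atlas, small_config):
    truth = small_atlas.truth
    sid = f"{small_config.tissues[0]}_r1"
    in_peak = truth.expected_assignment[sid].sum()
    off_peak = small_config.fragments_per_sample * (
        small_config.background_fraction + small_config.tss_fraction
    )
    assert in_peak + off_peak == pytest.approx(small_config.fragments_per_sample)


def test_expected_counts_unknown_sample(small_atlas):
    with pytest.raises(KeyError):
        aa.expected_counts(small_atlas.truth, "nope_r1")


@pytest.mark.parametrize("n_frags", [20_000, 200_000])
def test_observed_counts_converge_to_expectation(n_frags):
    """Relative error of observed vs expected counts shrinks with depth
    (dispersion off so the only noise is sampling)."""
    cfg = aa.SimulationConfig(
        n_tissues=2, n_chromosomes=2, chromosome_length=2_000_000,
        n_shared_peaks=40, n_restricted_peaks=10, n_tss=30,
        fragments_per_sample=n_frags, dispersion=0.0, seed=5,
    )
    atlas = aa.simulate_atlas(cfg)
    sid = "tissue_01_r1"
    exp = aa.expected_counts(atlas.truth, sid)
    obs = aa.count_fragments_in_peaks(atlas.fragments[sid], atlas.truth.peaks)
    obs = pd.Series(obs, index=[p.name for p in atlas.truth.peaks])
    rel = float(((obs - exp) / exp).abs().mean())
    # expected sampling error ~ 1/sqrt(mean count); allow 3x slack
    assert rel < 3.0 / np.sqrt(exp.mean())


def test_peak_calls_exercise_dropout(small_atlas, small_config):
    n_true = len(small_atlas.truth.peaks)
    sizes = [len(v) for v in small_atlas.peak_calls.values()]
    assert all(s <= n_true for s in sizes)
    mean_kept = np.mean(sizes) / n_true
    assert mean_kept == pytest.approx(1 - small_config.peak_dropout, abs=0.05)


def test_atlas_write_round_trip(tmp_path, small_atlas):
    small_atlas.write(tmp_path)
    records = aa.read_sample_sheet(tmp_path / "sample_sheet.tsv")
    assert len(records) == len(small_atlas.records)
    sid = records[0].sample_id
    frags = aa.FragmentSet.read_bed(tmp_path / "fragments" / f"{sid}.bed")
    assert len(frags) == len(small_atlas.fragments[sid])
    calls = aa.read_bed(tmp_path / "peak_calls" / f"{sid}.bed")
    assert len(calls) == len(small_atlas.peak_calls[sid])
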