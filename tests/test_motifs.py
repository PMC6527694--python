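import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import atacatlas as aa
from atacatlas.io import ValidationError
from atacatlas.motifs import reverse_complement, sample_background


def hypergeom_tail_oracle(k, m_total, k_total, n_draws):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for j in range(k, min(k_total, n_draws) + 1):
        total += comb(k_total, j) * comb(m_total - k_total, n_draws - j)
    return total / comb(m_total, n_draws)


# ------------------------------------------------------------ matching

def test_motif_model_validation():
    with pytest.raises(ValidationError):
        aa.MotifModel("m", "ACG")            # too short
    with pytest.raises(ValidationError):
        aa.MotifModel("m", "ACGT", max_mismatch=4)
    with pytest.raises(ValidationError):
        aa.MotifModel("m", "ACGZ")


def test_motif_occurs_exact_and_revcomp():
    m = aa.MotifModel("m", "TTGCGCAA")
    assert aa.motif_occurs("AAATTGCGCAATTT", m)
    assert aa.motif_occurs("AAA" + reverse_complement("TTGCGCAA") + "TTT", m)
    assert not aa.motif_occurs("ACGTACGTACGT", m)
    assert not aa.motif_occurs("TTGC", m)  # shorter than the motif


def test_motif_occurs_mismatch_budget_and_iupac():
    m = aa.MotifModel("m", "AAAAAA", max_mismatch=1)
    assert aa.motif_occurs("CCAAAATACC", m)       # one mismatch
    assert not aa.motif_occurs("CCAATATACC", m)   # needs two
    iupac = aa.MotifModel("m", "ARYN")            # R=A/G, Y=C/T
    assert aa.motif_occurs("TTAGCATT", iupac)
    assert aa.motif_occurs("TTAATATT", iupac)


# ------------------------------------------------------------ enrichment

def test_enrichment_matches_closed_form_20_vs_0():
    motif = aa.MotifModel("m", "TTGCGCAA")
    targets = [("A" * 10) + "TTGCGCAA" + ("C" * 10)] * 20
    background = ["ACGTACGTACGTACGTACGTACGTAC"] * 20
    got = aa.motif_enrichment_test(targets, background, motif)
    expected = -math.log10(hypergeom_tail_oracle(20, 40, 20, 20))
    assert got == pytest.approx(expected, rel=1e-9)


def test_enrichment_null_and_absent_motif():
    motif = aa.MotifModel("m", "TTGCGCAA")
    hit = ("A" * 5) + "TTGCGCAA" + ("C" * 5)
    miss = "ACGTACGTACGTACGTAC"
    # equal hit rates: no enrichment signal
    p_null = aa.motif_enrichment_test([hit, miss] * 30, [hit, miss] * 30, motif)
    assert p_null < 1.0
    # motif nowhere: tail probability is 1
    assert aa.motif_enrichment_test([miss] * 10, [miss] * 10, motif) == 0.0


def test_enrichment_motif_longer_than_sequences_rejected():
    motif = aa.MotifModel("m", "ACGTACGTACGT")
    with pytest.raises(ValidationError, match="longer"):
        aa.motif_enrichment_test(["ACGT"], ["ACGT"], motif)


def test_hypergeom_tail_matches_enumeration_all_small_tables():
    from scipy.stats import hypergeom
    for m_total in range(2, 13):
        for k_total in range(m_total + 1):
            for n_draws in range(1, m_total + 1):
                lo = max(0, k_total + n_draws - m_total)
                hi = min(k_total, n_draws)
                for k in range(lo, hi + 1):
                    got = float(hypergeom.sf(k - 1, m_total, k_total, n_draws))
                    want = hypergeom_tail_oracle(k, m_total, k_total, n_draws)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=15))
def test_enrichment_monotone_in_target_hits(k):
    """More target hits at fixed background can only increase -log10 P."""
    from scipy.stats import hypergeom
    n_t, n_b, kb = 15, 15, 3
    if k < 15:
        p1 = float(hypergeom.sf(k - 1, n_t + n_b, k + kb, n_t))
        p2 = float(hypergeom.sf(k, n_t + n_b, k + 1 + kb, n_t))
        assert -math.log10(p2) >= -math.log10(p1) - 1e-12


# ------------------------------------------------------------ selection rule

def _matrix(rows):
    df = pd.DataFrame(rows).T
    df.columns = [f"t{j}" for j in range(df.shape[1])]
    return aa.MotifEnrichmentMatrix.from_table(df)


def test_select_mean_floor_is_strict():
    m = _matrix({
        "just_below": [19.9, 19.9, 19.9],
        "constant": [30.0, 30.0, 30.0],
        "variable": [60.0, 5.0, 10.0],
    })
    chosen = aa.select_display_motifs(m, mean_floor=20.0, top_k=50)
    assert "just_below" not in chosen
    assert chosen[0] == "variable"       # highest CV first
    assert chosen[-1] == "constant"      # CV 0 ranks last


def test_select_undersized_pool_returns_all():
    m = _matrix({f"m{i}": [25.0 + i, 30.0, 40.0] for i in range(10)})
    assert len(aa.select_display_motifs(m, top_k=50)) == 10
    assert len(aa.select_display_motifs(m, top_k=4)) == 4


def test_select_monotone_in_mean_floor():
    rng = np.random.default_rng(5)
    m = _matrix({f"m{i}": list(rng.uniform(0, 80, 4)) for i in range(30)})
    prev = None
    for floor in (0.0, 10.0, 20.0, 40.0, 80.0):
        got = set(aa.select_display_motifs(m, mean_floor=floor, top_k=100))
        if prev is not None:
            assert got <= prev
        prev = got


def test_row_cv_definition():
    df = pd.DataFrame({"t1": [10.0, 0.0], "t2": [30.0, 0.0]},
                      index=["m1", "zero"])
    m = aa.MotifEnrichmentMatrix.from_table(df)
    assert m.row_mean["m1"] == 20.0
    assert m.row_cv["m1"] == pytest.approx(np.std([10, 30], ddof=1) / 20.0)
    assert math.isnan(m.row_cv["zero"])   # undefined at zero mean


# ------------------------------------------------------------ clustering

def test_identical_tissue_columns_merge_at_zero():
    df = pd.DataFrame({"t1": [5.0, 1.0], "t2": [5.0, 1.0], "t3": [0.0, 9.0]},
                      index=["m1", "m2"])
    m = aa.MotifEnrichmentMatrix.from_table(df)
    z, order = aa.cluster_tissues_by_motifs(m)
    assert z[0, 2] == 0.0
    assert set(order) == {"t1", "t2", "t3"}


def test_motif_row_permutation_leaves_distances_unchanged():
    rng = np.random.default_rng(6)
    df = pd.DataFrame(rng.uniform(0, 50, size=(12, 5)),
                      index=[f"m{i}" for i in range(12)],
                      columns=[f"t{j}" for j in range(5)])
    m1 = aa.MotifEnrichmentMatrix.from_table(df)
    m2 = aa.MotifEnrichmentMatrix.from_table(df.iloc[rng.permutation(12)])
    z1, _ = aa.cluster_tissues_by_motifs(m1)
    z2, _ = aa.cluster_tissues_by_motifs(m2)
    assert np.allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]))


def test_planted_motif_pairs_tissues_as_neighbors(small_atlas):
    """A motif planted only in two tissues' restricted peaks should make
    those tissues nearest neighbors in the enrichment clustering."""
    truth = small_atlas.truth
    tissues = small_atlas.config.tissues
    plan = {"CEBP": [tissues[0], tissues[1]], "GATA": [tissues[2]],
            "MEF2": [tissues[3]]}
    seqs = aa.simulate_peak_sequences(truth.peaks, truth.home_tissue,
                                      motif_plan=plan, seed=9)
    targets = {}
    for pid, tissue in truth.home_tissue.items():
        targets.setdefault(tissue, []).append(seqs[pid])
    background = sample_background(
        {pid: seqs[pid] for pid in truth.shared_peaks}, n=30, seed=9)
    models = [aa.MotifModel(mid, cons, mm)
              for mid, cons, mm in aa.simulate.DEFAULT_MOTIFS
              if mid in plan]
    enrich = aa.build_enrichment_matrix(targets, background, models)
    z, order = aa.cluster_tissues_by_motifs(enrich)
    pos = {t: order.index(t) for t in tissues}
    assert abs(pos[tissues[0]] - pos[tissues[1]]) == 1


# ------------------------------------------------------------ IO

def test_read_motif_table(tmp_path):
    path = tmp_path / "motifs.tsv"
    path.write_text("# library\nCEBP\tTTGCGCAAT\t1\nGATA\tAGATAAGA\n")
    models = aa.read_motifs(path)
    assert [m.motif_id for m in models] == ["CEBP", "GATA"]
    assert models[0].max_mismatch == 1 and models[1].max_mismatch == 0
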