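"""Motif x tissue enrichment matrix and its display-selection rule.

The scan is a deliberately simple consensus matcher: a sequence is a hit
when the motif (or its reverse complement) occurs with at most the allowed
number of mismatches, and enrichment of hits in a tissue's restricted-peak
sequences over a background set is scored with a one-sided hypergeometric
tail, reported as -log10 P. The matrix stage also accepts a precomputed
-log10 P table from an external scanner, so the selection rule — keep
motifs with row mean strictly above 20 and display the 50 with the highest
coefficient of variation — and the tissue clustering are usable on real
motif-discovery output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import ParseError, ValidationError
from .reproducibility import hierarchical_cluster

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASES = "ACGTN"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


def reverse_complement(consensus: str) -> str:
    return consensus.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A consensus motif over the IUPAC alphabet with a mismatch budget."""

    motif_id: str
    consensus: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if len(cons) < 4:
            raise ValidationError(f"{self.motif_id}: consensus shorter than 4")
        if not self.max_mismatch < len(cons):
            raise ValidationError(f"{self.motif_id}: mismatch budget >= length")
        bad = set(cons) - set(IUPAC_SETS)
        if bad:
            raise ValidationError(f"{self.motif_id}: non-IUPAC symbols {bad}")
        object.__setattr__(self, "consensus", cons)


def _allowed_table(consensus: str) -> np.ndarray:
    """(motif_len x 5) boolean: does sequence base b satisfy position k?
    An ``N`` in the *sequence* only satisfies an ``N`` in the consensus."""
    table = np.zeros((len(consensus), len(_BASES)), dtype=bool)
    for k, sym in enumerate(consensus):
        for base in IUPAC_SETS[sym]:
            table[k, _BASE_CODE[base]] = True
        if sym == "N":
            table[k, _BASE_CODE["N"]] = True
    return table


def _scan_one(codes: np.ndarray, table: np.ndarray, max_mismatch: int) -> bool:
    m = table.shape[0]
    n_win = len(codes) - m + 1
    if n_win <= 0:
        return False
    mismatches = np.zeros(n_win, dtype=np.int16)
    for k in range(m):
        mismatches += ~table[k, codes[k : k + n_win]]
        # early exit when every window is already over budget
        if mismatches.min() > max_mismatch:
            return False
    return bool((mismatches <= max_mismatch).any())


def motif_occurs(sequence: str, motif: MotifModel) -> bool:
    """Does the motif (either strand) occur with <= max_mismatch mismatches?"""
    seq = sequence.upper()
    codes = np.fromiter(
        (_BASE_CODE.get(b, _BASE_CODE["N"]) for b in seq),
        dtype=np.int8, count=len(seq),
    )
    if _scan_one(codes, _allowed_table(motif.consensus), motif.max_mismatch):
        return True
    rc = reverse_complement(motif.consensus)
    if rc == motif.consensus:
        return False
    return _scan_one(codes, _allowed_table(rc), motif.max_mismatch)


def count_hits(sequences: Sequence[str] | Mapping[str, str],
               motif: MotifModel) -> int:
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    return sum(motif_occurs(s, motif) for s in seqs)


def motif_enrichment_test(
    target_seqs: Sequence[str] | Mapping[str, str],
    background_seqs: Sequence[str] | Mapping[str, str],
    motif: MotifModel,
    cap: float = 300.0,
) -> float:
    """-log10 one-sided hypergeometric enrichment P of motif hits.

    With ``n_t`` targets of which ``k`` hit, and ``K`` hits among all
    ``M = n_t + n_b`` sequences, P is the probability of >= k target hits
    when K hits are distributed at random — ``hypergeom.sf(k-1, M, K, n_t)``.
    Values are capped at ``cap`` to avoid -log10(0).
    """
    targets = list(target_seqs.values()) if isinstance(target_seqs, Mapping) else list(target_seqs)
    background = (list(background_seqs.values())
                  if isinstance(background_seqs, Mapping) else list(background_seqs))
    if not targets or not background:
        raise ValidationError("target and background sets must be non-empty")
    if all(len(s) < len(motif.consensus) for s in targets + background):
        raise ValidationError(
            f"motif {motif.motif_id} is longer than every sequence"
        )
    k = count_hits(targets, motif)
    kb = count_hits(background, motif)
    m_total = len(targets) + len(background)
    p = float(hypergeom.sf(k - 1, m_total, k + kb, len(targets)))
    if p <= 0:
        return cap
    return float(min(max(-np.log10(p), 0.0), cap))


@dataclass
class MotifEnrichmentMatrix:
    """Motif x tissue matrix of -log10 enrichment P with row summaries.

    ``row_cv`` (sample standard deviation / mean of each -log10 P row) is
    defined only for rows with positive mean; others are NaN.
    """

    neglog10_p: pd.DataFrame
    row_mean: pd.Series
    row_cv: pd.Series

    @classmethod
    def from_table(cls, table: pd.DataFrame | str | Path) -> "MotifEnrichmentMatrix":
        if not isinstance(table, pd.DataFrame):
            from .io import read_matrix
            table = read_matrix(table)
        values = table.astype(float)
        if (values.to_numpy() < 0).any():
            raise ValidationError("-log10 P values must be non-negative")
        mean = values.mean(axis=1)
        sd = values.std(axis=1, ddof=1)
        cv = sd / mean.where(mean > 0)
        return cls(neglog10_p=values, row_mean=mean, row_cv=cv)

    @property
    def motifs(self) -> list[str]:
        return list(self.neglog10_p.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.neglog10_p.columns)


def build_enrichment_matrix(
    target_sets: Mapping[str, Sequence[str] | Mapping[str, str]],
    background_seqs: Sequence[str] | Mapping[str, str],
    motifs: Sequence[MotifModel],
    cap: float = 300.0,
) -> MotifEnrichmentMatrix:
    """Run the enrichment test for every motif against every tissue's
    restricted-peak sequences, with a common background set."""
    if not target_sets:
        raise ValidationError("no target sequence sets")
    data = {
        tissue: [motif_enrichment_test(seqs, background_seqs, m, cap) for m in motifs]
        for tissue, seqs in target_sets.items()
    }
    table = pd.DataFrame(data, index=[m.motif_id for m in motifs])
    return MotifEnrichmentMatrix.from_table(table)


def sample_background(sequences: Mapping[str, str], n: int,
                      seed: int = 0) -> dict[str, str]:
    """Deterministically downsample a background pool to ``n`` sequences."""
    names = sorted(sequences)
    if n >= len(names):
        return {k: sequences[k] for k in names}
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(names), size=n, replace=False)
    return {names[i]: sequences[names[i]] for i in sorted(chosen)}


def select_display_motifs(
    matrix: MotifEnrichmentMatrix,
    mean_floor: float = 20.0,
    top_k: int = 50,
) -> list[str]:
    """The display-selection rule: motifs whose row mean is strictly above
    ``mean_floor``, ranked by coefficient of variation (descending, ties
    broken by motif id), truncated to ``top_k``."""
    survivors = matrix.row_mean.index[matrix.row_mean > mean_floor]
    cv = matrix.row_cv.loc[survivors].fillna(0.0)
    ranked = sorted(survivors, key=lambda mid: (-cv[mid], mid))
    return ranked[:top_k]


def cluster_tissues_by_motifs(
    matrix: MotifEnrichmentMatrix,
    selected_motifs: Sequence[str] | None = None,
    linkage_method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchically cluster tissues (Euclidean distance, over the selected
    motifs' -log10 P columns). Returns the merge tree and tissue order."""
    sub = matrix.neglog10_p
    if selected_motifs is not None:
        sub = sub.loc[list(selected_motifs)]
    return hierarchical_cluster(sub, linkage_method=linkage_method)


def read_motifs(path: str | Path) -> list[MotifModel]:
    """Read a motif table: tab-separated ``motif_id  consensus  max_mismatch``
    (mismatch column optional, default 0; ``#`` comments skipped)."""
    models: list[MotifModel] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 fields")
            mm = int(fields[2]) if len(fields) > 2 else 0
            models.append(MotifModel(fields[0], fields[1], mm))
    if len({m.motif_id for m in models}) != len(models):
        raise ValidationError("duplicate motif ids")
    return models
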