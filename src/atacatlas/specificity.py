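"""Shannon-entropy tissue-specificity scoring of consensus peaks.

For each peak, the relative accessibility in tissue *i* is
``Ri = Ei / sum(E)`` where ``Ei`` is the peak's RPM in tissue *i*
(replicate-averaged). The specificity index is the entropy
``H = -sum(Ri * log2 Ri)`` in bits, ranging from 0 (perfectly
tissue-specific) to ``log2(N)`` (uniform across all N tissues). Peaks with
``H`` strictly below a threshold — 3.5 bits for a 20-tissue panel — are
classified as tissue-restricted and assigned to their argmax tissue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, SampleRecord, ValidationError

#: The reference threshold (bits) and the panel size it was chosen for.
DEFAULT_THRESHOLD = 3.5
REFERENCE_N_TISSUES = 20


def aggregate_by_tissue(
    rpm: pd.DataFrame,
    sample_sheet: Sequence[SampleRecord],
    mode: Literal["tissue", "tissue_sex"] = "tissue",
    stat: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Collapse the peak x sample RPM matrix to peak x tissue ``Ei`` values.

    ``mode="tissue"`` pools replicates and sexes per tissue label (the
    default, so N matches the number of tissue types); ``"tissue_sex"``
    keeps each tissue-sex combination as its own group. Aggregation is the
    arithmetic mean of RPM by default.
    """
    by_id = {r.sample_id: r for r in sample_sheet}
    groups: dict[str, list[str]] = {}
    for col in rpm.columns:
        if col not in by_id:
            raise ValidationError(f"sample {col!r} missing from the sample sheet")
        rec = by_id[col]
        key = rec.tissue if mode == "tissue" else f"{rec.tissue}|{rec.gender}"
        groups.setdefault(key, []).append(col)
    agg = {}
    for key in sorted(groups):
        block = rpm[groups[key]]
        agg[key] = block.mean(axis=1) if stat == "mean" else block.median(axis=1)
    return pd.DataFrame(agg, index=rpm.index)


def entropy_score(tissue_values: Sequence[float] | np.ndarray | pd.Series
                  ) -> tuple[np.ndarray, float]:
    """Relative accessibilities and entropy of one peak's tissue vector.

    Returns ``(Ri, H)`` with the convention ``0 * log2(0) = 0``. If the
    vector sums to zero the entropy is undefined: returns NaNs with a
    warning. Negative accessibilities are rejected.
    """
    values = np.asarray(tissue_values, dtype=float)
    if (values < 0).any():
        raise ValidationError("accessibilities must be non-negative")
    total = values.sum()
    if total == 0:
        warnings.warn("all-zero accessibility vector: entropy undefined",
                      stacklevel=2)
        return np.full_like(values, np.nan), float("nan")
    r = values / total
    nz = r > 0
    h = float(-(r[nz] * np.log2(r[nz])).sum())
    return r, h


def entropy_scores_matrix(tissue_matrix: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Vectorized :func:`entropy_score` over a peak x tissue matrix.

    Rows summing to zero get NaN entropy (and NaN Ri) rather than a warning
    per row; callers should report them separately.
    """
    values = tissue_matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("accessibilities must be non-negative")
    totals = values.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = values / totals[:, None]
        term = np.where(r > 0, r * np.log2(np.where(r > 0, r, 1.0)), 0.0)
        h = -term.sum(axis=1)
    h[totals == 0] = np.nan
    r[totals == 0] = np.nan
    return (
        pd.DataFrame(r, index=tissue_matrix.index, columns=tissue_matrix.columns),
        pd.Series(h, index=tissue_matrix.index, name="entropy"),
    )


def default_threshold(n_tissues: int) -> float:
    """Rescale the reference 3.5-bit cutoff to a panel of ``n_tissues``.

    3.5 bits is meaningful relative to the 20-tissue maximum of
    ``log2(20) ~ 4.32``; for other panel sizes the cutoff keeps the same
    fraction of the entropy range.
    """
    if n_tissues < 2:
        raise ValidationError("need at least 2 tissues")
    if n_tissues == REFERENCE_N_TISSUES:
        return DEFAULT_THRESHOLD
    return DEFAULT_THRESHOLD / math.log2(REFERENCE_N_TISSUES) * math.log2(n_tissues)


def classify_restricted(h: float, threshold: float = DEFAULT_THRESHOLD) -> bool | None:
    """True iff ``h`` is strictly below the threshold; None for undefined H."""
    if h is None or (isinstance(h, float) and math.isnan(h)):
        return None
    return bool(h < threshold)


def assign_tissue(ri: pd.Series | Sequence[float],
                  tissues: Sequence[str] | None = None) -> str:
    """Argmax tissue of a relative-accessibility vector.

    Exact ties break to the lexicographically first tissue label, with a
    warning. All-zero vectors are rejected.
    """
    if isinstance(ri, pd.Series):
        values = ri.to_numpy(dtype=float)
        labels = list(ri.index)
    else:
        values = np.asarray(ri, dtype=float)
        if tissues is None:
            raise ValidationError("tissue labels required for a bare vector")
        labels = list(tissues)
    if values.sum() == 0 or np.isnan(values).all():
        raise ValidationError("cannot assign a tissue to an all-zero vector")
    top = values.max()
    winners = sorted(labels[i] for i in np.flatnonzero(values == top))
    if len(winners) > 1:
        warnings.warn(
            f"tie between {winners}; assigning {winners[0]!r}", stacklevel=2
        )
    return winners[0]


@dataclass
class SpecificityResult:
    """Per-peak specificity call."""

    peak_id: str
    tissue_values: pd.Series   # Ei per tissue (RPM, replicate-aggregated)
    relative: pd.Series        # Ri per tissue
    entropy: float             # H in bits (NaN when sum(E) == 0)
    n_tissues: int
    restricted: bool | None
    assigned_tissue: str | None


def specificity_table(
    tissue_matrix: pd.DataFrame,
    threshold: float | None = None,
    peaks: Sequence[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Score every consensus peak and build the specificity output table.

    ``threshold=None`` uses :func:`default_threshold` for the panel size.
    Columns: coordinates (when ``peaks`` given), entropy, restricted flag,
    assigned tissue (restricted peaks only), and per-tissue Ri. Peaks whose
    accessibilities sum to zero get NaN entropy and are excluded from
    classification (restricted is NA).
    """
    n = tissue_matrix.shape[1]
    if threshold is None:
        threshold = default_threshold(n)
    r, h = entropy_scores_matrix(tissue_matrix)
    restricted = pd.Series(
        [classify_restricted(v, threshold) for v in h],
        index=h.index, dtype=object,
    )
    assigned = []
    for peak_id in tissue_matrix.index:
        if restricted[peak_id]:
            assigned.append(assign_tissue(r.loc[peak_id]))
        else:
            assigned.append(None)
    table = pd.DataFrame({"entropy": h, "restricted": restricted,
                          "assigned_tissue": assigned})
    if peaks is not None:
        coords = {p.name: p for p in peaks}
        table.insert(0, "chrom", [coords[i].chrom for i in table.index])
        table.insert(1, "start", [coords[i].start for i in table.index])
        table.insert(2, "end", [coords[i].end for i in table.index])
    for tissue in tissue_matrix.columns:
        table[f"Ri_{tissue}"] = r[tissue]
    table.index.name = "peak_id"
    return table


def write_specificity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA")


def entropy_distribution(
    entropies: pd.Series | Sequence[float],
    bin_width: float = 0.1,
    n_tissues: int | None = None,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of entropy scores over ``[0, log2 N]``.

    Returns ``(counts, bin_edges, restricted_fraction)`` where the fraction
    is taken over peaks with defined entropy. NaN entropies are dropped.
    """
    h = np.asarray(entropies, dtype=float)
    h = h[~np.isnan(h)]
    if len(h) == 0:
        raise ValidationError("no defined entropy values")
    if n_tissues is None:
        top = max(float(h.max()), bin_width)
    else:
        top = math.log2(n_tissues)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, top)
    counts, edges = np.histogram(h, bins=edges)
    if threshold is None:
        threshold = default_threshold(n_tissues) if n_tissues else DEFAULT_THRESHOLD
    restricted_fraction = float((h < threshold).mean())
    return counts, edges, restricted_fraction


def otsu_threshold(entropies: pd.Series | Sequence[float],
                   n_bins: int = 256) -> float:
    """Data-driven entropy cutoff separating a bimodal score distribution.

    Otsu's criterion: the threshold maximizing between-class variance of
    the entropy histogram. Useful when the restricted fold-change regime
    differs from the panel the reference cutoff was chosen for.
    """
    h = np.asarray(entropies, dtype=float)
    h = h[~np.isnan(h)]
    if len(h) < 2 or h.min() == h.max():
        raise ValidationError("need a spread of entropy values")
    counts, edges = np.histogram(h, bins=n_bins)
    mids = (edges[:-1] + edges[1:]) / 2
    weights = counts / counts.sum()
    w0 = np.cumsum(weights)
    mu = np.cumsum(weights * mids)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    between[~np.isfinite(between)] = -1.0
    return float(mids[int(np.argmax(between))])
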