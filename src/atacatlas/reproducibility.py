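"""Replicate and cross-tissue agreement.

Pearson correlation of log10 RPM profiles between samples, and hierarchical
clustering (for heatmap ordering of correlation or motif-enrichment
matrices). Strong within-tissue replicate correlation against weaker
between-tissue correlation is the expected signature of a sound atlas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import SampleRecord, ValidationError


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Requires equal length >= 3. Zero variance in either vector makes the
    coefficient undefined: returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with a display ordering from clustering."""

    labels: list[str]
    values: pd.DataFrame
    linkage: np.ndarray | None
    leaf_order: list[str] | None

    def reordered(self) -> pd.DataFrame:
        if self.leaf_order is None:
            return self.values
        return self.values.loc[self.leaf_order, self.leaf_order]


def correlation_matrix(
    log_rpm: pd.DataFrame,
    linkage_method: Literal["average", "complete", "single"] = "average",
) -> CorrelationMatrix:
    """All pairwise Pearson coefficients between sample columns.

    Computed over consensus-peak rows of the log10 RPM layer. Constant
    columns yield NaN rows/columns (flagged with a warning) and are placed
    last in the display order; clustering runs on the remaining samples.
    """
    if log_rpm.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    labels = list(log_rpm.columns)
    values = log_rpm.to_numpy(dtype=float)
    constant = np.ptp(values, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant columns {list(np.array(labels)[constant])}: "
            "correlations undefined", stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=labels, columns=labels)

    ok = [lab for lab, c in zip(labels, constant) if not c]
    z = None
    order = labels
    if len(ok) >= 2:
        z, ordered = hierarchical_cluster(df.loc[ok, ok], linkage_method=linkage_method)
        order = ordered + [lab for lab in labels if lab not in ok]
    return CorrelationMatrix(labels=labels, values=df, linkage=z, leaf_order=order)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: Literal["euclidean"] = "euclidean",
    linkage_method: Literal["average", "complete", "single"] = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the *columns* of a feature x item matrix.

    Euclidean distances between item columns, merged with the requested
    linkage. Returns the SciPy merge tree and the leaf order for heatmap
    display. Missing values are rejected (impute before clustering).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 items to cluster")
    data = matrix.to_numpy(dtype=float).T
    if np.isnan(data).any():
        raise ValidationError("matrix contains missing values; impute first")
    dist = pdist(data, metric=metric)
    z = linkage(dist, method=linkage_method)
    order = [matrix.columns[i] for i in leaves_list(z)]
    return z, list(order)


def replicate_correlation_summary(
    corr: CorrelationMatrix, sample_sheet: Sequence[SampleRecord]
) -> dict[str, float]:
    """Mean within-tissue vs between-tissue correlation.

    Within-tissue pairs are samples sharing a tissue label (replicates and
    both sexes); all other pairs are between-tissue.
    """
    tissue = {r.sample_id: r.tissue for r in sample_sheet}
    within: list[float] = []
    between: list[float] = []
    labels = corr.labels
    vals = corr.values.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            v = vals[i, j]
            if np.isnan(v):
                continue
            if tissue.get(labels[i]) == tissue.get(labels[j]):
                within.append(v)
            else:
                between.append(v)
    return {
        "mean_within_tissue": float(np.mean(within)) if within else float("nan"),
        "mean_between_tissue": float(np.mean(between)) if between else float("nan"),
        "n_within_pairs": float(len(within)),
        "n_between_pairs": float(len(between)),
    }
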