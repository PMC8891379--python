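"""Correlation-distance heat-map clustering of congeners across products.

Variables (the 16 congeners plus the Total and PAH4 scores) are
clustered on their group-mean profiles across product types using the
Pearson correlation distance ``d = 1 - r`` and average linkage (UPGMA),
the settings of the ClustVis-style heat map the study describes.  Rows
are standardized to zero mean / unit variance by default; congeners that
are non-detects in every group have constant (half-LOD) profiles, carry
no correlation signal, and are dropped with a warning before clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import ValidationError
from .summary import GroupSummaryTable

__all__ = [
    "feature_matrix",
    "pearson_distance",
    "Dendrogram",
    "average_linkage",
    "cut_clusters",
    "plot_heatmap",
]


def feature_matrix(
    summary: GroupSummaryTable,
    standardize: bool = True,
    drop_constant: bool = True,
) -> pd.DataFrame:
    """Variables x product-types matrix of group means.

    ``standardize`` scales each row to mean 0, unit variance (ddof=1).
    Constant rows are dropped (with a warning) when ``drop_constant``;
    otherwise they raise downstream in :func:`pearson_distance`.
    """
    mat = summary.means.T  # rows: congeners + Total + PAH4; cols: product types
    if drop_constant:
        const = mat.std(axis=1, ddof=1) <= 1e-12
        if const.any():
            warnings.warn(
                f"dropping constant (all non-detect) rows: {list(mat.index[const])}"
            )
            mat = mat.loc[~const]
    if standardize:
        mat = mat.sub(mat.mean(axis=1), axis=0).div(mat.std(axis=1, ddof=1), axis=0)
    return mat


def pearson_distance(matrix: pd.DataFrame, axis: int = 0) -> pd.DataFrame:
    """Pairwise ``1 - Pearson r`` distances between rows (axis=0) or columns.

    Symmetric with zero diagonal, values in [0, 2]; a zero-variance
    vector has no defined correlation and raises, naming the offender.
    """
    X = matrix if axis == 0 else matrix.T
    if X.shape[1] < 2:
        raise ValidationError("need >= 2 observations per vector")
    sd = X.std(axis=1, ddof=1)
    bad = list(X.index[sd <= 1e-12])
    if bad:
        raise ValidationError(f"zero-variance vectors: {bad}")
    r = np.corrcoef(X.to_numpy())
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away float noise
    return pd.DataFrame(d, index=X.index, columns=X.index)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree in scipy linkage form plus leaf labels."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]


def average_linkage(d: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage (UPGMA) tree over a distance matrix.

    Merge heights are non-decreasing (UPGMA distances are monotone under
    the Lance-Williams update).
    """
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    Z = hierarchy.linkage(squareform(arr, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=tuple(str(i) for i in d.index))


def cut_clusters(dendro: Dendrogram, k: int) -> dict[str, int]:
    """Assign the leaves to ``k`` flat clusters by cutting the tree."""
    n = len(dendro.labels)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    assignment = hierarchy.fcluster(dendro.linkage, t=k, criterion="maxclust")
    return {lab: int(c) for lab, c in zip(dendro.labels, assignment)}


def plot_heatmap(
    matrix: pd.DataFrame,
    row_dendro: Dendrogram,
    path: str,
    col_dendro: Dendrogram | None = None,
) -> None:
    """Render the clustered heat map (rows reordered by the dendrogram)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = row_dendro.leaf_order
    cols = col_dendro.leaf_order if col_dendro is not None else list(matrix.columns)
    data = matrix.loc[rows, cols]
    fig, ax = plt.subplots(figsize=(0.6 * len(cols) + 3, 0.3 * len(rows) + 2))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(rows)), rows, fontsize=7)
    ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right", fontsize=7)
    fig.colorbar(im, ax=ax, label="standardized group mean")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
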