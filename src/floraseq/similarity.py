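"""Sample-level QC: Pearson correlation and hierarchical clustering.

The heatmap/clustering view keeps genes with FPKM above 100 in at least one
sample, takes Manhattan (L1) distances of log10-transformed FPKM, clusters
genes with the group-average (UPGMA) method and samples with Ward's method,
and colors by per-gene z-scores (uncorrected SD).  Correlation is computed on
raw FPKM over all genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ComputationError, ContractError
from .expression import ExpressionMatrix

_METHOD_MAP = {"group_average": "average", "ward": "ward"}


@dataclass(frozen=True)
class LinkageResult:
    """Agglomerative clustering output.

    ``linkage`` is the (n-1) x 4 scipy linkage matrix; ``merge_heights`` its
    third column; ``leaf_order`` the dendrogram leaf permutation as labels.
    """

    linkage: np.ndarray
    labels: list[str]
    method: str
    metric: str = "manhattan"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Nested-parenthesis tree text with branch lengths from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = (h - height[a]) / 2.0
            lb = (h - height[b]) / 2.0
            node[n + idx] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + idx] = h
        return node[n + len(self.linkage) - 1] + ";"


def pearson_matrix(em: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples over all genes (raw FPKM)."""
    values = em.values.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ContractError("need at least 2 samples for a correlation matrix")
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = em.values.columns[int(np.flatnonzero(sd == 0)[0])]
        raise ComputationError(f"sample {bad!r} has zero variance")
    corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=em.values.columns, columns=em.values.columns)


def manhattan_log_distance(t: pd.DataFrame, axis: str = "samples") -> pd.DataFrame:
    """Pairwise L1 distances of an already log-transformed matrix, between
    rows (``genes``) or columns (``samples``)."""
    if axis == "genes":
        data, labels = t.to_numpy(dtype=float), t.index
    elif axis == "samples":
        data, labels = t.to_numpy(dtype=float).T, t.columns
    else:
        raise ContractError(f"axis must be 'genes' or 'samples', got {axis!r}")
    d = squareform(pdist(data, metric="cityblock"))
    return pd.DataFrame(d, index=labels, columns=labels)


def hcluster(d: pd.DataFrame, method: str = "group_average") -> LinkageResult:
    """Agglomerative clustering of a precomputed symmetric distance matrix with
    group-average (UPGMA) or Ward linkage."""
    if method not in _METHOD_MAP:
        raise ContractError(f"method must be one of {sorted(_METHOD_MAP)}, got {method!r}")
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ContractError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12) or not np.allclose(np.diag(arr), 0.0):
        raise ContractError("distance matrix must be symmetric with zero diagonal")
    labels = [str(x) for x in (d.index if isinstance(d, pd.DataFrame) else range(arr.shape[0]))]
    condensed = squareform(arr, checks=False)
    with warnings.catch_warnings():
        # Ward is applied to the given (Manhattan) distances by design, as R's
        # hclust does; scipy warns that it assumes Euclidean input.
        warnings.simplefilter("ignore", category=UserWarning)
        z = hierarchy.linkage(condensed, method=_METHOD_MAP[method])
    return LinkageResult(linkage=z, labels=labels, method=method)


def normalize_for_heatmap(t: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (row) centering and scaling to unit uncorrected SD; constant
    rows map to all-zeros."""
    arr = t.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ContractError("need at least 2 samples per gene row")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # ddof=0: uncorrected
    out = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=t.index, columns=t.columns)
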