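"""Exposome correlation structure: Spearman matrix, hierarchical clustering,
and Calinski-Harabasz selection of the number of exposure categories.

Exposures are clustered on the sign-blind distance 1 - |rho| (inversely
related exposures, e.g. vegetation cover and air pollution, belong
together), with average linkage.  The CH criterion needs a coordinate
embedding; each exposure is represented by its row of the correlation
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import calinski_harabasz_score

from .containers import ExposureSet

__all__ = ["ExposureClustering", "spearman_matrix", "cluster_exposures"]


@dataclass
class ExposureClustering:
    """Result of hierarchical exposure clustering with CH-based k selection."""

    correlation: pd.DataFrame
    linkage_tree: np.ndarray
    k: int
    labels: np.ndarray
    ch_by_k: dict[int, float] = field(default_factory=dict)
    reliable: bool = True
    tied: bool = False


def spearman_matrix(exposures: ExposureSet | pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations among exposures.

    Requires >= 3 complete observation pairs for every exposure pair.
    """
    values = exposures.values if isinstance(exposures, ExposureSet) else exposures
    if values.shape[1] < 2:
        raise ValueError("need >= 2 exposures")
    if values.shape[0] < 3:
        raise ValueError("need >= 3 participants")
    notna = values.notna().to_numpy().astype(int)
    pair_counts = notna.T @ notna
    off = pair_counts[~np.eye(len(pair_counts), dtype=bool)]
    if (off < 3).any():
        i, j = np.argwhere((pair_counts < 3) & ~np.eye(len(pair_counts), dtype=bool))[0]
        raise ValueError(
            f"exposures {values.columns[i]!r} and {values.columns[j]!r} share "
            "fewer than 3 complete observations"
        )
    corr = values.corr(method="spearman")
    # enforce exact symmetry / unit diagonal against float noise
    arr = corr.to_numpy()
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)


def cluster_exposures(
    corr: pd.DataFrame,
    k_range: tuple[int, int] | None = None,
    method: str = "average",
    distance: str = "one-minus-abs",
) -> ExposureClustering:
    """Agglomerative clustering of exposures with CH-selected cluster count.

    For each candidate k the Calinski-Harabasz index
    ``CH(k) = [B/(k-1)] / [W/(n-k)]`` (B, W between/within dispersion sums
    on the correlation-row embedding) is computed; the k with maximal CH
    wins, ties broken toward the smallest k and flagged.  A flat CH profile
    (no pronounced optimum) marks the clustering unreliable.
    """
    arr = corr.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    m = arr.shape[0]
    if k_range is None:
        k_range = (2, max(2, min(m - 1, 10)))
    k_lo, k_hi = k_range
    if not (2 <= k_lo <= k_hi <= m - 1):
        raise ValueError("k_range must lie within [2, n_exposures - 1]")
    if distance == "one-minus-abs":
        dist = 1.0 - np.abs(arr)
    elif distance == "one-minus-rho":
        dist = 1.0 - arr
    else:
        raise ValueError(f"unknown distance {distance!r}")
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dist, checks=False), method=method)

    features = arr  # rows of the correlation matrix as coordinates
    ch_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        lab = fcluster(tree, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) != k:
            # tied merge heights: the tree cannot realize this k
            ch_by_k[k] = np.nan
            continue
        ch_by_k[k] = float(calinski_harabasz_score(features, lab))

    finite = {k: v for k, v in ch_by_k.items() if np.isfinite(v)}
    if not finite:
        # fully degenerate structure (e.g. all pairwise correlations equal):
        # fall back to the smallest k, flagged unreliable
        return ExposureClustering(
            correlation=corr,
            linkage_tree=tree,
            k=k_lo,
            labels=labels_by_k[k_lo],
            ch_by_k=ch_by_k,
            reliable=False,
            tied=True,
        )
    best_ch = max(finite.values())
    best_k = min(k for k, v in finite.items() if v >= best_ch * (1 - 1e-12))
    tied = sum(np.isclose(v, best_ch, rtol=1e-9) for v in finite.values()) > 1
    others = [v for k, v in finite.items() if k != best_k]
    reliable = bool(others) and best_ch > 1.2 * max(others) and not tied
    if len(finite) == 1:
        reliable = True
    return ExposureClustering(
        correlation=corr,
        linkage_tree=tree,
        k=best_k,
        labels=labels_by_k[best_k],
        ch_by_k=ch_by_k,
        reliable=reliable,
        tied=tied,
    )
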