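"""Hierarchical clustering of DE-gene expression profiles.

DE genes are clustered by their pattern across the populations: each
gene's profile (its gene-by-population effects) is standardized to zero
mean and unit SD across populations, then clustered by Ward-linkage
agglomeration on Euclidean distances and the dendrogram cut to 2**n_levels
clusters (three levels of binary splitting give the 8 pattern groups of a
standard DE heatmap). Determinism: genes are processed in lexicographic id
order, so ties in the merge sequence break reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ClusterAssignment", "cluster_de_profiles"]

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene id -> cluster label in 1..n_clusters
    linkage: np.ndarray  # scipy linkage matrix (merge heights + counts)
    standardized_profiles: pd.DataFrame
    leaf_order: list[str]  # dendrogram leaf order, for heatmap output

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    centered = profiles.sub(profiles.mean(axis=1), axis=0)
    sd = centered.std(axis=1, ddof=0)
    flat = sd == 0.0
    if flat.any():
        log.warning(
            "%d gene(s) have constant profiles; left unstandardized", int(flat.sum())
        )
    sd = sd.mask(flat, 1.0)
    return centered.div(sd, axis=0)


def cluster_de_profiles(effects: pd.DataFrame, n_levels: int = 3) -> ClusterAssignment:
    """Ward-linkage clustering of standardized profiles, cut to 2**n_levels.

    ``effects`` holds one row per DE gene and one column per population.
    Cluster labels are 1..2**n_levels, numbered by dendrogram leaf order so
    repeated runs agree exactly; cutting at successive levels yields nested
    partitions.
    """
    if n_levels < 0:
        raise ValueError("n_levels must be >= 0")
    k = 2**n_levels
    if effects.shape[0] < k:
        raise ValueError(
            f"cannot form {k} clusters from {effects.shape[0]} genes"
        )
    effects = effects.sort_index()
    prof = _standardize(effects)
    Z = hierarchy.linkage(prof.to_numpy(), method="ward", metric="euclidean")
    flat = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    order = hierarchy.leaves_list(Z)
    leaf_order = [prof.index[i] for i in order]
    # relabel 1..k in leaf order
    relabel: dict[int, int] = {}
    for i in order:
        relabel.setdefault(int(flat[i]), len(relabel) + 1)
    labels = pd.Series([relabel[int(c)] for c in flat], index=prof.index, name="cluster")
    return ClusterAssignment(
        labels=labels,
        linkage=Z,
        standardized_profiles=prof,
        leaf_order=leaf_order,
    )
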