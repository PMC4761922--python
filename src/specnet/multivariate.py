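"""Sample-level PCA and Pearson-correlation hierarchical clustering of rows."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io_tables import TableValidationError
from .quant import NormalizedTable

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame                 # samples x components (PC1, PC2, ...)
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # proteins x components
    n_dropped: int                       # zero-variance proteins removed


@dataclass
class Dendrogram:
    linkage: np.ndarray                  # scipy linkage matrix (average linkage)
    labels: list[str]
    dropped: list[str]                   # zero-variance rows excluded

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return walk(tree) + ";"


def pca_samples(norm: NormalizedTable, scale: bool = False) -> PcaResult:
    """PCA of samples on centered (optionally z-scaled) normalized spectra.

    Zero-variance proteins are dropped with a logged count.  Signs are fixed
    so the loading of largest magnitude on each component is positive.
    """
    values = norm.values
    if values.shape[1] < 2:
        raise TableValidationError("PCA needs at least 2 samples")
    variances = values.var(axis=1, ddof=0)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance protein(s) before PCA", n_dropped)
    values = values[keep]
    if values.empty:
        raise TableValidationError("no variance to decompose: all proteins constant")
    X = values.to_numpy().T  # samples x proteins
    if scale:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    components = pca.components_
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_comp):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=norm.sample_ids, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(components.T, index=values.index, columns=cols),
        n_dropped=n_dropped,
    )


def hcluster_rows(norm: NormalizedTable, subset: list[str] | None = None) -> Dendrogram:
    """Average-linkage agglomeration of rows under 1 - Pearson r distance."""
    values = norm.values
    if subset is not None:
        missing = [p for p in subset if p not in values.index]
        if missing:
            raise TableValidationError(f"subset proteins absent from table: {missing}")
        values = values.loc[subset]
    variances = values.var(axis=1, ddof=0)
    dropped = list(values.index[variances == 0])
    if dropped:
        logger.warning("excluding %d zero-variance row(s) from clustering", len(dropped))
        values = values[variances > 0]
    if len(values) < 2:
        raise TableValidationError("clustering needs at least 2 rows with variance")
    # 'correlation' distance is exactly 1 - Pearson r
    dist = pdist(values.to_numpy(), metric="correlation")
    Z = hierarchy.linkage(dist, method="average")
    return Dendrogram(linkage=Z, labels=list(values.index), dropped=dropped)
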