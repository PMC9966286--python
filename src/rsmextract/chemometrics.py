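"""Chemometric post-analysis: Pearson correlation, correlation-matrix PCA
and agglomerative hierarchical clustering (HCA).

The activity matrix is a samples x variables table (extracts in rows;
totals and IC50s in columns).  Because the variables mix units, PCA is
performed on the correlation matrix: variables are implicitly
standardized, eigenvalues sum to the number of variables, and the
explained-variance share of component i is 100 * lambda_i / p.  HCA runs
on z-scored variables (Euclidean distance, Ward linkage by default) so
cluster geometry is invariant to affine rescaling of any raw column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "pearson_matrix",
    "PCAResult",
    "pca",
    "Dendrogram",
    "hca",
]


def _check_matrix(m: pd.DataFrame) -> pd.DataFrame:
    m = pd.DataFrame(m)
    if m.isna().any().any():
        raise ValueError("activity matrix has missing cells")
    return m.astype(float)


def pearson_matrix(m: pd.DataFrame):
    """Pairwise Pearson correlations with two-sided p-values.

    Returns ``(rho, p, flags)`` DataFrames; p-values come from the
    t transform with n-2 degrees of freedom.  Flags mark "**" for
    p < 0.01, "*" for p < 0.05, "" otherwise.  A zero-variance variable
    yields NaN correlations (reported, not raised) unless every variable
    is constant.
    """
    m = _check_matrix(m)
    n, p = m.shape
    if n < 3:
        raise ValueError("need >= 3 samples for correlation p-values")
    variances = m.var(axis=0, ddof=1)
    if (variances == 0).all():
        raise ValueError("all variables have zero variance")
    cols = list(m.columns)
    rho = pd.DataFrame(np.eye(p), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((p, p)), index=cols, columns=cols)
    for i in range(p):
        for j in range(i + 1, p):
            if variances.iloc[i] == 0 or variances.iloc[j] == 0:
                r, pv = np.nan, np.nan
            else:
                r, pv = stats.pearsonr(m.iloc[:, i], m.iloc[:, j])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = pv
    np.fill_diagonal(pval.values, 0.0)
    flags = pval.map(lambda q: "**" if q < 0.01 else ("*" if q < 0.05 else "")).where(pval.notna(), "")
    np.fill_diagonal(flags.values, "")
    return rho, pval, flags


@dataclass
class PCAResult:
    """Eigen-decomposition of the sample correlation matrix."""

    eigenvalues: np.ndarray
    explained_percent: np.ndarray
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca(m: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of a samples x variables table.

    Components are ordered by decreasing eigenvalue.  Sign convention:
    within each component the largest-magnitude loading is made
    positive, which fixes the otherwise arbitrary eigenvector signs.
    Scores are the z-scored data projected onto the loadings.
    """
    m = _check_matrix(m)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    sd = m.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant variables have undefined correlation: {bad}")
    z = (m - m.mean(axis=0)) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):  # deterministic sign: top |loading| positive
        i_max = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp_names = [f"PC{i+1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=m.columns, columns=comp_names)
    scores = pd.DataFrame(z.to_numpy() @ evecs, index=m.index, columns=comp_names)
    explained = 100.0 * evals / evals.sum()
    return PCAResult(eigenvalues=evals, explained_percent=explained, scores=scores, loadings=loadings)


@dataclass
class Dendrogram:
    """Agglomerative clustering result over samples.

    Wraps a scipy linkage matrix; merge heights are nondecreasing for
    Ward/average/complete linkage on Euclidean distances.  Ties in the
    distance matrix are broken by scipy's deterministic scan order over
    the condensed distances (row-major over sample index pairs), so two
    identical inputs always produce identical trees.
    """

    linkage_matrix: np.ndarray
    labels: tuple
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict:
        """Cluster membership (1..k) per sample label at k clusters."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in [1, {len(self.labels)}]")
        assignments = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hca(m: pd.DataFrame, distance: str = "euclidean", linkage: str = "ward") -> Dendrogram:
    """Hierarchical clustering of samples on z-scored variables.

    distance : only "euclidean" is supported (required by Ward).
    linkage : {"ward", "average", "complete"}.
    """
    if distance != "euclidean":
        raise ValueError("only euclidean distance is supported")
    if linkage not in {"ward", "average", "complete"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    m = _check_matrix(m)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = m.std(axis=0, ddof=1).replace(0.0, 1.0)  # constant column -> zero z-scores
    z = ((m - m.mean(axis=0)) / sd).to_numpy()
    Z = hierarchy.linkage(z, method=linkage, metric="euclidean")
    return Dendrogram(linkage_matrix=Z, labels=tuple(map(str, m.index)), method=linkage)
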