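"""Linear co-expression inference: all-pairs Pearson correlation and the
threshold / mutual k-nearest-neighbour (mKNN) network constructions.

The mKNN rule used here is the tie-inclusive variant: a gene's k-list holds
its k-1 highest-correlation partners plus *all* genes tied at the k-th largest
value, on the grounds that genes of equal correlation are equally valid
neighbours.  An edge requires mutual k-list membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from sklearn.base import BaseEstimator

from .datasets import TernaryExpressionMatrix, new_network

_SYMMETRY_TOL = 1e-12
TIE_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Symmetric labelled gene x gene similarity weights.

    ``kind`` tags the scale: 'pcc' (values in [-1,1], NaN marks undefined
    pairs), 'mi', 'clr_score' or 'mrnet_score'.  The diagonal is ignored.
    """

    gene_ids: list[str]
    weights: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape} != ({n}, {n})")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene IDs")
        diff = np.nan_to_num(self.weights) - np.nan_to_num(self.weights.T)
        if np.abs(diff).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("weights matrix is not symmetric")
        if self.kind == "pcc":
            finite = self.weights[np.isfinite(self.weights)]
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("pcc values outside [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def offdiagonal(self) -> np.ndarray:
        """Off-diagonal values as a flat array (both triangles)."""
        n = self.n_genes
        mask = ~np.eye(n, dtype=bool)
        return self.weights[mask]


def pearson_all(m: TernaryExpressionMatrix) -> SimilarityMatrix:
    """All-pairs sample Pearson correlation over conditions.

    Genes with zero variance across conditions get NaN rows/columns: their
    correlation is undefined and they never form edges downstream.
    """
    if m.n_conditions < 3:
        raise ValueError("at least 3 conditions required for correlation")
    values = m.values.astype(float)
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.asarray(corr, dtype=float)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    corr = np.clip(corr, -1.0, 1.0)  # NaN propagates through clip
    # enforce exact symmetry against floating-point asymmetry in BLAS paths
    corr = (corr + corr.T) / 2.0
    return SimilarityMatrix(list(m.gene_ids), corr, "pcc")


def pcc_threshold_network(
    s: SimilarityMatrix, t: float, absolute: bool = False
) -> nx.Graph:
    """Edge iff PCC >= t (signed comparison by default).

    All genes are retained as nodes, so isolated genes survive — the node
    count of a thresholded network equals the gene universe size.
    """
    if s.kind != "pcc":
        raise ValueError("threshold network requires kind='pcc'")
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    w = np.abs(s.weights) if absolute else s.weights
    n = s.n_genes
    iu = np.triu_indices(n, k=1)
    keep = np.isfinite(w[iu]) & (w[iu] >= t)
    edges = [
        (s.gene_ids[i], s.gene_ids[j], s.weights[i, j])
        for i, j in zip(iu[0][keep], iu[1][keep])
    ]
    return new_network(s.gene_ids, edges)


def _k_lists(
    w: np.ndarray, k: int, tie_tol: float = TIE_TOL
) -> list[np.ndarray]:
    """Tie-inclusive k-lists per gene; NaN partners rank below everything."""
    n = w.shape[0]
    lists: list[np.ndarray] = []
    for i in range(n):
        row = w[i].copy()
        row[i] = np.nan
        defined = np.flatnonzero(np.isfinite(row))
        if defined.size == 0:
            lists.append(np.array([], dtype=int))
            continue
        vals = row[defined]
        order = np.argsort(-vals, kind="stable")
        kk = min(k, defined.size)
        kth_value = vals[order[kk - 1]]
        member = vals >= kth_value - tie_tol
        lists.append(defined[member])
    return lists


def mknn_network(s: SimilarityMatrix, k: int, tie_tol: float = TIE_TOL) -> nx.Graph:
    """Mutual k-nearest-neighbour network with tie-inclusive k-lists.

    Edge (u, v) exists iff v is in u's k-list and u is in v's k-list.  Genes
    with undefined correlation (zero variance) are excluded from all k-lists.
    Isolated genes are dropped from the result.
    """
    if s.kind != "pcc":
        raise ValueError("mKNN requires kind='pcc'")
    n = s.n_genes
    if k < 1 or k >= n:
        raise ValueError("k must satisfy 1 <= k < n_genes")
    lists = _k_lists(s.weights, k, tie_tol)
    sets = [set(l.tolist()) for l in lists]
    edges = []
    for i in range(n):
        for j in sets[i]:
            if j > i and i in sets[j]:
                edges.append((s.gene_ids[i], s.gene_ids[j], s.weights[i, j]))
    nodes = {u for u, v, _ in edges} | {v for u, v, _ in edges}
    return new_network(sorted(nodes), edges)


class PearsonNetwork(BaseEstimator):
    """Correlation-based co-expression network estimator.

    Parameters
    ----------
    method : 'threshold' or 'mknn'.
    threshold : PCC cut-off for the threshold method (signed; default 0.9).
    k : neighbourhood size for the mKNN method (default 10).
    absolute : rank/threshold on the absolute PCC instead of the signed value.

    Attributes (after ``fit``)
    --------------------------
    similarity_ : SimilarityMatrix of PCC values.
    graph_ : networkx.Graph, the inferred co-expression network.
    n_zero_variance_ : number of genes with undefined correlation.
    """

    def __init__(self, method: str = "threshold", threshold: float = 0.9,
                 k: int = 10, absolute: bool = False):
        self.method = method
        self.threshold = threshold
        self.k = k
        self.absolute = absolute

    def fit(self, X, y=None):
        m = _as_ternary(X)
        if self.method not in ("threshold", "mknn"):
            raise ValueError(f"unknown method {self.method!r}")
        self.similarity_ = pearson_all(m)
        self.n_zero_variance_ = int(
            np.isnan(self.similarity_.weights).all(axis=1).sum()
        )
        if self.method == "threshold":
            self.graph_ = pcc_threshold_network(
                self.similarity_, self.threshold, absolute=self.absolute
            )
        else:
            w = self.similarity_
            if self.absolute:
                w = SimilarityMatrix(w.gene_ids, np.abs(w.weights), "pcc")
            self.graph_ = mknn_network(w, self.k)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).graph_


def _as_ternary(X) -> TernaryExpressionMatrix:
    if isinstance(X, TernaryExpressionMatrix):
        return X
    try:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return TernaryExpressionMatrix.from_frame(X)
    except ImportError:  # pragma: no cover
        pass
    X = np.asarray(X)
    return TernaryExpressionMatrix(
        [f"g{i}" for i in range(X.shape[0])],
        [f"c{j}" for j in range(X.shape[1])],
        X,
    )
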