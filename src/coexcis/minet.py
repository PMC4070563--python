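"""Non-linear co-expression inference.

Mutual information between gene expression profiles is estimated with the
Kraskov k-nearest-neighbour estimator (algorithm 1): for each sample the
Chebyshev distance to its k-th neighbour in the joint (x, y) space defines a
box, and the marginal neighbour counts n_x, n_y inside that box enter

    I(X, Y) = psi(k) + psi(N) - < psi(n_x + 1) + psi(n_y + 1) >

Ternary profiles are massively tied, so i.i.d. Gaussian jitter of scale
``jitter_sd`` is added before estimation; the jitter seed is part of the
configuration and reported with the results.

The raw MI matrix can be post-processed by ARACNE (data-processing-inequality
pruning, additive or multiplicative tolerance), CLR (background-corrected
z-scores) or MRNET (maximum-relevance-minimum-redundancy forward selection),
and finally thresholded at a fraction of the matrix maximum to give a graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree
from scipy.special import digamma
from sklearn.base import BaseEstimator

from .datasets import TernaryExpressionMatrix, new_network
from .linear import SimilarityMatrix, _as_ternary


@dataclass
class MiConfig:
    """Configuration of the MI estimation / pruning / thresholding chain."""

    k_neighbors: int = 3
    jitter_sd: float = 1e-12
    seed: int = 0
    dpi_mode: str = "multiplicative"
    dpi_tolerance: float = 1.0
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.jitter_sd <= 0:
            raise ValueError("jitter_sd must be positive")
        if self.dpi_mode not in ("additive", "multiplicative"):
            raise ValueError("dpi_mode must be 'additive' or 'multiplicative'")
        if self.dpi_mode == "additive" and self.dpi_tolerance < 0:
            raise ValueError("additive tolerance must be >= 0")
        if self.dpi_mode == "multiplicative" and not 0 < self.dpi_tolerance <= 1:
            raise ValueError("multiplicative tolerance must be in (0, 1]")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")


def kraskov_mi(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """Kraskov algorithm-1 MI estimate (nats) for two continuous samples.

    The caller is responsible for tie-breaking (see :func:`kraskov_mi_all`).
    Small negative estimates are possible and reported raw.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if k >= n:
        raise ValueError("k_neighbors must be smaller than the sample size")
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    # distance to the k-th neighbour (excluding self) in the max-norm
    eps = tree.query(pts, k=k + 1, p=np.inf)[0][:, -1]

    def strict_counts(v: np.ndarray) -> np.ndarray:
        order = np.sort(v)
        hi = np.searchsorted(order, v + eps, side="left")
        lo = np.searchsorted(order, v - eps, side="right")
        return hi - lo - 1  # exclude the point itself

    nx_, ny_ = strict_counts(x), strict_counts(y)
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    )


def kraskov_mi_all(m: TernaryExpressionMatrix, cfg: MiConfig) -> SimilarityMatrix:
    """All-pairs Kraskov MI over jittered ternary profiles."""
    if m.n_conditions < 3:
        raise ValueError("at least 3 conditions required")
    if cfg.k_neighbors >= m.n_conditions:
        raise ValueError("k_neighbors must be smaller than the number of conditions")
    rng = np.random.default_rng(cfg.seed)
    data = m.values.astype(float) + rng.normal(0.0, cfg.jitter_sd, size=m.values.shape)
    n = m.n_genes
    w = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mi = kraskov_mi(data[i], data[j], k=cfg.k_neighbors)
            w[i, j] = w[j, i] = mi
    return SimilarityMatrix(list(m.gene_ids), w, "mi")


def aracne_prune(
    s: SimilarityMatrix, mode: str = "multiplicative", tolerance: float = 1.0
) -> SimilarityMatrix:
    """Data-processing-inequality pruning of an MI matrix.

    For every unordered triple (i, j, k) the edge (i, j) is marked for removal
    when MI_ij < min(MI_ik, MI_jk) - eps (additive, eps = ``tolerance``) or
    MI_ij < tau * min(MI_ik, MI_jk) (multiplicative, tau = ``tolerance``).
    All removal decisions are computed on the input matrix and applied at
    once, so the scan order is irrelevant; removed entries become 0.
    """
    if s.kind != "mi":
        raise ValueError("ARACNE requires kind='mi'")
    if mode == "additive":
        if tolerance < 0:
            raise ValueError("additive tolerance must be >= 0")
    elif mode == "multiplicative":
        if not 0 < tolerance <= 1:
            raise ValueError("multiplicative tolerance must be in (0, 1]")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    w = s.weights.copy()
    n = s.n_genes
    if n < 3:
        return SimilarityMatrix(list(s.gene_ids), w, "mi")
    m = w.copy()
    np.fill_diagonal(m, -np.inf)
    # bound[i, j] = max over k != i, j of min(MI_ik, MI_jk); the -inf diagonal
    # removes k in {i, j} from the maximisation automatically
    bound = np.empty_like(m)
    for i in range(n):
        bound[i] = np.minimum(m[i][None, :], m).max(axis=1)
    if mode == "additive":
        remove = m < bound - tolerance
    else:
        remove = m < tolerance * bound
    np.fill_diagonal(remove, False)
    remove |= remove.T  # decisions are symmetric by construction; be explicit
    w[remove] = 0.0
    return SimilarityMatrix(list(s.gene_ids), w, "mi")


def clr_transform(s: SimilarityMatrix) -> SimilarityMatrix:
    """Context-likelihood-of-relatedness scores from an MI matrix.

    Each gene's off-diagonal MI row gives a background (mu_i, sigma_i);
    z_i(j) = max(0, (MI_ij - mu_i) / sigma_i) and the pair score is
    sqrt(z_i(j)^2 + z_j(i)^2).  A zero-variance row contributes 0.
    """
    if s.kind != "mi":
        raise ValueError("CLR requires kind='mi'")
    n = s.n_genes
    if n < 3:
        raise ValueError("CLR requires at least 3 genes")
    w = s.weights
    mask = ~np.eye(n, dtype=bool)
    mu = np.array([w[i, mask[i]].mean() for i in range(n)])
    sd = np.array([w[i, mask[i]].std() for i in range(n)])
    z = np.zeros((n, n), dtype=float)
    ok = sd > 0
    z[ok] = (w[ok] - mu[ok, None]) / sd[ok, None]
    z = np.maximum(z, 0.0)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return SimilarityMatrix(list(s.gene_ids), scores, "clr_score")


def mrnet_build(s: SimilarityMatrix) -> SimilarityMatrix:
    """Maximum-relevance-minimum-redundancy network scores.

    For each target gene Y a forward selection runs over candidates X_j with
    score s_j = MI(X_j, Y) - mean_{X_k selected} MI(X_j, X_k); candidates are
    selected while the best score is positive.  The output weight of a pair is
    the maximum of its two directional selection scores; never-selected pairs
    stay 0, so the matrix is non-negative.
    """
    if s.kind != "mi":
        raise ValueError("MRNET requires kind='mi'")
    n = s.n_genes
    w = s.weights
    out = np.zeros((n, n), dtype=float)
    for target in range(n):
        candidates = [j for j in range(n) if j != target]
        selected: list[int] = []
        remaining = set(candidates)
        while remaining:
            best_j, best_score = -1, 0.0
            for j in remaining:
                relevance = w[j, target]
                redundancy = np.mean([w[j, k] for k in selected]) if selected else 0.0
                score = relevance - redundancy
                if score > best_score:
                    best_j, best_score = j, score
            if best_j < 0:
                break
            selected.append(best_j)
            remaining.discard(best_j)
            out[target, best_j] = max(out[target, best_j], best_score)
    out = np.maximum(out, out.T)
    return SimilarityMatrix(list(s.gene_ids), out, "mrnet_score")


def fraction_threshold_network(s: SimilarityMatrix, fraction: float) -> nx.Graph:
    """Edges where weight >= fraction x (max off-diagonal weight).

    Genes without any edge at the threshold are dropped, so the node count of
    an MI-derived network can be smaller than the gene universe.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    off = s.offdiagonal()
    off = off[np.isfinite(off)]
    if off.size == 0 or off.max() <= 0:
        raise ValueError("no edges at any threshold: similarity matrix has no positive weight")
    threshold = fraction * off.max()
    n = s.n_genes
    iu = np.triu_indices(n, k=1)
    vals = s.weights[iu]
    keep = np.isfinite(vals) & (vals >= threshold)
    edges = [
        (s.gene_ids[i], s.gene_ids[j], s.weights[i, j])
        for i, j in zip(iu[0][keep], iu[1][keep])
    ]
    nodes = {u for u, v, _ in edges} | {v for u, v, _ in edges}
    return new_network(sorted(nodes), edges)


class MutualInfoNetwork(BaseEstimator):
    """MI-based co-expression network estimator.

    Parameters
    ----------
    algorithm : 'aracne_multiplicative', 'aracne_additive', 'clr', 'mrnet'
        or 'mi' (no post-processing).
    k_neighbors : Kraskov estimator neighbourhood size (default 3).
    jitter_sd : tie-breaking jitter scale (default 1e-12).
    dpi_tolerance : ARACNE tolerance (eps for additive, tau for
        multiplicative); default 1.0, the strict DPI for the multiplicative rule.
    fraction : max-fraction threshold in (0, 1] (default 0.8).
    random_state : jitter seed.

    Attributes (after ``fit``)
    --------------------------
    mi_ : raw Kraskov MI SimilarityMatrix.
    scores_ : post-processed SimilarityMatrix the threshold was applied to.
    graph_ : networkx.Graph of the thresholded network.
    """

    _ALGORITHMS = ("aracne_multiplicative", "aracne_additive", "clr", "mrnet", "mi")

    def __init__(self, algorithm: str = "aracne_multiplicative", k_neighbors: int = 3,
                 jitter_sd: float = 1e-12, dpi_tolerance: float = 1.0,
                 fraction: float = 0.8, random_state: int = 0):
        self.algorithm = algorithm
        self.k_neighbors = k_neighbors
        self.jitter_sd = jitter_sd
        self.dpi_tolerance = dpi_tolerance
        self.fraction = fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.algorithm not in self._ALGORITHMS:
            raise ValueError(f"algorithm must be one of {self._ALGORITHMS}")
        m = _as_ternary(X)
        dpi_mode = (
            "additive" if self.algorithm == "aracne_additive" else "multiplicative"
        )
        cfg = MiConfig(
            k_neighbors=self.k_neighbors,
            jitter_sd=self.jitter_sd,
            seed=self.random_state,
            dpi_mode=dpi_mode,
            dpi_tolerance=self.dpi_tolerance,
            threshold_fraction=self.fraction,
        )
        self.mi_ = kraskov_mi_all(m, cfg)
        if self.algorithm in ("aracne_multiplicative", "aracne_additive"):
            self.scores_ = aracne_prune(self.mi_, dpi_mode, self.dpi_tolerance)
        elif self.algorithm == "clr":
            self.scores_ = clr_transform(self.mi_)
        elif self.algorithm == "mrnet":
            self.scores_ = mrnet_build(self.mi_)
        else:
            self.scores_ = self.mi_
        self.graph_ = fraction_threshold_network(self.scores_, self.fraction)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).graph_
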