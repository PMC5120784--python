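"""Edge-edge significance graph and hypergraph metrics.

Every pair of edge-weight time series is correlated to form the E x E matrix
X; two-sided p-values from the t-transform are thresholded by a
Benjamini-Hochberg false discovery rate correction per subject, surviving
pairs keep their correlation in the sparse matrix xi, and the binarized
matrix xi' defines an undirected graph over edge-vertices.  Its connected
components are the hyperedges: groups of node-pair connections whose
strengths co-fluctuate across windows.  Both correlation signs count —
relations are absolute-valued.  Singletons (edges with no significant
partner) are excluded from the metrics; a subject's hypergraph cardinality
is the number of non-singleton hyperedges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .dfc import EdgeIndexMap, EdgeTimeSeries

__all__ = [
    "EdgeEdgeGraph",
    "Hyperedge",
    "Hypergraph",
    "NodeDegreeProfile",
    "edge_edge_correlation",
    "fdr_binarize",
    "extract_hypergraph",
    "node_degree",
    "shuffle_null",
    "size_distribution",
    "powerlaw_fit",
]

# above this many edge-vertices the xi matrices are kept sparse
DENSE_EDGE_LIMIT = 512


def edge_edge_correlation(ets: EdgeTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between every pair of edge time series.

    Returns the symmetric (E, E) correlation matrix and the matching matrix
    of two-sided p-values from the t-transform ``t = r sqrt((W-2)/(1-r^2))``
    with W-2 degrees of freedom.  Rows constant across windows get
    correlation 0 and p = 1 against everything (their correlation is
    undefined).  The diagonal never produces a link.
    """
    W = ets.n_windows
    if W < 4:
        raise ValueError(f"need at least 4 windows for p-values, got {W}")
    weights = ets.weights
    sd = weights.std(axis=1)
    constant = sd < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(weights)
    corr = np.nan_to_num(corr, nan=0.0)
    corr = np.clip(corr, -1.0, 1.0)
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    df = W - 2
    r2 = np.clip(corr**2, 0.0, 1.0 - 1e-15)
    with np.errstate(divide="ignore"):
        t = np.abs(corr) * np.sqrt(df / (1.0 - r2))
    p = 2.0 * stats.t.sf(t, df)
    p = np.clip(p, 0.0, 1.0)
    if constant.any():
        p[constant, :] = 1.0
        p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)
    return corr, p


@dataclass(frozen=True)
class EdgeEdgeGraph:
    """FDR-thresholded edge-edge graph G' = {V', E'} over E edge-vertices.

    ``xi`` keeps the correlation of every surviving pair (zero elsewhere);
    ``xi_binary`` is its 0/1 indicator.  Links exist exactly where a pair's
    two-sided p-value survived the per-subject FDR correction over all
    E(E-1)/2 upper-triangle tests; the diagonal is excluded.
    """

    xi: sparse.csr_matrix
    xi_binary: sparse.csr_matrix
    alpha: float
    n_tests: int

    @property
    def n_edges(self) -> int:
        return self.xi.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.xi_binary.nnz // 2)


def fdr_binarize(
    p_values: np.ndarray,
    correlations: np.ndarray,
    alpha: float = 0.05,
    method: str = "fdr_bh",
    *,
    dense: bool = False,
) -> EdgeEdgeGraph:
    """Benjamini-Hochberg threshold of the edge-edge p-value matrix.

    The step-up rule runs over all E(E-1)/2 upper-triangle p-values of one
    subject; surviving pairs keep their correlation in xi, all other entries
    are zero.  ``method`` may be ``"fdr_bh"`` (default) or ``"fdr_by"`` for
    the dependence-robust Benjamini-Yekutieli variant.  ``dense=True``
    stores the matrices densely wrapped in CSR; results are value-identical.
    """
    p_values = np.asarray(p_values, dtype=float)
    correlations = np.asarray(correlations, dtype=float)
    E = p_values.shape[0]
    if p_values.shape != (E, E) or correlations.shape != (E, E):
        raise ValueError("p_values and correlations must be square and matching")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rows, cols = np.triu_indices(E, k=1)
    flat_p = p_values[rows, cols]
    n_tests = flat_p.size
    if alpha <= 0 or n_tests == 0:
        reject = np.zeros(n_tests, dtype=bool)
    else:
        reject = multipletests(flat_p, alpha=alpha, method=method)[0]
    r_sel, c_sel = rows[reject], cols[reject]
    vals = correlations[r_sel, c_sel]
    sym_r = np.concatenate([r_sel, c_sel])
    sym_c = np.concatenate([c_sel, r_sel])
    xi = sparse.coo_matrix(
        (np.concatenate([vals, vals]), (sym_r, sym_c)), shape=(E, E)
    ).tocsr()
    xi_binary = xi.copy()
    xi_binary.data = np.ones_like(xi_binary.data)
    if dense or E <= DENSE_EDGE_LIMIT:
        # densify-then-wrap keeps one storage contract downstream
        xi = sparse.csr_matrix(xi.toarray())
        xi_binary = sparse.csr_matrix(xi_binary.toarray())
    return EdgeEdgeGraph(xi, xi_binary, float(alpha), n_tests)


@dataclass(frozen=True)
class Hyperedge:
    """A connected component of xi' with at least one member edge.

    ``size`` is the member-edge count s(h); ``link_count`` is the number of
    significant edge-edge links inside the component (a secondary
    diagnostic).
    """

    edge_ids: frozenset[int]
    link_count: int = 0

    @property
    def size(self) -> int:
        return len(self.edge_ids)

    def min_edge_id(self) -> int:
        return min(self.edge_ids)


@dataclass(frozen=True)
class Hypergraph:
    """All non-singleton hyperedges of one subject plus the singleton list."""

    hyperedges: tuple[Hyperedge, ...]
    singletons: tuple[int, ...]
    n_edges: int

    def __post_init__(self) -> None:
        covered = sum(h.size for h in self.hyperedges) + len(self.singletons)
        if covered != self.n_edges:
            raise ValueError(
                "hyperedges and singletons must partition the edge set: "
                f"{covered} covered of {self.n_edges}"
            )

    @property
    def cardinality(self) -> int:
        return len(self.hyperedges)

    @property
    def sizes(self) -> list[int]:
        return [h.size for h in self.hyperedges]

    @property
    def max_size(self) -> int:
        return max((h.size for h in self.hyperedges), default=1 if self.singletons else 0)

    def largest_hyperedge(self) -> Hyperedge | None:
        """Largest hyperedge; ties broken by lowest member edge id."""
        if not self.hyperedges:
            return None
        return max(self.hyperedges, key=lambda h: (h.size, -h.min_edge_id()))


def extract_hypergraph(g: EdgeEdgeGraph) -> Hypergraph:
    """Connected components of the binarized edge-edge graph.

    Components with >= 2 member edges become hyperedges (sorted by lowest
    member edge id); isolated edge-vertices are singletons.
    """
    n_comp, labels = connected_components(g.xi_binary, directed=False)
    members: dict[int, list[int]] = {}
    for edge_id, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(edge_id)
    hyperedges = []
    singletons = []
    bin_csr = g.xi_binary
    for lab in sorted(members, key=lambda l: members[l][0]):
        ids = members[lab]
        if len(ids) == 1:
            singletons.append(ids[0])
        else:
            sub = bin_csr[ids][:, ids]
            hyperedges.append(Hyperedge(frozenset(ids), int(sub.nnz // 2)))
    return Hypergraph(tuple(hyperedges), tuple(singletons), g.n_edges)


@dataclass(frozen=True)
class NodeDegreeProfile:
    """Per-node count of hyperedges containing at least one incident edge."""

    degree: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.degree, dtype=int)
        if d.ndim != 1 or np.any(d < 0):
            raise ValueError("degree must be a 1-D nonnegative integer vector")
        object.__setattr__(self, "degree", d)


def node_degree(h: Hypergraph, index: EdgeIndexMap) -> NodeDegreeProfile:
    """Hyperedge node degree: hyperedges containing the node, each counted
    at most once per node regardless of how many member edges touch it."""
    degree = np.zeros(index.n_nodes, dtype=int)
    for he in h.hyperedges:
        nodes = set()
        for edge_id in he.edge_ids:
            i, j = index.pair_of(edge_id)
            nodes.add(i)
            nodes.add(j)
        for n in nodes:
            degree[n] += 1
    return NodeDegreeProfile(degree)


def shuffle_null(ets: EdgeTimeSeries, seed: int | np.random.Generator) -> EdgeTimeSeries:
    """Temporal-reshuffle null model.

    Each edge's window sequence is independently and uniformly permuted,
    destroying temporal correspondence between edges while exactly
    preserving every row's mean and variance.
    """
    if ets.n_windows < 2:
        raise ValueError("need at least 2 windows to shuffle")
    rng = np.random.default_rng(seed)
    shuffled = np.empty_like(ets.weights)
    W = ets.n_windows
    for e in range(ets.n_edges):
        shuffled[e] = ets.weights[e, rng.permutation(W)]
    return EdgeTimeSeries(shuffled, ets.index, ets.window_task)


def size_distribution(
    hypergraphs,
    drop_largest_per_subject: bool = False,
) -> dict[int, int]:
    """Empirical cumulative hyperedge-size counts pooled over subjects.

    Returns ``{s: count of hyperedges with size >= s}`` for every integer s
    between the smallest and largest pooled size.  With
    ``drop_largest_per_subject`` each subject's single largest hyperedge
    (ties: lowest member edge id) is removed before pooling.
    """
    sizes: list[int] = []
    for hg in hypergraphs:
        hes = list(hg.hyperedges)
        if drop_largest_per_subject and hes:
            hes.remove(hg.largest_hyperedge())
        sizes.extend(h.size for h in hes)
    if not sizes:
        return {}
    arr = np.asarray(sizes)
    return {
        s: int(np.sum(arr >= s)) for s in range(int(arr.min()), int(arr.max()) + 1)
    }


def powerlaw_fit(distribution: dict[int, int]) -> tuple[float, float]:
    """Log-log least-squares line through the cumulative size counts.

    Fits log10(count >= s) against log10(s) over sizes with positive count
    and returns ``(power, intercept)`` where the intercept is on the count
    scale (10 ** fitted intercept).  Requires >= 3 distinct sizes.
    """
    items = [(s, c) for s, c in distribution.items() if c > 0]
    if len({s for s, _ in items}) < 3:
        raise ValueError("power-law fit needs at least 3 distinct sizes")
    s = np.log10([float(k) for k, _ in items])
    c = np.log10([float(v) for _, v in items])
    slope, intercept = np.polyfit(s, c, 1)
    return float(slope), float(10.0**intercept)
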