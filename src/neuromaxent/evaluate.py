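"""Model-versus-data comparison machinery.

Induced graphlet counts (triangle, square, diamond, K4), standard network
measures (efficiencies, clustering, path lengths), degree-distribution
summaries, the wiring-length position-shuffle test, edge-classification
(ROC / precision-recall) curves, probability-weight rank correlation, and
z-score comparison of a data statistic against a model ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats as sps
from sklearn.metrics import (auc, average_precision_score,
                             precision_recall_curve, roc_curve)

from .core import SpatialNetwork


# ---------------------------------------------------------------------------
# Graphlets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphletCounts:
    """Induced counts of the four undirected 3-4 node graphlets."""

    n_triangle: int
    n_square: int       # 4-cycle with no diagonal
    n_diamond: int      # 4-cycle plus one diagonal
    n_k4: int           # complete graph on 4 nodes

    def as_array(self) -> np.ndarray:
        return np.array([self.n_triangle, self.n_square,
                         self.n_diamond, self.n_k4])


def graphlet_counts(net) -> GraphletCounts:
    """Count induced triangles, squares, diamonds and K4s.

    Works from per-edge common-neighbour counts with algebraic overlap
    corrections: every K4 contains 6 non-induced diamonds and 3
    non-induced 4-cycles, and every diamond contains 1 non-induced
    4-cycle. Accepts a SpatialNetwork or a boolean adjacency matrix.
    """
    a = net.adjacency() if isinstance(net, SpatialNetwork) else \
        np.asarray(net, dtype=bool)
    n = a.shape[0]
    if n < 3:
        return GraphletCounts(0, 0, 0, 0)
    cn = (a.astype(np.int64) @ a.astype(np.int64))
    iu, ju = np.triu_indices(n, k=1)
    cn_pairs = cn[iu, ju]
    edge = a[iu, ju]

    triangles = int(cn_pairs[edge].sum()) // 3
    # non-induced 4-cycles: choose an antipodal pair and 2 of its common
    # neighbours; each cycle has 2 antipodal pairs
    c4_ni = int((cn_pairs * (cn_pairs - 1) // 2).sum()) // 2
    # non-induced diamonds: an edge (the diagonal) plus 2 common neighbours
    diamond_ni = int((cn_pairs[edge] * (cn_pairs[edge] - 1) // 2).sum())
    # K4: an edge whose common neighbourhood contains an edge; each K4 is
    # seen once per its 6 edges
    k4_times_6 = 0
    eu, ev = iu[edge], ju[edge]
    for u, v in zip(eu, ev):
        common = a[u] & a[v]
        if common.sum() >= 2:
            sub = a[np.ix_(common, common)]
            k4_times_6 += int(sub.sum()) // 2
    n_k4 = k4_times_6 // 6
    n_diamond = diamond_ni - 6 * n_k4
    n_square = c4_ni - n_diamond - 3 * n_k4
    return GraphletCounts(triangles, n_square, n_diamond, n_k4)


# ---------------------------------------------------------------------------
# Network measures
# ---------------------------------------------------------------------------

@dataclass
class NetMeasures:
    lcc_size: int
    diameter: int
    avg_shortest_path: float
    E_global: float
    E_local: float
    transitivity: float
    avg_clustering: float


def network_measures(net: SpatialNetwork) -> NetMeasures:
    """Standard global and local measures of an undirected simple graph.

    Diameter and average geodesic distance are computed on the largest
    connected component (they are infinite otherwise); global efficiency
    averages 1/delta_ij over all ordered pairs with 1/delta = 0 for
    disconnected ones; local efficiency averages the global efficiency of
    each node's neighbour-induced subgraph. Clustering of nodes with
    fewer than two neighbours is zero.
    """
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    g = nx.Graph()
    g.add_nodes_from(net.nodes.ids)
    g.add_edges_from(net.edges.pairs)
    lcc = max(nx.connected_components(g), key=len)
    sub = g.subgraph(lcc)
    diameter = nx.diameter(sub) if len(lcc) > 1 else 0
    avg_sp = nx.average_shortest_path_length(sub) if len(lcc) > 1 else 0.0
    return NetMeasures(
        lcc_size=len(lcc),
        diameter=int(diameter),
        avg_shortest_path=float(avg_sp),
        E_global=float(nx.global_efficiency(g)),
        E_local=float(nx.local_efficiency(g)),
        transitivity=float(nx.transitivity(g)),
        avg_clustering=float(nx.average_clustering(g)),
    )


@dataclass(frozen=True)
class DegreeStats:
    mean: float
    median: float
    mean_over_median: float
    iqr: float


def degree_stats(degrees: Sequence[float]) -> DegreeStats:
    """Mean, median, their ratio, and the IQR of a degree sequence.

    Degrees are taken over all nodes including isolated ones (so the mean
    is 2E/N). Quartiles use linear interpolation.
    """
    k = np.asarray(degrees, dtype=float)
    if k.size == 0:
        raise ValueError("empty degree sequence")
    mean = float(k.mean())
    median = float(np.median(k))
    q1, q3 = np.percentile(k, [25, 75])
    ratio = mean / median if median != 0 else float("inf")
    return DegreeStats(mean=mean, median=median, mean_over_median=ratio,
                       iqr=float(q3 - q1))


# ---------------------------------------------------------------------------
# Wiring length and the position-shuffle test
# ---------------------------------------------------------------------------

def wiring_length(net: SpatialNetwork) -> float:
    """Total wiring length L = sum of edge distances, soma-size units."""
    return net.wiring_length()


def wiring_shuffle_test(net: SpatialNetwork, n_perm: int = 1000,
                        seed: int = 0) -> Tuple[float, float]:
    """Shuffle node positions, keeping the topology intact.

    Returns (ratio_mean, p_value): the mean shuffled-to-observed wiring
    length ratio, and the one-sided permutation p-value for the observed
    length being short, p = (#{L_perm <= L_obs} + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pos = net.nodes.positions / net.nodes.soma_size_unit
    u, v = net.edges.index_arrays(net.nodes)
    l_obs = float(np.linalg.norm(pos[u] - pos[v], axis=1).sum())
    n = len(net.nodes)
    l_perm = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(n)
        pp = pos[perm]
        l_perm[r] = np.linalg.norm(pp[u] - pp[v], axis=1).sum()
    p = (int((l_perm <= l_obs).sum()) + 1) / (n_perm + 1)
    return float(l_perm.mean() / l_obs), float(p)


# ---------------------------------------------------------------------------
# Edge classification and weight correlation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationCurves:
    fpr: np.ndarray
    tpr: np.ndarray
    auc_roc: float
    precision: np.ndarray
    recall: np.ndarray
    auc_pr: float


def edge_classification_curves(scores: np.ndarray, labels: np.ndarray
                               ) -> ClassificationCurves:
    """ROC and precision-recall curves for edge prediction scores.

    AUC-ROC via the trapezoid rule on the tie-grouped threshold sweep;
    AUC-PR as step-interpolated average precision (robust under the
    heavy class imbalance of sparse graphs).
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("labels contain a single class")
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    return ClassificationCurves(
        fpr=fpr, tpr=tpr, auc_roc=float(auc(fpr, tpr)),
        precision=precision, recall=recall,
        auc_pr=float(average_precision_score(y, s)),
    )


def weight_correlation(scores: np.ndarray, weights: np.ndarray
                       ) -> Tuple[float, float]:
    """Spearman rank correlation of edge probabilities with edge weights.

    Average ranks over ties; two-sided p via the large-sample t
    approximation. A constant input makes the correlation undefined and
    returns (nan, nan).
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(s) == 0 or np.ptp(w) == 0:
        return float("nan"), float("nan")
    r, p = sps.spearmanr(s, w)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Ensemble z-score comparison
# ---------------------------------------------------------------------------

@dataclass
class EnsembleComparison:
    stat_name: str
    data_value: float
    model_mean: float
    model_sd: float
    inverse_fold_change: float   # <n_model> / n_true
    z: float
    p_two_sided: float
    significance: str            # "n.s.", "*", "**", or "***"


def ensemble_compare(data_value: float, model_stats: Sequence[float],
                     stat_name: str = "") -> EnsembleComparison:
    """Compare a data statistic with its distribution over realizations.

    z = (data - mean)/sd with the two-sided normal p = 2(1 - Phi(|z|));
    stars at p < 0.05 / 0.01 / 0.001. A zero model SD leaves z and p
    undefined (nan).
    """
    m = np.asarray(model_stats, dtype=float)
    if len(m) < 2:
        raise ValueError("need at least 2 model realizations")
    mean, sd = float(m.mean()), float(m.std(ddof=1))
    if sd == 0.0:
        z = p = float("nan")
    else:
        z = (data_value - mean) / sd
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    if np.isnan(p) or p > 0.05:
        stars = "n.s."
    elif p < 0.001:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    else:
        stars = "*"
    inv_fold = mean / data_value if data_value != 0 else float("inf")
    return EnsembleComparison(stat_name=stat_name, data_value=data_value,
                              model_mean=mean, model_sd=sd,
                              inverse_fold_change=inv_fold, z=float(z),
                              p_two_sided=float(p), significance=stars)
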