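"""Core data model for spatial neural networks.

Nodes are neurons with 3D positions (stored in micrometres); edges are
undirected and unweighted (connectome: at least one chemical synapse) or
carry positive integer synapse counts. Distances are reported in soma-size
units: Euclidean micrometre distance divided by ``soma_size_unit``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]


def canonical_pair(u: str, v: str) -> Pair:
    """Unordered pair as a sorted tuple of string ids."""
    u, v = str(u), str(v)
    if u == v:
        raise ValueError(f"self-loop on node {u!r}")
    return (u, v) if u < v else (v, u)


class NodeTable:
    """Neuron table: unique ids, 3D positions in μm, and a distance unit.

    Node order is fixed by sorted id, which also fixes the deterministic
    enumeration order of unordered pairs throughout the package.
    """

    def __init__(self, ids: Sequence, positions: np.ndarray,
                 soma_size_unit: float = 1.0):
        ids = [str(i) for i in ids]
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(ids) != positions.shape[0]:
            raise ValueError("ids and positions length mismatch")
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate node id {dup!r}")
        if not np.all(np.isfinite(positions)):
            raise ValueError("non-finite node position")
        if not soma_size_unit > 0:
            raise ValueError("soma_size_unit must be positive")
        order = np.argsort(np.asarray(ids, dtype=object))
        self.ids: Tuple[str, ...] = tuple(np.asarray(ids, dtype=object)[order])
        self.positions: np.ndarray = positions[order]
        self.soma_size_unit: float = float(soma_size_unit)
        self._index: Dict[str, int] = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, node_id) -> int:
        return self._index[str(node_id)]

    def __contains__(self, node_id) -> bool:
        return str(node_id) in self._index

    def __eq__(self, other) -> bool:
        return (isinstance(other, NodeTable)
                and self.ids == other.ids
                and np.array_equal(self.positions, other.positions)
                and self.soma_size_unit == other.soma_size_unit)


class EdgeList:
    """Set of unordered node-id pairs with optional positive integer weights."""

    def __init__(self, pairs: Iterable[Pair],
                 weights: Optional[Dict[Pair, int]] = None):
        self.pairs: Set[Pair] = {canonical_pair(*p) for p in pairs}
        if weights is not None:
            weights = {canonical_pair(*p): int(w) for p, w in weights.items()}
            missing = set(weights) - self.pairs
            if missing:
                raise ValueError(f"weights for unknown pairs: {sorted(missing)[:5]}")
            bad = [p for p, w in weights.items() if w < 1]
            if bad:
                raise ValueError(f"non-positive weight on {bad[0]}")
        self.weights: Optional[Dict[Pair, int]] = weights

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in self.pairs

    def __iter__(self) -> Iterator[Pair]:
        return iter(sorted(self.pairs))

    def index_arrays(self, nodes: NodeTable) -> Tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as node-order index arrays (i < j), sorted."""
        if not self.pairs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        idx = np.array(sorted(
            tuple(sorted((nodes.index(u), nodes.index(v)))) for u, v in self.pairs
        ), dtype=np.int64)
        return idx[:, 0], idx[:, 1]

    def condensed_mask(self, nodes: NodeTable) -> np.ndarray:
        """Boolean vector over the n(n-1)/2 pairs in condensed (pdist) order."""
        n = len(nodes)
        mask = np.zeros(n * (n - 1) // 2, dtype=bool)
        u, v = self.index_arrays(nodes)
        mask[condensed_index(u, v, n)] = True
        return mask


def condensed_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Condensed (scipy pdist order) index of pairs with i < j."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    return i * n - i * (i + 1) // 2 + j - i - 1


@dataclass
class SpatialNetwork:
    """Undirected spatial network: a NodeTable plus an EdgeList."""

    nodes: NodeTable
    edges: EdgeList

    def __post_init__(self):
        for u, v in self.edges.pairs:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint {u if u not in self.nodes else v!r}"
                                 " missing from node table")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Degree of every node (isolated nodes included), node order."""
        k = np.zeros(len(self.nodes), dtype=np.int64)
        u, v = self.edges.index_arrays(self.nodes)
        np.add.at(k, u, 1)
        np.add.at(k, v, 1)
        return k

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix (symmetric, zero diagonal)."""
        n = len(self.nodes)
        a = np.zeros((n, n), dtype=bool)
        u, v = self.edges.index_arrays(self.nodes)
        a[u, v] = True
        a[v, u] = True
        return a

    def wiring_length(self) -> float:
        """Total edge length L = sum of pair distances, soma-size units."""
        u, v = self.edges.index_arrays(self.nodes)
        d = np.linalg.norm(self.nodes.positions[u] - self.nodes.positions[v],
                           axis=1)
        return float(d.sum() / self.nodes.soma_size_unit)


@dataclass
class MultilayerConnectome:
    """Connectome/contactome pair on one node set; connectome ⊆ contactome."""

    connectome: SpatialNetwork
    contactome: SpatialNetwork

    def __post_init__(self):
        report = validate_multilayer(self.connectome, self.contactome)
        if report.violations:
            raise ValueError(
                f"{len(report.violations)} connectome edges missing from the "
                f"contactome, e.g. {sorted(report.violations)[:3]}")


@dataclass
class MultilayerReport:
    violations: Set[Pair]
    coverage: float

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps({
            "coverage": self.coverage,
            "n_violations": len(self.violations),
            "violations": sorted(map(list, self.violations)),
        })


def validate_multilayer(conn: SpatialNetwork,
                        cont: SpatialNetwork) -> MultilayerReport:
    """Check the subset invariant: every synaptic edge is a contact edge.

    Returns the synaptic edges absent from the contactome and the covered
    fraction (1.0 for an empty connectome).
    """
    if conn.nodes.ids != cont.nodes.ids:
        raise ValueError("connectome and contactome node sets differ")
    violations = conn.edges.pairs - cont.edges.pairs
    n = len(conn.edges)
    coverage = 1.0 if n == 0 else 1.0 - len(violations) / n
    return MultilayerReport(violations=violations, coverage=coverage)


def pairwise_distances(nodes: NodeTable,
                       block_size: int = 256) -> Iterator[Tuple[Pair, float]]:
    """Stream all unordered pair distances in soma-size units.

    Yields ((id_i, id_j), d) for every i < j in sorted-id order, exactly
    once, computing distances in row blocks so the full N×N matrix is never
    materialised (peak working set O(block_size · N)).
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = len(nodes)
    pos = nodes.positions
    unit = nodes.soma_size_unit
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = cdist(pos[start:stop], pos) / unit
        for i in range(start, stop):
            row = block[i - start]
            for j in range(i + 1, n):
                yield (nodes.ids[i], nodes.ids[j]), float(row[j])


def condensed_distances(nodes: NodeTable) -> np.ndarray:
    """All-pairs distances in soma-size units, condensed (pdist) order."""
    return pdist(nodes.positions) / nodes.soma_size_unit


# ---------------------------------------------------------------------------
# File I/O: delimited node tables and edge lists
# ---------------------------------------------------------------------------

_UNIT_TO_UM = {"um": 1.0, "nm": 1e-3, "mm": 1e3}


def load_node_table(path, soma_size_unit: Optional[float] = None,
                    unit: str = "um") -> NodeTable:
    """Read a delimited node table with columns id, x, y, z.

    ``unit`` declares the coordinate unit of the file (um, nm or mm);
    positions are converted to μm for storage.
    """
    if unit not in _UNIT_TO_UM:
        raise ValueError(f"unknown coordinate unit {unit!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["id", "x", "y", "z"]
    if not all(c in df.columns for c in required):
        raise ValueError(f"node table must have columns {required}")
    ids = df["id"].astype(str).tolist()
    dupes = df["id"][df["id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate node id {dupes.iloc[0]!r}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric coordinate at row {row}")
    positions = coords.to_numpy(dtype=float) * _UNIT_TO_UM[unit]
    return NodeTable(ids, positions,
                     soma_size_unit=1.0 if soma_size_unit is None
                     else soma_size_unit)


def save_node_table(nodes: NodeTable, path) -> None:
    df = pd.DataFrame({"id": nodes.ids,
                       "x": nodes.positions[:, 0],
                       "y": nodes.positions[:, 1],
                       "z": nodes.positions[:, 2]})
    df.to_csv(path, index=False)


def load_edge_list(path, nodes: NodeTable, weighted: bool = False) -> EdgeList:
    """Read a delimited edge list (columns u, v and optionally weight).

    Rows are deduplicated as unordered pairs. Duplicate weighted rows are
    summed (synapse lists enumerate individual synapses); duplicate
    unweighted rows collapse silently with a logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"u", "v"} <= set(df.columns):
        raise ValueError("edge list must have columns u, v")
    if weighted and "weight" not in df.columns:
        raise ValueError("weighted=True but no weight column")
    pairs: Set[Pair] = set()
    weights: Dict[Pair, int] = {}
    n_dup = 0
    for row in df.itertuples(index=False):
        u, v = str(row.u), str(row.v)
        if u not in nodes or v not in nodes:
            missing = u if u not in nodes else v
            raise ValueError(f"edge endpoint {missing!r} not in node table")
        p = canonical_pair(u, v)
        if p in pairs:
            n_dup += 1
        pairs.add(p)
        if weighted:
            w = int(row.weight)
            if w < 1:
                raise ValueError(f"non-positive weight on edge {p}")
            weights[p] = weights.get(p, 0) + w
    if n_dup and not weighted:
        logger.info("collapsed %d duplicate edge rows", n_dup)
    return EdgeList(pairs, weights if weighted else None)


def save_edge_list(edges: EdgeList, path) -> None:
    if edges.weights is not None:
        df = pd.DataFrame(
            [(u, v, edges.weights[(u, v)]) for u, v in sorted(edges.pairs)],
            columns=["u", "v", "weight"])
    else:
        df = pd.DataFrame(sorted(edges.pairs), columns=["u", "v"])
    df.to_csv(path, index=False)
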