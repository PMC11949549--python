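"""Contact-network (contactome) construction from per-neuron point clouds.

Each neuron surface is represented by a point cloud (mesh vertices or
surface samples, μm). A pair of neurons is a contact candidate with
minimum inter-cloud distance d_min; the contactome keeps pairs with
d_min strictly below a threshold chosen so that a target fraction
(default 99%) of the synaptic edges is covered, rounded up to the next
integer nanometre. The remaining synaptic edges are then added, making
the connectome a subnetwork of the contactome by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor, isfinite
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import (EdgeList, MultilayerConnectome, NodeTable, Pair,
                   SpatialNetwork, canonical_pair)

NM_PER_UM = 1000.0


@dataclass
class PointCloud:
    """Surface samples of one neuron, μm coordinates."""

    node_id: str
    points: np.ndarray  # (m, 3)

    def __post_init__(self):
        self.node_id = str(self.node_id)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (m, 3) array")
        if len(self.points) < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite point coordinate")


@dataclass(frozen=True)
class ContactCandidate:
    """A node pair with its minimum inter-cloud distance in nm."""

    pair: Pair
    d_min: float


def center_of_mesh(cloud: PointCloud) -> np.ndarray:
    """Arithmetic mean of the surface points (the node position), μm."""
    return cloud.points.mean(axis=0)


def min_cloud_distance(a: PointCloud, b: PointCloud) -> float:
    """Exact smallest distance between two point clouds, in nm.

    KD-tree nearest-neighbour queries from the smaller cloud into the
    larger one; exact, no approximation.
    """
    small, large = (a, b) if len(a.points) <= len(b.points) else (b, a)
    tree = cKDTree(large.points)
    d, _ = tree.query(small.points, k=1)
    return float(d.min() * NM_PER_UM)


def select_contact_threshold(candidates: Iterable[ContactCandidate],
                             synaptic_pairs: Iterable[Pair],
                             coverage: float = 0.99) -> int:
    """Smallest integer-nm threshold covering the target synaptic fraction.

    Returns the least integer t such that at least ``coverage`` of the
    synaptic pairs satisfy d_min < t (strict inequality, matching the
    contact rule); equivalently the minimal real threshold rounded up to
    the next nanometre.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    dmin: Dict[Pair, float] = {c.pair: c.d_min for c in candidates}
    syn = [canonical_pair(*p) for p in synaptic_pairs]
    if not syn:
        raise ValueError("no synaptic pairs given")
    missing = [p for p in syn if p not in dmin]
    if missing:
        raise ValueError(f"synaptic pairs without a contact candidate: "
                         f"{missing[:5]}")
    values = np.sort([dmin[p] for p in syn])
    m = ceil(coverage * len(values))  # this many must lie strictly below t
    quantile = values[m - 1]
    if not isfinite(quantile):
        raise ValueError("coverage unattainable: required quantile of "
                         "d_min is not finite")
    return int(floor(quantile)) + 1


def assemble_contactome(candidates: Iterable[ContactCandidate],
                        threshold: float,
                        synaptic_edges: EdgeList,
                        nodes: NodeTable) -> MultilayerConnectome:
    """Build the contactome and pair it with the connectome.

    Contact edges are the candidate pairs with d_min strictly below the
    threshold (nm), united with all synaptic edges (the forced top-up for
    any uncovered ones), so the subset invariant holds exactly.
    """
    contact_pairs: Set[Pair] = {c.pair for c in candidates
                                if c.d_min < threshold}
    contact_pairs |= synaptic_edges.pairs
    contactome = SpatialNetwork(nodes, EdgeList(contact_pairs))
    connectome = SpatialNetwork(nodes, EdgeList(synaptic_edges.pairs,
                                                synaptic_edges.weights))
    return MultilayerConnectome(connectome=connectome, contactome=contactome)


def contact_candidates(clouds: Dict[str, PointCloud],
                       max_center_distance_um: Optional[float] = None
                       ) -> list:
    """Minimum inter-cloud distance for every cloud pair.

    ``max_center_distance_um`` prunes pairs whose cloud centers are too
    far apart to ever touch (a speed-up; pruned pairs are simply absent).
    """
    ids = sorted(clouds)
    centers = {i: center_of_mesh(clouds[i]) for i in ids}
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            u, v = ids[a], ids[b]
            if max_center_distance_um is not None:
                if np.linalg.norm(centers[u] - centers[v]
                                  ) > max_center_distance_um:
                    continue
            out.append(ContactCandidate(
                pair=canonical_pair(u, v),
                d_min=min_cloud_distance(clouds[u], clouds[v])))
    return out
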