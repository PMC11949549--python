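"""Seeded synthetic multilayer scenarios with planted ground truth.

The generators emulate the structure of volumetric connectome data: 3D
neuron positions in a (optionally anisotropic) box, a contactome whose
connection probability decays exponentially with distance, a connectome
that is a subset of the contactome with heterogeneous (broad,
non-power-law) node propensities, heavy-tailed positive integer synapse
counts that rise with edge probability, and per-neuron surface point
clouds (a dense soma shell plus sparse neurite samples).

Default parameters mirror the observed scales of real connectomes when
distances are read in soma-size units: contact decay scale ~12 soma
sizes, a connectome-to-contactome edge fraction of 0.25, and a
log-normal propensity spread of 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from .core import EdgeList, NodeTable, SpatialNetwork

DEFAULT_BOX = (100.0, 100.0, 100.0)
DEFAULT_D0_CONTACT = 12.0
DEFAULT_FRACTION = 0.25
DEFAULT_HETEROGENEITY = 1.0


@dataclass
class SyntheticScenario:
    """A planted multilayer scenario with its ground truth."""

    seed: int
    nodes: NodeTable
    contactome: SpatialNetwork
    connectome: SpatialNetwork
    x_true: np.ndarray                 # node propensities of the subset law
    d0_contact: float
    weights: Optional[Dict[Tuple[str, str], int]] = None
    clouds: Optional[Dict[str, "object"]] = None
    contact_threshold_nm: Optional[float] = None
    candidates: Optional[list] = None      # ContactCandidate list, if clouds


def _ids(n: int) -> list:
    return [f"n{i:05d}" for i in range(n)]


def generate_positions(n: int, box: Tuple[float, float, float] = DEFAULT_BOX,
                       anisotropy: Tuple[float, float, float] = (1, 1, 1),
                       seed: int = 0) -> NodeTable:
    """Uniform node positions in an anisotropically scaled box (μm)."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    extents = np.asarray(box, dtype=float) * np.asarray(anisotropy,
                                                        dtype=float)
    pos = rng.random((n, 3)) * extents
    return NodeTable(_ids(n), pos)


def plant_contactome(nodes: NodeTable, d0_c: float = DEFAULT_D0_CONTACT,
                     density_scale: float = 1.0, seed: int = 0
                     ) -> SpatialNetwork:
    """Distance-decaying random contact network.

    Each pair is an edge independently with probability
    min(1, density_scale * exp(-d/d0_c)), so the binned connection
    probability of the output decays exponentially with scale ~ d0_c.
    """
    if not d0_c > 0:
        raise ValueError("d0_c must be positive")
    rng = np.random.default_rng(seed)
    d = pdist(nodes.positions) / nodes.soma_size_unit
    p = np.minimum(1.0, density_scale * np.exp(-d / d0_c))
    hit = rng.random(len(p)) < p
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    edges = EdgeList((nodes.ids[i], nodes.ids[j])
                     for i, j in zip(iu[hit], ju[hit]))
    return SpatialNetwork(nodes, edges)


def plant_connectome(contactome: SpatialNetwork,
                     heterogeneity: float = DEFAULT_HETEROGENEITY,
                     fraction: float = DEFAULT_FRACTION,
                     seed: int = 0) -> Tuple[SpatialNetwork, np.ndarray]:
    """Keep each contact edge with probability 1/(1 + x_i x_j).

    x_true is log-normal with spread ``heterogeneity`` (sigma of log x),
    rescaled by a root solve so the expected kept fraction over contact
    edges equals ``fraction``. heterogeneity = 0 reduces to a uniform
    random subset; heterogeneity > 0 yields broad degrees and a
    superlinear relation between connectome and contactome degrees.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be nonnegative")
    rng = np.random.default_rng(seed)
    nodes = contactome.nodes
    n = len(nodes)
    if fraction == 1.0:
        full = SpatialNetwork(nodes, EdgeList(contactome.edges.pairs))
        return full, np.zeros(n)
    base = rng.lognormal(mean=0.0, sigma=heterogeneity, size=n) \
        if heterogeneity > 0 else np.ones(n)
    u, v = contactome.edges.index_arrays(nodes)
    prod = base[u] * base[v]

    def kept(log_c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(log_c) * prod))) - fraction

    # mean keep prob is monotone decreasing in the scale c
    log_c = brentq(kept, -80.0, 80.0, xtol=1e-12)
    x_true = np.exp(0.5 * log_c) * base
    keep_p = 1.0 / (1.0 + x_true[u] * x_true[v])
    hit = rng.random(len(keep_p)) < keep_p
    edges = EdgeList((nodes.ids[i], nodes.ids[j])
                     for i, j in zip(u[hit], v[hit]))
    return SpatialNetwork(nodes, edges), x_true


def generate_weights(connectome: SpatialNetwork, p_true: np.ndarray,
                     seed: int = 0, scale: float = 20.0,
                     sigma: float = 1.0) -> Dict[Tuple[str, str], int]:
    """Heavy-tailed synapse counts rising with edge probability.

    For edge e with planted probability p_e, the count is
    w = 1 + floor(LogNormal(ln(scale * p_e), sigma)), guaranteeing
    w >= 1 and a positive rank association between p and w.
    """
    p_true = np.asarray(p_true, dtype=float)
    if np.any((p_true <= 0) | (p_true > 1)):
        raise ValueError("p_true must lie in (0, 1]")
    pairs = sorted(connectome.edges.pairs)
    if len(pairs) != len(p_true):
        raise ValueError("p_true must have one entry per connectome edge")
    rng = np.random.default_rng(seed)
    draw = rng.lognormal(mean=np.log(scale * p_true), sigma=sigma)
    w = 1 + np.floor(draw).astype(int)
    return {pair: int(wi) for pair, wi in zip(pairs, w)}


def generate_point_clouds(nodes: NodeTable, soma_radius_um: float = 2.5,
                          neurite_extent_um: float = 15.0,
                          points_per_node: int = 300,
                          seed: int = 0) -> Dict[str, "object"]:
    """Surface point clouds: a dense soma shell plus sparse neurite tips.

    80% of the points sample a sphere of radius ``soma_radius_um`` around
    the node position; the rest sit at uniform radii out to
    ``neurite_extent_um``. The center-to-contact distance sample of such
    clouds has its density peak near the soma radius.
    """
    from .contact import PointCloud

    if not (soma_radius_um > 0 and neurite_extent_um > soma_radius_um):
        raise ValueError("need 0 < soma_radius < neurite_extent")
    rng = np.random.default_rng(seed)
    clouds: Dict[str, PointCloud] = {}
    n_soma = int(0.8 * points_per_node)
    n_far = points_per_node - n_soma
    for i, nid in enumerate(nodes.ids):
        center = nodes.positions[i]
        dirs = rng.normal(size=(points_per_node, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = np.concatenate([
            np.full(n_soma, soma_radius_um),
            rng.uniform(soma_radius_um, neurite_extent_um, size=n_far),
        ])
        clouds[nid] = PointCloud(nid, center + dirs * radii[:, None])
    return clouds


def generate_scenario(n: int = 500, seed: int = 0,
                      box: Tuple[float, float, float] = DEFAULT_BOX,
                      anisotropy: Tuple[float, float, float] = (1, 1, 1),
                      d0_contact: float = DEFAULT_D0_CONTACT,
                      density_scale: float = 1.0,
                      fraction: float = DEFAULT_FRACTION,
                      heterogeneity: float = DEFAULT_HETEROGENEITY,
                      with_weights: bool = True) -> SyntheticScenario:
    """Planted multilayer scenario: positions, contactome ⊇ connectome.

    Sub-seeds are derived deterministically from ``seed`` for each stage,
    so the whole scenario is reproducible from the one integer.
    """
    nodes = generate_positions(n, box=box, anisotropy=anisotropy, seed=seed)
    contactome = plant_contactome(nodes, d0_c=d0_contact,
                                  density_scale=density_scale, seed=seed + 1)
    connectome, x_true = plant_connectome(contactome,
                                          heterogeneity=heterogeneity,
                                          fraction=fraction, seed=seed + 2)
    weights = None
    if with_weights and len(connectome.edges):
        u, v = connectome.edges.index_arrays(nodes)
        keep_p = 1.0 / (1.0 + x_true[u] * x_true[v])
        # index_arrays order matches sorted pairs in generate_weights
        order = np.argsort([f"{nodes.ids[i]}|{nodes.ids[j]}"
                            for i, j in zip(u, v)])
        pairs_sorted_p = keep_p[order]
        weights = generate_weights(connectome, pairs_sorted_p, seed=seed + 3)
    return SyntheticScenario(seed=seed, nodes=nodes, contactome=contactome,
                             connectome=connectome, x_true=x_true,
                             d0_contact=d0_contact, weights=weights)


def generate_cloud_scenario(n: int = 60, seed: int = 0,
                            box: Tuple[float, float, float] = (40.0, 40.0,
                                                               40.0),
                            soma_radius_um: float = 2.5,
                            neurite_extent_um: float = 15.0,
                            points_per_node: int = 300,
                            contact_quantile: float = 0.15,
                            synapse_fraction: float = 0.5
                            ) -> SyntheticScenario:
    """Scenario with point clouds for the contactome-construction pipeline.

    All-pairs minimum inter-cloud distances are computed; the pairs below
    the ``contact_quantile`` of that distribution form the true contact
    set, and a random ``synapse_fraction`` of those become synaptic
    edges. The quantile distance (nm) is recorded as the planted contact
    threshold.
    """
    from .contact import contact_candidates

    nodes = generate_positions(n, box=box, seed=seed)
    clouds = generate_point_clouds(nodes, soma_radius_um=soma_radius_um,
                                   neurite_extent_um=neurite_extent_um,
                                   points_per_node=points_per_node,
                                   seed=seed + 1)
    candidates = contact_candidates(clouds)
    dmin = np.array([c.d_min for c in candidates])
    t_true = float(np.quantile(dmin, contact_quantile))
    contact_pairs = [c.pair for c in candidates if c.d_min < t_true]
    rng = np.random.default_rng(seed + 2)
    hit = rng.random(len(contact_pairs)) < synapse_fraction
    syn_pairs = [p for p, h in zip(contact_pairs, hit) if h]
    if not syn_pairs:
        raise ValueError("no synaptic edges planted; enlarge the scenario")
    contactome = SpatialNetwork(nodes, EdgeList(contact_pairs))
    connectome = SpatialNetwork(nodes, EdgeList(syn_pairs))
    return SyntheticScenario(seed=seed, nodes=nodes, contactome=contactome,
                             connectome=connectome,
                             x_true=np.ones(len(nodes)),
                             d0_contact=float("nan"), clouds=clouds,
                             contact_threshold_nm=t_true,
                             candidates=candidates)
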