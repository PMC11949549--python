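"""Distance-dependence and spatial-scale estimation.

Connection probability p(d) is measured as the connected fraction of node
pairs per linear distance bin. Assuming p(d) = alpha * exp(-d/d0), the
decay scale d0 is estimated by count-weighted least squares on ln p_b.
The finite extent of an experimental volume distorts p(d) at large d; the
cutoff d_fs is taken at the mode of the all-pairs distance histogram.
Soma radii are estimated as the peak of a triangular-kernel density of
center-to-contact distances, and define the soma-size distance unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.neighbors import KernelDensity

from .core import EdgeList, NodeTable, condensed_distances
from .models import DistanceBinTable, bin_pair_distances

logger = logging.getLogger(__name__)


@dataclass
class DistanceDependence:
    """Binned connection-probability curve plus its finite-size cutoff."""

    bin_table: DistanceBinTable
    d_fs: float
    source: str = "connectome"  # or "contactome", "conditional-on-contact"

    def __post_init__(self):
        if not self.d_fs > 0:
            raise ValueError("finite-size cutoff must be positive")


@dataclass
class ExponentialFit:
    """p(d) = alpha * exp(-d / d0) fitted over eligible bins."""

    d0: float
    alpha: float
    fit_range: Tuple[float, float]
    min_edges_per_bin: int
    n_bins_used: int

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("decay scale d0 must be positive")


@dataclass
class DirectionalFit:
    """Per-principal-axis decay scales of connection probability.

    ``axes`` rows are orthonormal and ordered by decreasing positional
    variance, so d_axis[0] is the scale along the dominant alignment
    direction.
    """

    axes: np.ndarray            # (3, 3), rows are unit vectors
    d_axis: Tuple[float, float, float]
    variances: Tuple[float, float, float]


def binned_connection_probability(nodes: NodeTable, edges: EdgeList,
                                  n_bins: int = 50,
                                  restrict_to: Optional[EdgeList] = None
                                  ) -> DistanceBinTable:
    """Fraction of node pairs connected, per linear distance bin.

    ``restrict_to`` limits both numerator and denominator to a pair subset
    (e.g. contact pairs), yielding the conditional connection curve.
    """
    d = condensed_distances(nodes)
    edge_mask = edges.condensed_mask(nodes)
    keep = None
    if restrict_to is not None:
        keep = restrict_to.condensed_mask(nodes)
    return bin_pair_distances(d, edge_mask, n_bins=n_bins, restrict_to=keep)


def fit_exponential(dd, fit_range: Optional[Tuple[float, float]] = None,
                    min_edges_per_bin: int = 10) -> ExponentialFit:
    """Weighted least-squares fit of ln p_b against bin centers.

    Accepts a DistanceDependence (whose d_fs caps the default fit range)
    or a bare DistanceBinTable. Only bins with at least
    ``min_edges_per_bin`` edges and p_b > 0 participate; weights are the
    per-bin edge counts.
    """
    if isinstance(dd, DistanceDependence):
        table = dd.bin_table
        default_hi = dd.d_fs
    else:
        table = dd
        default_hi = float(table.bin_edges[-1])
    lo, hi = fit_range if fit_range is not None else (0.0, default_hi)
    centers = table.centers
    p = table.p
    eligible = ((table.n_edges >= min_edges_per_bin) & (p > 0)
                & (centers >= lo) & (centers <= hi))
    if eligible.sum() < 2:
        raise ValueError(f"only {int(eligible.sum())} eligible bins; "
                         "need at least 2 to fit an exponential")
    xs = centers[eligible]
    ys = np.log(p[eligible])
    w = np.sqrt(table.n_edges[eligible].astype(float))
    slope, intercept = np.polyfit(xs, ys, 1, w=w)
    if slope >= 0:
        raise ValueError("connection probability does not decay with "
                         "distance; no exponential scale")
    return ExponentialFit(d0=-1.0 / slope, alpha=float(np.exp(intercept)),
                          fit_range=(float(lo), float(hi)),
                          min_edges_per_bin=min_edges_per_bin,
                          n_bins_used=int(eligible.sum()))


def finite_size_threshold(nodes: NodeTable, n_bins: int = 50) -> float:
    """Mode of the all-pairs distance histogram (soma-size units).

    Distances past this cutoff are increasingly depleted by the bounded
    experimental volume, so p(d) fits should stop here. Ties resolve to
    the smaller distance.
    """
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes")
    d = condensed_distances(nodes)
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, d.max()))
    b = int(np.argmax(counts))  # argmax takes the first (smaller) tie
    return float(0.5 * (edges[b] + edges[b + 1]))


def soma_size_estimate(contact_distances: np.ndarray, bandwidth: float,
                       ) -> float:
    """Peak of a triangular-kernel density of center-to-contact distances.

    Returns the estimated soma radius in the unit of the input sample
    (μm). Grid resolution is bandwidth/10; ties go to the smaller mode.
    """
    x = np.asarray(contact_distances, dtype=float).ravel()
    if len(x) < 50:
        raise ValueError("need at least 50 contact-distance samples")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    kde = KernelDensity(kernel="linear", bandwidth=bandwidth)
    kde.fit(x[:, None])
    grid = np.arange(max(x.min() - bandwidth, 0.0), x.max() + bandwidth,
                     bandwidth / 10.0)
    dens = kde.score_samples(grid[:, None])
    peak = int(np.argmax(dens))
    ties = np.flatnonzero(np.isclose(dens, dens[peak]))
    if len(ties) > 1:
        logger.info("density peak tie over %d grid points; smallest taken",
                    len(ties))
    return float(grid[ties[0]])


def principal_axes(nodes: NodeTable) -> Tuple[np.ndarray, np.ndarray]:
    """Orthonormal principal axes of the position cloud, variance-ordered."""
    pos = nodes.positions - nodes.positions.mean(axis=0)
    cov = pos.T @ pos / max(len(nodes) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate position covariance (coplanar nodes)")
    return evecs.T, evals


def directional_dependence(nodes: NodeTable, edges: EdgeList,
                           n_bins: int = 50,
                           min_edges_per_bin: int = 10) -> DirectionalFit:
    """Exponential decay scale of p per principal axis of the node cloud.

    For each axis the pair separation is the absolute projected offset
    |delta position . axis| (soma-size units); connection probability is
    binned against it and fitted with :func:`fit_exponential` over the
    full projected range.
    """
    if len(nodes) < 4:
        raise ValueError("need at least 4 nodes")
    axes, evals = principal_axes(nodes)
    pos = nodes.positions / nodes.soma_size_unit
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    delta = pos[iu] - pos[ju]
    edge_mask = edges.condensed_mask(nodes)
    scales = []
    for axis in axes:
        d_axis = np.abs(delta @ axis)
        table = bin_pair_distances(d_axis, edge_mask, n_bins=n_bins)
        fit = fit_exponential(table, fit_range=(0.0, float(d_axis.max())),
                              min_edges_per_bin=min_edges_per_bin)
        scales.append(fit.d0)
    return DirectionalFit(axes=axes, d_axis=tuple(scales),
                          variances=tuple(float(v) for v in evals))
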