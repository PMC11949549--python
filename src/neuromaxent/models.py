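"""Canonical maximum-entropy ensembles for spatial neural networks.

Six model kinds are supported, named after their constraints:

==========  =====================================================  ==========
kind        soft constraints                                       hard mask
==========  =====================================================  ==========
``d``       binned connection probability vs distance p(d)         no
``k``       expected degree sequence (soft configuration model)    no
``k+L``     expected degrees and expected total wiring length L    no
``c``       expected number of edges                               contactome
``d+c``     binned p(d) conditional on contact                     contactome
``k+c``     expected degree sequence                               contactome
==========  =====================================================  ==========

Every model defines independent edge probabilities p_ij, so ensembles are
sampled directly, edge by edge, without Markov-chain Monte Carlo. Degree
models use x_i = e^{theta_i} (exponentiated Lagrange multipliers) with

    p_ij = 1 / (1 + x_i x_j)                      (k, k+c)
    p_ij = 1 / (1 + x_i x_j e^{d_ij/d0})          (k+L)

fitted by the standard fixed-point iteration on x. The hard contact mask
forces p_ij = 0 outside the contactome.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import EdgeList, NodeTable, SpatialNetwork, condensed_index

logger = logging.getLogger(__name__)

_X_FLOOR = 1e-150
_X_CEIL = 1e150
_EXP_MAX = 700.0  # exp argument clip; beyond this p underflows to 0 anyway

KINDS = ("d", "k", "k+L", "c", "d+c", "k+c")


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


class InfeasibleConstraintsError(ValueError):
    """Constraint set cannot be realised by any ensemble."""


@dataclass
class DistanceBinTable:
    """Binned connection probability: p_b = n_edges_b / n_pairs_b.

    Bins are half-open [lo, hi) with the last bin closed; a queried
    distance beyond the final edge is assigned the last bin (with a
    warning at scoring time).
    """

    bin_edges: np.ndarray
    n_pairs: np.ndarray
    n_edges: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        self.n_edges = np.asarray(self.n_edges, dtype=np.int64)
        if len(self.bin_edges) != len(self.n_pairs) + 1:
            raise ValueError("bin_edges must have len(n_pairs)+1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.n_edges > self.n_pairs):
            raise ValueError("n_edges_b cannot exceed n_pairs_b")

    @property
    def n_bins(self) -> int:
        return len(self.n_pairs)

    @property
    def p(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.n_pairs > 0,
                           self.n_edges / np.maximum(self.n_pairs, 1), 0.0)
        return out

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def assign(self, distances: np.ndarray, warn: bool = True) -> np.ndarray:
        """Bin index for each distance (last bin for out-of-range values)."""
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(self.bin_edges, d, side="right") - 1
        beyond = d >= self.bin_edges[-1]
        if warn and np.any(d > self.bin_edges[-1]):
            warnings.warn("distances beyond the last bin edge assigned to "
                          "the last bin", stacklevel=2)
        idx[beyond] = self.n_bins - 1
        idx[d < self.bin_edges[0]] = 0
        return idx


def _linear_bins(d_max: float, n_bins: int) -> np.ndarray:
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    hi = d_max if d_max > 0 else 1.0
    return np.linspace(0.0, hi, n_bins + 1)


def bin_pair_distances(distances: np.ndarray, edge_mask: np.ndarray,
                       n_bins: int = 50,
                       restrict_to: Optional[np.ndarray] = None,
                       bin_edges: Optional[np.ndarray] = None
                       ) -> DistanceBinTable:
    """Build a DistanceBinTable from condensed pair distances and edges.

    ``restrict_to`` (condensed boolean) limits both the pair denominator
    and the edge numerator to a pair subset, e.g. contact pairs.
    """
    d = np.asarray(distances, dtype=float)
    e = np.asarray(edge_mask, dtype=bool)
    if restrict_to is not None:
        keep = np.asarray(restrict_to, dtype=bool)
        d, e = d[keep], e[keep]
    if bin_edges is None:
        bin_edges = _linear_bins(d.max() if d.size else 1.0, n_bins)
    table = DistanceBinTable(bin_edges, np.zeros(len(bin_edges) - 1),
                             np.zeros(len(bin_edges) - 1))
    idx = table.assign(d, warn=False)
    table.n_pairs = np.bincount(idx, minlength=table.n_bins).astype(np.int64)
    table.n_edges = np.bincount(idx[e], minlength=table.n_bins).astype(np.int64)
    return table


@dataclass
class FittedEnsemble:
    """A fitted maximum-entropy ensemble with independent edge probabilities.

    The Boltzmann weight e^{-H(G)}/Z is never materialised; everything
    (sampling, likelihoods, expectations) is computed from p_ij directly.
    """

    kind: str
    node_ids: Tuple[str, ...]
    x: Optional[np.ndarray] = None          # e^{theta_i}; inf where k*=0
    d0: Optional[float] = None              # soma-size units, kind k+L
    bin_table: Optional[DistanceBinTable] = None  # kinds d, d+c
    uniform_p: Optional[float] = None       # kind c
    hard_mask: Optional[np.ndarray] = None  # condensed bool, allowed pairs
    forced_mask: Optional[np.ndarray] = None  # condensed bool, p = 1 exactly
    distances: Optional[np.ndarray] = None  # condensed, soma-size units
    n_iterations: int = 0
    residual: float = 0.0
    boundary_nodes: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def _require_distances(self, distances):
        d = distances if distances is not None else self.distances
        if d is None:
            raise ValueError(f"model {self.kind!r} needs pair distances")
        return np.asarray(d, dtype=float)

    def probabilities(self, distances: Optional[np.ndarray] = None
                      ) -> np.ndarray:
        """Edge probability for every unordered pair, condensed order."""
        n = self.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        if self.kind in ("k", "k+c"):
            with np.errstate(over="ignore"):
                p = 1.0 / (1.0 + self.x[iu] * self.x[ju])
        elif self.kind == "k+L":
            d = self._require_distances(distances)
            with np.errstate(over="ignore"):
                w = np.exp(np.minimum(d / self.d0, _EXP_MAX))
                p = 1.0 / (1.0 + self.x[iu] * self.x[ju] * w)
        elif self.kind in ("d", "d+c"):
            d = self._require_distances(distances)
            if self.hard_mask is not None:
                # assign bins for allowed pairs only; the rest are zeroed
                p = np.zeros(len(d))
                p[self.hard_mask] = self.bin_table.p[
                    self.bin_table.assign(d[self.hard_mask])]
            else:
                p = self.bin_table.p[self.bin_table.assign(d)]
        elif self.kind == "c":
            p = np.full(n * (n - 1) // 2, self.uniform_p)
        if self.hard_mask is not None:
            p = np.where(self.hard_mask, p, 0.0)
        if self.forced_mask is not None:
            p = np.where(self.forced_mask, 1.0, p)
        return p

    def expected_degrees(self, distances: Optional[np.ndarray] = None
                         ) -> np.ndarray:
        p = self.probabilities(distances)
        n = self.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        k = np.zeros(n)
        np.add.at(k, iu, p)
        np.add.at(k, ju, p)
        return k

    def expected_edge_count(self, distances: Optional[np.ndarray] = None
                            ) -> float:
        return float(self.probabilities(distances).sum())

    def expected_wiring_length(self, distances: Optional[np.ndarray] = None
                               ) -> float:
        d = self._require_distances(distances)
        return float((self.probabilities(d) * d).sum())

    # -- single-pair interface ------------------------------------------
    def edge_probability(self, pair: Tuple[str, str],
                         distance: Optional[float] = None) -> float:
        """p_ij for one unordered pair (symmetric, deterministic)."""
        u, v = str(pair[0]), str(pair[1])
        ids = self.node_ids
        try:
            i, j = ids.index(u), ids.index(v)
        except ValueError as err:
            raise KeyError(f"pair {pair} outside the model node set") from err
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        ci = condensed_index(np.array([i]), np.array([j]), self.n_nodes)[0]
        if self.forced_mask is not None and self.forced_mask[ci]:
            return 1.0
        if self.hard_mask is not None and not self.hard_mask[ci]:
            return 0.0
        if self.kind in ("k", "k+c"):
            return float(1.0 / (1.0 + self.x[i] * self.x[j]))
        if self.kind == "c":
            return float(self.uniform_p)
        if distance is None:
            if self.distances is None:
                raise ValueError("distance required for kind "
                                 f"{self.kind!r}")
            distance = float(self.distances[ci])
        if self.kind == "k+L":
            w = np.exp(min(distance / self.d0, _EXP_MAX))
            return float(1.0 / (1.0 + self.x[i] * self.x[j] * w))
        b = self.bin_table.assign(np.array([distance]))[0]
        return float(self.bin_table.p[b])

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {"kind": self.kind, "node_ids": list(self.node_ids)}
        if self.x is not None:
            d["x"] = [None if not np.isfinite(v) else float(v)
                      for v in self.x]
        if self.d0 is not None:
            d["d0"] = float(self.d0)
        if self.uniform_p is not None:
            d["uniform_p"] = float(self.uniform_p)
        if self.bin_table is not None:
            d["bin_table"] = {
                "bin_edges": self.bin_table.bin_edges.tolist(),
                "n_pairs": self.bin_table.n_pairs.tolist(),
                "n_edges": self.bin_table.n_edges.tolist(),
            }
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        if self.hard_mask is not None:
            keep = self.hard_mask
            d["hard_mask_pairs"] = [[self.node_ids[i], self.node_ids[j]]
                                    for i, j in zip(iu[keep], ju[keep])]
        if self.forced_mask is not None and self.forced_mask.any():
            keep = self.forced_mask
            d["forced_pairs"] = [[self.node_ids[i], self.node_ids[j]]
                                 for i, j in zip(iu[keep], ju[keep])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedEnsemble":
        node_ids = tuple(d["node_ids"])
        n = len(node_ids)
        x = None
        if "x" in d:
            x = np.array([np.inf if v is None else v for v in d["x"]])
        bt = None
        if "bin_table" in d:
            b = d["bin_table"]
            bt = DistanceBinTable(np.asarray(b["bin_edges"]),
                                  np.asarray(b["n_pairs"]),
                                  np.asarray(b["n_edges"]))
        index = {nid: i for i, nid in enumerate(node_ids)}

        def pairs_to_mask(pairs):
            mask = np.zeros(n * (n - 1) // 2, dtype=bool)
            for u, v in pairs:
                i, j = sorted((index[u], index[v]))
                mask[condensed_index(np.array([i]), np.array([j]), n)[0]] = True
            return mask

        mask = (pairs_to_mask(d["hard_mask_pairs"])
                if "hard_mask_pairs" in d else None)
        forced = (pairs_to_mask(d["forced_pairs"])
                  if "forced_pairs" in d else None)
        return cls(kind=d["kind"], node_ids=node_ids, x=x,
                   d0=d.get("d0"), bin_table=bt,
                   uniform_p=d.get("uniform_p"), hard_mask=mask,
                   forced_mask=forced)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "FittedEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Degree-constrained models (k, k+c) — fixed-point iteration
# ---------------------------------------------------------------------------

def _check_feasible(k_star: np.ndarray, allowed_degree: np.ndarray,
                    node_ids: Sequence[str]) -> None:
    """Raise when any k* exceeds the node's allowed partner count."""
    over = k_star > allowed_degree + 1e-9
    if np.any(over):
        i = int(np.flatnonzero(over)[0])
        raise InfeasibleConstraintsError(
            f"target degree {k_star[i]} of node {node_ids[i]!r} exceeds its "
            f"{int(allowed_degree[i])} allowed partners")


def _peel_boundary(k_star: np.ndarray, allowed: np.ndarray,
                   iu: np.ndarray, ju: np.ndarray,
                   node_ids: Sequence[str]
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve deterministic parts of the degree constraints.

    A node whose residual target equals its remaining partner count can
    only be satisfied with p = 1 on all its pairs (the multiplier
    diverges); one with residual 0 forces p = 0. Both make the interior
    fixed point unreachable, so such nodes are peeled iteratively —
    forcing their pairs and decrementing partner targets — until only an
    interior problem remains.

    Returns (free, residual_targets, remaining_pairs, forced_pairs,
    boundary_flags).
    """
    n = len(k_star)
    free = np.ones(n, dtype=bool)
    remaining = allowed.copy()
    forced = np.zeros_like(allowed)
    at_boundary = np.zeros(n, dtype=bool)
    r = k_star.astype(float).copy()
    while True:
        live = remaining & free[iu] & free[ju]
        deg = np.zeros(n)
        np.add.at(deg, iu[live], 1.0)
        np.add.at(deg, ju[live], 1.0)
        if np.any(r[free] < -1e-9):
            i = int(np.flatnonzero(free)[np.argmin(r[free])])
            raise InfeasibleConstraintsError(
                f"node {node_ids[i]!r}: forced edges exceed its target "
                "degree (constraints unrealisable)")
        over = free & (r > deg + 1e-9)
        if np.any(over):
            i = int(np.flatnonzero(over)[0])
            raise InfeasibleConstraintsError(
                f"target degree {k_star[i]} of node {node_ids[i]!r} exceeds "
                f"its {int(deg[i])} remaining partners")
        zero = free & np.isclose(r, 0.0)
        if np.any(zero):
            free &= ~zero
            continue
        bnd = free & (r > 0) & np.isclose(r, deg)
        if not np.any(bnd):
            return free, r, remaining & free[iu] & free[ju], forced, \
                at_boundary
        at_boundary |= bnd
        fpairs = live & (bnd[iu] | bnd[ju])
        forced |= fpairs
        remaining &= ~fpairs
        dec = np.zeros(n)
        np.add.at(dec, iu[fpairs], 1.0)
        np.add.at(dec, ju[fpairs], 1.0)
        r -= dec
        free &= ~bnd


def fit_degree_model(k_star: Sequence[float],
                     node_ids: Optional[Sequence[str]] = None,
                     hard_mask: Optional[np.ndarray] = None,
                     tol: float = 1e-8,
                     max_iter: int = 10_000) -> FittedEnsemble:
    """Fit the soft configuration model (kind k, or k+c with a mask).

    Solves k_i* = sum_{j != i, allowed} 1/(1 + x_i x_j) by the fixed-point
    update x_i <- (1/k_i*) sum_j 1/(1/x_i + x_j), with 0.5 damping when the
    residual oscillates. Nodes with k_i* = 0 get p_ij = 0 exactly; nodes
    whose target equals their allowed partner count get p_ij = 1 on those
    pairs (reported via ``boundary_nodes``). With a mask, sums run over
    allowed (contact) pairs only and p is zero elsewhere.
    """
    k_star = np.asarray(k_star, dtype=float)
    n = len(k_star)
    if node_ids is None:
        node_ids = [f"n{i:05d}" for i in range(n)]
    node_ids = tuple(str(i) for i in node_ids)
    if np.any(k_star < 0):
        raise ValueError("target degrees must be nonnegative")
    iu, ju = np.triu_indices(n, k=1)
    if hard_mask is None:
        allowed = np.ones(n * (n - 1) // 2, dtype=bool)
    else:
        hard_mask = np.asarray(hard_mask, dtype=bool)
        allowed = hard_mask.copy()
    free, r, live, forced, at_boundary = _peel_boundary(k_star, allowed,
                                                        iu, ju, node_ids)

    x_full = np.full(n, np.inf)
    x_full[at_boundary] = _X_FLOOR
    if np.any(free):
        if hard_mask is None:
            x_full[free] = _solve_k_dense(r[free], tol, max_iter)
        else:
            x = _solve_k_masked(r, free, iu[live], ju[live], tol, max_iter)
            x_full[free] = x[free]

    boundary = [node_ids[i] for i in np.flatnonzero(at_boundary)]
    model = FittedEnsemble(kind="k" if hard_mask is None else "k+c",
                           node_ids=node_ids, x=x_full,
                           hard_mask=hard_mask,
                           forced_mask=forced if forced.any() else None,
                           boundary_nodes=tuple(boundary))
    model.residual = _degree_residual(model.expected_degrees(), k_star)
    return model


def _degree_residual(k_hat: np.ndarray, k_star: np.ndarray) -> float:
    return float(np.max(np.abs(k_hat - k_star) / np.maximum(k_star, 1.0),
                        initial=0.0))


def _init_x(k_star: np.ndarray) -> np.ndarray:
    # x ~ sqrt(sum k)/k gives p_ij ~ k_i k_j / sum(k) for sparse graphs
    return np.clip(np.sqrt(k_star.sum()) / np.maximum(k_star, 1e-12),
                   _X_FLOOR, _X_CEIL)


def _solve_k_dense(k_star: np.ndarray, tol: float, max_iter: int
                   ) -> np.ndarray:
    """Fixed point for model k over the free nodes (all-to-all pairs)."""
    m = len(k_star)
    if m == 0:
        return np.empty(0)
    if m == 1:
        raise InfeasibleConstraintsError(
            "a single node with positive target degree has no partners")
    x = _init_x(k_star)
    prev_res = np.inf
    res = np.inf
    for _ in range(max_iter):
        inv = 1.0 / x
        denom = inv[:, None] + x[None, :]
        s = (1.0 / denom).sum(axis=1) - 1.0 / (inv + x)
        x_new = np.clip(s / k_star, _X_FLOOR, _X_CEIL)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.outer(x_new, x_new))
        np.fill_diagonal(p, 0.0)
        res = _degree_residual(p.sum(axis=1), k_star)
        if res <= tol:
            return x_new
        x = 0.5 * (x + x_new) if res > prev_res else x_new
        prev_res = res
    raise ConvergenceError(f"model k not converged in {max_iter} iterations",
                           res)


def _solve_k_masked(k_star: np.ndarray, free: np.ndarray,
                    u: np.ndarray, v: np.ndarray,
                    tol: float, max_iter: int) -> np.ndarray:
    """Fixed point for model k+c: sums over the remaining pairs (u, v)."""
    n = len(k_star)
    x = np.full(n, 1.0)
    x[free] = _init_x(np.where(free, k_star, 1.0))[free]
    prev_res = np.inf
    res = np.inf
    for _ in range(max_iter):
        tu = 1.0 / (1.0 / x[u] + x[v])
        tv = 1.0 / (1.0 / x[v] + x[u])
        s = (np.bincount(u, weights=tu, minlength=n)
             + np.bincount(v, weights=tv, minlength=n))
        x_new = np.where(free,
                         np.clip(s / np.maximum(k_star, 1e-300),
                                 _X_FLOOR, _X_CEIL), 1.0)
        pe = 1.0 / (1.0 + x_new[u] * x_new[v])
        k_hat = (np.bincount(u, weights=pe, minlength=n)
                 + np.bincount(v, weights=pe, minlength=n))
        res = _degree_residual(k_hat[free], k_star[free])
        if res <= tol:
            return x_new
        x = np.where(free, 0.5 * (x + x_new) if res > prev_res else x_new,
                     1.0)
        prev_res = res
    raise ConvergenceError(f"model k+c not converged in {max_iter} "
                           "iterations", res)


# ---------------------------------------------------------------------------
# Degree + wiring-length model (k+L)
# ---------------------------------------------------------------------------

def _solve_kL_inner(k_star: np.ndarray, dmat: np.ndarray, d0: float,
                    x0: Optional[np.ndarray], tol: float, max_iter: int
                    ) -> np.ndarray:
    """Fixed point of x_i <- (1/k_i*) sum_j 1/(1/x_i + x_j e^{d_ij/d0})."""
    m = len(k_star)
    with np.errstate(over="ignore"):
        w = np.exp(np.minimum(dmat / d0, _EXP_MAX))
    np.fill_diagonal(w, 0.0)  # excludes j = i from all sums
    x = _init_x(k_star) if x0 is None else x0.copy()
    prev_res = np.inf
    for it in range(max_iter):
        inv = 1.0 / x
        with np.errstate(over="ignore"):
            denom = inv[:, None] + x[None, :] * w
            s = np.where(w > 0, 1.0 / denom, 0.0).sum(axis=1)
        x_new = np.clip(s / k_star, _X_FLOOR, _X_CEIL)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.outer(x_new, x_new) * w)
        p[w == 0] = 0.0
        res = _degree_residual(p.sum(axis=1), k_star)
        if res <= tol:
            return x_new
        x = 0.5 * (x + x_new) if res > prev_res else x_new
        prev_res = res
    raise ConvergenceError(f"model k+L inner solve (d0={d0:.4g}) not "
                           f"converged in {max_iter} iterations", res)


def fit_degree_wiring_model(k_star: Sequence[float], L_star: float,
                            distances: np.ndarray,
                            node_ids: Optional[Sequence[str]] = None,
                            tol_k: float = 1e-8,
                            tol_L: float = 1e-4,
                            d0_bracket: Optional[Tuple[float, float]] = None,
                            max_iter: int = 10_000,
                            max_outer: int = 200) -> FittedEnsemble:
    """Fit kind k+L: expected degrees k* and expected wiring length L*.

    p_ij = 1/(1 + x_i x_j e^{d_ij/d0}). For each probe d0 the degree fixed
    point is re-solved (warm started), then d0 is bisected on the monotone
    map d0 -> <L> = sum p_ij d_ij until |<L> - L*|/L* <= tol_L (default
    1e-4, i.e. 0.01% of the total edge length).

    ``distances`` is the condensed all-pairs vector in soma-size units.
    """
    from scipy.spatial.distance import squareform

    k_star = np.asarray(k_star, dtype=float)
    n = len(k_star)
    if node_ids is None:
        node_ids = [f"n{i:05d}" for i in range(n)]
    node_ids = tuple(str(i) for i in node_ids)
    distances = np.asarray(distances, dtype=float)
    if len(distances) != n * (n - 1) // 2:
        raise ValueError("distances must be condensed over all node pairs")
    if not L_star > 0:
        raise ValueError("target wiring length must be positive")
    active = k_star > 0
    _check_feasible(k_star, np.where(active, active.sum() - 1, 0).astype(float),
                    node_ids)

    dmat_full = squareform(distances)
    dmat = dmat_full[np.ix_(active, active)]
    ka = k_star[active]

    if d0_bracket is None:
        # small d0 concentrates edges on the shortest pairs (<L> low); large
        # d0 approaches model k (<L> high); /20 keeps exponents e^{d/d0}
        # within the solvable range for realistic geometries
        dbar = distances.mean()
        d0_bracket = (dbar / 20.0, 50.0 * dbar)
    lo, hi = d0_bracket
    if not 0 < lo < hi:
        raise ValueError("d0 bracket must satisfy 0 < lo < hi")

    def expected_L(d0, x0):
        x = _solve_kL_inner(ka, dmat, d0, x0, tol_k, max_iter)
        with np.errstate(over="ignore"):
            w = np.exp(np.minimum(dmat / d0, _EXP_MAX))
            p = 1.0 / (1.0 + np.outer(x, x) * w)
        np.fill_diagonal(p, 0.0)
        return float((p * dmat).sum() / 2.0), x

    L_lo, x_lo = expected_L(lo, None)
    L_hi, x_hi = expected_L(hi, None)
    it = 0
    if abs(L_lo - L_star) / L_star <= tol_L:
        d0, x = lo, x_lo
    elif abs(L_hi - L_star) / L_star <= tol_L:
        d0, x = hi, x_hi
    elif not (L_lo < L_star < L_hi):
        raise ValueError(
            f"L* = {L_star:.6g} outside [<L>(lo), <L>(hi)] = "
            f"[{L_lo:.6g}, {L_hi:.6g}]; widen the d0 bracket")
    else:
        x = x_hi
        for it in range(max_outer):
            d0 = np.sqrt(lo * hi)  # geometric bisection: spans decades
            L_mid, x = expected_L(d0, x)
            if abs(L_mid - L_star) / L_star <= tol_L:
                break
            if L_mid < L_star:
                lo = d0
            else:
                hi = d0
        else:
            raise ConvergenceError(
                "k+L outer search on d0 did not reach tol_L",
                abs(L_mid - L_star) / L_star)

    x_full = np.full(n, np.inf)
    x_full[active] = x
    model = FittedEnsemble(kind="k+L", node_ids=node_ids, x=x_full, d0=d0,
                           distances=distances, n_iterations=it)
    model.residual = abs(model.expected_wiring_length() - L_star) / L_star
    return model


# ---------------------------------------------------------------------------
# Distance-binned model (d, d+c) and uniform contact model (c)
# ---------------------------------------------------------------------------

def fit_distance_model(nodes: NodeTable, edges: EdgeList, n_bins: int = 50,
                       hard_mask: Optional[np.ndarray] = None,
                       distances: Optional[np.ndarray] = None
                       ) -> FittedEnsemble:
    """Fit kind d (or d+c with a contact mask): binned p(d).

    Distances between node "centers of mesh" are split into ``n_bins``
    linear bins spanning [0, max distance]; each bin's probability is the
    connected fraction of its pairs. With a mask, the denominator is
    contact pairs per bin and the probability applies to contact pairs
    only (the conditional curve). Either way the expected edge total
    equals the observed edge count exactly.
    """
    from .core import condensed_distances

    if distances is None:
        distances = condensed_distances(nodes)
    edge_mask = edges.condensed_mask(nodes)
    if hard_mask is not None:
        hard_mask = np.asarray(hard_mask, dtype=bool)
        if np.any(edge_mask & ~hard_mask):
            raise InfeasibleConstraintsError(
                "observed edges outside the contact mask")
    table = bin_pair_distances(distances, edge_mask, n_bins=n_bins,
                               restrict_to=hard_mask)
    empty = (table.n_pairs == 0) & (table.n_edges == 0)
    if np.any(empty):
        logger.warning("%d of %d distance bins contain no pairs (p=0)",
                       int(empty.sum()), table.n_bins)
    return FittedEnsemble(kind="d" if hard_mask is None else "d+c",
                          node_ids=nodes.ids, bin_table=table,
                          hard_mask=hard_mask, distances=distances)


def fit_uniform_contact_model(E_syn: int, contact_mask: np.ndarray,
                              node_ids: Sequence[str]) -> FittedEnsemble:
    """Fit kind c: uniform p on contact pairs preserving <E> = E_syn."""
    contact_mask = np.asarray(contact_mask, dtype=bool)
    n_cont = int(contact_mask.sum())
    if E_syn < 0:
        raise ValueError("edge count must be nonnegative")
    if E_syn > n_cont:
        raise InfeasibleConstraintsError(
            f"{E_syn} edges cannot fit in {n_cont} contact pairs")
    p = 0.0 if n_cont == 0 else E_syn / n_cont
    return FittedEnsemble(kind="c", node_ids=tuple(str(i) for i in node_ids),
                          uniform_p=p, hard_mask=contact_mask)


# ---------------------------------------------------------------------------
# Sampling and likelihood
# ---------------------------------------------------------------------------

def sample_ensemble(model: FittedEnsemble, seed: int,
                    n_realizations: int = 100,
                    distances: Optional[np.ndarray] = None
                    ) -> List[EdgeList]:
    """Draw independent realizations: each pair is an edge w.p. p_ij.

    Realization r uses its own generator seeded with seed + r, so any
    prefix of a longer run is reproducible.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    p = model.probabilities(distances)
    n = model.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    ids = model.node_ids
    out = []
    for r in range(n_realizations):
        rng = np.random.default_rng(seed + r)
        hit = rng.random(len(p)) < p
        out.append(EdgeList((ids[i], ids[j])
                            for i, j in zip(iu[hit], ju[hit])))
    return out


def log_likelihood(model: FittedEnsemble, observed: SpatialNetwork,
                   distances: Optional[np.ndarray] = None,
                   return_diagnostics: bool = False):
    """Bernoulli log-likelihood of an observed network under the model.

    sum_edges ln p_ij + sum_non-edges ln(1 - p_ij). An observed edge with
    p_ij = 0 (e.g. outside the hard contact mask) makes the result -inf;
    the offending pairs are available via ``return_diagnostics=True``.
    """
    if tuple(observed.nodes.ids) != tuple(model.node_ids):
        raise ValueError("observed network node set differs from the model")
    p = model.probabilities(distances)
    y = observed.edges.condensed_mask(observed.nodes)
    zero_edges = y & (p == 0.0)
    one_nonedges = (~y) & (p == 1.0)
    with np.errstate(divide="ignore"):
        ll_edges = np.log(p[y & ~zero_edges]).sum()
        ll_non = np.log1p(-p[~y & ~one_nonedges]).sum()
    value = float(ll_edges + ll_non)
    offenders: List[Tuple[str, str]] = []
    if zero_edges.any() or one_nonedges.any():
        n = model.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        bad = zero_edges | one_nonedges
        offenders = [(model.node_ids[i], model.node_ids[j])
                     for i, j in zip(iu[bad], ju[bad])]
        logger.warning("log-likelihood is -inf: %d impossible pairs, e.g. %s",
                       len(offenders), offenders[:3])
        value = float("-inf")
    if return_diagnostics:
        return value, offenders
    return value
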