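"""Geometric preferential attachment (GPA) network growth.

The model grows a network one node per time step t = 1, 2, ..., n in the
hyperbolic plane of curvature K = -1:

1. The new node t draws t candidate angles uniformly on the circle, scores
   each candidate phi by its *attractiveness* A_t(phi) — the number of
   existing nodes inside the hyperbolic disk of radius r_t centred at
   (r_t, phi) — and settles at candidate i with probability proportional to
   A_t(phi_i) + Lambda.  The offset Lambda ("initial attractiveness") tunes
   how strongly newcomers follow the existing node density: Lambda -> 0 is
   pure density-following, Lambda -> infinity recovers the homogeneous
   popularity x similarity (PS) model with uniform angles.
2. Node t is placed at radius r_t = 2 ln t and every older node s drifts
   outward to r_s(t) = beta * r_s + (1 - beta) * r_t (popularity fading with
   speed beta; the implied degree exponent is gamma = 1 + 1/beta).
3. Node t links to the m hyperbolically closest existing nodes (to all of
   them while t <= m).

Attractiveness counting is implemented by reducing disk membership to an
angular window per existing node (``geometry.disk_angular_halfwidth``) and
counting candidates inside all windows with a sorted sweep, which brings the
whole growth to O(n^2 log n) without changing the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import (
    TWO_PI,
    angular_distance,
    birth_radius,
    disk_angular_halfwidth,
    updated_radius,
)

__all__ = [
    "ModelParams",
    "GPANetwork",
    "attractiveness",
    "attractiveness_profile",
    "select_candidate",
    "sample_angle",
    "grow_network",
    "follower_probability",
    "expected_edge_count",
]


@dataclass(frozen=True)
class ModelParams:
    """Generation controls for a GPA growth run.

    lambda_schedule may be a nonnegative constant Lambda or a callable
    t -> Lambda(t) evaluated at each birth time (the model itself imposes no
    parametric decay law).
    """

    n: int
    m: int = 3
    beta: float = 2.0 / 3.0
    lambda_schedule: float | Callable[[int], float] = 1.0
    distance_mode: str = "approx"
    seed: int | None = None
    zero_weight_policy: str = "resample"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if self.distance_mode not in ("approx", "exact"):
            raise ValueError("distance_mode must be 'approx' or 'exact'")
        if not callable(self.lambda_schedule) and self.lambda_schedule < 0:
            raise ValueError("Lambda must be >= 0")
        if self.zero_weight_policy not in ("resample", "uniform"):
            raise ValueError("zero_weight_policy must be 'resample' or 'uniform'")

    def lambda_at(self, t: int) -> float:
        lam = self.lambda_schedule(t) if callable(self.lambda_schedule) else self.lambda_schedule
        lam = float(lam)
        if lam < 0:
            raise ValueError(f"Lambda({t}) < 0")
        return lam

    @property
    def gamma(self) -> float:
        """Implied power-law exponent of the degree distribution, 1 + 1/beta."""
        return 1.0 + 1.0 / self.beta


@dataclass
class GPANetwork:
    """A grown network: angles by birth order plus the undirected edge set.

    Node ids are 1-based birth times (node 1 is the oldest).  ``angles[i]``
    is the similarity coordinate of node i+1.  Edges are stored as an
    (E, 2) integer array with u < v.
    """

    angles: np.ndarray
    edges: np.ndarray
    params: ModelParams

    @property
    def n(self) -> int:
        return len(self.angles)

    def degrees(self) -> np.ndarray:
        """Degree of each node, indexed by birth time - 1."""
        deg = np.zeros(self.n, dtype=np.int64)
        if len(self.edges):
            np.add.at(deg, self.edges.ravel() - 1, 1)
        return deg

    def radii(self, t: int | None = None) -> np.ndarray:
        """Radial coordinates of all nodes at time t (default: final time n)."""
        t = self.n if t is None else t
        return updated_radius(np.arange(1, self.n + 1), t, self.params.beta)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(1, self.n + 1))
        g.add_edges_from(map(tuple, self.edges))
        return g


def expected_edge_count(n: int, m: int) -> int:
    """Edge count forced by the growth rule: m(m-1)/2 + m(n-m) for n >= m."""
    if n <= m:
        return n * (n - 1) // 2
    return m * (m - 1) // 2 + m * (n - m)


def _count_in_windows(candidates: np.ndarray, centers: np.ndarray, halfwidths: np.ndarray) -> np.ndarray:
    """For each candidate angle, count windows [center - hw, center + hw]
    (taken on the circle) that contain it.

    Equivalent to summing, over window centers, the indicator
    angular_distance(candidate, center) <= hw.  O((C + W) log C).
    """
    c = np.asarray(candidates, dtype=float)
    order = np.argsort(c, kind="stable")
    cs = c[order]
    nC = len(cs)
    diff = np.zeros(nC + 1, dtype=np.int64)

    full = halfwidths >= math.pi
    diff[0] += int(np.count_nonzero(full))
    centers = centers[~full]
    hw = halfwidths[~full]

    a = centers - hw
    b = centers + hw
    # windows split at the 0/2*pi seam so every segment lies within one period
    wrap_lo = a < 0.0
    wrap_hi = b >= TWO_PI
    plain = ~(wrap_lo | wrap_hi)
    n_lo = int(np.count_nonzero(wrap_lo))
    n_hi = int(np.count_nonzero(wrap_hi))
    a_all = np.concatenate([a[plain], np.zeros(n_lo), a[wrap_lo] + TWO_PI,
                            a[wrap_hi], np.zeros(n_hi)])
    b_all = np.concatenate([b[plain], b[wrap_lo], np.full(n_lo, TWO_PI),
                            np.full(n_hi, TWO_PI), b[wrap_hi] - TWO_PI])
    i_lo = np.searchsorted(cs, a_all, side="left")
    i_hi = np.searchsorted(cs, b_all, side="right")
    np.add.at(diff, i_lo, 1)
    np.add.at(diff, i_hi, -1)

    counts_sorted = np.cumsum(diff[:-1])
    counts = np.empty(nC, dtype=np.int64)
    counts[order] = counts_sorted
    return counts


def attractiveness_profile(phis, t: int, existing_angles, beta: float, distance_mode: str = "approx") -> np.ndarray:
    """A_t(phi) for an array of locations phi: the number of existing nodes
    s = 1..t-1 (with radii updated to time t) lying within hyperbolic
    distance r_t of the point (r_t, phi)."""
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    existing = np.asarray(existing_angles, dtype=float)
    if len(existing) != t - 1:
        raise ValueError(f"state holds {len(existing)} nodes, expected t - 1 = {t - 1}")
    if t == 1:
        return np.zeros(len(phis), dtype=np.int64)
    r_t = birth_radius(t)
    r_s = updated_radius(np.arange(1, t), t, beta)
    hw = disk_angular_halfwidth(r_s, r_t, distance_mode)
    return _count_in_windows(phis, existing, np.atleast_1d(hw))


def attractiveness(phi: float, t: int, network_state, beta: float | None = None, distance_mode: str | None = None) -> int:
    """Attractiveness A_t(phi) of a single location for the newborn node t.

    ``network_state`` is either a GPANetwork prefix (exactly nodes 1..t-1) or
    a bare sequence of existing angles (then beta must be given).
    """
    if isinstance(network_state, GPANetwork):
        angles = network_state.angles
        beta = network_state.params.beta if beta is None else beta
        distance_mode = network_state.params.distance_mode if distance_mode is None else distance_mode
    else:
        angles = np.asarray(network_state, dtype=float)
        if beta is None:
            raise ValueError("beta is required when passing bare angles")
    distance_mode = distance_mode or "approx"
    return int(attractiveness_profile([phi], t, angles, beta, distance_mode)[0])


def select_candidate(attract: np.ndarray, lam: float, u: float) -> int:
    """Index of the chosen candidate given attractivenesses, Lambda and a
    uniform variate u in [0, 1): candidate i wins with probability
    (A_i + Lambda) / sum_j (A_j + Lambda).

    If Lambda = 0 and every attractiveness is 0 (e.g. t = 1) the weights are
    degenerate and the choice falls back to uniform — the 0/0 limit of the
    selection rule.
    """
    if lam < 0:
        raise ValueError("Lambda must be >= 0")
    w = np.asarray(attract, dtype=float) + lam
    total = w.sum()
    if total <= 0.0:
        return min(int(u * len(w)), len(w) - 1)
    cw = np.cumsum(w)
    return int(np.searchsorted(cw, u * total, side="right").clip(0, len(w) - 1))


def sample_angle(t: int, lambda_t: float, network_state, rng, beta: float | None = None,
                 distance_mode: str = "approx") -> float:
    """Draw the similarity coordinate theta_t of the newborn node t.

    Draws t uniform candidate angles, scores each by attractiveness, then
    selects one with probability proportional to A + Lambda.  Consumes
    exactly t + 1 variates from rng (t candidates, then one selector).
    """
    if isinstance(network_state, GPANetwork):
        angles = network_state.angles
        beta = network_state.params.beta if beta is None else beta
        distance_mode = network_state.params.distance_mode
    else:
        angles = np.asarray(network_state, dtype=float)
        if beta is None:
            raise ValueError("beta is required when passing bare angles")
    candidates = rng.uniform(0.0, TWO_PI, size=t)
    attract = attractiveness_profile(candidates, t, angles, beta, distance_mode)
    i = select_candidate(attract, lambda_t, rng.random())
    return float(candidates[i])


def follower_probability(t: int, lambda_t: float, candidate_attractivenesses) -> float:
    """Probability p_f that node t acts as a *follower* (places itself by pure
    density-following rather than uniformly among its candidates):
    p_f = sum A / (sum A + t * Lambda).  Since the mean attractiveness of a
    uniform location is ~ 1, p_f is approximately 1 / (1 + Lambda)."""
    a = np.asarray(candidate_attractivenesses)
    if len(a) != t:
        raise ValueError("need one attractiveness per candidate (t of them)")
    if lambda_t < 0:
        raise ValueError("Lambda must be >= 0")
    total = float(a.sum())
    denom = total + t * lambda_t
    if denom == 0.0:
        raise ZeroDivisionError("follower probability undefined: sum A + t*Lambda = 0")
    return total / denom


def _closest_existing(t: int, theta_t: float, angles: np.ndarray, beta: float,
                      distance_mode: str, m: int) -> np.ndarray:
    """Birth times of the m hyperbolically closest existing nodes to
    (r_t, theta_t), ties broken by smaller birth time."""
    r_t = birth_radius(t)
    s = np.arange(1, t)
    r_s = updated_radius(s, t, beta)
    dtheta = angular_distance(theta_t, angles[: t - 1])
    if distance_mode == "approx":
        with np.errstate(divide="ignore"):
            d = r_s + r_t + 2.0 * np.log(dtheta / 2.0)  # -inf at dtheta = 0: closest
    else:
        arg = np.cosh(r_s) * math.cosh(r_t) - np.sinh(r_s) * math.sinh(r_t) * np.cos(dtheta)
        d = np.arccosh(np.maximum(arg, 1.0))
        d[dtheta < 1e-9] = np.abs(r_s - r_t)[dtheta < 1e-9]
    order = np.lexsort((s, d))
    return s[order[:m]]


def grow_network(params: ModelParams, rng=None) -> GPANetwork:
    """Grow a GPA network of params.n nodes.

    Deterministic given (params, seed): per node, the t candidate angles are
    drawn first, then one selection variate, so the variate stream is fixed.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n, m, beta, mode = params.n, params.m, params.beta, params.distance_mode
    angles = np.empty(n, dtype=float)
    edge_u: list[np.ndarray] = []
    edge_v: list[np.ndarray] = []

    for t in range(1, n + 1):
        lam = params.lambda_at(t)
        candidates = rng.uniform(0.0, TWO_PI, size=t)
        attract = attractiveness_profile(candidates, t, angles[: t - 1], beta, mode)
        if params.zero_weight_policy == "resample" and t > 1 and lam == 0.0:
            # Under pure density-following (Lambda = 0) a new node always follows
            # somebody: a candidate set in which every location is empty carries
            # zero total weight and is redrawn, so zero-attractiveness placements
            # have probability zero — consistent with the likelihood, which
            # assigns them -inf at Lambda = 0.
            attempts = 0
            while attract.sum() == 0 and attempts < 10_000:
                candidates = rng.uniform(0.0, TWO_PI, size=t)
                attract = attractiveness_profile(candidates, t, angles[: t - 1], beta, mode)
                attempts += 1
        theta_t = candidates[select_candidate(attract, lam, rng.random())]
        angles[t - 1] = theta_t
        if t > 1:
            if t <= m:
                nbrs = np.arange(1, t)
            else:
                nbrs = _closest_existing(t, theta_t, angles, beta, mode, m)
            edge_u.append(nbrs.astype(np.int64))
            edge_v.append(np.full(len(nbrs), t, dtype=np.int64))

    if edge_u:
        edges = np.column_stack([np.concatenate(edge_u), np.concatenate(edge_v)])
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    return GPANetwork(angles=angles, edges=edges, params=params)
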