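"""Topology diagnostics: degree CCDF, discrete power-law fitting, clustering
spectra, and the Kolmogorov-Smirnov distance of angular coordinates from
uniformity.

The power-law fit follows the standard discrete maximum-likelihood recipe for
empirical degree data: for each candidate lower cutoff k_min the tail exponent
is fitted by MLE (normalised by the Hurwitz zeta function), k_min is chosen to
minimise the KS distance between the fitted tail and the empirical tail, and
an optional semi-parametric bootstrap yields a goodness-of-fit p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .geometry import TWO_PI

__all__ = [
    "PowerLawFit",
    "ClusteringProfile",
    "degree_ccdf",
    "fit_power_law",
    "sample_discrete_power_law",
    "clustering_profile",
    "ks_uniform",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a discrete power-law tail fit P(k) ~ k^-gamma for k >= k_min."""

    gamma_hat: float
    k_min: int
    ks_tail: float
    n_tail: int
    gof_pvalue: float | None = None


@dataclass(frozen=True)
class ClusteringProfile:
    """Degree-resolved mean local clustering c(k) plus the overall mean.

    Nodes of degree < 2 carry no triangle information and are excluded.
    """

    by_degree: dict[int, float]
    mean_clustering: float


def _degrees_of(network) -> np.ndarray:
    if hasattr(network, "degrees"):
        deg = np.asarray(network.degrees())
    elif hasattr(network, "degree"):
        deg = np.asarray([d for _, d in network.degree()])
    else:
        deg = np.asarray(network)
    if deg.size == 0:
        raise ValueError("empty network / degree sample")
    return deg.astype(np.int64)


def degree_ccdf(network) -> dict[int, float]:
    """Empirical complementary cumulative degree distribution P_c(k) = P(K >= k),
    evaluated at every observed degree."""
    deg = _degrees_of(network)
    ks, counts = np.unique(deg, return_counts=True)
    # P(K >= k) = 1 - P(K < k): cumulative counts of strictly smaller degrees
    below = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pc = 1.0 - below / deg.size
    return dict(zip(ks.tolist(), pc.tolist()))


def _mle_gamma(tail: np.ndarray, k_min: int) -> float:
    """Discrete MLE of the exponent: maximise -n ln zeta(g, k_min) - g sum ln k."""
    sum_log = float(np.log(tail).sum())
    n = tail.size

    def negll(g):
        return n * math.log(special.zeta(g, k_min)) + g * sum_log

    res = optimize.minimize_scalar(negll, bounds=(1.01, 12.0), method="bounded")
    return float(res.x)


def _tail_ks(tail: np.ndarray, k_min: int, gamma: float) -> float:
    """KS distance between the empirical tail CDF and the fitted discrete model."""
    ks = np.unique(tail)
    z0 = special.zeta(gamma, k_min)
    model_cdf = 1.0 - special.zeta(gamma, ks + 1) / z0
    emp_cdf = np.searchsorted(np.sort(tail), ks, side="right") / tail.size
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def sample_discrete_power_law(size: int, gamma: float, k_min: int, rng) -> np.ndarray:
    """Exact inverse-CDF sampling from P(k) = k^-gamma / zeta(gamma, k_min),
    k = k_min, k_min+1, ... (a continuous-approximation fallback covers the
    astronomically rare values beyond the precomputed table)."""
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    k_max = 10**6
    ks = np.arange(k_min, k_max + 1)
    ccdf = special.zeta(gamma, ks) / special.zeta(gamma, k_min)  # P(K >= k)
    u = rng.random(size)
    # find largest k with ccdf(k) >= u  (ccdf decreasing)
    idx = np.searchsorted(-ccdf, -u, side="right") - 1
    out = ks[np.clip(idx, 0, len(ks) - 1)]
    beyond = u < ccdf[-1]
    if np.any(beyond):
        out = out.astype(np.int64)
        out[beyond] = np.floor(
            (k_min - 0.5) * (1.0 - u[beyond]) ** (-1.0 / (gamma - 1.0)) + 0.5
        ).astype(np.int64)
    return out.astype(np.int64)


def fit_power_law(degrees, min_tail: int = 10, gof_bootstrap: int = 0, seed: int | None = None) -> PowerLawFit:
    """Fit a discrete power law to a degree sample with automatic k_min.

    Every observed degree is tried as the cutoff (subject to the tail keeping
    at least ``min_tail`` points and two distinct values); the cutoff with the
    smallest tail KS distance wins.  ``gof_bootstrap`` > 0 adds a
    semi-parametric bootstrap goodness-of-fit p-value (fraction of refitted
    synthetic samples whose KS distance exceeds the observed one; the
    conventional acceptance threshold is p > 0.1).
    """
    deg = _degrees_of(degrees)
    if np.any(deg < 1):
        raise ValueError("degrees must be >= 1")
    uniq = np.unique(deg)
    if uniq.size < 2:
        raise ValueError("power-law fit impossible: all degrees equal")

    best = None
    for k_min in uniq:
        tail = deg[deg >= k_min]
        if tail.size < min_tail or np.unique(tail).size < 2:
            continue
        g = _mle_gamma(tail, int(k_min))
        d = _tail_ks(tail, int(k_min), g)
        if best is None or d < best[0]:
            best = (d, int(k_min), g, tail.size)
    if best is None:
        raise ValueError("power-law fit impossible: no admissible cutoff")
    d, k_min, gamma_hat, n_tail = best

    pval = None
    if gof_bootstrap > 0:
        rng = np.random.default_rng(seed)
        body = deg[deg < k_min]
        p_tail = n_tail / deg.size
        exceed = 0
        for _ in range(gof_bootstrap):
            from_tail = rng.random(deg.size) < p_tail
            n_t = int(from_tail.sum())
            synth = np.concatenate([
                sample_discrete_power_law(n_t, gamma_hat, k_min, rng),
                rng.choice(body, size=deg.size - n_t, replace=True) if deg.size > n_t else np.empty(0, dtype=np.int64),
            ])
            try:
                boot = fit_power_law(synth, min_tail=min_tail)
            except ValueError:
                continue
            exceed += boot.ks_tail >= d
        pval = exceed / gof_bootstrap
    return PowerLawFit(gamma_hat=gamma_hat, k_min=k_min, ks_tail=d, n_tail=n_tail, gof_pvalue=pval)


def clustering_profile(network, include_low_degree: bool = False) -> ClusteringProfile:
    """Local clustering (triangle density of each node's neighbourhood),
    averaged per degree class and overall.

    By default nodes of degree < 2 are excluded everywhere, matching the
    conditional-probability definition; ``include_low_degree`` counts them as
    zero instead.
    """
    import networkx as nx

    g = network.to_networkx() if hasattr(network, "to_networkx") else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    local = nx.clustering(g)
    by_deg: dict[int, list[float]] = {}
    vals = []
    for node, c in local.items():
        k = g.degree(node)
        if k < 2 and not include_low_degree:
            continue
        by_deg.setdefault(k, []).append(c)
        vals.append(c)
    if not vals:
        raise ValueError("no nodes of degree >= 2")
    return ClusteringProfile(
        by_degree={k: float(np.mean(v)) for k, v in sorted(by_deg.items())},
        mean_clustering=float(np.mean(vals)),
    )


def ks_uniform(angles) -> float:
    """KS statistic rho of a sample of angles against the uniform law on
    [0, 2*pi]: the supremum distance between the empirical CDF and theta/2*pi,
    taking both sides of every jump."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    u = np.sort(a) / TWO_PI
    n = a.size
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - u), np.max(u - (i - 1) / n)))
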