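"""Soft communities from angular coordinates.

A soft community is a maximal run of circularly consecutive nodes whose
internal angular gaps do not exceed the critical gap theta_c — the expected
largest gap among n points thrown uniformly on the circle.  Gaps larger than
theta_c act as "fault lines" between communities; how far the two bounding
gaps of a community exceed theta_c measures how sharply it is separated from
the rest of the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .geometry import TWO_PI, reduce_angle

__all__ = [
    "GapSequence",
    "CommunityPartition",
    "SeparationUndefinedError",
    "circular_gaps",
    "critical_gap",
    "detect_communities",
    "separation",
    "gap_autocorrelation",
    "community_size_ccdf",
]

EULER_GAMMA = float(np.euler_gamma)


class SeparationUndefinedError(ValueError):
    """Raised when community separation is requested for a single-community
    partition: with no fault lines there are no bounding gaps to rescale."""


@dataclass(frozen=True)
class GapSequence:
    """Circular gaps between consecutive sorted angles (wrap-around included),
    so that len(gaps) == len(angles) and the gaps sum to 2*pi."""

    sorted_angles: np.ndarray
    gaps: np.ndarray
    theta_c: float

    @property
    def rescaled_gaps(self) -> np.ndarray:
        return self.gaps / self.theta_c


@dataclass(frozen=True)
class CommunityPartition:
    """Ordered contiguous blocks of node ids on the circle.

    ``bounding_gaps[i]`` is the (left, right) pair of fault-line gaps around
    community i, or None when the whole circle is one community.
    """

    theta_c: float
    communities: list[np.ndarray]
    bounding_gaps: list[tuple[float, float]] | None

    @property
    def n_c(self) -> int:
        return len(self.communities)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.communities], dtype=np.int64)


def circular_gaps(angles, theta_c: float | None = None) -> GapSequence:
    """Sorted angles and the n circular gaps between consecutive ones.

    theta_c defaults to the closed-form critical gap for n = len(angles).
    """
    a = reduce_angle(np.asarray(angles, dtype=float))
    a = np.atleast_1d(a)
    if a.size == 0:
        raise ValueError("need at least one angle")
    s = np.sort(a)
    gaps = np.diff(s, append=s[0] + TWO_PI)
    if theta_c is None:
        theta_c = critical_gap(a.size)
    return GapSequence(sorted_angles=s, gaps=gaps, theta_c=theta_c)


def critical_gap(n: int, mode: str = "approx") -> float:
    """Expected largest of n uniform circular gaps.

    exact_harmonic: (2*pi/n) * H_n with H_n the n-th harmonic number (the
    Poisson-process calculation of E[max gap]); approx replaces H_n by
    ln n + Euler's gamma.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "approx":
        return (TWO_PI / n) * (math.log(n) + EULER_GAMMA)
    if mode == "exact_harmonic":
        h_n = float(special.digamma(n + 1)) + EULER_GAMMA
        return (TWO_PI / n) * h_n
    raise ValueError(f"unknown critical-gap mode: {mode!r}")


def detect_communities(angles, theta_c: float, ids=None) -> CommunityPartition:
    """Split nodes into soft communities at every circular gap strictly
    greater than theta_c.

    Blocks are contiguous runs on the circle; the run spanning the 2*pi -> 0
    wrap is a single community.  Communities are ordered by the angle of
    their first (most clockwise) member; node ids default to 1..n in input
    (birth) order.
    """
    if theta_c <= 0:
        raise ValueError("theta_c must be positive")
    a = np.atleast_1d(reduce_angle(np.asarray(angles, dtype=float)))
    n = a.size
    if n == 0:
        raise ValueError("need at least one angle")
    ids = np.arange(1, n + 1) if ids is None else np.asarray(ids)
    if len(ids) != n:
        raise ValueError("ids and angles must have equal length")

    order = np.argsort(a, kind="stable")
    gs = circular_gaps(a, theta_c=theta_c)
    fault = np.flatnonzero(gs.gaps > theta_c)  # gap i sits after sorted node i
    if fault.size == 0:
        return CommunityPartition(theta_c=theta_c, communities=[ids[order]], bounding_gaps=None)

    blocks: list[np.ndarray] = []
    bounds: list[tuple[float, float]] = []
    # block k starts after fault k-1 and ends at fault k (circularly)
    starts = np.concatenate([[fault[-1] + 1 - n], fault[:-1] + 1])
    for start, end in zip(starts, fault):
        idx = np.arange(start, end + 1) % n
        blocks.append(ids[order[idx]])
        left_gap = gs.gaps[(start - 1) % n]
        right_gap = gs.gaps[end]
        bounds.append((float(left_gap), float(right_gap)))
    # order blocks by their first member's angle
    first_angle = [a[order[(s % n)]] for s in starts]
    perm = np.argsort(first_angle, kind="stable")
    return CommunityPartition(
        theta_c=theta_c,
        communities=[blocks[i] for i in perm],
        bounding_gaps=[bounds[i] for i in perm],
    )


def separation(partition: CommunityPartition) -> tuple[np.ndarray, float]:
    """Per-community separation S and the size-weighted mean S-bar.

    S(C) = (g_left + g_right) / (2 * theta_c) >= 1 rescales a community's two
    bounding fault-line gaps by the critical gap; S-bar = sum n_i S_i / sum n_i
    is the expected separation of the community of a randomly chosen node.
    """
    if partition.n_c < 2 or partition.bounding_gaps is None:
        raise SeparationUndefinedError(
            "separation requires at least two communities (no bounding gaps exist)"
        )
    g = np.asarray(partition.bounding_gaps, dtype=float)
    s = g.sum(axis=1) / (2.0 * partition.theta_c)
    sizes = partition.sizes
    return s, float(np.sum(sizes * s) / np.sum(sizes))


def gap_autocorrelation(gaps, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation of the circularly ordered gap sequence,
    normalised to 1 at lag 0; returned for lags 0..max_lag."""
    g = np.asarray(gaps.gaps if isinstance(gaps, GapSequence) else gaps, dtype=float)
    if g.size < max_lag + 2:
        raise ValueError("need at least max_lag + 2 gaps")
    if np.ptp(g) == 0.0:
        raise ValueError("autocorrelation undefined for a constant gap sequence")
    from statsmodels.tsa.stattools import acf

    return acf(g, nlags=max_lag, adjusted=False, fft=True)


def community_size_ccdf(partition: CommunityPartition) -> dict[int, float]:
    """Fraction of communities of size >= s, at every observed size s."""
    sizes = partition.sizes
    uniq, counts = np.unique(sizes, return_counts=True)
    below = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return dict(zip(uniq.tolist(), (1.0 - below / sizes.size).tolist()))
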