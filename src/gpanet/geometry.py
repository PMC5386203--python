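"""Hyperbolic-polar primitives for the curvature K = -1 plane.

Nodes live in polar coordinates (r, theta): the radial coordinate encodes
popularity (older nodes sit deeper, but drift outward as the disk grows —
"popularity fading"), the angular coordinate encodes similarity.  All angular
arithmetic is performed on the circle [0, 2*pi) and all distances refer to the
hyperbolic plane of curvature K = -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "PolarPoint",
    "angular_distance",
    "birth_radius",
    "updated_radius",
    "hyperbolic_distance_exact",
    "hyperbolic_distance_approx",
    "disk_angular_halfwidth",
    "reduce_angle",
]

# below this angular separation the exact distance degenerates to the radial one
_THETA_EPS = 1e-9
# cosh overflows float64 around r ~ 710; switch to the log-sum form well before
_COSH_SAFE_R = 350.0


def reduce_angle(theta):
    """Reduce an angle (scalar or array) into the canonical range [0, 2*pi)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("angles must be finite")
    out = np.mod(theta, TWO_PI)
    # mod can return 2*pi for tiny negative inputs due to rounding
    out = np.where(out >= TWO_PI, 0.0, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PolarPoint:
    """A point (r, theta) in the hyperbolic plane, theta reduced to [0, 2*pi)."""

    radial: float
    angle: float

    def __post_init__(self):
        if not (math.isfinite(self.radial) and math.isfinite(self.angle)):
            raise ValueError("PolarPoint coordinates must be finite")
        if self.radial < 0:
            raise ValueError("radial coordinate must be >= 0")
        object.__setattr__(self, "angle", float(reduce_angle(self.angle)))


def angular_distance(theta_a, theta_b):
    """Angular distance pi - |pi - |theta_a - theta_b|| on the circle, in [0, pi].

    Accepts scalars or arrays (broadcast); inputs are reduced mod 2*pi first.
    """
    a = reduce_angle(theta_a)
    b = reduce_angle(theta_b)
    d = np.abs(np.asarray(a) - np.asarray(b))
    out = math.pi - np.abs(math.pi - d)
    return float(out) if np.ndim(out) == 0 else out


def birth_radius(t):
    """Radial coordinate r_t = 2 ln t assigned to node t at its birth (t >= 1)."""
    t_arr = np.asarray(t)
    if np.any(t_arr < 1):
        raise ValueError("birth time must be >= 1")
    out = 2.0 * np.log(t_arr)
    return float(out) if np.ndim(out) == 0 else out


def updated_radius(s, t, beta):
    """Radial coordinate of node s at time t >= s: r_s(t) = beta*r_s + (1-beta)*r_t.

    beta in (0, 1] is the popularity-fading speed; beta = 1 freezes radii.
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    s_arr = np.asarray(s)
    t_arr = np.asarray(t)
    if np.any(s_arr < 1) or np.any(t_arr < s_arr):
        raise ValueError("require 1 <= s <= t")
    out = beta * birth_radius(s_arr) + (1.0 - beta) * birth_radius(t_arr)
    return float(out) if np.ndim(out) == 0 else out


def _coords(p):
    if isinstance(p, PolarPoint):
        return p.radial, p.angle
    r, theta = p
    return float(r), float(theta)


def hyperbolic_distance_exact(p, q):
    """Exact distance in the K = -1 plane via the hyperbolic law of cosines.

    cosh x = cosh r_p cosh r_q - sinh r_p sinh r_q cos(dtheta), evaluated in a
    numerically stable form: for nearly coincident angles it returns
    |r_p - r_q| exactly, and for large radii it switches to a log-sum
    formulation that avoids overflow of cosh.
    """
    rp, tp = _coords(p)
    rq, tq = _coords(q)
    dtheta = angular_distance(tp, tq)
    if dtheta < _THETA_EPS:
        return abs(rp - rq)
    if max(rp, rq) > _COSH_SAFE_R:
        # cosh x ~ exp(rp+rq)/2 * (1 - cos dt)/2 for large radii (plus lower-order
        # terms exp(|rp-rq|) which are negligible at this scale)
        return rp + rq + 2.0 * math.log(math.sin(dtheta / 2.0))
    arg = math.cosh(rp) * math.cosh(rq) - math.sinh(rp) * math.sinh(rq) * math.cos(dtheta)
    return math.acosh(max(arg, 1.0))


def hyperbolic_distance_approx(p, q):
    """Large-radius approximation x ~ r_p + r_q + 2 ln(dtheta / 2).

    This is the standard working approximation for hyperbolic random graphs;
    it diverges to -inf as dtheta -> 0, so coincident angles are rejected.
    For any fixed current time the ranking of nodes s by this quantity equals
    the ranking by the popularity-similarity score s**beta * theta_st.
    """
    rp, tp = _coords(p)
    rq, tq = _coords(q)
    dtheta = angular_distance(tp, tq)
    if dtheta <= 0.0:
        raise ValueError(
            "approximate distance diverges at zero angular separation; "
            "use the exact mode for coincident angles"
        )
    return rp + rq + 2.0 * math.log(dtheta / 2.0)


def disk_angular_halfwidth(r_s, r_center, mode="approx"):
    """Maximum angular separation at which a node of radius r_s lies within
    hyperbolic distance r_center of a point at radius r_center.

    This turns disk membership ("is s inside the disk of radius r_t centred at
    (r_t, phi)?") into a pure angular test dtheta <= halfwidth, which is what
    makes attractiveness counting fast.  Vectorised over r_s.

    approx mode solves r_s + r_center + 2 ln(dt/2) <= r_center, giving
    dt = 2 exp(-r_s / 2); exact mode inverts the law of cosines.  Results are
    capped at pi (the whole circle is within reach).
    """
    r_s = np.asarray(r_s, dtype=float)
    scalar = r_s.ndim == 0
    r_s = np.atleast_1d(r_s)
    if mode == "approx":
        hw = np.minimum(2.0 * np.exp(-r_s / 2.0), math.pi)
    elif mode == "exact":
        hw = np.empty_like(r_s)
        tiny = r_s < _THETA_EPS
        hw[tiny] = math.pi  # a node at the origin is at distance r_center exactly
        rs = r_s[~tiny]
        if rs.size:
            if r_center > _COSH_SAFE_R:
                hw[~tiny] = np.minimum(2.0 * np.arcsin(np.exp(-rs / 2.0)), math.pi)
            else:
                cos_dt = (
                    math.cosh(r_center)
                    * (np.cosh(rs) - 1.0)
                    / (math.sinh(r_center) * np.sinh(rs))
                )
                hw[~tiny] = np.arccos(np.clip(cos_dt, -1.0, 1.0))
    else:
        raise ValueError(f"unknown distance mode: {mode!r}")
    return float(hw[0]) if scalar else hw
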