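"""TSV readers/writers for edge lists, coordinate tables, Lambda schedules,
and community partitions.

All formats are plain tab-separated text: edge lists carry two integer node
ids per line ('#' starts a comment), coordinate tables carry a header naming
``node`` and ``theta`` plus optional ``r`` and ``birth`` columns, and Lambda
schedules carry (t, Lambda) rows interpreted as a step function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import reduce_angle

__all__ = [
    "CoordinateTable",
    "read_edge_list",
    "write_edge_list",
    "read_coordinates",
    "write_coordinates",
    "read_lambda_schedule",
    "write_partition",
]


@dataclass
class CoordinateTable:
    """Per-node hyperbolic coordinates: angle theta (radians, reduced to
    [0, 2*pi)), optional radius r, optional birth time."""

    node: np.ndarray
    theta: np.ndarray
    r: np.ndarray | None = None
    birth: np.ndarray | None = None

    def __post_init__(self):
        self.node = np.asarray(self.node, dtype=np.int64)
        if len(np.unique(self.node)) != len(self.node):
            raise ValueError("node ids must be unique")
        self.theta = np.atleast_1d(reduce_angle(np.asarray(self.theta, dtype=float)))
        if self.birth is not None:
            self.birth = np.asarray(self.birth, dtype=np.int64)
            if sorted(self.birth.tolist()) != list(range(1, len(self.birth) + 1)):
                raise ValueError("birth times must be a permutation of 1..n")

    def __len__(self):
        return len(self.node)

    def angles_by_birth(self) -> np.ndarray:
        """Angles ordered by birth time (defaulting to node-id order)."""
        if self.birth is None:
            order = np.argsort(self.node, kind="stable")
        else:
            order = np.argsort(self.birth, kind="stable")
        return self.theta[order]


def read_edge_list(path) -> set[tuple[int, int]]:
    """Undirected, deduplicated edge set from a two-column integer TSV."""
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            try:
                u, v = (int(p) for p in parts)
            except (ValueError, TypeError):
                raise ValueError(f"{path}:{lineno}: malformed edge line {raw!r}") from None
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on node {u}")
            edges.add((min(u, v), max(u, v)))
    return edges


def write_edge_list(network, path) -> None:
    """Write a network's edges (or a bare edge iterable) as sorted TSV."""
    edges = network.edges if hasattr(network, "edges") else network
    norm = sorted({(min(int(u), int(v)), max(int(u), int(v))) for u, v in edges})
    with open(path, "w") as fh:
        for u, v in norm:
            fh.write(f"{u}\t{v}\n")


def read_coordinates(path) -> CoordinateTable:
    """Coordinate table from TSV with header columns node, theta[, r][, birth]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "node" not in cols or "theta" not in cols:
        raise ValueError(f"{path}: header must name 'node' and 'theta' columns")
    theta = df[cols["theta"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError(f"{path}: non-finite theta values")
    return CoordinateTable(
        node=df[cols["node"]].to_numpy(),
        theta=theta,
        r=df[cols["r"]].to_numpy(dtype=float) if "r" in cols else None,
        birth=df[cols["birth"]].to_numpy() if "birth" in cols else None,
    )


def write_coordinates(table, path) -> None:
    """Write a CoordinateTable (or a GPANetwork, whose nodes are birth-ordered)
    as TSV with 12 significant digits on the angles."""
    if hasattr(table, "angles"):  # GPANetwork
        n = len(table.angles)
        tab = CoordinateTable(
            node=np.arange(1, n + 1),
            theta=table.angles,
            r=np.asarray(table.radii()),
            birth=np.arange(1, n + 1),
        )
    else:
        tab = table
    cols = {"node": tab.node, "theta": [f"{x:.12g}" for x in tab.theta]}
    if tab.r is not None:
        cols["r"] = [f"{x:.12g}" for x in tab.r]
    if tab.birth is not None:
        cols["birth"] = tab.birth
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_lambda_schedule(path):
    """Step-function Lambda(t) from a two-column (t, Lambda) TSV: the value at
    time t is the entry with the largest breakpoint <= t (the first entry
    extends backward to t = 1)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["t", "lam"])
    ts = df["t"].to_numpy(dtype=np.int64)
    lams = df["lam"].to_numpy(dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError(f"{path}: schedule times must be strictly ascending")
    if np.any(lams < 0):
        raise ValueError(f"{path}: Lambda values must be >= 0")

    def schedule(t: int) -> float:
        i = int(np.searchsorted(ts, t, side="right")) - 1
        return float(lams[max(i, 0)])

    return schedule


def write_partition(partition, path) -> None:
    """Write a CommunityPartition as (node id, 1-based community id) TSV."""
    with open(path, "w") as fh:
        fh.write("node\tcommunity\n")
        for cid, block in enumerate(partition.communities, start=1):
            for node in block:
                fh.write(f"{int(node)}\t{cid}\n")
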