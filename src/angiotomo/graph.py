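"""Vascular graph containers.

A :class:`VascularGraph` is the vectorized form of a voxel skeleton:
nodes are junctions and endpoints, branches are the centerline paths
between them, with geometric length and a diameter estimate in μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Node", "Branch", "VascularGraph"]


@dataclass
class Node:
    """A junction or endpoint of the vascular network.

    ``position_um`` is in (z, y, x) order, micrometres.  ``degree`` is the
    number of branch incidences (a self-loop counts twice).
    """

    id: int
    position_um: np.ndarray
    kind: str  # "junction" or "endpoint"
    degree: int = 0

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        if self.kind not in ("junction", "endpoint"):
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass
class Branch:
    """A centerline path between two nodes.

    ``path`` is an (N, 3) integer voxel-index array in (z, y, x) order;
    its first and last voxels belong to the incident nodes.
    """

    id: int
    node_a: int
    node_b: int
    path: np.ndarray
    length_um: float
    diameter_um: float

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.int64)
        if self.path.ndim != 2 or self.path.shape[1] != 3:
            raise ValueError("branch path must be an (N, 3) voxel array")


@dataclass
class VascularGraph:
    nodes: list[Node] = field(default_factory=list)
    branches: list[Branch] = field(default_factory=list)
    spacing_um: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def node_by_id(self, node_id: int) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))

    def diameters_um(self) -> np.ndarray:
        return np.array([b.diameter_um for b in self.branches], dtype=float)

    def lengths_um(self) -> np.ndarray:
        return np.array([b.length_um for b in self.branches], dtype=float)

    def n_components(self) -> int:
        """Connected components over nodes joined by branches.

        Isolated nodes count as their own component.
        """
        parent = {n.id: n.id for n in self.nodes}

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for b in self.branches:
            ra, rb = find(b.node_a), find(b.node_b)
            if ra != rb:
                parent[ra] = rb
        return len({find(n.id) for n in self.nodes})

    def recompute_degrees(self) -> None:
        deg = {n.id: 0 for n in self.nodes}
        for b in self.branches:
            deg[b.node_a] += 1
            deg[b.node_b] += 1
        for n in self.nodes:
            n.degree = deg[n.id]

    def drop_orphan_nodes(self) -> None:
        used = set()
        for b in self.branches:
            used.add(b.node_a)
            used.add(b.node_b)
        self.nodes = [n for n in self.nodes if n.id in used]

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids")
        known = set(ids)
        for b in self.branches:
            if b.node_a not in known or b.node_b not in known:
                raise ValueError(f"branch {b.id} references unknown node")
            if b.length_um < 0 or b.diameter_um < 0:
                raise ValueError(f"branch {b.id} has negative geometry")
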