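"""Thinning skeletonization and skeleton → vascular graph vectorization.

Skeletonization delegates to the parallel 3D thinning of
``skimage.morphology.skeletonize`` (topology-preserving, deterministic)
and carries a per-voxel radius from the Euclidean distance transform of
the source mask.

Vectorization classifies skeleton voxels by their 26-neighbor count
(1 → endpoint, ≥3 → junction candidate), merges 26-adjacent junction
candidates into single nodes at their centroid, and traces degree-2
chains into branches.  Two details make the recovered topology exact on
clean tubes:

- redundant diagonal adjacencies (a diagonal step that is shortcut by an
  intermediate skeleton voxel) are pruned before classification, which
  removes the spurious junctions/loops that raw 26-adjacency creates
  along staircase chains;
- terminal branches shorter than ``prune_factor`` times their own
  diameter are removed (thinning spurs) and the skeleton is re-vectorized
  once.

Branch length sums per-step chamfer weights (0.9016, 1.289, 1.615 voxels
× spacing for axis, face- and body-diagonal steps), which are
near-unbiased for digitized straight lines at random orientations;
branch diameter is twice the median distance-transform radius over the
interior path voxels, the median resisting inflation near junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from angiotomo.graph import Branch, Node, VascularGraph
from angiotomo.segmentation import VesselMask

__all__ = ["Skeleton", "skeletonize", "skeleton_to_graph", "filter_by_diameter"]

# the 13 positive-halfspace neighbor offsets, grouped by squared step
_AXIS_OFFSETS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_FACE_DIAG_OFFSETS = [
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
]
_BODY_DIAG_OFFSETS = [(1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]


@dataclass
class Skeleton:
    """One-voxel-wide centerline voxels with per-voxel radius in μm."""

    voxels: np.ndarray  # (N, 3) int64, lexicographically sorted
    radius_um: np.ndarray  # (N,)
    spacing_um: float
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def skeletonize(mask: VesselMask, extend_tips: bool = True) -> Skeleton:
    """Topology-preserving 3D thinning of a vessel mask, with radii from
    the Euclidean distance transform.  An empty mask gives an empty
    skeleton.

    Thinning retracts centerlines from free tube ends by roughly the tube
    radius; with ``extend_tips`` each skeleton endpoint is marched outward
    along its local direction while still inside the mask, restoring the
    centerline to the cap of the tube.
    """
    m = mask.mask
    shape = tuple(m.shape)
    if not m.any():
        return Skeleton(
            np.empty((0, 3), dtype=np.int64), np.empty(0), mask.spacing_um, shape
        )
    skel = _sk_skeletonize(m).astype(bool)
    if not skel.any():
        # perfectly symmetric objects can erode away entirely (the medial
        # axis falls between voxels); keep the deepest voxel per component
        edt0 = ndimage.distance_transform_edt(m)
        labels, n = ndimage.label(m, structure=np.ones((3, 3, 3), bool))
        for lab in range(1, n + 1):
            comp = labels == lab
            idx = np.unravel_index(np.argmax(np.where(comp, edt0, -1)), m.shape)
            skel[idx] = True
    if extend_tips:
        _extend_skeleton_tips(skel, m)
    edt = ndimage.distance_transform_edt(m) * mask.spacing_um
    vox = np.argwhere(skel).astype(np.int64)  # lexicographic order
    radii = edt[vox[:, 0], vox[:, 1], vox[:, 2]]
    return Skeleton(vox, radii, mask.spacing_um, shape)


_ALL_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _extend_skeleton_tips(skel: np.ndarray, mask: np.ndarray, max_steps: int = 100) -> None:
    """March every skeleton endpoint along its terminal direction while the
    voxel stays inside the mask (in place)."""
    shape = np.array(skel.shape)
    skel_set = {tuple(v) for v in np.argwhere(skel)}

    def neighbors(v: tuple) -> list[tuple]:
        out = []
        for off in _ALL_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in skel_set:
                out.append(w)
        return out

    endpoints = [v for v in sorted(skel_set) if len(neighbors(v)) == 1]
    for end in endpoints:
        # estimate the terminal direction from a few chain steps back
        back = end
        prev = None
        for _ in range(4):
            nbs = [w for w in neighbors(back) if w != prev]
            if len(nbs) != 1:
                break
            prev, back = back, nbs[0]
        direction = np.array(end, dtype=float) - np.array(back, dtype=float)
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        direction /= norm
        pos = np.array(end, dtype=float)
        last = end
        for _ in range(max_steps):
            pos = pos + direction
            v = tuple(int(round(c)) for c in pos)
            if v == last:
                continue
            if any(c < 0 or c >= s for c, s in zip(v, shape)):
                break
            if not mask[v] or v in skel_set:
                break
            skel[v] = True
            skel_set.add(v)
            last = v


def _lookup(idx_vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Voxel index per coordinate row, -1 when outside or not skeleton."""
    shape = idx_vol.shape
    ok = np.all((coords >= 0) & (coords < np.array(shape)), axis=1)
    out = np.full(len(coords), -1, dtype=np.int64)
    c = coords[ok]
    out[ok] = idx_vol[c[:, 0], c[:, 1], c[:, 2]]
    return out


def _build_adjacency(voxels: np.ndarray, shape: tuple[int, int, int]) -> list[list[int]]:
    """Pruned 26-adjacency lists (sorted), dropping diagonal edges that are
    shortcut by an intermediate skeleton voxel."""
    n = len(voxels)
    idx_vol = np.full(shape, -1, dtype=np.int64)
    idx_vol[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = np.arange(n)

    edges_u: list[np.ndarray] = []
    edges_v: list[np.ndarray] = []

    def has(off: tuple[int, int, int], base: np.ndarray) -> np.ndarray:
        return _lookup(idx_vol, base + np.array(off)) >= 0

    for off in _AXIS_OFFSETS:
        v = _lookup(idx_vol, voxels + np.array(off))
        keep = v >= 0
        edges_u.append(np.nonzero(keep)[0])
        edges_v.append(v[keep])

    for off in _FACE_DIAG_OFFSETS:
        v = _lookup(idx_vol, voxels + np.array(off))
        present = v >= 0
        ei = (off[0], 0, 0) if off[0] else (0, off[1], 0)
        ej = (0, off[1], 0) if off[0] and off[1] else (0, 0, off[2])
        if off[0] and off[2] and not off[1]:
            ei, ej = (off[0], 0, 0), (0, 0, off[2])
        shortcut = has(ei, voxels) | has(ej, voxels)
        keep = present & ~shortcut
        edges_u.append(np.nonzero(keep)[0])
        edges_v.append(v[keep])

    for off in _BODY_DIAG_OFFSETS:
        v = _lookup(idx_vol, voxels + np.array(off))
        present = v >= 0
        oz, oy, ox = off
        subs = [
            (oz, 0, 0), (0, oy, 0), (0, 0, ox),
            (oz, oy, 0), (oz, 0, ox), (0, oy, ox),
        ]
        shortcut = np.zeros(len(voxels), dtype=bool)
        for s in subs:
            shortcut |= has(s, voxels)
        keep = present & ~shortcut
        edges_u.append(np.nonzero(keep)[0])
        edges_v.append(v[keep])

    adjacency: list[list[int]] = [[] for _ in range(n)]
    for uu, vv in zip(edges_u, edges_v):
        for u, v in zip(uu.tolist(), vv.tolist()):
            adjacency[u].append(v)
            adjacency[v].append(u)
    for lst in adjacency:
        lst.sort()
    return adjacency


def _vectorize(
    voxels: np.ndarray,
    radii: np.ndarray,
    spacing: float,
    shape: tuple[int, int, int],
    cycle_collapse_factor: float = 8.0,
) -> VascularGraph:
    """Raw vectorization plus cleanup passes: collapse of small cycles
    (thinning handles at thick junctions), then dissolution of any
    degree-2 junction nodes."""
    graph, members_of, adjacency = _vectorize_raw(voxels, radii, spacing, shape)
    if cycle_collapse_factor > 0:
        _collapse_small_cycles(graph, members_of, voxels, radii, cycle_collapse_factor)
    _dissolve_degree2_junctions(graph, members_of, voxels, adjacency, radii, spacing)
    return graph


def _vectorize_raw(
    voxels: np.ndarray,
    radii: np.ndarray,
    spacing: float,
    shape: tuple[int, int, int],
) -> tuple[VascularGraph, list[list[int]], list[list[int]]]:
    n = len(voxels)
    if n == 0:
        return VascularGraph([], [], spacing, {"cycle_nodes": []}), [], []
    adjacency = _build_adjacency(voxels, shape)
    deg = np.array([len(a) for a in adjacency])

    # node units: junction clusters (connected deg>=3 voxels), endpoints,
    # isolated voxels
    junction = deg >= 3
    units: list[tuple[list[int], str]] = []
    seen = np.zeros(n, dtype=bool)
    for i in np.nonzero(junction)[0]:
        if seen[i]:
            continue
        stack, members = [int(i)], []
        seen[i] = True
        while stack:
            u = stack.pop()
            members.append(u)
            for v in adjacency[u]:
                if junction[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        units.append((sorted(members), "junction"))
    for i in np.nonzero(deg == 1)[0]:
        units.append(([int(i)], "endpoint"))
    for i in np.nonzero(deg == 0)[0]:
        units.append(([int(i)], "endpoint"))
    units.sort(key=lambda u: u[0][0])

    node_of = np.full(n, -1, dtype=np.int64)
    nodes: list[Node] = []
    members_of: list[list[int]] = []
    for nid, (members, kind) in enumerate(units):
        for m in members:
            node_of[m] = nid
        pos = voxels[members].mean(axis=0) * spacing
        nodes.append(Node(nid, pos, kind, 0))
        members_of.append(members)

    # bias-corrected 26-chain step weights: the naive 1/√2/√3 weights
    # overestimate digitized straight lines by ~9% on average; these
    # classical chamfer weights are near-unbiased for random orientations
    step_len = {1: 0.9016, 2: 1.289, 3: 1.615}

    def path_length(path: list[int]) -> float:
        total = 0.0
        for a, b in zip(path, path[1:]):
            s = int(((voxels[a] - voxels[b]) ** 2).sum())
            total += step_len[s]
        return total * spacing

    def branch_diameter(path: list[int]) -> float:
        interior = path[1:-1] if len(path) > 2 else path
        return 2.0 * float(np.median(radii[interior]))

    branches: list[Branch] = []
    visited_slab = np.zeros(n, dtype=bool)
    short_edges: set[tuple[int, int]] = set()

    def add_branch(path: list[int]) -> None:
        bid = len(branches)
        branches.append(
            Branch(
                bid,
                int(node_of[path[0]]),
                int(node_of[path[-1]]),
                voxels[path],
                path_length(path),
                branch_diameter(path),
            )
        )

    for nid, members in enumerate(members_of):
        for m in members:
            for nb in adjacency[m]:
                if node_of[nb] >= 0:
                    if node_of[nb] == nid and nb in members:
                        continue  # internal cluster adjacency
                    key = (min(m, nb), max(m, nb))
                    if key in short_edges:
                        continue
                    short_edges.add(key)
                    add_branch([m, nb])
                elif not visited_slab[nb]:
                    path = [m, nb]
                    visited_slab[nb] = True
                    prev, cur = m, nb
                    while True:
                        nxt = [v for v in adjacency[cur] if v != prev]
                        if not nxt:
                            break  # dangling chain end (shouldn't happen)
                        v = nxt[0]
                        path.append(v)
                        if node_of[v] >= 0:
                            break
                        visited_slab[v] = True
                        prev, cur = cur, v
                    add_branch(path)

    # leftover slab voxels form pure cycles: one flagged single-node branch
    cycle_nodes: list[int] = []
    remaining = np.nonzero((deg == 2) & ~visited_slab & (node_of < 0))[0]
    handled = set()
    for start in remaining:
        start = int(start)
        if start in handled or visited_slab[start]:
            continue
        nid = len(nodes)
        nodes.append(Node(nid, voxels[start] * spacing, "junction", 0))
        members_of.append([start])
        node_of[start] = nid
        cycle_nodes.append(nid)
        path = [start]
        prev, cur = start, adjacency[start][0]
        while cur != start:
            path.append(cur)
            visited_slab[cur] = True
            handled.add(cur)
            nxt = [v for v in adjacency[cur] if v != prev]
            prev, cur = cur, nxt[0]
        path.append(start)
        handled.add(start)
        add_branch(path)

    graph = VascularGraph(nodes, branches, spacing, {"cycle_nodes": cycle_nodes})
    graph.recompute_degrees()
    return graph, members_of, adjacency


def _collapse_small_cycles(
    graph: VascularGraph,
    members_of: list[list[int]],
    voxels: np.ndarray,
    radii: np.ndarray,
    factor: float,
) -> None:
    """Contract graph cycles whose circumference is below ``factor`` times
    the thickest cycle branch's diameter.

    Noise handles (tunnels through a thick junction region) force thinning
    to keep a loop of circumference ~π × diameter; genuine vascular rings
    are far longer relative to their calibre.  All nodes on such a cycle
    merge into one junction, absorbing the cycle branches' voxels.
    """
    coord_index = {tuple(v): i for i, v in enumerate(voxels)}
    cycle_node_ids = set(graph.provenance.get("cycle_nodes", []))

    for _ in range(100):  # safety bound; each pass contracts one cycle
        node_ids = {n.id for n in graph.nodes}
        parent = {nid: nid for nid in node_ids}

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        forest: dict[int, list[tuple[int, Branch]]] = {nid: [] for nid in node_ids}
        chords: list[Branch] = []
        for b in sorted(graph.branches, key=lambda b: (b.length_um, b.id)):
            if b.node_a == b.node_b:
                if b.node_a not in cycle_node_ids:
                    chords.append(b)  # self-loop at a regular node
                continue
            ra, rb = find(b.node_a), find(b.node_b)
            if ra == rb:
                chords.append(b)
            else:
                parent[ra] = rb
                forest[b.node_a].append((b.node_b, b))
                forest[b.node_b].append((b.node_a, b))

        contracted = False
        for chord in chords:
            if chord.node_a == chord.node_b:
                cycle_branches = [chord]
                cycle_nodes = {chord.node_a}
            else:
                path = _forest_path(forest, chord.node_a, chord.node_b)
                if path is None:
                    continue
                cycle_branches = [chord] + [b for _, b in path]
                cycle_nodes = {chord.node_a, chord.node_b}
                for nid, _b in path:
                    cycle_nodes.add(nid)
            total = sum(b.length_um for b in cycle_branches)
            max_d = max(b.diameter_um for b in cycle_branches)
            if total >= factor * max_d:
                continue
            # contract the cycle into its lowest-id node
            keep = min(cycle_nodes)
            absorbed: list[int] = []
            for b in cycle_branches:
                for vox_coord in b.path[1:-1]:
                    idx = coord_index.get(tuple(vox_coord))
                    if idx is not None:
                        absorbed.append(idx)
            for nid in cycle_nodes:
                if nid != keep:
                    absorbed.extend(members_of[nid])
                    members_of[nid] = []
            members_of[keep] = sorted(set(members_of[keep]) | set(absorbed))
            drop_ids = {b.id for b in cycle_branches}
            graph.branches = [b for b in graph.branches if b.id not in drop_ids]
            gone = cycle_nodes - {keep}
            graph.nodes = [n for n in graph.nodes if n.id not in gone]
            for b in graph.branches:
                if b.node_a in gone:
                    b.node_a = keep
                if b.node_b in gone:
                    b.node_b = keep
            for n in graph.nodes:
                if n.id == keep:
                    n.kind = "junction"
                    if members_of[keep]:
                        n.position_um = voxels[members_of[keep]].mean(axis=0) * graph.spacing_um
            graph.recompute_degrees()
            contracted = True
            break
        if not contracted:
            return


def _forest_path(
    forest: dict[int, list[tuple[int, Branch]]], start: int, goal: int
) -> list[tuple[int, Branch]] | None:
    """Path from start to goal in the spanning forest as (node, branch)
    steps, excluding the start node."""
    prev: dict[int, tuple[int, Branch] | None] = {start: None}
    queue = [start]
    while queue:
        u = queue.pop(0)
        if u == goal:
            break
        for v, b in forest[u]:
            if v not in prev:
                prev[v] = (u, b)
                queue.append(v)
    if goal not in prev:
        return None
    path: list[tuple[int, Branch]] = []
    cur = goal
    while prev[cur] is not None:
        u, b = prev[cur]
        path.append((cur, b))
        cur = u
    return path


def _dissolve_degree2_junctions(
    graph: VascularGraph,
    members_of: list[list[int]],
    voxels: np.ndarray,
    adjacency: list[list[int]],
    radii: np.ndarray,
    spacing: float,
) -> None:
    """Merge the two branches meeting at any junction node of degree 2
    (a cluster whose external connectivity degenerated); such nodes must
    not survive vectorization."""
    cycle_ids = set(graph.provenance.get("cycle_nodes", []))
    changed = False
    while True:
        target = None
        for node in graph.nodes:
            if node.kind == "junction" and node.degree == 2 and node.id not in cycle_ids:
                incident = [b for b in graph.branches if node.id in (b.node_a, b.node_b)]
                if len(incident) == 2:
                    target = (node, incident)
                    break
        if target is None:
            break
        node, (b1, b2) = target
        changed = True

        def oriented_into(b: Branch) -> np.ndarray:
            return b.path if b.node_b == node.id else b.path[::-1]

        p1 = oriented_into(b1)  # ends at the node
        p2 = oriented_into(b2)[::-1]  # starts at the node
        # connect through the cluster members if the two attachment voxels differ
        joint = _cluster_path(members_of[node.id], tuple(p1[-1]), tuple(p2[0]), voxels, adjacency)
        merged_path = np.concatenate([p1, joint, p2], axis=0)
        other_a = b1.node_a if b1.node_b == node.id else b1.node_b
        other_b = b2.node_b if b2.node_a == node.id else b2.node_a
        dedup = [merged_path[0]]
        for row in merged_path[1:]:
            if not np.array_equal(row, dedup[-1]):
                dedup.append(row)
        merged_path = np.array(dedup)
        length = 0.0
        for a, b in zip(merged_path[:-1], merged_path[1:]):
            length += float(np.sqrt(((a - b) ** 2).sum()))
        length *= spacing
        interior = merged_path[1:-1] if len(merged_path) > 2 else merged_path
        idx_map = {tuple(v): i for i, v in enumerate(voxels)}
        r = [radii[idx_map[tuple(v)]] for v in interior if tuple(v) in idx_map]
        diameter = 2.0 * float(np.median(r)) if r else max(b1.diameter_um, b2.diameter_um)
        new = Branch(b1.id, other_a, other_b, merged_path, length, diameter)
        graph.branches = [b for b in graph.branches if b.id not in (b1.id, b2.id)] + [new]
        graph.nodes = [n for n in graph.nodes if n.id != node.id]
        graph.recompute_degrees()
    if changed:
        for i, b in enumerate(sorted(graph.branches, key=lambda b: b.id)):
            b.id = i
        graph.branches.sort(key=lambda b: b.id)


def _cluster_path(
    members: list[int],
    start: tuple,
    goal: tuple,
    voxels: np.ndarray,
    adjacency: list[list[int]],
) -> np.ndarray:
    if start == goal:
        return np.empty((0, 3), dtype=np.int64)
    index_of = {tuple(voxels[m]): m for m in members}
    member_set = set(members)
    s, g = index_of[start], index_of[goal]
    prev = {s: None}
    queue = [s]
    while queue:
        u = queue.pop(0)
        if u == g:
            break
        for v in adjacency[u]:
            if v in member_set and v not in prev:
                prev[v] = u
                queue.append(v)
    if g not in prev:
        return np.empty((0, 3), dtype=np.int64)
    path = []
    cur = g
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    path.reverse()
    return voxels[path[1:-1]] if len(path) > 2 else np.empty((0, 3), dtype=np.int64)


def skeleton_to_graph(skel: Skeleton, prune_factor: float = 2.0) -> VascularGraph:
    """Vectorize a skeleton into a vascular graph, pruning terminal spur
    branches shorter than ``prune_factor`` × their own diameter and
    re-vectorizing once."""
    if prune_factor < 0:
        raise ValueError("prune_factor must be nonnegative")
    graph = _vectorize(skel.voxels, skel.radius_um, skel.spacing_um, skel.shape)
    if prune_factor == 0 or not graph.branches:
        graph.provenance["prune_factor"] = prune_factor
        graph.provenance["pruned_branches"] = 0
        return graph

    node_by_id = {n.id: n for n in graph.nodes}
    drop_voxels: set[tuple] = set()
    n_pruned = 0
    for b in graph.branches:
        na, nb = node_by_id[b.node_a], node_by_id[b.node_b]
        spur_end = None
        if na.kind == "endpoint" and na.degree == 1 and nb.kind == "junction":
            spur_end = "a"
        elif nb.kind == "endpoint" and nb.degree == 1 and na.kind == "junction":
            spur_end = "b"
        if spur_end is None:
            continue
        if b.length_um < prune_factor * b.diameter_um:
            # drop the interior plus the free endpoint, keep the junction voxel
            kept = b.path[-1] if spur_end == "a" else b.path[0]
            for v in b.path:
                if not np.array_equal(v, kept):
                    drop_voxels.add(tuple(v))
            n_pruned += 1
    if n_pruned == 0:
        graph.provenance["prune_factor"] = prune_factor
        graph.provenance["pruned_branches"] = 0
        return graph

    keep = np.array([tuple(v) not in drop_voxels for v in skel.voxels])
    graph = _vectorize(skel.voxels[keep], skel.radius_um[keep], skel.spacing_um, skel.shape)
    graph.provenance["prune_factor"] = prune_factor
    graph.provenance["pruned_branches"] = n_pruned
    return graph


def filter_by_diameter(
    graph: VascularGraph, min_um: float = 0.0, max_um: float = float("inf")
) -> VascularGraph:
    """Retain branches with min_um ≤ diameter < max_um; node degrees are
    recomputed and orphaned nodes dropped."""
    if min_um > max_um:
        raise ValueError(f"min_um ({min_um}) exceeds max_um ({max_um})")
    out = VascularGraph(
        nodes=[Node(n.id, n.position_um.copy(), n.kind, n.degree) for n in graph.nodes],
        branches=[
            Branch(b.id, b.node_a, b.node_b, b.path.copy(), b.length_um, b.diameter_um)
            for b in graph.branches
            if min_um <= b.diameter_um < max_um
        ],
        spacing_um=graph.spacing_um,
        provenance=dict(graph.provenance, diameter_filter_um=(min_um, max_um)),
    )
    out.recompute_degrees()
    out.drop_orphan_nodes()
    for i, b in enumerate(out.branches):
        b.id = i
    return out
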