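"""Synthetic 3D vascular phantoms with known ground truth.

The generator emulates reconstructed micro-CT volumes of cerebral
vasculature: bright tubular vessels (radii ~5–25 μm, i.e. diameters
covering the 10–50 μm display range) on a darker parenchyma background
at 5.2 μm isotropic voxels.  A sample is a *forest* of stochastic binary
branching trees whose radii split by Murray's law
(r_parent^m = r_child1^m + r_child2^m, m = 3 by default); trees are
non-self-intersecting by construction so the ground-truth topology
(branch and node counts) is well defined for recovery tests.

Five condition templates mimic an ischemic-stroke time course:

- ``sham``  — baseline network, no focal changes;
- ``4h``/``6h`` — extra short small-calibre microvessels (radii 5–10 μm)
  attached in the penumbral shell around the focus, denser at 6 h;
- ``3d``/``18d`` — a vessel-free spherical cavity carved at the focus,
  larger at 18 d.

Everything is driven by a single seeded RNG stream per sample, so
identical specs yield bit-identical volumes and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from angiotomo.io import Volume

__all__ = [
    "TreeSpec",
    "ConditionSpec",
    "ImagingModel",
    "GroundTruth",
    "CONDITIONS",
    "condition_template",
    "grow_tree",
    "grow_forest",
    "rasterize",
    "rasterize_mask",
    "simulate_sample",
    "SimulatedSample",
]

CONDITIONS = ("sham", "4h", "6h", "3d", "18d")

#: added penumbral microvessels per μm³ of penumbral shell at multiplier 1
PENUMBRA_DENSITY_PER_UM3 = 4.0e-6
#: radius range of penumbral microvessels, μm (diameters 10–20 μm)
PENUMBRA_RADIUS_RANGE_UM = (5.0, 10.0)
#: length range of penumbral microvessels, μm ("short and discontinuous")
PENUMBRA_LENGTH_RANGE_UM = (50.0, 90.0)
#: surface clearance kept between distinct vessel segments, μm
_CLEARANCE_UM = 4.0
#: centerline sampling step as a fraction of voxel spacing
_STEP_FRACTION = 0.5
#: segment length scales with calibre: drawn length × (r/root_r)^this
_LENGTH_RADIUS_EXPONENT = 0.7
#: forest target centerline length per μm³ (sets inter-vessel gaps ~100 μm)
DEFAULT_LENGTH_DENSITY_PER_UM2 = 2.8e-4


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of one stochastic vascular tree.

    ``n_branch_events`` counts bifurcation attempts; children whose Murray
    radius falls below ``min_radius_um`` or that cannot be placed without
    collision are not generated, so realized branch counts can be lower.
    """

    seed: int
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_um: float = 5.2
    root_radius_um: float = 25.0
    n_branch_events: int = 60
    branch_angle_deg: float = 40.0
    murray_exponent: float = 3.0
    min_radius_um: float = 5.0
    segment_length_range_um: tuple[float, float] = (115.0, 185.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.volume_shape)
        object.__setattr__(self, "volume_shape", shape)
        if len(shape) != 3 or min(shape) < 16:
            raise ValueError("volume_shape must be three integers, each >= 16")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be positive")
        if not 0 < self.min_radius_um < self.root_radius_um:
            raise ValueError("need 0 < min_radius_um < root_radius_um")
        if self.n_branch_events < 0:
            raise ValueError("n_branch_events must be nonnegative")
        if not 0 < self.branch_angle_deg <= 90:
            raise ValueError("branch_angle_deg must lie in (0, 90]")
        if not self.murray_exponent > 0:
            raise ValueError("murray_exponent must be positive")
        lo, hi = self.segment_length_range_um
        if not 0 < lo <= hi:
            raise ValueError("segment_length_range_um must be positive and ordered")


@dataclass(frozen=True)
class ConditionSpec:
    """Concrete focal parameters of one experimental condition.

    ``focal_center`` is in voxel coordinates (z, y, x).  The penumbral
    shell is the annulus between ``focal_radius_um`` and twice it; extra
    microvessels attach only there, never inside the focus itself.
    """

    condition: str
    focal_center: tuple[float, float, float]
    focal_radius_um: float
    penumbra_density_multiplier: float
    cavity_radius_um: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; valid labels: {', '.join(CONDITIONS)}"
            )
        if not self.focal_radius_um > 0:
            raise ValueError("focal_radius_um must be positive")
        if self.penumbra_density_multiplier < 0 or self.cavity_radius_um < 0:
            raise ValueError("density multiplier and cavity radius must be nonnegative")


@dataclass(frozen=True)
class ImagingModel:
    """Stand-in for the reconstructed-slice appearance of the vasculature.

    Vessels are imaged bright on a darker parenchyma; blur emulates the
    system PSF, additive Gaussian noise the reconstruction noise, and the
    optional concentric modulation a ring artifact.
    """

    vessel_intensity: float = 100.0
    background_intensity: float = 20.0
    psf_sigma_um: float = 2.6
    noise_sigma: float = 8.0
    ring_artifact_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not self.vessel_intensity > self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity")
        if self.psf_sigma_um < 0 or self.noise_sigma < 0 or self.ring_artifact_amplitude < 0:
            raise ValueError("psf, noise and ring amplitudes must be nonnegative")

    @property
    def snr(self) -> float:
        if self.noise_sigma == 0:
            return math.inf
        return (self.vessel_intensity - self.background_intensity) / self.noise_sigma


@dataclass
class GroundTruth:
    """Known geometry and topology of a phantom.

    ``centerlines`` are (N, 3) μm coordinate arrays in (z, y, x) order,
    one per branch after merging degree-2 joints; ``radii_um`` is the
    length-weighted mean radius per branch, ``point_radii_um`` the
    per-sample radii used for rasterization.
    """

    centerlines: list[np.ndarray]
    radii_um: list[float]
    point_radii_um: list[np.ndarray]
    n_branches: int
    n_nodes: int
    total_length_um: float
    cavity_mask: np.ndarray | None
    spacing_um: float
    volume_shape: tuple[int, int, int]
    bifurcations: list[tuple[float, float, float]] = field(default_factory=list)
    clip_warnings: int = 0


def condition_template(
    name: str,
    volume_shape: tuple[int, int, int] = (96, 96, 96),
    spacing_um: float = 5.2,
) -> ConditionSpec:
    """Default :class:`ConditionSpec` for one of the five groups.

    Focal and cavity radii scale with the field of view (minimum volume
    extent F): focal radius 0.20 F; cavity radius 0.34 F at 3 d and
    0.46 F at 18 d.  Penumbral multipliers are 0 (sham), 1.0 (4 h),
    1.5 (6 h) and 0 again at 3 d/18 d, which orders expected branch
    counts sham < 4h < 6h with 3 d/18 d falling below the 6 h peak once
    the cavity removes focal vessels.
    """
    if name not in CONDITIONS:
        raise ValueError(
            f"unknown condition {name!r}; valid labels: {', '.join(CONDITIONS)}"
        )
    field_um = min(volume_shape) * spacing_um
    center = tuple(s / 2.0 for s in volume_shape)
    multiplier = {"sham": 0.0, "4h": 1.0, "6h": 1.5, "3d": 0.0, "18d": 0.0}[name]
    cavity = {"sham": 0.0, "4h": 0.0, "6h": 0.0, "3d": 0.34, "18d": 0.46}[name] * field_um
    return ConditionSpec(
        condition=name,
        focal_center=center,
        focal_radius_um=0.20 * field_um,
        penumbra_density_multiplier=multiplier,
        cavity_radius_um=cavity,
    )


# ---------------------------------------------------------------------------
# growth machinery


class _Growth:
    """Shared state of a growing forest: all centerline sample points with
    their radii, for collision tests, plus the polyline pieces."""

    def __init__(self, spec: TreeSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.bounds_um = np.array(spec.volume_shape, dtype=float) * spec.spacing_um
        self.step_um = spec.spacing_um * _STEP_FRACTION
        self.total_length_um = 0.0
        self.pieces: list[dict] = []  # {"points": (N,3) μm, "radius": float}
        self._pts: list[np.ndarray] = []
        self._radii: list[np.ndarray] = []
        self._tree: cKDTree | None = None
        self._max_radius = 0.0
        self.clip_warnings = 0
        self.bifurcations: list[tuple[float, float, float]] = []

    # -- collision field ----------------------------------------------------
    def _kdtree(self) -> cKDTree | None:
        if not self._pts:
            return None
        if self._tree is None:
            self._tree = cKDTree(np.concatenate(self._pts, axis=0))
        return self._tree

    def _register(self, points: np.ndarray, radius: float) -> None:
        self._pts.append(points)
        self._radii.append(np.full(len(points), radius))
        self._tree = None
        self._max_radius = max(self._max_radius, radius)

    def collides(self, points: np.ndarray, radius: float, anchor_um: np.ndarray | None,
                 anchor_clear_um: float = 0.0) -> bool:
        """True if any sample point comes within (radius + r_other + clearance)
        of an existing centerline point, ignoring points near ``anchor_um``
        (the attachment site on the parent)."""
        tree = self._kdtree()
        if tree is None:
            return False
        all_radii = np.concatenate(self._radii)
        query_r = radius + self._max_radius + _CLEARANCE_UM
        check = points
        if anchor_um is not None:
            keep = np.linalg.norm(points - anchor_um, axis=1) > anchor_clear_um
            check = points[keep]
        for p in check:
            for j in tree.query_ball_point(p, query_r):
                if anchor_um is not None:
                    # neighbours belonging to the immediate parent vicinity
                    pt = tree.data[j]
                    if np.linalg.norm(pt - anchor_um) <= anchor_clear_um:
                        continue
                if np.linalg.norm(tree.data[j] - p) < radius + all_radii[j] + _CLEARANCE_UM:
                    return True
        return False

    # -- segment construction ----------------------------------------------
    def propose_segment(
        self,
        start_um: np.ndarray,
        direction: np.ndarray,
        length_um: float,
        radius: float,
        check_collision: bool = True,
    ) -> np.ndarray | None:
        """Sampled straight segment from ``start_um``, clipped to the volume;
        None if it cannot be placed."""
        # generous boundary margin: blur and noise must not push the tube's
        # mask against the volume face, where a flat cut breeds artifacts
        margin = radius + 3.0 * self.spec.spacing_um
        lo = np.full(3, margin)
        hi = self.bounds_um - margin
        # clip length so the endpoint stays inside the margin box
        t_max = length_um
        for ax in range(3):
            d = direction[ax]
            if d > 1e-12:
                t_max = min(t_max, (hi[ax] - start_um[ax]) / d)
            elif d < -1e-12:
                t_max = min(t_max, (lo[ax] - start_um[ax]) / d)
        if t_max < length_um - 1e-9:
            self.clip_warnings += 1
        # a tube must clearly outlast both its parent's girth and the
        # spur-pruning scale (2x diameter) — shorter stubs are not vessels
        min_len = max(2 * self.spec.spacing_um, 3 * self.step_um, 4.5 * radius)
        if t_max < min_len:
            return None
        n = max(2, int(math.ceil(t_max / self.step_um)) + 1)
        ts = np.linspace(0.0, t_max, n)
        points = start_um[None, :] + ts[:, None] * direction[None, :]
        if check_collision:
            anchor_clear = 2.0 * (radius + self._max_radius) + 2 * self.step_um
            if self.collides(points, radius, start_um, anchor_clear):
                return None
        return points

    def add_piece(self, points: np.ndarray, radius: float) -> int:
        self.pieces.append({"points": points, "radius": radius})
        self._register(points, radius)
        self.total_length_um += _polyline_length(points)
        return len(self.pieces) - 1


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _rotate_from(direction: np.ndarray, angle_rad: float, azimuth_rad: float) -> np.ndarray:
    """Unit vector at ``angle_rad`` from ``direction``, azimuth measured in
    the plane orthogonal to it."""
    d = direction / np.linalg.norm(direction)
    # orthonormal frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return (
        math.cos(angle_rad) * d
        + math.sin(angle_rad) * (math.cos(azimuth_rad) * e1 + math.sin(azimuth_rad) * e2)
    )


def _grow_one_tree(
    growth: _Growth,
    root_um: np.ndarray,
    root_dir: np.ndarray,
    root_radius_um: float | None = None,
) -> None:
    """Grow one binary tree into the shared collision field.

    Drawn segment lengths scale with calibre as (r / root_r)^0.7, so
    distal branches are proportionally shorter — matching vascular
    morphometry and letting thin branches fill inter-vessel gaps.
    """
    spec = growth.spec
    rng = growth.rng
    m = spec.murray_exponent
    lo, hi = spec.segment_length_range_um
    r_root = spec.root_radius_um if root_radius_um is None else root_radius_um

    def draw_length(radius: float) -> float:
        scale = (radius / spec.root_radius_um) ** _LENGTH_RADIUS_EXPONENT
        return rng.uniform(lo, hi) * scale

    seg = growth.propose_segment(
        root_um, root_dir, draw_length(r_root), r_root, check_collision=True
    )
    if seg is None:
        growth.clip_warnings += 1
        return
    growth.add_piece(seg, r_root)
    # tips: (end point, direction, radius)
    tips: list[tuple[np.ndarray, np.ndarray, float]] = [(seg[-1], root_dir, r_root)]

    events = 0
    while events < spec.n_branch_events and tips:
        idx = int(rng.integers(len(tips)))
        tip_pos, tip_dir, tip_r = tips.pop(idx)
        events += 1
        u = rng.uniform(0.35, 0.65)
        r_children = (tip_r * u ** (1.0 / m), tip_r * (1.0 - u) ** (1.0 / m))
        growth.bifurcations.append((tip_r, r_children[0], r_children[1]))
        base_azimuth = rng.uniform(0.0, 2.0 * math.pi)
        for child_idx, r_child in enumerate(r_children):
            if r_child < spec.min_radius_um:
                continue
            placed = False
            for _attempt in range(6):
                angle = math.radians(spec.branch_angle_deg) * rng.uniform(0.6, 1.2)
                # siblings leave on opposite sides of the parent axis so the
                # two daughter tubes separate cleanly at the junction
                azimuth = base_azimuth + child_idx * math.pi + rng.uniform(-0.5, 0.5)
                direction = _rotate_from(tip_dir, angle, azimuth)
                seg = growth.propose_segment(
                    tip_pos, direction, draw_length(r_child), r_child
                )
                if seg is not None:
                    growth.add_piece(seg, r_child)
                    tips.append((seg[-1], direction, r_child))
                    placed = True
                    break
            if not placed:
                growth.clip_warnings += 1


def _attach_penumbral_vessels(growth: _Growth, condition: ConditionSpec) -> None:
    """Attach short small-calibre microvessels in the penumbral shell
    (outside the focus, within twice its radius), splitting host pieces at
    the attachment point so topology stays well defined."""
    if condition.penumbra_density_multiplier <= 0:
        return
    spec = growth.spec
    rng = growth.rng
    center = np.asarray(condition.focal_center, dtype=float) * spec.spacing_um
    r_in = condition.focal_radius_um
    r_out = 2.0 * condition.focal_radius_um
    shell_volume = 4.0 / 3.0 * math.pi * (r_out**3 - r_in**3)
    n_target = int(round(
        condition.penumbra_density_multiplier * PENUMBRA_DENSITY_PER_UM3 * shell_volume
    ))
    for _ in range(n_target):
        # eligible attachment samples (recomputed: hosts get split as we go)
        candidates = []
        for pi, piece in enumerate(growth.pieces):
            d = np.linalg.norm(piece["points"] - center, axis=1)
            ok = np.nonzero((d > r_in) & (d <= r_out))[0]
            if len(ok):
                candidates.append((pi, ok))
        if not candidates:
            break
        weights = np.array([len(ok) for _, ok in candidates], dtype=float)
        pick = int(rng.choice(len(candidates), p=weights / weights.sum()))
        pi, ok = candidates[pick]
        k = int(ok[rng.integers(len(ok))])
        host = growth.pieces[pi]
        anchor = host["points"][k].copy()
        radius = rng.uniform(*PENUMBRA_RADIUS_RANGE_UM)
        placed = None
        for _attempt in range(6):
            direction = _random_unit(rng)
            seg = growth.propose_segment(
                anchor, direction, rng.uniform(*PENUMBRA_LENGTH_RANGE_UM), radius
            )
            if seg is not None:
                placed = seg
                break
        if placed is None:
            continue
        # split the host at the anchor so the attachment becomes a junction
        if 0 < k < len(host["points"]) - 1:
            left = host["points"][: k + 1]
            right = host["points"][k:]
            host_radius = host["radius"]
            growth.pieces[pi] = {"points": left, "radius": host_radius}
            growth.pieces.append({"points": right, "radius": host_radius})
        growth.add_piece(placed, radius)


def _carve_cavity(pieces: list[dict], condition: ConditionSpec, spacing_um: float) -> list[dict]:
    """Delete all centerline geometry within the cavity radius of the focus."""
    if condition.cavity_radius_um <= 0:
        return pieces
    center = np.asarray(condition.focal_center, dtype=float) * spacing_um
    out: list[dict] = []
    for piece in pieces:
        keep = np.linalg.norm(piece["points"] - center, axis=1) >= condition.cavity_radius_um
        if keep.all():
            out.append(piece)
            continue
        # contiguous surviving runs of at least two samples become pieces
        idx = np.nonzero(keep)[0]
        if len(idx) < 2:
            continue
        splits = np.nonzero(np.diff(idx) > 1)[0]
        for run in np.split(idx, splits + 1):
            if len(run) >= 2:
                out.append({"points": piece["points"][run], "radius": piece["radius"]})
    return out


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _merge_topology(pieces: list[dict]) -> tuple[list[dict], int, int, float]:
    """Merge polyline pieces through degree-2 joints and count topology.

    Returns (merged branches with per-point radii, n_branches, n_nodes,
    total length).  Nodes are coordinates where exactly one piece ends
    (endpoints) or at least three meet (junctions); pure cycles count one
    node each.
    """
    def key(p: np.ndarray) -> tuple:
        return tuple(np.round(p, 4))

    ends: dict[tuple, list[tuple[int, int]]] = {}
    for pi, piece in enumerate(pieces):
        ends.setdefault(key(piece["points"][0]), []).append((pi, 0))
        ends.setdefault(key(piece["points"][-1]), []).append((pi, 1))

    degree = {k: len(v) for k, v in ends.items()}
    merged: list[dict] = []
    used = [False] * len(pieces)

    def piece_arrays(pi: int, forward: bool) -> tuple[np.ndarray, np.ndarray]:
        piece = pieces[pi]
        pts = piece["points"] if forward else piece["points"][::-1]
        return pts, np.full(len(pts), piece["radius"])

    def walk(pi: int, start_end: int) -> dict:
        """Follow a chain starting by traversing piece ``pi`` away from its
        ``start_end`` (0=first point, 1=last point)."""
        pts, rad = piece_arrays(pi, forward=(start_end == 0))
        used[pi] = True
        chain_pts = [pts]
        chain_rad = [rad]
        cur = key(pts[-1])
        while degree.get(cur, 0) == 2:
            nxt = [(qj, e) for qj, e in ends[cur] if not used[qj]]
            if not nxt:
                break  # closed back onto the start (cycle) or already consumed
            qj, e = nxt[0]
            pts, rad = piece_arrays(qj, forward=(e == 0))
            used[qj] = True
            chain_pts.append(pts[1:])
            chain_rad.append(rad[1:])
            cur = key(pts[-1])
        return {
            "points": np.concatenate(chain_pts, axis=0),
            "point_radii": np.concatenate(chain_rad),
        }

    # start walks at non-degree-2 ends
    for k, incid in sorted(ends.items()):
        if degree[k] == 2:
            continue
        for pi, e in incid:
            if not used[pi]:
                merged.append(walk(pi, e))
    n_cycles = 0
    for pi in range(len(pieces)):  # pure cycles
        if not used[pi]:
            merged.append(walk(pi, 0))
            n_cycles += 1

    n_branches = len(merged)
    n_endpoints = sum(1 for k, d in degree.items() if d == 1)
    n_junctions = sum(1 for k, d in degree.items() if d >= 3)
    n_nodes = n_endpoints + n_junctions + n_cycles
    total = float(sum(_polyline_length(m["points"]) for m in merged))
    return merged, n_branches, n_nodes, total


def _build_truth(growth: _Growth, condition: ConditionSpec | None) -> GroundTruth:
    spec = growth.spec
    pieces = growth.pieces
    cavity_mask = None
    if condition is not None:
        pieces = _carve_cavity(pieces, condition, spec.spacing_um)
        if condition.cavity_radius_um > 0:
            cavity_mask = _ball_mask(
                spec.volume_shape,
                np.asarray(condition.focal_center, dtype=float),
                condition.cavity_radius_um / spec.spacing_um,
            )
    merged, n_branches, n_nodes, total = _merge_topology(pieces)
    centerlines = [m["points"] for m in merged]
    point_radii = [m["point_radii"] for m in merged]
    radii = []
    for pts, rad in zip(centerlines, point_radii):
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mid = 0.5 * (rad[:-1] + rad[1:])
        radii.append(float(np.average(mid, weights=seg)) if seg.sum() > 0 else float(rad.mean()))
    return GroundTruth(
        centerlines=centerlines,
        radii_um=radii,
        point_radii_um=point_radii,
        n_branches=n_branches,
        n_nodes=n_nodes,
        total_length_um=total,
        cavity_mask=cavity_mask,
        spacing_um=spec.spacing_um,
        volume_shape=spec.volume_shape,
        bifurcations=list(growth.bifurcations),
        clip_warnings=growth.clip_warnings,
    )


def _ball_mask(shape: tuple[int, int, int], center_vox: np.ndarray, radius_vox: float) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        (zz - center_vox[0]) ** 2
        + (yy - center_vox[1]) ** 2
        + (xx - center_vox[2]) ** 2
    )
    return d2 <= radius_vox**2


def grow_tree(spec: TreeSpec, condition: ConditionSpec | None = None) -> GroundTruth:
    """Grow a single connected branching tree (plus any condition effects).

    The root is placed in the interior of the volume with a random
    orientation; radii at each bifurcation satisfy Murray's law with the
    spec's exponent, and children falling below ``min_radius_um`` are not
    generated.  Geometry escaping the volume is clipped (counted in
    ``clip_warnings``).
    """
    rng = np.random.default_rng(spec.seed)
    growth = _Growth(spec, rng)
    bounds = growth.bounds_um
    for _attempt in range(10):
        root = rng.uniform(0.2, 0.8, size=3) * bounds
        _grow_one_tree(growth, root, _random_unit(rng))
        if growth.pieces:
            break
    if condition is not None:
        _attach_penumbral_vessels(growth, condition)
    return _build_truth(growth, condition)


def grow_forest(
    spec: TreeSpec,
    condition: ConditionSpec | None = None,
    n_trees: int | None = None,
    target_length_density: float | None = None,
) -> GroundTruth:
    """Grow several trees into one shared, collision-free field.

    A single Murray tree rooted at ~25 μm exhausts its radius budget after
    a handful of splits, so realistic tissue-level vessel density needs a
    forest.  With ``n_trees`` unset, trees (the first at the spec's root
    calibre, later ones down to ~55% of it) are added until the centerline
    length density reaches ``target_length_density`` (default 2.8×10⁻⁴
    μm/μm³, putting typical inter-vessel gaps near 100 μm) or a hard tree
    cap is hit.
    """
    rng = np.random.default_rng(spec.seed)
    growth = _Growth(spec, rng)
    bounds = growth.bounds_um
    vol_um3 = float(np.prod(bounds))
    if n_trees is not None:
        target_len = None
        max_trees = n_trees
    else:
        density = target_length_density or DEFAULT_LENGTH_DENSITY_PER_UM2
        target_len = density * vol_um3
        max_trees = 400
    for tree_idx in range(max_trees):
        if target_len is not None and growth.total_length_um >= target_len:
            break
        r_root = spec.root_radius_um if tree_idx == 0 else (
            spec.root_radius_um * rng.uniform(0.55, 1.0)
        )
        for _attempt in range(10):
            root = rng.uniform(0.07, 0.93, size=3) * bounds
            direction = _random_unit(rng)
            before = len(growth.pieces)
            _grow_one_tree(growth, root, direction, r_root)
            if len(growth.pieces) > before:
                break
    if condition is not None:
        _attach_penumbral_vessels(growth, condition)
    return _build_truth(growth, condition)


# ---------------------------------------------------------------------------
# rasterization


def _stamp_cylinder(mask: np.ndarray, a: np.ndarray, b: np.ndarray, r_vox: float) -> None:
    """Mark voxels inside the flat-capped finite cylinder from a to b
    (voxel coordinates)."""
    dims = np.array(mask.shape)
    lo = np.maximum(np.floor(np.minimum(a, b) - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(a, b) + r_vox).astype(int) + 1, dims)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    p = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = b - a
    L2 = float(np.dot(d, d))
    if L2 < 1e-18:
        inside = np.sum((p - a) ** 2, axis=-1) <= r_vox**2 + 1e-9
    else:
        t = np.tensordot(p - a, d, axes=([-1], [0])) / L2
        perp2 = np.sum((p - a - t[..., None] * d) ** 2, axis=-1)
        inside = (t >= 0.0) & (t <= 1.0) & (perp2 <= r_vox**2 + 1e-9)
    view = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    view |= inside


def _stamp_ball(mask: np.ndarray, c: np.ndarray, r_vox: float) -> None:
    dims = np.array(mask.shape)
    lo = np.maximum(np.floor(c - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c + r_vox).astype(int) + 1, dims)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
    view = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    view |= d2 <= r_vox**2 + 1e-9


def _straight_runs(pts: np.ndarray, radii: np.ndarray):
    """Split a sampled polyline into maximal straight constant-radius runs:
    yields (start_point, end_point, radius, is_first, is_last)."""
    n = len(pts)
    start = 0
    runs = []
    for i in range(1, n):
        if i == n - 1:
            runs.append((start, i))
            break
        d1 = pts[i] - pts[start]
        d2 = pts[i + 1] - pts[i]
        collinear = np.linalg.norm(np.cross(d1, d2)) <= 1e-6 * max(
            np.linalg.norm(d1) * np.linalg.norm(d2), 1e-12
        )
        if not collinear or radii[i + 1] != radii[start]:
            runs.append((start, i))
            start = i
    for k, (i, j) in enumerate(runs):
        yield pts[i], pts[j], float(radii[i]), k == 0, k == len(runs) - 1


def rasterize_mask(truth: GroundTruth) -> np.ndarray:
    """Binary voxel mask of the phantom: flat-capped tubes around every
    centerline, so the mask's axial extent matches the centerline extent
    (no hemispherical overhang past branch tips).  Interior bend points get
    a ball to fill the outer wedge between consecutive straight runs."""
    shape = truth.volume_shape
    spacing = truth.spacing_um
    mask = np.zeros(shape, dtype=bool)
    for pts, radii in zip(truth.centerlines, truth.point_radii_um):
        vox = pts / spacing
        for a, b, r_um, first, last in _straight_runs(vox, radii):
            r_vox = r_um / spacing
            _stamp_cylinder(mask, a, b, r_vox)
            if not first:
                _stamp_ball(mask, a, r_vox)
    return mask


def rasterize(truth: GroundTruth, spec: TreeSpec, model: ImagingModel) -> Volume:
    """Render the phantom as an imaged volume: vessel/background intensities,
    Gaussian PSF blur, additive Gaussian noise and an optional concentric
    ring modulation.  Deterministic for a fixed spec seed."""
    mask = rasterize_mask(truth)
    data = np.full(truth.volume_shape, model.background_intensity, dtype=np.float32)
    data[mask] = model.vessel_intensity
    if model.psf_sigma_um > 0:
        data = gaussian_filter(data, model.psf_sigma_um / spec.spacing_um, mode="mirror")
    if model.ring_artifact_amplitude > 0:
        shape = truth.volume_shape
        yy, xx = np.meshgrid(
            np.arange(shape[1]) - shape[1] / 2.0,
            np.arange(shape[2]) - shape[2] / 2.0,
            indexing="ij",
        )
        r = np.sqrt(yy**2 + xx**2)
        rings = model.ring_artifact_amplitude * np.sin(2 * math.pi * r / 8.0)
        data = data + rings[None, :, :].astype(np.float32)
    if model.noise_sigma > 0:
        noise_rng = np.random.default_rng([spec.seed, 0x5EED])
        data = data + noise_rng.normal(0.0, model.noise_sigma, size=data.shape).astype(np.float32)
    return Volume(data.astype(np.float32), spec.spacing_um)


# ---------------------------------------------------------------------------
# one-call sample simulation


@dataclass
class SimulatedSample:
    volume: Volume
    truth: GroundTruth
    tree_spec: TreeSpec
    condition_spec: ConditionSpec
    imaging_model: ImagingModel


def simulate_sample(
    condition: str,
    seed: int,
    volume_shape: tuple[int, int, int] = (96, 96, 96),
    spacing_um: float = 5.2,
    model: ImagingModel | None = None,
    tree_spec: TreeSpec | None = None,
    n_trees: int | None = None,
) -> SimulatedSample:
    """Simulate one imaged sample of the given condition template."""
    if tree_spec is None:
        tree_spec = TreeSpec(seed=seed, volume_shape=tuple(volume_shape), spacing_um=spacing_um)
    else:
        tree_spec = replace(tree_spec, seed=seed, volume_shape=tuple(volume_shape),
                            spacing_um=spacing_um)
    cond = condition_template(condition, tree_spec.volume_shape, spacing_um)
    truth = grow_forest(tree_spec, cond, n_trees=n_trees)
    model = model or ImagingModel()
    vol = rasterize(truth, tree_spec, model)
    return SimulatedSample(vol, truth, tree_spec, cond, model)
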