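import numpy as np
import pytest

from angiotomo import TreeSpec, VesselMask, Volume

SPACING = 5.2


@pytest.fixture
def spacing():
    return SPACING


def make_cylinder_mask(r_vox: float, length_vox: int = 41, pad: int = 12,
                       axis: str = "z") -> np.ndarray:
    """Solid axis-aligned cylinder of the given radius and axial extent."""
    n_ax = length_vox + 2 * pad
    n_tr = 2 * int(r_vox + pad) + 1  # odd: integer-centered axis
    shape = (n_ax, n_tr, n_tr)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    c = n_tr // 2
    half = (length_vox - 1) / 2
    inside = (np.abs(zz - (n_ax - 1) / 2) <= half) & ((yy - c) ** 2 + (xx - c) ** 2 <= r_vox**2)
    mask = np.zeros(shape, dtype=bool)
    mask |= inside
    if axis == "z":
        return mask
    raise ValueError(axis)


def make_cylinder_volume(r_vox: float, shape=(64, 64, 64), vessel=100.0, bg=0.0) -> Volume:
    """Infinite (through-volume) bright cylinder along z."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cy, cx = shape[1] / 2 - 0.5, shape[2] / 2 - 0.5
    m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_vox**2
    data = np.where(np.broadcast_to(m, shape), vessel, bg).astype(np.float64)
    return Volume(data, SPACING)


def make_ball_volume(r_vox: float, shape=(64, 64, 64), vessel=100.0, bg=0.0) -> Volume:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    c = [s / 2 - 0.5 for s in shape]
    m = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r_vox**2
    return Volume(np.where(m, vessel, bg).astype(np.float64), SPACING)


def recovery_tree_spec(seed: int) -> TreeSpec:
    """Small Y-tree spec with branch radii ≥ 3 voxels, used by the
    topology-recovery checks."""
    return TreeSpec(
        seed=seed,
        volume_shape=(80, 80, 80),
        n_branch_events=2,
        root_radius_um=25.0,
        min_radius_um=15.6,
        segment_length_range_um=(130.0, 190.0),
    )


@pytest.fixture
def cylinder_mask_factory():
    return make_cylinder_mask


@pytest.fixture
def vessel_mask_factory():
    def factory(mask: np.ndarray) -> VesselMask:
        return VesselMask(mask, SPACING)

    return factory
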