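import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from angiotomo import Volume, VesselnessParams, hessian_eigenvalues, vesselness
from angiotomo.vesselness import default_scales_um

from conftest import SPACING, make_ball_volume, make_cylinder_volume


def test_params_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        VesselnessParams((5.0, 5.0, 7.0))
    with pytest.raises(ValueError, match="nonempty"):
        VesselnessParams(())
    with pytest.raises(ValueError):
        VesselnessParams((5.0,), alpha=0.0)
    with pytest.raises(ValueError, match="bright"):
        VesselnessParams((5.0,), bright_vessels=False)


def test_default_scales_cover_target_radii():
    scales = default_scales_um(SPACING)
    assert all(s >= SPACING for s in scales)
    assert scales == tuple(sorted(scales))
    # coarsest scale targets ~20 μm radius tubes (σ = r/√2)
    assert scales[-1] == pytest.approx(20 / np.sqrt(2), rel=0.01)


def test_constant_volume_zero_eigenvalues_and_response():
    vol = Volume(np.full((24, 24, 24), 7.0), SPACING)
    l1, l2, l3 = hessian_eigenvalues(vol, 6.0)
    assert np.abs(l3).max() < 1e-9
    res = vesselness(vol, VesselnessParams((6.0, 9.0)))
    assert res.response.data.max() == 0.0


def test_sigma_below_resolution_rejected():
    vol = Volume(np.zeros((16, 16, 16)), SPACING)
    with pytest.raises(ValueError, match="coarser scale"):
        hessian_eigenvalues(vol, SPACING / 4)


def test_eigenvalue_trace_matches_laplacian():
    """The eigenvalue sum must equal the γ-normalized Laplacian of Gaussian
    response (trace invariance).  The oracle builds the zero-DC
    sampled-Gaussian second-derivative kernel from the textbook formula and
    applies it per axis with plain separable correlation."""
    from scipy.ndimage import correlate1d

    rng = np.random.default_rng(0)
    vol = Volume(gaussian_filter(rng.standard_normal((32, 32, 32)), 2.0), SPACING)
    sigma_um = 8.0
    sig = sigma_um / SPACING
    l1, l2, l3 = hessian_eigenvalues(vol, sigma_um)

    x = np.arange(-int(4 * sig + 0.5), int(4 * sig + 0.5) + 1, dtype=float)
    g = np.exp(-0.5 * (x / sig) ** 2)
    g /= g.sum()
    d2 = (x**2 - sig**2) / sig**4 * g
    d2 = d2 - d2.mean()  # exact zero response to constants

    log = np.zeros(vol.shape)
    for axis in range(3):
        out = vol.data
        for ax2 in range(3):
            out = correlate1d(out, d2 if ax2 == axis else g, axis=ax2, mode="mirror")
        log += out
    log *= sig**2
    num = np.abs((l1 + l2 + l3) - log).max()
    assert num / max(np.abs(log).max(), 1e-12) < 1e-6


def test_cylinder_axis_eigen_signature():
    """On the axis of a bright tube: λ1 ≈ 0, λ2 ≈ λ3 < 0."""
    vol = make_cylinder_volume(4.0)
    l1, l2, l3 = hessian_eigenvalues(vol, 4 * SPACING / np.sqrt(2))
    c = (32, 31, 31)
    assert abs(l1[c]) < 0.1 * abs(l3[c])
    assert l2[c] < 0 and l3[c] < 0
    assert l2[c] == pytest.approx(l3[c], rel=0.25)


def test_response_bounded_and_zero_on_flat_regions():
    vol = make_cylinder_volume(3.0)
    res = vesselness(vol, VesselnessParams(default_scales_um(SPACING)))
    data = res.response.data
    assert data.min() >= 0.0 and data.max() <= 1.0
    # far corner is locally constant background
    assert data[2, 2, 2] == pytest.approx(0.0, abs=1e-12)


def test_argmax_scale_tracks_radius():
    scales = default_scales_um(SPACING)
    for r_vox in (2, 4):
        vol = make_cylinder_volume(float(r_vox))
        res = vesselness(vol, VesselnessParams(scales))
        am = res.argmax_scale_um.data[32, 31, 31]
        ideal = r_vox * SPACING / np.sqrt(2)
        nearest = int(np.argmin([abs(s - ideal) for s in scales]))
        picked = int(np.argmin([abs(s - am) for s in scales]))
        assert abs(picked - nearest) <= 1


def test_blob_suppressed_relative_to_tube():
    scales = default_scales_um(SPACING)
    params = VesselnessParams(scales)
    cyl = vesselness(make_cylinder_volume(4.0), params).response.data[32, 31, 31]
    ball = vesselness(make_ball_volume(4.0), params).response.data[31, 31, 31]
    assert ball < 0.2 * cyl


def test_contrast_invariance_with_auto_c():
    vol = make_cylinder_volume(3.0)
    params = VesselnessParams(default_scales_um(SPACING))
    r1 = vesselness(vol, params).response.data
    r2 = vesselness(Volume(vol.data * 37.0, SPACING), params).response.data
    assert np.abs(r1 - r2).max() < 1e-6


def test_rotation_robustness():
    """Response at the center of a 45°-rotated tube stays within 15% of the
    axis-aligned case."""
    shape = (64, 64, 64)
    r_vox = 4.0
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    c = np.array([31.5, 31.5, 31.5])
    axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    rel = np.stack([zz - c[0], yy - c[1], xx - c[2]], axis=-1)
    along = rel @ axis
    perp = rel - along[..., None] * axis
    tilted = Volume((np.linalg.norm(perp, axis=-1) <= r_vox) * 100.0, SPACING)
    params = VesselnessParams(default_scales_um(SPACING))
    v_tilted = vesselness(tilted, params).response.data[32, 32, 32]
    v_axis = vesselness(make_cylinder_volume(r_vox), params).response.data[32, 31, 31]
    assert abs(v_tilted - v_axis) / v_axis < 0.15
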