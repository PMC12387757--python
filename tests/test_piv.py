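"""Planar velocity-field decomposition and averaging."""

import numpy as np
import pytest

from chiroflow.piv import (
    PlanarVelocityField,
    angular_average,
    decompose,
    read_field_csv,
    rescale_radius,
    temporal_average,
    write_field_csv,
)


def grid_field(v_x, v_y, n=41, spacing=1.0, center=(0.0, 0.0), mask=None):
    coords = (np.arange(n) - n // 2) * spacing
    if mask is None:
        mask = np.ones((n, n), bool)
    return PlanarVelocityField(
        x_um=coords, y_um=coords.copy(), v_x=v_x, v_y=v_y, mask=mask, center_um=center
    )


def rigid_clockwise(omega_rad_s, n=41, spacing=1.0, center=(0.0, 0.0)):
    coords = (np.arange(n) - n // 2) * spacing
    x = coords[None, :] - center[0]
    y = coords[:, None] - center[1]
    return grid_field(-omega_rad_s * y * np.ones_like(x), omega_rad_s * x * np.ones_like(y),
                      n=n, spacing=spacing, center=center)


def test_rigid_clockwise_rotation_recovered_exactly():
    omega = 2.42e-4
    d = decompose(rigid_clockwise(omega))
    valid = d.omega_mask
    np.testing.assert_allclose(d.omega[valid], omega, rtol=1e-12)
    np.testing.assert_allclose(d.v_r[valid], 0.0, atol=1e-18)


def test_pure_radial_outflow_has_no_swirl():
    k = 0.003
    coords = (np.arange(41) - 20) * 1.0
    x, y = coords[None, :], coords[:, None]
    r = np.hypot(x, y)
    with np.errstate(invalid="ignore"):
        vx, vy = np.where(r > 0, k * x / r, 0.0), np.where(r > 0, k * y / r, 0.0)
    d = decompose(grid_field(vx, vy))
    m = d.mask & (d.r_um > 0)
    np.testing.assert_allclose(d.v_phi[m], 0.0, atol=1e-15)
    np.testing.assert_allclose(d.v_r[m], k, rtol=1e-12)


def test_energy_identity_pointwise():
    rng = np.random.default_rng(5)
    vx = rng.normal(size=(31, 31))
    vy = rng.normal(size=(31, 31))
    d = decompose(grid_field(vx, vy, n=31))
    m = d.r_um > 0
    np.testing.assert_allclose(
        (d.v_phi**2 + d.v_r**2)[m], (vx**2 + vy**2)[m], rtol=1e-10
    )


def test_decomposition_statistics_invariant_under_quarter_turn():
    """Rotating the whole field by 90 deg about the centre leaves the radial statistics unchanged."""
    rng = np.random.default_rng(11)
    vx = rng.normal(size=(41, 41))
    vy = rng.normal(size=(41, 41))
    base = grid_field(vx, vy)
    # rotate grid positions and vectors by 90 deg (x,y)->(-y,x); on the same
    # grid this is a transpose/flip plus the vector map (vx,vy)->(-vy,vx)
    vx_r = -np.rot90(vy, k=-1)
    vy_r = np.rot90(vx, k=-1)
    rot = grid_field(vx_r, vy_r)
    p1 = angular_average(decompose(base), bins=8)
    p2 = angular_average(decompose(rot), bins=8)
    np.testing.assert_allclose(p1.mean("v_phi"), p2.mean("v_phi"), rtol=1e-10)
    np.testing.assert_allclose(p1.mean("v_r"), p2.mean("v_r"), rtol=1e-10)


def test_center_outside_grid_rejected():
    with pytest.raises(ValueError, match="center"):
        decompose(rigid_clockwise(1.0e-4, center=(100.0, 0.0)))


def test_temporal_average_constant_and_alternating():
    f = rigid_clockwise(1.0e-4)
    d = decompose(f)
    avg = temporal_average([d, d, d])
    np.testing.assert_allclose(avg.v_phi, d.v_phi, rtol=1e-14)
    neg = decompose(grid_field(-f.v_x, -f.v_y))
    zero = temporal_average([d, neg])
    np.testing.assert_allclose(zero.v_phi[zero.mask], 0.0, atol=1e-18)
    with pytest.raises(ValueError):
        temporal_average([d])


def test_temporal_average_mask_intersection():
    f = rigid_clockwise(1.0e-4)
    m2 = f.mask.copy()
    m2[:5] = False
    f2 = PlanarVelocityField(x_um=f.x_um, y_um=f.y_um, v_x=f.v_x, v_y=f.v_y,
                             mask=m2, center_um=f.center_um)
    avg = temporal_average([decompose(f), decompose(f2)])
    assert not avg.mask[:5].any() and avg.mask[5:].any()


def test_angular_average_flat_for_rigid_rotation():
    omega = 3.3e-4
    prof = angular_average(decompose(rigid_clockwise(omega)))
    m = prof.table["omega_n"] > 0
    np.testing.assert_allclose(prof.table.loc[m, "omega_mean"], omega, rtol=1e-12)
    # SEM of an exact rigid rotation is zero
    assert np.nanmax(prof.table.loc[m, "omega_sem"]) < 1e-15


def test_angular_average_single_point_bin_and_empty_bin():
    d = decompose(rigid_clockwise(1.0e-4, n=5))
    prof = angular_average(d, bins=np.array([0.9, 1.1, 1.2, 1.5]))
    t = prof.table
    row = t.iloc[0]  # bin [0.9, 1.1) catches exactly the four r=1 points
    assert row["omega_n"] == 4
    assert row["omega_mean"] == pytest.approx(1.0e-4, rel=1e-12)
    assert t.iloc[1]["omega_n"] == 0 and np.isnan(t.iloc[1]["omega_mean"])


def test_rescale_radius_identity_and_scaling():
    prof = angular_average(decompose(rigid_clockwise(1.0e-4)))
    same = rescale_radius(prof, 1.0)
    np.testing.assert_allclose(same.table["radius"], prof.table["radius"])
    scaled = rescale_radius(prof, 15.0)
    np.testing.assert_allclose(scaled.table["radius"], prof.table["radius"] / 15.0)
    np.testing.assert_allclose(scaled.mean("omega"), prof.mean("omega"))
    with pytest.raises(ValueError):
        rescale_radius(prof, 0.0)


def test_field_csv_round_trip(tmp_path):
    f = rigid_clockwise(1.0e-4, n=11)
    path = tmp_path / "frame.csv"
    write_field_csv(path, f)
    g = read_field_csv(path, center_um=f.center_um)
    np.testing.assert_allclose(g.v_x, f.v_x)
    np.testing.assert_allclose(g.v_y, f.v_y)
    np.testing.assert_array_equal(g.mask, f.mask)


try:
    from hypothesis import given, settings, strategies as st

    @given(
        omega=st.floats(-1e-3, 1e-3, allow_nan=False),
        k=st.floats(-0.01, 0.01, allow_nan=False),
        cx=st.floats(-5.0, 5.0),
        cy=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_superposed_swirl_decomposes_exactly(omega, k, cx, cy):
        """Rotation + radial flow about any centre decomposes back exactly."""
        coords = (np.arange(31) - 15) * 1.0
        x = coords[None, :] - cx
        y = coords[:, None] - cy
        r = np.hypot(x, y)
        with np.errstate(invalid="ignore"):
            xh = np.where(r > 0, x / r, 0.0)
            yh = np.where(r > 0, y / r, 0.0)
        vx = xh * k - yh * omega * r
        vy = yh * k + xh * omega * r
        d = decompose(grid_field(vx, vy, n=31, center=(cx, cy)))
        m = d.mask & (d.r_um > 0)
        np.testing.assert_allclose(d.v_r[m], k, atol=1e-12)
        np.testing.assert_allclose(d.v_phi[m], omega * d.r_um[m], atol=1e-12)
        # energy identity holds pointwise
        np.testing.assert_allclose(
            (d.v_phi**2 + d.v_r**2)[m], (vx**2 + vy**2)[m], rtol=1e-10, atol=1e-20
        )
except ImportError:  # hypothesis is an optional test dependency
    pass
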