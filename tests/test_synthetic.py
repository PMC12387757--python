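"""Synthetic generators: determinism, exact recovery, solver bridging."""

import numpy as np
import pytest

from chiroflow.piv import angular_average, decompose, temporal_average
from chiroflow.synthetic import (
    SwirlSpec,
    make_landmark_tracks,
    make_swirl_series,
    manufactured_forcing,
    sample_solution_to_grid,
)

DEG_HR = np.pi / 180.0 / 3600.0


def test_noiseless_swirl_recovered_to_machine_precision():
    spec = SwirlSpec(omega_deg_per_hr=50.0, v_r_um_s=-0.002, noise_sd_frac=0.0, n_frames=1)
    frame = make_swirl_series(spec)[0]
    d = decompose(frame)
    m = d.omega_mask
    np.testing.assert_allclose(d.omega[m], 50.0 * DEG_HR, rtol=1e-12)
    np.testing.assert_allclose(d.v_r[d.mask & (d.r_um > 0)], -0.002, rtol=1e-12)


def test_same_seed_is_bit_identical_and_seeds_differ():
    a = make_swirl_series(SwirlSpec(seed=123, n_frames=3))
    b = make_swirl_series(SwirlSpec(seed=123, n_frames=3))
    c = make_swirl_series(SwirlSpec(seed=124, n_frames=3))
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.v_x, fb.v_x)
        np.testing.assert_array_equal(fa.v_y, fb.v_y)
    assert not np.array_equal(a[0].v_x, c[0].v_x)


def test_peaked_omega_profile_peaks_at_construction_radius():
    r0 = 15.0
    spec = SwirlSpec(
        omega_deg_per_hr=lambda r: 60.0 * np.exp(-((r - r0) ** 2) / 18.0),
        v_r_um_s=0.0,
        noise_sd_frac=0.0,
        n_frames=1,
    )
    prof = angular_average(decompose(make_swirl_series(spec)[0]))
    t = prof.table
    k = int(np.nanargmax(t["omega_mean"].to_numpy()))
    assert abs(t["radius"][k] - r0) <= prof.bin_edges[1] - prof.bin_edges[0]


def test_noise_statistics_match_declared_model():
    """Per-component residuals are Gaussian with sd = frac * local speed."""
    spec = SwirlSpec(noise_sd_frac=0.1, n_frames=200, seed=5)
    frames = make_swirl_series(spec)
    clean = make_swirl_series(SwirlSpec(noise_sd_frac=0.0, n_frames=1, seed=5))[0]
    speed = np.hypot(clean.v_x, clean.v_y)
    sel = clean.mask & (speed > 1e-6)
    res = np.stack([(f.v_x - clean.v_x)[sel] / (0.1 * speed[sel]) for f in frames])
    z = res.ravel()
    assert abs(z.mean()) < 3.0 / np.sqrt(z.size)
    assert abs(z.std() - 1.0) < 0.01
    from scipy import stats

    # normality on a subsample (Kolmogorov-Smirnov against N(0,1))
    assert stats.kstest(z[:5000], "norm").pvalue > 1e-3


def test_landmark_generator_exact_and_drift_invariant():
    from chiroflow.rotation import cumulative_angle

    clean = make_landmark_tracks(omega_deg_per_hr=50.0, angular_noise_sd_deg=0.0)
    assert cumulative_angle(clean).theta_deg[-1] == pytest.approx(500.0, abs=1e-9)
    drift = make_landmark_tracks(omega_deg_per_hr=50.0, center_drift_um_per_hr=(2.0, 0.0))
    np.testing.assert_allclose(
        cumulative_angle(drift).theta_deg, cumulative_angle(clean).theta_deg, atol=1e-9
    )


def test_landmark_mean_omega_unbiased_over_seeds():
    from chiroflow.rotation import cumulative_angle, mean_angular_velocity

    est = np.array(
        [
            mean_angular_velocity(
                cumulative_angle(
                    make_landmark_tracks(omega_deg_per_hr=50.0, angular_noise_sd_deg=5.0, seed=s)
                ),
                (0.0, 10.0),
            )
            for s in range(100)
        ]
    )
    se = est.std(ddof=1) / np.sqrt(est.size)
    assert abs(est.mean() - 50.0) <= 3.0 * se


def test_sample_solution_round_trip_against_solver_profile(coarse_solution):
    """decompose(sample(sol)) reproduces the solver's layer velocities."""
    from chiroflow.geometry import dorsal_height

    sol = coarse_solution
    field = sample_solution_to_grid(sol, z_mode="dorsal", grid_spacing_um=0.5)
    d = decompose(field)
    prof = angular_average(d, bins=np.linspace(0.0, 35.0, 36))
    t = prof.table
    # solver reference at the same layer
    radii = t["radius"].to_numpy()
    sel = (radii > 3.0) & (radii < 32.0) & (t["v_phi_n"].to_numpy() > 3)
    r_nd = radii[sel] / sol.r0_um
    h = dorsal_height(r_nd, sol.mesh.params, sol.mesh.derived)
    vr_ref, vp_ref, _ = sol.sample(r_nd, h * 0.92)
    scale = np.max(np.abs(vp_ref))
    np.testing.assert_allclose(t["v_phi_mean"].to_numpy()[sel], -vp_ref, atol=0.15 * scale)
    np.testing.assert_allclose(t["v_r_mean"].to_numpy()[sel], vr_ref, atol=0.15 * scale)
    # the clockwise model flow appears clockwise on screen: positive v_phi
    assert np.nanmean(t["v_phi_mean"]) > 0.0


def test_sample_solution_zero_chirality_and_rotation_symmetry(shape, activity):
    from chiroflow import SolverConfig, solve_meridional

    sol = solve_meridional(shape, activity, SolverConfig(h_um=0.7))  # v_phi = 0
    field = sample_solution_to_grid(sol, z_mode="ventral", grid_spacing_um=1.0)
    d = decompose(field)
    assert np.nanmax(np.abs(d.v_phi[d.mask])) < 1e-14
    # axisymmetry: rotating the sampled grid by 90 deg changes nothing
    vx_r = -np.rot90(field.v_y, k=-1)
    vy_r = np.rot90(field.v_x, k=-1)
    np.testing.assert_allclose(vx_r, field.v_x, atol=1e-12)
    np.testing.assert_allclose(vy_r, field.v_y, atol=1e-12)


def test_sample_solution_rejects_unknown_layer(coarse_solution):
    with pytest.raises(ValueError, match="z_mode"):
        sample_solution_to_grid(coarse_solution, z_mode="apex")


def test_manufactured_zero_target_gives_zero_forcing():
    case = manufactured_forcing("0", "0", "1", v_phi="0")
    r = np.linspace(0.1, 1.0, 5)
    z = np.linspace(0.0, 1.0, 5)
    assert np.allclose(case.f_rho(r, z), 0.0)
    assert np.allclose(case.f_z(r, z), 0.0)
    assert np.allclose(case.g_phi(r, z), 0.0)


def test_manufactured_polynomial_forcing_matches_hand_derivation():
    """For v_phi = rho z^2 the 1/rho terms cancel and g = L1 v_phi = 2 rho."""
    case = manufactured_forcing("-rho*z", "z**2", "0", v_phi="rho*z**2")
    r = np.linspace(0.2, 1.5, 7)
    z = np.linspace(0.1, 0.9, 7)
    np.testing.assert_allclose(case.g_phi(r, z), 2.0 * r, rtol=1e-12)
    # and the meridional forces for this linear-in-z pair, by hand:
    # L1(-rho z) = z/rho... cancels to 0 - 0 = -z/rho + z/rho = 0; f_z = 2
    np.testing.assert_allclose(case.f_rho(r, z), 0.0, atol=1e-12)
    np.testing.assert_allclose(case.f_z(r, z), 2.0, rtol=1e-12)


def test_manufactured_rejects_compressible_or_axis_violating_targets():
    with pytest.raises(ValueError, match="continuity"):
        manufactured_forcing("rho", "0", "0")
    with pytest.raises(ValueError, match="axis"):
        manufactured_forcing("1/rho", "0", "0")
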