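"""Flow solver: structure of the solution, linearity, verification."""

import numpy as np
import pytest

from chiroflow import SolverConfig, solve, solve_azimuthal, solve_meridional
from chiroflow.fem import build_space
from chiroflow.geometry import rectangle_mesh
from chiroflow.solver import StokesSystem
from chiroflow.synthetic import manufactured_forcing

COARSE = dict(h_um=0.7)


def test_zero_chirality_gives_zero_azimuthal_flow(shape, activity):
    sol = solve_azimuthal(shape, activity, SolverConfig(zeta=0.0, **COARSE))
    assert np.all(sol.v_phi == 0.0)


def test_z_independent_order_parameter_gives_zero_azimuthal_flow(shape, activity):
    """Without a vertical activity gradient the torque-dipole forcing vanishes."""
    from chiroflow.geometry import build_mesh

    mesh = build_mesh(shape.scaled(1 / shape.r0_um), h=0.7 / shape.r0_um)
    space = build_space(mesh)
    sys_ = StokesSystem(space)
    xq = space.quad_points()
    s_q = np.exp(-((xq[:, :, 0] - 0.5) ** 2))  # any z-independent S(rho)
    ds_dz = np.zeros_like(s_q)
    v_phi = sys_.solve_azimuthal(0.004 * s_q * ds_dz)
    assert np.all(v_phi == 0.0)


def test_azimuthal_flow_linear_in_zeta(shape, activity):
    s1 = solve_azimuthal(shape, activity, SolverConfig(zeta=0.004, **COARSE))
    s2 = solve_azimuthal(shape, activity, SolverConfig(zeta=0.008, **COARSE))
    denom = np.max(np.abs(s2.v_phi))
    assert np.max(np.abs(s2.v_phi - 2.0 * s1.v_phi)) / denom < 1e-8


def test_meridional_flow_independent_of_zeta_and_sign_flip(shape, activity):
    a = solve(shape, activity, SolverConfig(zeta=0.004, **COARSE))
    b = solve(shape, activity, SolverConfig(zeta=-0.004, **COARSE))
    np.testing.assert_allclose(b.v_phi, -a.v_phi, rtol=0, atol=1e-12 + 1e-8 * np.max(np.abs(a.v_phi)))
    np.testing.assert_array_equal(a.v_rho, b.v_rho)
    np.testing.assert_array_equal(a.v_z, b.v_z)
    np.testing.assert_array_equal(a.p, b.p)


def test_azimuthal_flow_clockwise_everywhere(coarse_solution):
    """The reference parameters rotate the whole cytoplasm clockwise (v_phi < 0)."""
    interior = coarse_solution.interior_p2_mask()
    assert np.all(coarse_solution.v_phi[interior] < 0.0)


def test_meridional_circulation_pattern(coarse_solution):
    """Inward flow under the dorsal surface in the ring band, outward return near the substrate."""
    from chiroflow.geometry import dorsal_height

    sol = coarse_solution
    rho = np.linspace(0.45, 0.7, 24)  # ring band, dimensionless radius
    h = dorsal_height(rho, sol.mesh.params, sol.mesh.derived)
    vr_dorsal, _, _ = sol.sample(rho, 0.9 * h)
    vr_ventral, _, _ = sol.sample(rho, 0.1 * h)
    assert np.mean(vr_dorsal) < 0.0
    assert np.mean(vr_ventral) > 0.0


def test_zero_activity_is_hydrostatic():
    """With S = 0 the meridional problem returns v = 0 and constant pressure."""
    mesh = rectangle_mesh(1.0, 0.3, 10, 4)
    space = build_space(mesh)
    sys_ = StokesSystem(space)
    zero = np.zeros_like(space.quad_points()[:, :, 0])
    v_rho, v_z, p, info = sys_.solve_meridional(zero)
    assert np.max(np.abs(v_rho)) < 1e-14 and np.max(np.abs(v_z)) < 1e-14
    assert np.max(np.abs(p - p[0])) < 1e-12


def test_discrete_divergence_residual_small(coarse_solution, default_solution):
    for sol in (coarse_solution, default_solution):
        assert sol.info["div_residual_rel"] < 1e-6


def test_free_slip_no_penetration_on_dorsal_boundary(coarse_solution):
    sol = coarse_solution
    dofs, normals, _ = sol.space.assemble_boundary_vv("dorsal")
    vn = (sol.v_rho[dofs] * normals[:, None, 0] + sol.v_z[dofs] * normals[:, None, 1])
    assert np.max(np.abs(vn)) < 1e-3 * sol.peak_speed


def test_velocity_zero_on_ventral_boundary_and_axis(coarse_solution):
    from chiroflow.fem import tagged_p2_dofs

    sol = coarse_solution
    ventral = tagged_p2_dofs(sol.space, ("ventral",))
    axis = tagged_p2_dofs(sol.space, ("axis",))
    assert np.max(np.abs(sol.v_rho[ventral])) == 0.0
    assert np.max(np.abs(sol.v_z[ventral])) == 0.0
    assert np.max(np.abs(sol.v_phi[ventral])) == 0.0
    assert np.max(np.abs(sol.v_rho[axis])) == 0.0
    assert np.max(np.abs(sol.v_phi[axis])) == 0.0


MMS_CASE = dict(
    v_rho="-rho*(2*z - 3*z**2)",
    v_z="2*z**2*(1 - z)",
    pressure="rho**2 + z**3",
    v_phi="rho*z*(1-z)",
)


def _mms_errors(n: int):
    case = manufactured_forcing(**MMS_CASE)
    mesh = rectangle_mesh(1.0, 1.0, n, n)
    space = build_space(mesh)
    sys_ = StokesSystem(space)
    xq = space.quad_points()
    rq, zq = xq[:, :, 0], xq[:, :, 1]
    walls = ("ventral", "dorsal", "rim")
    vr, vz, p, _ = sys_.solve_meridional(
        rq * case.f_rho(rq, zq), rq * case.f_z(rq, zq),
        dirichlet={t: (case.exact["v_rho"], case.exact["v_z"]) for t in walls},
    )
    vphi = sys_.solve_azimuthal(
        rq * case.g_phi(rq, zq), dirichlet={t: case.exact["v_phi"] for t in walls + ("axis",)}
    )
    pts = space.p2_points
    det, _ = space._geom()
    bary, wq = space.quad

    def l2(coeffs):
        vals = space.dof_values_on_quad(coeffs)
        return np.sqrt(np.einsum("q,tq->", wq, vals**2 * det[:, None]))

    errs = {
        "v_rho": l2(vr - case.exact["v_rho"](pts[:, 0], pts[:, 1])),
        "v_z": l2(vz - case.exact["v_z"](pts[:, 0], pts[:, 1])),
        "v_phi": l2(vphi - case.exact["v_phi"](pts[:, 0], pts[:, 1])),
    }
    pex = case.exact["pressure"](space.points[:, 0], space.points[:, 1])
    dp = p - pex
    dp -= (sys_.gauge @ dp) / sys_.gauge.sum()
    errs["pressure"] = float(np.sqrt(np.mean(dp**2)))
    return errs


def test_manufactured_solution_convergence_at_theoretical_order():
    """Velocities converge at order >= 3 (P2), pressure at order >= 2 (P1)."""
    errs = {n: _mms_errors(n) for n in (4, 8, 16)}
    for name, theo in (("v_rho", 3.0), ("v_z", 3.0), ("v_phi", 3.0), ("pressure", 2.0)):
        order = np.log2(errs[4][name] / errs[16][name]) / 2.0
        assert order > theo - 0.35, f"{name}: observed order {order:.2f}"


def test_solver_peak_speeds_comparable(coarse_solution):
    """Azimuthal and meridional peak speeds are within a factor ~2 at zeta=0.004."""
    ratio = coarse_solution.peak_azimuthal / coarse_solution.peak_meridional
    assert 0.5 < ratio < 2.0


def test_solve_meridional_entry_point(shape, activity):
    sol = solve_meridional(shape, activity, SolverConfig(**COARSE))
    assert np.all(sol.v_phi == 0.0)
    assert sol.peak_meridional > 0.0


def test_invalid_solver_config():
    with pytest.raises(ValueError):
        SolverConfig(tol=1e-3)
    with pytest.raises(ValueError):
        SolverConfig(zeta=float("nan"))
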