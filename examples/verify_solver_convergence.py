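"""Verify the flow solver with the method of manufactured solutions.

Chooses smooth target fields that satisfy the cylindrical continuity
equation exactly, derives (symbolically) the body forces that make them the
exact solution of the axisymmetric Stokes operators, solves on a sequence
of meshes and reports L2 errors and observed convergence orders — cubic for
the quadratic velocity elements, quadratic for the linear pressure.
"""

import numpy as np

from chiroflow import manufactured_forcing
from chiroflow.fem import build_space
from chiroflow.geometry import rectangle_mesh
from chiroflow.solver import StokesSystem

case = manufactured_forcing(
    v_rho="-rho*(2*z - 3*z**2)",
    v_z="2*z**2*(1 - z)",
    pressure="rho**2 + z**3",
    v_phi="rho*z*(1-z)",
)

errors = {}
for n in (4, 8, 16, 32):
    space = build_space(rectangle_mesh(1.0, 1.0, n, n))
    system = StokesSystem(space)
    xq = space.quad_points()
    rq, zq = xq[:, :, 0], xq[:, :, 1]
    walls = ("ventral", "dorsal", "rim")
    vr, vz, p, _ = system.solve_meridional(
        rq * case.f_rho(rq, zq), rq * case.f_z(rq, zq),
        dirichlet={t: (case.exact["v_rho"], case.exact["v_z"]) for t in walls},
    )
    pts = space.p2_points
    err = vr - case.exact["v_rho"](pts[:, 0], pts[:, 1])
    errors[n] = float(np.sqrt(np.mean(err**2)))
    print(f"n = {n:3d}:  v_rho L2 error = {errors[n]:.3e}")

ns = sorted(errors)
for a, b in zip(ns[:-1], ns[1:]):
    print(f"order {a}->{b}: {np.log2(errors[a] / errors[b]):.2f}   (theoretical 3 for P2)")
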