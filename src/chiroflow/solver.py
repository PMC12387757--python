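"""Axisymmetric active chiral Stokes solver.

Solves the dimensionless momentum balance of an active chiral fluid in
cylindrical coordinates ``(rho, phi, z)`` on the meridional cell domain,
with the orientational field ``p = S e_phi`` held fixed:

* azimuthal:   ``L1 v_phi = (zeta / rho) S dS/dz``
* radial:      ``L1 v_rho = dP/drho + S^2 / rho``
* vertical:    ``L0 v_z  = dP/dz``
* continuity:  ``v_rho / rho + d(v_rho)/drho + d(v_z)/dz = 0``

where ``L1 = d^2/drho^2 + d^2/dz^2 + (1/rho) d/drho - 1/rho^2`` and ``L0``
is the same without the ``1/rho^2`` term.  Lengths are scaled by the cell
radius R0, velocities by ``zeta_a R0 / eta`` and pressure by the achiral
activity ``zeta_a``; the single control parameter is the chirality ratio
``zeta = zeta_c / (zeta_a R0)``.

The azimuthal problem decouples and is linear in ``zeta``; the meridional
(rho, z) Stokes problem is independent of ``zeta``.  Discretisation:
Taylor-Hood P2 velocity / P1 pressure with the standard rho-weighted weak
form, no-slip on the ventral boundary, essential ``v_rho = v_phi = 0`` on
the axis, and free slip on the dorsal boundary (``v.n = 0`` by boundary
penalty, zero tangential pseudo-traction and zero normal flux of ``v_phi``
as the natural conditions).  The pressure is gauged to zero volume mean via
a scalar Lagrange multiplier.  A deterministic direct sparse solve is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .activity import ActivityParams, OrientationField
from .fem import FeSpace, build_space, solve_constrained, tagged_p2_dofs
from .geometry import CellShapeParams, MeridionalMesh, build_mesh

__all__ = ["SolverConfig", "FlowSolution", "StokesSystem", "solve", "solve_azimuthal", "solve_meridional"]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the flow solver.

    ``zeta`` — dimensionless chiral activity; ``h_um`` — target mesh edge
    length in µm (on the physical scale); ``penalty`` — free-slip penalty
    weight; ``tol`` — linear-solver relative-residual bound used to accept a
    solution (the solve itself is direct).
    """

    zeta: float = 0.004
    h_um: float = 0.35
    penalty: float = 1.0e8
    tol: float = 1.0e-8

    def __post_init__(self) -> None:
        if not np.isfinite(self.zeta):
            raise ValueError("zeta must be finite")
        if not 0.0 < self.tol <= 1.0e-6:
            raise ValueError("tol must lie in (0, 1e-6]")


class StokesSystem:
    """Assembled axisymmetric operators on a fixed P2/P1 space.

    Caches the rho-weighted stiffness, the 1/rho mass, the P1-tested
    divergence operators, the pressure-gauge vector and the dorsal penalty
    blocks, so that repeated solves (zeta sweeps, manufactured solutions)
    reuse the assembly.
    """

    def __init__(self, space: FeSpace, penalty: float = 1.0e8):
        self.space = space
        self.penalty = penalty
        xq = space.quad_points()
        rho_q = xq[:, :, 0]
        self.rho_q = rho_q
        self.K = space.assemble_p2_bilinear(c_grad=rho_q)
        self.M_inv_rho = space.assemble_p2_bilinear(c_mass=1.0 / rho_q)
        self.B_r, self.B_z = space.assemble_divergence()
        self.gauge = space.assemble_p1_load(rho_q)
        self._pen_blocks = self._assemble_penalty("dorsal") if "dorsal" in space.boundary else None

    def _assemble_penalty(self, tag: str):
        dofs, normals, me = self.space.assemble_boundary_vv(tag)
        n2 = self.space.n_p2
        blocks = {}
        for (a, ca) in (("r", 0), ("z", 1)):
            for (b, cb) in (("r", 0), ("z", 1)):
                vals = me * (normals[:, ca] * normals[:, cb])[:, None, None]
                rows = np.repeat(dofs, 3, axis=1).ravel()
                cols = np.tile(dofs, (1, 3)).ravel()
                blocks[a + b] = sp.coo_matrix(
                    (vals.ravel(), (rows, cols)), shape=(n2, n2)
                ).tocsr()
        return blocks

    # -- azimuthal ---------------------------------------------------------
    def solve_azimuthal(self, rhs_q: np.ndarray, dirichlet: dict | None = None) -> np.ndarray:
        """Solve ``L1 v_phi = g`` with ``rhs_q = rho * g`` at quadrature points.

        Default boundary conditions: ``v_phi = 0`` on ventral boundary and
        axis, natural zero flux (free slip) on the dorsal boundary.
        ``dirichlet`` may map tag -> callable(rho, z) for inhomogeneous data.
        """
        A = self.K + self.M_inv_rho
        rhs = self.space.assemble_p2_load(-rhs_q)
        tags = ("ventral", "axis") if dirichlet is None else tuple(dirichlet)
        fixed = tagged_p2_dofs(self.space, tags)
        vals = None
        if dirichlet is not None:
            vals = np.zeros(fixed.shape[0])
            pts = self.space.p2_points
            for tag, fun in dirichlet.items():
                d = tagged_p2_dofs(self.space, (tag,))
                idx = np.searchsorted(fixed, d)
                vals[idx] = fun(pts[d, 0], pts[d, 1])
        return solve_constrained(A, rhs, fixed, vals)

    # -- meridional --------------------------------------------------------
    def solve_meridional(
        self,
        frho_q: np.ndarray,
        fz_q: np.ndarray | None = None,
        dirichlet: dict | None = None,
    ):
        """Solve the meridional Stokes system.

        ``frho_q``/``fz_q`` are ``rho * F_rho`` and ``rho * F_z`` at the
        quadrature points, where ``F`` is the body-force side of the momentum
        equations (for the active cell, ``F_rho = S^2/rho`` so
        ``frho_q = S^2`` and ``F_z = 0``).

        Default BCs: no slip ventral, ``v_rho = 0`` on axis, penalty free
        slip dorsal.  ``dirichlet`` overrides with tag -> (g_rho, g_z)
        callables applied to both components (used by manufactured-solution
        verification); the axis keeps ``v_rho = 0`` and natural ``v_z``.

        Returns ``(v_rho, v_z, p, info)``.
        """
        sp_ = self.space
        n2, n1 = sp_.n_p2, sp_.n_p1
        if fz_q is None:
            fz_q = np.zeros_like(frho_q)

        Arr = self.K + self.M_inv_rho
        Azz = self.K.copy()
        Arz = sp.csr_matrix((n2, n2))
        if dirichlet is None and self._pen_blocks is not None:
            pen = self.penalty
            Arr = Arr + pen * self._pen_blocks["rr"]
            Azz = Azz + pen * self._pen_blocks["zz"]
            Arz = pen * self._pen_blocks["rz"]

        g = sp.csr_matrix(self.gauge[:, None])
        A = sp.bmat(
            [
                [Arr, Arz, -self.B_r.T, None],
                [Arz.T, Azz, -self.B_z.T, None],
                [-self.B_r, -self.B_z, None, g],
                [None, None, g.T, None],
            ],
            format="csr",
        )
        rhs = np.concatenate(
            [sp_.assemble_p2_load(-frho_q), sp_.assemble_p2_load(-fz_q), np.zeros(n1 + 1)]
        )

        pts = sp_.p2_points
        if dirichlet is None:
            fixed_r = tagged_p2_dofs(sp_, ("ventral", "axis"))
            fixed_z = tagged_p2_dofs(sp_, ("ventral",))
            fixed = np.concatenate([fixed_r, n2 + fixed_z])
            vals = None
        else:
            tags = tuple(dirichlet)
            fixed_r_t = tagged_p2_dofs(sp_, tags)
            axis = tagged_p2_dofs(sp_, ("axis",)) if "axis" in sp_.boundary else np.array([], dtype=int)
            fixed_r = np.union1d(fixed_r_t, axis)
            fixed_z = fixed_r_t
            vr_vals = np.zeros(fixed_r.shape[0])
            vz_vals = np.zeros(fixed_z.shape[0])
            for tag, (g_r, g_z) in dirichlet.items():
                d = tagged_p2_dofs(sp_, (tag,))
                vr_vals[np.searchsorted(fixed_r, d)] = g_r(pts[d, 0], pts[d, 1])
                vz_vals[np.searchsorted(fixed_z, d)] = g_z(pts[d, 0], pts[d, 1])
            fixed = np.concatenate([fixed_r, n2 + fixed_z])
            vals = np.concatenate([vr_vals, vz_vals])

        u = solve_constrained(A, rhs, fixed, vals)
        v_rho, v_z = u[:n2], u[n2 : 2 * n2]
        p, gamma = u[2 * n2 : 2 * n2 + n1], u[-1]

        div = self.B_r @ v_rho + self.B_z @ v_z - gamma * self.gauge
        scale = np.abs(self.B_r) @ np.abs(v_rho) + np.abs(self.B_z) @ np.abs(v_z)
        info = {
            "gamma": gamma,
            "div_residual_rel": float(
                np.linalg.norm(div) / max(np.linalg.norm(scale), 1e-300)
            ),
        }
        return v_rho, v_z, p, info


@dataclass
class FlowSolution:
    """Dimensionless flow field on the rescaled (R0 = 1) meridional mesh.

    ``v_rho``, ``v_phi``, ``v_z`` are P2 coefficient vectors and ``p`` the
    P1 pressure, all in the non-dimensional units of the model (velocity
    scale ``zeta_a R0 / eta``).  ``r0_um`` restores physical lengths.
    """

    space: FeSpace
    mesh: MeridionalMesh
    v_rho: np.ndarray
    v_phi: np.ndarray
    v_z: np.ndarray
    p: np.ndarray
    zeta: float
    r0_um: float
    shape: CellShapeParams
    activity: ActivityParams
    orientation: OrientationField = field(repr=False, default=None)
    info: dict = field(default_factory=dict)

    @property
    def peak_speed(self) -> float:
        """Maximum dimensionless speed over the P2 nodes."""
        return float(np.max(np.sqrt(self.v_rho**2 + self.v_phi**2 + self.v_z**2)))

    @property
    def peak_azimuthal(self) -> float:
        return float(np.max(np.abs(self.v_phi)))

    @property
    def peak_meridional(self) -> float:
        return float(np.max(np.sqrt(self.v_rho**2 + self.v_z**2)))

    def sample(self, rho_nd, z_nd):
        """Evaluate ``(v_rho, v_phi, v_z)`` at dimensionless points."""
        vr = self.space.evaluate_p2(self.v_rho, rho_nd, z_nd)
        vp = self.space.evaluate_p2(self.v_phi, rho_nd, z_nd)
        vz = self.space.evaluate_p2(self.v_z, rho_nd, z_nd)
        return vr, vp, vz

    def sample_um(self, rho_um, z_um):
        """Evaluate at physical (µm) coordinates; velocities stay dimensionless."""
        return self.sample(np.asarray(rho_um) / self.r0_um, np.asarray(z_um) / self.r0_um)

    def interior_p2_mask(self) -> np.ndarray:
        """Mask of P2 dofs not lying on any tagged boundary."""
        bdofs = tagged_p2_dofs(self.space, tuple(self.space.boundary))
        mask = np.ones(self.space.n_p2, dtype=bool)
        mask[bdofs] = False
        return mask

    def save_vtk(self, path) -> None:
        from .vtkio import write_vtk_mesh

        s_vals = self.orientation.s(self.space.points[:, 0], self.space.points[:, 1]) if self.orientation else None
        data = {
            "v_rho": self.v_rho[: self.space.n_p1],
            "v_phi": self.v_phi[: self.space.n_p1],
            "v_z": self.v_z[: self.space.n_p1],
            "pressure": self.p,
        }
        if s_vals is not None:
            data["S"] = np.asarray(s_vals)
        write_vtk_mesh(path, self.space.points, self.space.triangles, point_data=data)


def _build_nd(shape: CellShapeParams, act: ActivityParams, config: SolverConfig):
    r0 = shape.r0_um
    mesh = build_mesh(shape.scaled(1.0 / r0), h=config.h_um / r0)
    space = build_space(mesh)
    field_nd = OrientationField(shape.scaled(1.0 / r0), act.scaled(1.0 / r0))
    return mesh, space, field_nd


def solve_azimuthal(shape: CellShapeParams, act: ActivityParams, config: SolverConfig | None = None):
    """Solve only the azimuthal problem; returns a FlowSolution with zero (v_rho, v_z, P)."""
    config = config or SolverConfig()
    mesh, space, field_nd = _build_nd(shape, act, config)
    sys_ = StokesSystem(space, penalty=config.penalty)
    xq = space.quad_points()
    s_q = field_nd.s(xq[:, :, 0], xq[:, :, 1])
    ds_q = field_nd.ds_dz(xq[:, :, 0], xq[:, :, 1])
    v_phi = sys_.solve_azimuthal(config.zeta * s_q * ds_q)
    zeros2, zeros1 = np.zeros(space.n_p2), np.zeros(space.n_p1)
    return FlowSolution(
        space=space, mesh=mesh, v_rho=zeros2, v_phi=v_phi, v_z=zeros2.copy(), p=zeros1,
        zeta=config.zeta, r0_um=shape.r0_um, shape=shape, activity=act, orientation=field_nd,
    )


def solve_meridional(shape: CellShapeParams, act: ActivityParams, config: SolverConfig | None = None):
    """Solve only the meridional Stokes problem (independent of zeta)."""
    config = config or SolverConfig()
    mesh, space, field_nd = _build_nd(shape, act, config)
    sys_ = StokesSystem(space, penalty=config.penalty)
    xq = space.quad_points()
    s_q = field_nd.s(xq[:, :, 0], xq[:, :, 1])
    v_rho, v_z, p, info = sys_.solve_meridional(s_q**2)
    return FlowSolution(
        space=space, mesh=mesh, v_rho=v_rho, v_phi=np.zeros(space.n_p2), v_z=v_z, p=p,
        zeta=config.zeta, r0_um=shape.r0_um, shape=shape, activity=act, orientation=field_nd, info=info,
    )


def solve(
    shape: CellShapeParams | None = None,
    act: ActivityParams | None = None,
    config: SolverConfig | None = None,
) -> FlowSolution:
    """Full solve: azimuthal + meridional on a shared mesh and assembly.

    Defaults reproduce the reference parameter set (R0 = 35 µm cell with the
    concentric ring activity and zeta = 0.004).
    """
    shape = shape or CellShapeParams()
    act = act or ActivityParams()
    config = config or SolverConfig()
    mesh, space, field_nd = _build_nd(shape, act, config)
    sys_ = StokesSystem(space, penalty=config.penalty)
    xq = space.quad_points()
    s_q = field_nd.s(xq[:, :, 0], xq[:, :, 1])
    ds_q = field_nd.ds_dz(xq[:, :, 0], xq[:, :, 1])
    v_phi = sys_.solve_azimuthal(config.zeta * s_q * ds_q)
    v_rho, v_z, p, info = sys_.solve_meridional(s_q**2)
    if info["div_residual_rel"] > 10.0 * config.tol:
        raise RuntimeError(
            f"meridional solve rejected: discrete divergence residual "
            f"{info['div_residual_rel']:.3e} exceeds 10*tol={10*config.tol:.1e}"
        )
    return FlowSolution(
        space=space, mesh=mesh, v_rho=v_rho, v_phi=v_phi, v_z=v_z, p=p,
        zeta=config.zeta, r0_um=shape.r0_um, shape=shape, activity=act, orientation=field_nd, info=info,
    )
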