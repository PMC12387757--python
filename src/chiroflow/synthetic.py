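"""Synthetic ground-truth inputs for every quantification stage.

The experimental pipeline consumes gridded planar velocity fields (PIV
exports) and two-landmark trajectory tables.  This module generates both
with known ground truth — rotational plus centripetal swirl fields with a
clockwise bias, masked circular domains, Gaussian velocity noise, noisy
rotating landmark pairs — and bridges the simulation to the planar pipeline
by sampling a flow solution onto a Cartesian grid.  It also builds
manufactured-solution forcings for solver verification.

Noise is applied to velocity components (the post-PIV world); microscopy
images are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import dorsal_height
from .piv import PlanarVelocityField
from .rotation import LandmarkTrack
from .solver import FlowSolution

__all__ = [
    "SwirlSpec",
    "make_swirl_series",
    "make_landmark_tracks",
    "sample_solution_to_grid",
    "manufactured_forcing",
]

DEG_PER_HR_TO_RAD_PER_S = np.pi / 180.0 / 3600.0


def _as_profile(value):
    return value if callable(value) else (lambda r, v=float(value): np.full_like(np.asarray(r, float), v))


@dataclass(frozen=True)
class SwirlSpec:
    """Ground truth for a synthetic swirl velocity-field series.

    ``omega_deg_per_hr`` and ``v_r_um_s`` are constants or callables of the
    centre distance r (µm): angular velocity (positive clockwise on screen)
    and radial speed (negative inward).  Defaults emulate the measured
    cytoplasmic flow: 50 deg/hr clockwise rotation with a 0.002 µm/s
    centripetal drift inside a 30 µm cell, on a 1 µm PIV grid, with
    per-component Gaussian noise of 10% of the local speed.
    """

    omega_deg_per_hr: object = 50.0
    v_r_um_s: object = -0.002
    domain_radius_um: float = 30.0
    grid_spacing_um: float = 1.0
    frame_interval_s: float = 15.0
    n_frames: int = 40
    noise_sd_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing_um <= 0:
            raise ValueError("grid_spacing_um must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")

    def truth(self) -> dict:
        """Scalar ground-truth parameters (for metadata files)."""
        out = {"domain_radius_um": self.domain_radius_um, "noise_sd_frac": self.noise_sd_frac,
               "n_frames": self.n_frames, "seed": self.seed}
        if not callable(self.omega_deg_per_hr):
            out["omega_deg_per_hr"] = float(self.omega_deg_per_hr)
        if not callable(self.v_r_um_s):
            out["v_r_um_s"] = float(self.v_r_um_s)
        return out


def make_swirl_series(spec: SwirlSpec) -> list[PlanarVelocityField]:
    """Generate a reproducible series of noisy swirl velocity fields.

    The noiseless field is steady: clockwise (on-screen, y down) rotation at
    ``omega(r)`` plus radial flow ``v_r(r)``, masked to the circular domain.
    Each frame adds i.i.d. Gaussian noise per velocity component with
    standard deviation ``noise_sd_frac`` times the local speed.
    """
    omega_fn = _as_profile(spec.omega_deg_per_hr)
    vr_fn = _as_profile(spec.v_r_um_s)
    half = np.floor(spec.domain_radius_um / spec.grid_spacing_um)
    coords = np.arange(-half, half + 1) * spec.grid_spacing_um
    x = coords[None, :]
    y = coords[:, None]
    r = np.hypot(x, y)
    mask = r <= spec.domain_radius_um
    with np.errstate(invalid="ignore", divide="ignore"):
        xh, yh = np.where(r > 0, x / r, 0.0), np.where(r > 0, y / r, 0.0)
    v_phi = omega_fn(r) * DEG_PER_HR_TO_RAD_PER_S * r      # µm/s, clockwise on screen
    v_r = vr_fn(r)
    v_x0 = xh * v_r - yh * v_phi
    v_y0 = yh * v_r + xh * v_phi
    speed = np.hypot(v_x0, v_y0)

    rng = np.random.default_rng(spec.seed)
    frames = []
    for k in range(spec.n_frames):
        sd = spec.noise_sd_frac * speed
        v_x = v_x0 + rng.normal(0.0, 1.0, v_x0.shape) * sd
        v_y = v_y0 + rng.normal(0.0, 1.0, v_y0.shape) * sd
        frames.append(
            PlanarVelocityField(
                x_um=coords.copy(), y_um=coords.copy(), v_x=v_x, v_y=v_y,
                mask=mask.copy(), center_um=(0.0, 0.0), time_s=k * spec.frame_interval_s,
            )
        )
    return frames


def make_landmark_tracks(
    omega_deg_per_hr: float = 50.0,
    radius_um: float = 3.0,
    center_drift_um_per_hr: tuple = (0.0, 0.0),
    angular_noise_sd_deg: float = 0.0,
    dt_hr: float = 0.25,
    t_total_hr: float = 10.0,
    seed: int = 0,
    theta0_deg: float = 0.0,
    center0_um: tuple = (0.0, 0.0),
) -> LandmarkTrack:
    """Two landmarks at fixed separation rotating about a drifting centre.

    Clockwise-on-screen rotation at ``omega_deg_per_hr`` with i.i.d. per-frame
    angular jitter of ``angular_noise_sd_deg``; the centre translates at
    ``center_drift_um_per_hr``.  ``radius_um`` is half the landmark
    separation.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_total_hr + 0.5 * dt_hr, dt_hr)
    theta = np.radians(theta0_deg + omega_deg_per_hr * t + rng.normal(0.0, angular_noise_sd_deg, t.size))
    cx = center0_um[0] + center_drift_um_per_hr[0] * t
    cy = center0_um[1] + center_drift_um_per_hr[1] * t
    # y-down image coordinates: (cos, sin) advances clockwise on screen
    ux, uy = np.cos(theta), np.sin(theta)
    a = np.column_stack([cx + radius_um * ux, cy + radius_um * uy])
    b = np.column_stack([cx - radius_um * ux, cy - radius_um * uy])
    return LandmarkTrack(time_hr=t, a_xy=a, b_xy=b)


def sample_solution_to_grid(
    sol: FlowSolution,
    z_mode: str = "dorsal",
    grid_spacing_um: float = 1.0,
    offset_frac: float = 0.08,
    velocity_scale_um_s: float = 1.0,
    n_z_scan: int = 40,
) -> PlanarVelocityField:
    """Project a flow solution onto a planar grid as seen from above.

    ``z_mode`` selects the sampled layer per radius: ``'dorsal'`` /
    ``'ventral'`` (a fractional offset inside the respective surface) or
    ``'z-max-speed'`` (the height of maximum speed in each column).  The
    simulation's azimuthal velocity is negative for clockwise rotation
    viewed from above; on the image grid (y down) that same rotation is
    clockwise on screen, so the planar components are composed with
    ``v_phi_screen = -v_phi_model``.  Velocities are multiplied by
    ``velocity_scale_um_s`` (1.0 keeps model units).
    """
    if z_mode not in ("dorsal", "ventral", "z-max-speed"):
        raise ValueError("z_mode must be 'dorsal', 'ventral' or 'z-max-speed'")
    r0 = sol.r0_um
    half = np.floor(r0 / grid_spacing_um)
    coords = np.arange(-half, half + 1) * grid_spacing_um
    x, y = coords[None, :], coords[:, None]
    r = np.hypot(x, y)
    mask = r <= r0 * 0.995
    r_nd = np.where(mask, r / r0, 0.0)
    h_nd = dorsal_height(r_nd.ravel(), sol.mesh.params, sol.mesh.derived).reshape(r.shape)

    if z_mode == "dorsal":
        z_nd = h_nd * (1.0 - offset_frac)
    elif z_mode == "ventral":
        z_nd = h_nd * offset_frac
    else:
        fracs = (np.arange(n_z_scan) + 0.5) / n_z_scan
        z_nd = np.zeros_like(h_nd)
        flat_r, flat_h = r_nd.ravel(), h_nd.ravel()
        best = np.zeros_like(flat_r)
        zbest = flat_h * 0.5
        for f in fracs:
            vr, vp, vz = sol.sample(flat_r, flat_h * f)
            spd = np.sqrt(np.nan_to_num(vr) ** 2 + np.nan_to_num(vp) ** 2 + np.nan_to_num(vz) ** 2)
            upd = spd > best
            best, zbest = np.where(upd, spd, best), np.where(upd, flat_h * f, zbest)
        z_nd = zbest.reshape(h_nd.shape)

    vr_nd, vp_nd, _ = sol.sample(r_nd.ravel(), z_nd.ravel())
    vr_nd = np.nan_to_num(vr_nd).reshape(r.shape)
    vp_cw = -np.nan_to_num(vp_nd).reshape(r.shape)       # clockwise-on-screen positive
    with np.errstate(invalid="ignore", divide="ignore"):
        xh, yh = np.where(r > 0, x / r, 0.0), np.where(r > 0, y / r, 0.0)
    v_x = (xh * vr_nd - yh * vp_cw) * velocity_scale_um_s
    v_y = (yh * vr_nd + xh * vp_cw) * velocity_scale_um_s
    return PlanarVelocityField(
        x_um=coords.copy(), y_um=coords.copy(), v_x=v_x, v_y=v_y, mask=mask,
        center_um=(0.0, 0.0),
    )


# ---------------------------------------------------------------------------
# manufactured solutions


@dataclass(frozen=True)
class ManufacturedCase:
    """Symbolic target fields and the body forces that reproduce them."""

    v_rho: object
    v_z: object
    pressure: object
    v_phi: object | None
    f_rho: object = field(repr=False, default=None)   # callables (rho, z)
    f_z: object = field(repr=False, default=None)
    g_phi: object = field(repr=False, default=None)
    exact: dict = field(default_factory=dict, repr=False)


def manufactured_forcing(v_rho, v_z, pressure, v_phi=None) -> ManufacturedCase:
    """Compute body forces whose exact solution is the given target fields.

    Inputs are sympy expressions in symbols ``rho, z``.  The target must
    satisfy the cylindrical continuity equation identically and the axis
    condition ``v_rho(0, z) = 0``; otherwise a ValueError is raised.
    Returns vectorised callables for

    * ``f_rho = L1 v_rho - dP/drho`` (radial body force),
    * ``f_z  = L0 v_z  - dP/dz`` (vertical body force),
    * ``g_phi = L1 v_phi`` (azimuthal forcing), when ``v_phi`` is given,

    where ``L1 = lap - 1/rho^2`` and ``L0 = lap`` are the axisymmetric
    component operators, plus point-evaluators for the exact fields.
    """
    import sympy as sp

    rho, z = sp.symbols("rho z", positive=True)
    subs = {"rho": rho, "z": z}
    v_rho = sp.sympify(v_rho, locals=subs)
    v_z = sp.sympify(v_z, locals=subs)
    pressure = sp.sympify(pressure, locals=subs)

    cont = sp.simplify(v_rho / rho + sp.diff(v_rho, rho) + sp.diff(v_z, z))
    if cont != 0:
        raise ValueError(f"target violates continuity: div = {cont}")
    if sp.simplify(v_rho.subs(rho, 0)) != 0:
        raise ValueError("target violates the axis condition v_rho(0, z) = 0")

    def lap(u):
        return sp.diff(u, rho, 2) + sp.diff(u, z, 2) + sp.diff(u, rho) / rho

    f_rho = sp.simplify(lap(v_rho) - v_rho / rho**2 - sp.diff(pressure, rho))
    f_z = sp.simplify(lap(v_z) - sp.diff(pressure, z))
    exprs = {"v_rho": v_rho, "v_z": v_z, "pressure": pressure}
    g_phi_fn = None
    if v_phi is not None:
        v_phi = sp.sympify(v_phi, locals=subs)
        g_phi = sp.simplify(lap(v_phi) - v_phi / rho**2)
        g_phi_fn = sp.lambdify((rho, z), g_phi, "numpy")
        exprs["v_phi"] = v_phi
    exact = {k: sp.lambdify((rho, z), v, "numpy") for k, v in exprs.items()}
    return ManufacturedCase(
        v_rho=v_rho, v_z=v_z, pressure=pressure, v_phi=v_phi,
        f_rho=sp.lambdify((rho, z), f_rho, "numpy"),
        f_z=sp.lambdify((rho, z), f_z, "numpy"),
        g_phi=g_phi_fn, exact=exact,
    )
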