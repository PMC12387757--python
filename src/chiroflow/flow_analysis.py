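"""Post-processing of a flow solution into observable rotation quantities.

Produces the quantities that the experimental quantification also measures:
the z-averaged angular-velocity radial profile (clockwise viewed from above
counted positive), the inner radius of the actomyosin ring (leftmost radius
where the order parameter reaches a threshold), the profile peak and its
location scaled by the ring radius, the dorsal/ventral swirl classification,
and the dimensional calibration that converts the dimensionless model
velocities into µm/s and deg/hr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ActivityParams, OrientationField
from .geometry import CellShapeParams, derive_shape, dorsal_height
from .solver import FlowSolution

__all__ = [
    "AngularVelocityProfile",
    "DimensionalCalibration",
    "z_average_omega",
    "ring_inner_radius",
    "peak_of_profile",
    "calibrate",
    "surface_swirl",
]

RAD_PER_S_TO_DEG_PER_HR = 180.0 / np.pi * 3600.0


@dataclass
class AngularVelocityProfile:
    """z-averaged angular velocity versus radius.

    ``omega_cw`` is the column average of ``-v_phi / rho`` (dimensionless
    model units; positive means clockwise viewed from above).  ``rho_um`` is
    the radial grid in µm.  ``rho_a_um`` (ring inner radius), ``peak_value``
    and ``peak_location_scaled`` (= rho_peak / rho_a) are attached by
    :func:`ring_inner_radius` / :func:`peak_of_profile`.
    """

    rho_um: np.ndarray
    omega_cw: np.ndarray
    r0_um: float
    rho_a_um: float | None = None
    peak_value: float | None = None
    peak_location_scaled: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.rho_um) > 0):
            raise ValueError("radial grid must be strictly increasing")
        if not np.all(np.isfinite(self.omega_cw)):
            raise ValueError("omega_cw contains non-finite values")

    @property
    def rho_scaled(self) -> np.ndarray:
        if self.rho_a_um is None:
            raise ValueError("rho_a_um not set; call ring_inner_radius first")
        return self.rho_um / self.rho_a_um

    def in_deg_per_hr(self, cal: "DimensionalCalibration") -> np.ndarray:
        return cal.omega_to_deg_per_hr(self.omega_cw)


def z_average_omega(sol: FlowSolution, n_rho: int = 240, n_z: int = 60) -> AngularVelocityProfile:
    """Column-average the clockwise angular velocity over the cell height.

    For each radius on a uniform grid, ``omega_cw(rho)`` is the plain mean of
    ``-v_phi(rho, z) / rho`` over ``z`` uniformly sampled between the
    substrate and the dorsal surface (a per-column average, no volume
    weighting).  At radii below one grid step the axis limit
    ``omega = -d(v_phi)/d(rho)`` is used instead of the 0/0 ratio.
    """
    shape_nd = sol.mesh.params
    derived_nd = sol.mesh.derived
    r0 = sol.r0_um
    drho = 1.0 / n_rho
    rho_nd = np.linspace(drho, 1.0 - 0.5 * drho, n_rho)
    heights = dorsal_height(rho_nd, shape_nd, derived_nd)
    # keep samples strictly inside the mesh (boundary rounding safety)
    zfrac = (np.arange(n_z) + 0.5) / n_z
    omega = np.empty(n_rho)
    for i, (r, h) in enumerate(zip(rho_nd, heights)):
        z = zfrac * h
        if r < drho * 0.999:  # axis limit via one-sided difference of v_phi
            vphi = sol.space.evaluate_p2(sol.v_phi, np.full(n_z, drho), z, fill=0.0)
            omega[i] = float(np.mean(-vphi / drho))
            continue
        vphi = sol.space.evaluate_p2(sol.v_phi, np.full(n_z, r), z)
        ok = np.isfinite(vphi)
        omega[i] = float(np.mean(-vphi[ok] / r)) if np.any(ok) else 0.0
    return AngularVelocityProfile(rho_um=rho_nd * r0, omega_cw=omega, r0_um=r0)


def ring_inner_radius(
    shape_or_field,
    act: ActivityParams | None = None,
    threshold: float = 0.8,
    n_scan: int = 700,
    n_z: int = 120,
) -> float:
    """Leftmost radius (µm) where the order parameter reaches ``threshold``.

    Accepts either ``(shape, act)`` parameters or any object with an
    ``s(rho, z)`` evaluator and a ``shape`` attribute (e.g. an
    :class:`~chiroflow.activity.OrientationField`).  The order parameter is
    reduced over each vertical column by its maximum over z; the first
    crossing on a fine radial scan is refined by bisection to 1e-3 µm.
    """
    if act is not None:
        field = OrientationField(shape_or_field, act)
    else:
        field = shape_or_field
    shape = field.shape
    derived = derive_shape(shape)

    def col_max(rho: float) -> float:
        h = dorsal_height(rho, shape, derived)
        z = np.linspace(0.0, h, n_z)
        return float(np.max(field.s(np.full(n_z, rho), z)))

    rhos = np.linspace(0.0, shape.r0_um, n_scan)
    vals = np.array([col_max(r) for r in rhos])
    above = vals >= threshold
    if not np.any(above):
        raise ValueError(f"order parameter never reaches threshold {threshold}")
    k = int(np.argmax(above))
    if k == 0:
        return float(rhos[0])
    lo, hi = rhos[k - 1], rhos[k]
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        if col_max(mid) >= threshold:
            hi = mid
        else:
            lo = mid
    return float(hi)


def peak_of_profile(profile: AngularVelocityProfile, rho_a_um: float | None = None):
    """Locate the profile maximum by parabolic interpolation.

    Returns ``(peak_value, peak_location_scaled)`` with the location divided
    by the ring inner radius; also stores both on the profile.  A maximum on
    the grid boundary is flagged (no interpolation possible).
    """
    if rho_a_um is not None:
        profile.rho_a_um = float(rho_a_um)
    if profile.rho_a_um is None:
        raise ValueError("ring inner radius required to scale the peak location")
    y = profile.omega_cw
    k = int(np.argmax(y))
    if k == 0 or k == y.size - 1:
        raise ValueError("profile maximum lies on the grid boundary; refine the grid")
    x = profile.rho_um
    # parabola through (x[k-1..k+1], y[k-1..k+1]); exact for quadratic data
    denom = (y[k - 1] - 2.0 * y[k] + y[k + 1])
    if denom == 0.0:
        xp, yp = x[k], y[k]
    else:
        dx = x[k + 1] - x[k]
        delta = 0.5 * (y[k - 1] - y[k + 1]) / denom
        xp = x[k] + delta * dx
        yp = y[k] - 0.25 * (y[k - 1] - y[k + 1]) * delta
    profile.peak_value = float(yp)
    profile.peak_location_scaled = float(xp / profile.rho_a_um)
    return profile.peak_value, profile.peak_location_scaled


@dataclass(frozen=True)
class DimensionalCalibration:
    """Velocity and time scales fixing the model's physical units.

    The model velocity unit is the ratio of achiral active stress to
    viscosity times the cell radius; it is calibrated by matching the peak
    dimensionless simulation speed to the measured peak cytoplasmic flow
    speed.  ``velocity_scale_um_s = exp_peak / sim_peak`` and
    ``time_scale_s = R0 / velocity_scale``.
    """

    exp_peak_speed_um_s: float
    sim_peak_speed: float
    r0_um: float

    def __post_init__(self) -> None:
        if not self.sim_peak_speed > 0:
            raise ValueError("simulated peak speed must be positive")
        if not self.exp_peak_speed_um_s > 0:
            raise ValueError("experimental peak speed must be positive")

    @property
    def velocity_scale_um_s(self) -> float:
        return self.exp_peak_speed_um_s / self.sim_peak_speed

    @property
    def time_scale_s(self) -> float:
        return self.r0_um / self.velocity_scale_um_s

    def omega_to_deg_per_hr(self, omega_nd):
        """Convert a dimensionless angular velocity to degrees per hour."""
        return np.asarray(omega_nd) / self.time_scale_s * RAD_PER_S_TO_DEG_PER_HR


def calibrate(
    sim_peak_speed: float,
    exp_peak_speed_um_s: float = 1.0e-2,
    r0_um: float = 35.0,
) -> DimensionalCalibration:
    """Build the dimensional calibration from simulated and measured peaks.

    The default experimental peak speed of 1e-2 µm/s is the upper end of the
    measured cytoplasmic-flow range (5e-3 to 1e-2 µm/s).
    """
    return DimensionalCalibration(
        exp_peak_speed_um_s=exp_peak_speed_um_s, sim_peak_speed=sim_peak_speed, r0_um=r0_um
    )


def surface_swirl(
    sol: FlowSolution,
    side: str,
    offset_frac: float = 0.08,
    n_samples: int = 120,
    noise_floor: float = 1.0e-12,
) -> dict:
    """Classify the swirl pattern in a layer hugging one surface.

    Samples ``(v_rho, v_phi)`` at a fractional height ``offset_frac`` above
    the substrate (``side='ventral'``) or below the dorsal surface
    (``side='dorsal'``).  The radial sense is the sign of the mean
    ``v_rho`` (inward/outward); the rotation sense is the sign of the mean
    ``v_phi``; the spiral handedness follows from their combination —
    streamlines obey ``d(phi)/d(rho) = v_phi / (rho v_rho)``, so equal signs
    wind counter-clockwise outward (sinistral, left-handed viewed from
    above) and opposite signs wind clockwise outward (dextral).  Means below
    ``noise_floor`` (dimensionless velocity) give ``'indeterminate'``.
    """
    if side not in ("dorsal", "ventral"):
        raise ValueError("side must be 'dorsal' or 'ventral'")
    shape_nd, derived_nd = sol.mesh.params, sol.mesh.derived
    rho = np.linspace(0.05, 0.95, n_samples)
    h = dorsal_height(rho, shape_nd, derived_nd)
    z = h * (1.0 - offset_frac) if side == "dorsal" else h * offset_frac
    vr, vp, _ = sol.sample(rho, z)
    ok = np.isfinite(vr) & np.isfinite(vp)
    mean_vr, mean_vp = float(np.mean(vr[ok])), float(np.mean(vp[ok]))

    radial = "indeterminate" if abs(mean_vr) < noise_floor else ("inward" if mean_vr < 0 else "outward")
    rotation = "indeterminate" if abs(mean_vp) < noise_floor else ("clockwise" if mean_vp < 0 else "counterclockwise")
    if abs(mean_vp) < noise_floor or abs(mean_vr) < noise_floor:
        handedness = "indeterminate"
    else:
        handedness = "sinistral" if mean_vp * mean_vr > 0 else "dextral"
    return {
        "side": side,
        "handedness": handedness,
        "radial": radial,
        "rotation": rotation,
        "mean_v_rho": mean_vr,
        "mean_v_phi": mean_vp,
    }
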