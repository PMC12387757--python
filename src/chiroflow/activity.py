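"""Concentric actomyosin ring: orientational order parameter field.

The actomyosin bundles under the dorsal membrane are azimuthally oriented,
``p = S(rho, z) e_phi``, with an effective order parameter ``S`` in [0, 1]
that is ~1 inside the ring band hugging the dorsal surface and decays to 0
elsewhere.  ``S`` is a product of smoothed (tanh) step functions: a sharp
step across the inner edge of the band (sharpness ``lambda1``) and a softer
radial cutoff at ``xi3`` from the cell edge (sharpness ``lambda2``).  The
band is tilted by an angle ``beta`` (slightly steeper than the cell contact
angle), and near the apex the inner edge follows a circle concentric with a
shoulder circle recomputed with ``beta`` and an auxiliary height ``Z0'`` in
place of the shape's ``alpha`` and ``Z0``.

Only ``S**2`` (contractile force dipole) and ``S dS/dz`` (torque-dipole
gradient) enter the flow equations, so the field is invariant under
``p -> -p`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CellShapeParams, DerivedShape, InvalidGeometryError, _shoulder_center_height

__all__ = [
    "ActivityParams",
    "DerivedActivityShape",
    "derive_activity_shape",
    "OrientationField",
    "order_parameter",
    "order_parameter_dz",
]


@dataclass(frozen=True)
class ActivityParams:
    """Parameters of the actomyosin-ring activity distribution.

    ``lambda1_per_um`` — sharpness of the band inner edge (µm⁻¹);
    ``lambda2_per_um`` — sharpness of the radial cutoff (µm⁻¹);
    ``beta_rad`` — tilt angle of the band (rad);
    ``xi_um`` — inward offset of the band inner edge (µm);
    ``xi3_um`` — radial cutoff position measured from the axis (µm);
    ``z0p_um`` — auxiliary height Z0' replacing the cell height in the
    tilted-shoulder construction (µm);
    ``lambda_cap_per_um`` — sharpness used for the circular inner edge near
    the apex; defaults to ``lambda1_per_um``.

    Defaults are expressed relative to the default cell shape
    (R0 = 35 µm, Z0 = 8.2 µm, alpha = 7°).
    """

    lambda1_per_um: float = 150.0 / 35.0
    lambda2_per_um: float = 20.0 / 35.0
    beta_rad: float = 1.7 * 7.0 * 2.0 * np.pi / 360.0
    xi_um: float = 0.06 * 35.0
    xi3_um: float = 0.7 * 35.0
    z0p_um: float = 1.5 * 8.2
    lambda_cap_per_um: float | None = None

    def __post_init__(self) -> None:
        if not (self.lambda1_per_um > 0 and self.lambda2_per_um > 0):
            raise ValueError("lambda1_per_um and lambda2_per_um must be positive")
        if not 0.0 < self.beta_rad < np.pi / 2.0:
            raise ValueError("beta_rad must lie in (0, pi/2)")
        if np.sin(self.beta_rad) < 1e-8:
            raise ValueError("tilt angle too small: sin(beta) < 1e-8")
        if self.xi_um < 0 or self.xi3_um < 0:
            raise ValueError("xi_um and xi3_um must be non-negative")
        if not self.z0p_um > 0:
            raise ValueError("z0p_um must be positive")

    @property
    def lam_cap(self) -> float:
        return self.lambda1_per_um if self.lambda_cap_per_um is None else self.lambda_cap_per_um

    def scaled(self, factor: float) -> "ActivityParams":
        """Rescale all lengths by ``factor`` (sharpness scales inversely)."""
        return ActivityParams(
            lambda1_per_um=self.lambda1_per_um / factor,
            lambda2_per_um=self.lambda2_per_um / factor,
            beta_rad=self.beta_rad,
            xi_um=self.xi_um * factor,
            xi3_um=self.xi3_um * factor,
            z0p_um=self.z0p_um * factor,
            lambda_cap_per_um=None if self.lambda_cap_per_um is None else self.lambda_cap_per_um / factor,
        )


@dataclass(frozen=True)
class DerivedActivityShape:
    """Tilted-shoulder construction for the band inner edge near the apex.

    Same tangency system as the cell shoulder, with ``beta`` for ``alpha``
    and ``Z0'`` for ``Z0``: ``rho3p_um`` is the junction radius, ``r2p_um``
    the circle radius and ``z2p_um`` its centre height.
    """

    rho3p_um: float
    r2p_um: float
    z2p_um: float


def derive_activity_shape(shape: CellShapeParams, act: ActivityParams) -> DerivedActivityShape:
    """Solve the tilted tangency construction (beta, Z0') for the band edge."""
    try:
        z2p = _shoulder_center_height(
            act.z0p_um, shape.r0_um, shape.r1_um, shape.rho2_um, act.beta_rad
        )
    except InvalidGeometryError as exc:
        raise InvalidGeometryError(f"invalid activity geometry: {exc}") from exc
    sb, cb = np.sin(act.beta_rad), np.cos(act.beta_rad)
    r2p = sb * (shape.rho2_um - shape.r0_um) + cb * z2p
    if not r2p > 0.0:
        raise InvalidGeometryError(f"invalid activity geometry: r2' = {r2p:.6g} <= 0")
    rho3p = shape.rho2_um - r2p * sb
    return DerivedActivityShape(rho3p_um=rho3p, r2p_um=r2p, z2p_um=z2p)


def _branch_indicator(rho, z, shape: CellShapeParams, act: ActivityParams, da: DerivedActivityShape):
    """Signed dividing-line function splitting the two inner-edge formulas.

    The line ``cos(b) rho - sin(b) z = rho3'/cos(b) - sin(b) tan(b) R0``
    passes through the tangency point between the straight tilted band edge
    and the circular edge concentric with the tilted shoulder.  On the
    cell-edge side (indicator > 0) the inner edge is the straight tilted
    plane; on the apex side (indicator <= 0) it is the circular arc, which
    carves the central hole of the ring (the apical dome carries no
    actomyosin, so the leftmost radius with S >= 0.8 is the ring inner
    radius rather than zero).
    """
    sb, cb = np.sin(act.beta_rad), np.cos(act.beta_rad)
    return cb * rho - sb * z - da.rho3p_um / cb + sb * np.tan(act.beta_rad) * shape.r0_um


def order_parameter(rho, z, shape: CellShapeParams, act: ActivityParams,
                    derived_act: DerivedActivityShape | None = None):
    """Evaluate the order parameter ``S(rho, z)`` (dimensionless, in [0, 1]).

    Two branches: on the cell-edge side of the dividing line, a tilted
    straight band (product of the inner-edge and radial-cutoff tanh steps);
    on the apex side, a circular inner edge concentric with the tilted
    shoulder circle, which keeps the apical dome free of activity.  Accepts
    scalars or arrays.
    """
    if derived_act is None:
        derived_act = derive_activity_shape(shape, act)
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    sb, cb = np.sin(act.beta_rad), np.cos(act.beta_rad)

    edge = 0.5 * np.tanh(act.lambda1_per_um * (sb * rho + cb * z - sb * shape.r0_um + act.xi_um)) + 0.5
    cutoff = 0.5 * np.tanh(-act.lambda2_per_um * (cb * rho - sb * z - act.xi3_um)) + 0.5
    s_band = edge * cutoff

    dist = np.sqrt((rho - shape.rho2_um) ** 2 + (z - derived_act.z2p_um) ** 2)
    s_cap = 0.5 * np.tanh(act.lam_cap * (derived_act.r2p_um + act.xi_um - dist)) + 0.5

    s = np.where(_branch_indicator(rho, z, shape, act, derived_act) > 0.0, s_band, s_cap)
    s = np.clip(s, 0.0, 1.0)  # guards sub-1e-12 rounding excursions only
    return s if s.shape else float(s)


def order_parameter_dz(rho, z, shape: CellShapeParams, act: ActivityParams,
                       derived_act: DerivedActivityShape | None = None):
    """Analytic ``dS/dz`` (µm⁻¹), branch-consistent with :func:`order_parameter`."""
    if derived_act is None:
        derived_act = derive_activity_shape(shape, act)
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    sb, cb = np.sin(act.beta_rad), np.cos(act.beta_rad)
    lam1, lam2 = act.lambda1_per_um, act.lambda2_per_um

    a1 = lam1 * (sb * rho + cb * z - sb * shape.r0_um + act.xi_um)
    a2 = -lam2 * (cb * rho - sb * z - act.xi3_um)
    edge = 0.5 * np.tanh(a1) + 0.5
    cutoff = 0.5 * np.tanh(a2) + 0.5
    d_edge = 0.5 * lam1 * cb / np.cosh(a1) ** 2
    d_cutoff = 0.5 * lam2 * sb / np.cosh(a2) ** 2
    d_band = d_edge * cutoff + edge * d_cutoff

    dist = np.sqrt((rho - shape.rho2_um) ** 2 + (z - derived_act.z2p_um) ** 2)
    a3 = act.lam_cap * (derived_act.r2p_um + act.xi_um - dist)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_cap = 0.5 * act.lam_cap / np.cosh(a3) ** 2 * (-(z - derived_act.z2p_um) / dist)
    d_cap = np.where(dist > 0.0, d_cap, 0.0)

    d = np.where(_branch_indicator(rho, z, shape, act, derived_act) > 0.0, d_band, d_cap)
    return d if d.shape else float(d)


@dataclass(frozen=True)
class OrientationField:
    """Bundle of shape + activity parameters exposing vectorised evaluators.

    The direction of ``p`` is the fixed azimuthal unit vector; only the
    scalar amplitude ``S`` and its z-derivative vary in the meridional plane.
    """

    shape: CellShapeParams
    act: ActivityParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "_derived_act", derive_activity_shape(self.shape, self.act))

    @property
    def derived_act(self) -> DerivedActivityShape:
        return self._derived_act

    def s(self, rho, z):
        return order_parameter(rho, z, self.shape, self.act, self._derived_act)

    def ds_dz(self, rho, z):
        return order_parameter_dz(rho, z, self.shape, self.act, self._derived_act)

    def scaled(self, factor: float) -> "OrientationField":
        return OrientationField(self.shape.scaled(factor), self.act.scaled(factor))
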