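"""Axisymmetric cell geometry: dorsal boundary curve and meridional mesh.

The cultured epithelial cell is modelled as an axisymmetric body of
revolution sitting on the substrate (ventral plane ``z = 0``).  Its dorsal
surface is a piecewise curve in the meridional ``(rho, z)`` plane built from
three tangent pieces:

1. an apical spherical cap of radius ``r1`` centred on the symmetry axis,
2. a shoulder circle of radius ``r2`` centred at ``(rho2, Z2)`` that is
   externally tangent to the cap, and
3. a straight contact wedge meeting the substrate at radius ``R0`` with
   contact angle ``alpha``.

The shoulder circle is determined by the two tangency conditions (to the cap
and to the wedge line); the junction radii ``rho1`` and ``rho3`` follow.  All
lengths are in micrometres, angles in radians.  The formulas are homogeneous
of degree one in length, so the same code is used for the rescaled
(dimensionless) domain of the flow solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CellShapeParams",
    "DerivedShape",
    "InvalidGeometryError",
    "derive_shape",
    "dorsal_height",
    "cross_section_area",
    "MeridionalMesh",
    "build_mesh",
]

_SIN_ALPHA_MIN = 1e-8


class InvalidGeometryError(ValueError):
    """Raised when shape parameters do not define a valid tangent boundary."""


@dataclass(frozen=True)
class CellShapeParams:
    """Primary cell-shape parameters.

    Parameters
    ----------
    z0_um : float
        Cell height at the axis (µm).
    r0_um : float
        Cell (contact-line) radius (µm).
    r1_um : float
        Radius of the apical cap circle (µm).
    rho2_um : float
        Radial position of the shoulder-circle centre (µm).
    alpha_rad : float
        Contact angle of the cell edge with the substrate (rad).
    """

    z0_um: float = 8.2
    r0_um: float = 35.0
    r1_um: float = 15.0
    rho2_um: float = 22.0
    alpha_rad: float = 7.0 * 2.0 * np.pi / 360.0

    def __post_init__(self) -> None:
        for name in ("z0_um", "r0_um", "r1_um", "rho2_um", "alpha_rad"):
            if not getattr(self, name) > 0.0:
                raise InvalidGeometryError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not self.alpha_rad < np.pi / 2.0:
            raise InvalidGeometryError("alpha_rad must lie in (0, pi/2)")
        if abs(np.sin(self.alpha_rad)) < _SIN_ALPHA_MIN:
            raise InvalidGeometryError("contact angle too small: |sin(alpha)| < 1e-8")
        if not self.rho2_um < self.r0_um:
            raise InvalidGeometryError("rho2_um must be smaller than r0_um")

    def scaled(self, factor: float) -> "CellShapeParams":
        """Return a copy with all lengths multiplied by ``factor`` (angle kept)."""
        return replace(
            self,
            z0_um=self.z0_um * factor,
            r0_um=self.r0_um * factor,
            r1_um=self.r1_um * factor,
            rho2_um=self.rho2_um * factor,
        )


@dataclass(frozen=True)
class DerivedShape:
    """Quantities derived from :class:`CellShapeParams` by tangency.

    Attributes
    ----------
    rho1_um, rho3_um : float
        Junction radii between cap/shoulder and shoulder/wedge (µm).
    r2_um : float
        Shoulder circle radius (µm).
    z2_um : float
        Shoulder circle centre height (µm); may be negative (centre below
        the substrate plane is geometrically admissible).
    """

    rho1_um: float
    rho3_um: float
    r2_um: float
    z2_um: float


def _shoulder_center_height(z0: float, r0: float, r1: float, rho2: float, alpha: float) -> float:
    """Closed form for the shoulder-circle centre height Z2.

    Obtained by eliminating r2 between the wedge-line tangency
    ``r2 = sin(a)(rho2 - R0) + cos(a) Z2`` and the external cap tangency
    ``rho2^2 + (Z2 - (Z0 - r1))^2 = (r1 + r2)^2`` and solving the resulting
    quadratic for Z2 (root giving a positive radius).
    """
    sa, ca = np.sin(alpha), np.cos(alpha)
    radical = (-r1 + (r1 - z0) * ca + r0 * sa) * (-r1 + (r1 - z0) * ca + (r0 - 2.0 * rho2) * sa)
    if radical < 0.0:
        raise InvalidGeometryError(
            "invalid geometry: negative argument of the square root in the Z2 "
            f"expression (got {radical:.6g}); the cap, shoulder and edge line "
            "admit no tangent configuration for these parameters"
        )
    return -(r1 - z0 - ca * (r1 + (rho2 - r0) * sa) + np.sqrt(radical)) / (sa * sa)


def derive_shape(params: CellShapeParams) -> DerivedShape:
    """Solve the tangency construction for the dorsal boundary.

    Returns the junction radii ``rho1``/``rho3``, shoulder radius ``r2`` and
    shoulder centre height ``Z2``.  Raises :class:`InvalidGeometryError` when
    the parameters admit no tangent shoulder circle.
    """
    z0, r0, r1 = params.z0_um, params.r0_um, params.r1_um
    rho2, alpha = params.rho2_um, params.alpha_rad
    sa, ca = np.sin(alpha), np.cos(alpha)

    z2 = _shoulder_center_height(z0, r0, r1, rho2, alpha)
    r2 = sa * (rho2 - r0) + ca * z2
    if not r2 > 0.0:
        raise InvalidGeometryError(f"invalid geometry: shoulder radius r2 = {r2:.6g} <= 0")
    rho1 = r1 * rho2 / (r1 + r2)
    rho3 = rho2 - r2 * sa
    if not (0.0 < rho1 < rho3 < r0):
        raise InvalidGeometryError(
            f"invalid geometry: junction radii not ordered (rho1={rho1:.6g}, rho3={rho3:.6g}, R0={r0:.6g})"
        )
    return DerivedShape(rho1_um=rho1, rho3_um=rho3, r2_um=r2, z2_um=z2)


def dorsal_height(rho, params: CellShapeParams, derived: DerivedShape | None = None):
    """Height of the dorsal boundary above the substrate at radius ``rho``.

    Piecewise: apical cap on ``[0, rho1]``, shoulder arc on ``[rho1, rho3]``,
    straight wedge on ``[rho3, R0]``.  Accepts scalars or arrays (µm in, µm out).
    """
    if derived is None:
        derived = derive_shape(params)
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < -1e-12) or np.any(rho_arr > params.r0_um * (1.0 + 1e-12)):
        raise ValueError(f"rho outside [0, R0={params.r0_um}]")
    rho_c = np.clip(rho_arr, 0.0, params.r0_um)

    z0, r1 = params.z0_um, params.r1_um
    rho1, rho3 = derived.rho1_um, derived.rho3_um
    r2, z2 = derived.r2_um, derived.z2_um
    rho2 = params.rho2_um
    tana = np.tan(params.alpha_rad)

    cap = z0 - r1 + np.sqrt(np.maximum(r1 * r1 - rho_c * rho_c, 0.0))
    shoulder = z2 - np.sqrt(np.maximum(r2 * r2 - (rho_c - rho2) ** 2, 0.0))
    wedge = -tana * (rho_c - params.r0_um)
    z = np.where(rho_c <= rho1, cap, np.where(rho_c <= rho3, shoulder, wedge))
    return z if z.shape else float(z)


def cross_section_area(params: CellShapeParams, derived: DerivedShape | None = None) -> float:
    """Analytic-quadrature area of the meridional cross-section (µm²)."""
    from scipy.integrate import quad

    if derived is None:
        derived = derive_shape(params)
    val, _ = quad(
        lambda r: dorsal_height(r, params, derived),
        0.0,
        params.r0_um,
        points=[derived.rho1_um, derived.rho3_um],
        limit=200,
    )
    return val


# ---------------------------------------------------------------------------
# meshing


@dataclass(frozen=True)
class MeridionalMesh:
    """Conforming triangulation of the meridional cross-section.

    ``points`` is ``(n_nodes, 2)`` with columns ``(rho, z)``; ``triangles``
    is ``(n_tri, 3)`` (counter-clockwise).  Boundary edges are stored as
    vertex pairs per tag: ``ventral`` (z = 0), ``dorsal`` (the piecewise
    curve) and ``axis`` (rho = 0).  ``h`` is the characteristic edge length.
    """

    points: np.ndarray
    triangles: np.ndarray
    boundary: dict  # tag -> (n_edges, 2) int array of vertex pairs
    h: float
    params: CellShapeParams
    derived: DerivedShape

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    def area(self) -> float:
        p = self.points
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return float(0.5 * np.sum(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]))

    def save_vtk(self, path) -> None:
        from .vtkio import write_vtk_mesh

        write_vtk_mesh(path, self.points, self.triangles)


def build_mesh(
    params: CellShapeParams,
    derived: DerivedShape | None = None,
    h: float | None = None,
) -> MeridionalMesh:
    """Triangulate the cell cross-section with target edge length ``h`` (µm).

    A boundary-fitted tensor grid is used: radial columns at uniform rho and,
    within each column, nodes uniformly spaced between the substrate and the
    exact dorsal curve.  The contact line (where the height vanishes) is a
    single node closing the mesh with a fan of triangles, so every boundary
    node lies exactly on the boundary curve.
    """
    if derived is None:
        derived = derive_shape(params)
    r0, z0 = params.r0_um, params.z0_um
    if h is None:
        h = r0 / 100.0
    if not 0.0 < h <= r0 / 10.0:
        raise ValueError(f"mesh size h={h} must lie in (0, R0/10]; params={params}")

    n_r = max(int(np.ceil(r0 / h)), 10)
    n_z = max(int(np.ceil(z0 / h)), 4)

    rho_cols = np.linspace(0.0, r0, n_r + 1)
    s_levels = np.linspace(0.0, 1.0, n_z + 1)

    # nodes: full columns for i < n_r, a single apex node at the contact line
    heights = dorsal_height(rho_cols[:-1], params, derived)
    node_id = np.arange(n_r * (n_z + 1)).reshape(n_r, n_z + 1)
    pts = np.empty((n_r * (n_z + 1) + 1, 2))
    for i in range(n_r):
        pts[node_id[i], 0] = rho_cols[i]
        pts[node_id[i], 1] = s_levels * heights[i]
    tip = n_r * (n_z + 1)
    pts[tip] = (r0, 0.0)

    tris = []
    for i in range(n_r - 1):
        a, b = node_id[i], node_id[i + 1]
        for j in range(n_z):
            # split each quad along the same diagonal; CCW orientation
            tris.append((a[j], b[j], b[j + 1]))
            tris.append((a[j], b[j + 1], a[j + 1]))
    last = node_id[n_r - 1]
    for j in range(n_z):
        tris.append((last[j], tip, last[j + 1]) if j == 0 else (last[j], last[j + 1], tip))
    # fan orientation: ensure CCW via signed area fix below
    triangles = np.asarray(tris, dtype=np.int64)
    p = pts
    d1 = p[triangles[:, 1]] - p[triangles[:, 0]]
    d2 = p[triangles[:, 2]] - p[triangles[:, 0]]
    signed = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    flip = signed < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    if np.any(np.abs(signed) <= 0.0):
        raise RuntimeError(f"meshing failure: degenerate triangle; params={params}, h={h}")

    boundary = {
        "ventral": np.array(
            [(node_id[i, 0], node_id[i + 1, 0]) for i in range(n_r - 1)]
            + [(node_id[n_r - 1, 0], tip)],
            dtype=np.int64,
        ),
        "dorsal": np.array(
            [(node_id[i, n_z], node_id[i + 1, n_z]) for i in range(n_r - 1)]
            + [(node_id[n_r - 1, n_z], tip)],
            dtype=np.int64,
        ),
        "axis": np.array([(node_id[0, j], node_id[0, j + 1]) for j in range(n_z)], dtype=np.int64),
    }
    return MeridionalMesh(
        points=pts, triangles=triangles, boundary=boundary, h=float(h), params=params, derived=derived
    )


def rectangle_mesh(width: float, height: float, n_x: int, n_z: int) -> MeridionalMesh:
    """Structured triangulation of ``[0, width] x [0, height]``.

    Verification helper (manufactured solutions): tags mirror the cell mesh
    — ``ventral`` (z=0), ``dorsal`` (z=height), ``axis`` (rho=0) — plus
    ``rim`` for the outer wall rho=width.
    """
    xs = np.linspace(0.0, width, n_x + 1)
    zs = np.linspace(0.0, height, n_z + 1)
    nid = np.arange((n_x + 1) * (n_z + 1)).reshape(n_x + 1, n_z + 1)
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    pts = np.column_stack([xx.ravel(), zz.ravel()])
    tris = []
    for i in range(n_x):
        for j in range(n_z):
            tris.append((nid[i, j], nid[i + 1, j], nid[i + 1, j + 1]))
            tris.append((nid[i, j], nid[i + 1, j + 1], nid[i, j + 1]))
    boundary = {
        "ventral": np.array([(nid[i, 0], nid[i + 1, 0]) for i in range(n_x)], dtype=np.int64),
        "dorsal": np.array([(nid[i, n_z], nid[i + 1, n_z]) for i in range(n_x)], dtype=np.int64),
        "axis": np.array([(nid[0, j], nid[0, j + 1]) for j in range(n_z)], dtype=np.int64),
        "rim": np.array([(nid[n_x, j], nid[n_x, j + 1]) for j in range(n_z)], dtype=np.int64),
    }
    params = CellShapeParams(z0_um=height, r0_um=width, r1_um=width, rho2_um=width / 2.0)
    derived = DerivedShape(rho1_um=width / 4, rho3_um=width / 2, r2_um=width, z2_um=height)
    return MeridionalMesh(points=pts, triangles=np.asarray(tris, dtype=np.int64),
                          boundary=boundary, h=float(max(width / n_x, height / n_z)),
                          params=params, derived=derived)
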