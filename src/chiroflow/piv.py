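"""Post-processing of gridded planar velocity fields (PIV output).

Consumes the gridded vector fields exported by PIV software (the window
cross-correlation itself is delegated to such tools) and reduces them the
way the live-imaging analysis does: decomposition into azimuthal and radial
components about the cell centre, angular velocity, temporal averaging,
angular (per-radius-bin) averaging, and rescaling of the radial axis by the
actomyosin-ring inner radius.

Image convention throughout: ``y`` increases downward, so the azimuthal
component ``v_phi = x_hat v_y - y_hat v_x`` is positive for motion that is
clockwise on screen — which is clockwise viewed from the dorsal side, the
sign convention in which all rotation results are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PlanarVelocityField",
    "PolarDecomposition",
    "RadialProfile",
    "decompose",
    "temporal_average",
    "angular_average",
    "rescale_radius",
    "read_field_csv",
    "write_field_csv",
]


@dataclass(frozen=True)
class PlanarVelocityField:
    """One frame (or a temporal average) of a gridded planar velocity field.

    ``x_um``/``y_um`` are 1-D rectilinear grid coordinates (µm, image
    convention with y down); ``v_x``/``v_y`` are (ny, nx) velocities (µm/s);
    ``mask`` marks valid vectors; ``center_um`` is the cell centre (taken in
    the experiments as the xy position of the cell's highest point, supplied
    by the user); ``time_s`` stamps the frame.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    v_x: np.ndarray
    v_y: np.ndarray
    mask: np.ndarray
    center_um: tuple
    time_s: float = 0.0

    def __post_init__(self) -> None:
        nx, ny = self.x_um.size, self.y_um.size
        if self.v_x.shape != (ny, nx) or self.v_y.shape != (ny, nx) or self.mask.shape != (ny, nx):
            raise ValueError("v_x, v_y and mask must have shape (len(y), len(x))")
        for g in (self.x_um, self.y_um):
            d = np.diff(g)
            if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-6)):
                raise ValueError("grids must be uniform and increasing")

    @property
    def grid_spacing_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0])


@dataclass(frozen=True)
class PolarDecomposition:
    """Azimuthal/radial decomposition of one field about the cell centre.

    ``v_phi`` (µm/s, clockwise-on-screen positive), ``v_r`` (µm/s, outward
    positive), ``omega`` (rad/s, = v_phi / r, masked within ``r_min_um`` of
    the centre), ``r_um`` the centre distance per grid point.
    """

    r_um: np.ndarray
    v_phi: np.ndarray
    v_r: np.ndarray
    omega: np.ndarray
    mask: np.ndarray
    omega_mask: np.ndarray
    grid_spacing_um: float
    time_s: float = 0.0


def decompose(field: PlanarVelocityField, r_min_um: float | None = None) -> PolarDecomposition:
    """Project a planar field onto azimuthal and radial unit vectors.

    With ``(x, y)`` the position relative to the centre and ``r`` its norm:
    ``v_phi = (x v_y - y v_x)/r``, ``v_r = (x v_x + y v_y)/r``, and the
    angular velocity ``omega = v_phi / r``.  Points closer to the centre
    than ``r_min_um`` (default: one grid spacing) are excluded from
    ``omega`` to avoid the division blow-up.
    """
    xc, yc = field.center_um
    if not (field.x_um[0] <= xc <= field.x_um[-1] and field.y_um[0] <= yc <= field.y_um[-1]):
        raise ValueError("cell center lies outside the grid")
    if r_min_um is None:
        r_min_um = field.grid_spacing_um
    x = field.x_um[None, :] - xc
    y = field.y_um[:, None] - yc
    r = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        xh, yh = x / r, y / r
        v_phi = xh * field.v_y - yh * field.v_x
        v_r = xh * field.v_x + yh * field.v_y
        omega = v_phi / r
    at_center = r == 0.0
    v_phi = np.where(at_center, 0.0, v_phi)
    v_r = np.where(at_center, 0.0, v_r)
    omega_mask = field.mask & (r >= r_min_um)
    omega = np.where(omega_mask, omega, np.nan)
    return PolarDecomposition(
        r_um=r, v_phi=v_phi, v_r=v_r, omega=omega, mask=field.mask.copy(),
        omega_mask=omega_mask, grid_spacing_um=field.grid_spacing_um, time_s=field.time_s,
    )


def temporal_average(series: list[PolarDecomposition]) -> PolarDecomposition:
    """Per-grid-point mean over frames, restricted to jointly valid points."""
    if len(series) < 2:
        raise ValueError("temporal average needs at least 2 frames")
    ref = series[0]
    for d in series[1:]:
        if d.r_um.shape != ref.r_um.shape:
            raise ValueError("frames have inconsistent grids")
    mask = np.logical_and.reduce([d.mask for d in series])
    omask = np.logical_and.reduce([d.omega_mask for d in series])
    if not mask.any():
        raise ValueError("no grid point is valid in every frame")
    v_phi = np.mean([d.v_phi for d in series], axis=0)
    v_r = np.mean([d.v_r for d in series], axis=0)
    omega = np.where(omask, np.mean([np.where(d.omega_mask, d.omega, 0.0) for d in series], axis=0), np.nan)
    return PolarDecomposition(
        r_um=ref.r_um.copy(), v_phi=v_phi, v_r=v_r, omega=omega, mask=mask,
        omega_mask=omask, grid_spacing_um=ref.grid_spacing_um, time_s=float(np.mean([d.time_s for d in series])),
    )


@dataclass(frozen=True)
class RadialProfile:
    """Radius-binned means and standard errors of v_phi, v_r and omega.

    ``radius`` holds bin centres (µm, or dimensionless after rescaling by
    the ring inner radius); per-bin columns carry mean, SEM (= sd/sqrt(n))
    and the count ``n``; empty bins keep ``n = 0`` with NaN values.
    """

    table: pd.DataFrame           # columns: radius, then <q>_mean/_sem/_n
    bin_edges: np.ndarray
    scaled: bool = False

    def mean(self, quantity: str) -> np.ndarray:
        return self.table[f"{quantity}_mean"].to_numpy()

    def sem(self, quantity: str) -> np.ndarray:
        return self.table[f"{quantity}_sem"].to_numpy()


def angular_average(decomp: PolarDecomposition, bins: np.ndarray | int | None = None) -> RadialProfile:
    """Bin grid points by centre distance and average within each annulus.

    ``bins`` may be explicit edges, a bin count, or None for one-grid-step
    bins from 0 to the largest valid radius (the temporal average should be
    formed first, matching the order of the experimental analysis).
    """
    rmax = float(np.max(decomp.r_um[decomp.mask])) if decomp.mask.any() else 0.0
    if bins is None:
        bins = np.arange(0.0, rmax + decomp.grid_spacing_um, decomp.grid_spacing_um)
    elif np.isscalar(bins):
        bins = np.linspace(0.0, rmax, int(bins) + 1)
    bins = np.asarray(bins, float)

    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = decomp.mask & (decomp.r_um >= lo) & (decomp.r_um < hi)
        row = {"radius": 0.5 * (lo + hi)}
        for name, vals, msk in (
            ("v_phi", decomp.v_phi, sel),
            ("v_r", decomp.v_r, sel),
            ("omega", decomp.omega, sel & decomp.omega_mask),
        ):
            v = vals[msk]
            n = v.size
            row[f"{name}_mean"] = float(np.mean(v)) if n else np.nan
            row[f"{name}_sem"] = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else np.nan)
            row[f"{name}_n"] = n
        rows.append(row)
    return RadialProfile(table=pd.DataFrame(rows), bin_edges=bins)


def rescale_radius(profile: RadialProfile, ring_inner_radius_um: float) -> RadialProfile:
    """Divide the radial axis by the (manually identified) ring inner radius."""
    if not ring_inner_radius_um > 0:
        raise ValueError("ring inner radius must be positive")
    table = profile.table.copy()
    table["radius"] = table["radius"] / ring_inner_radius_um
    return RadialProfile(table=table, bin_edges=profile.bin_edges / ring_inner_radius_um, scaled=True)


# ---------------------------------------------------------------------------
# text I/O in the common per-frame PIV export dialect


def write_field_csv(path, field: PlanarVelocityField) -> None:
    """Write one frame as tidy CSV with columns x_um, y_um, vx, vy, valid."""
    xx, yy = np.meshgrid(field.x_um, field.y_um)
    pd.DataFrame(
        {
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "vx_um_s": field.v_x.ravel(),
            "vy_um_s": field.v_y.ravel(),
            "valid": field.mask.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def read_field_csv(path, center_um: tuple, time_s: float = 0.0) -> PlanarVelocityField:
    """Read a frame written by :func:`write_field_csv` (or equivalent export)."""
    df = pd.read_csv(path)
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    shape = (y.size, x.size)
    order = np.lexsort((df["x_um"].to_numpy(), df["y_um"].to_numpy()))
    return PlanarVelocityField(
        x_um=x,
        y_um=y,
        v_x=df["vx_um_s"].to_numpy()[order].reshape(shape),
        v_y=df["vy_um_s"].to_numpy()[order].reshape(shape),
        mask=df["valid"].to_numpy()[order].reshape(shape).astype(bool),
        center_um=tuple(center_um),
        time_s=time_s,
    )
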