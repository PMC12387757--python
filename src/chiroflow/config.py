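"""Run configuration: TOML schema with unit-suffixed keys.

All defaults equal the reference parameter set of the model (35 µm cell,
7° contact angle, concentric ring activity, zeta = 0.004, experimental peak
flow speed 1e-2 µm/s).  Angles are degrees in the file and converted
exactly to radians on load.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .activity import ActivityParams
from .geometry import CellShapeParams
from .solver import SolverConfig

__all__ = ["AnalysisConfig", "RunConfig", "load_config", "save_config"]

DEG = 2.0 * math.pi / 360.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Post-processing options.

    ``exp_peak_speed_um_s`` — measured peak cytoplasmic flow speed used for
    dimensional calibration (upper end of the observed 5e-3..1e-2 µm/s
    range); ``ring_threshold`` — order-parameter level defining the ring
    inner radius; ``n_rho_profile``/``n_z_profile`` — profile sampling;
    ``r_min_factor`` — omega exclusion radius in grid spacings (planar
    pipeline); ``swirl_offset_frac`` — fractional height of the sampled
    surface layers.
    """

    exp_peak_speed_um_s: float = 1.0e-2
    ring_threshold: float = 0.8
    n_rho_profile: int = 240
    n_z_profile: int = 60
    r_min_factor: float = 1.0
    swirl_offset_frac: float = 0.08

    def __post_init__(self) -> None:
        if not 0.0 < self.ring_threshold < 1.0:
            raise ValueError("ring_threshold must lie in (0, 1)")
        if self.exp_peak_speed_um_s <= 0:
            raise ValueError("exp_peak_speed_um_s must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a simulation + quantification run."""

    shape: CellShapeParams = field(default_factory=CellShapeParams)
    activity: ActivityParams = field(default_factory=ActivityParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    return f'"{v}"'


def save_config(config: RunConfig, path) -> None:
    """Write the configuration as TOML (flat sections of scalar keys)."""
    sections = {
        "geometry": {
            "z0_um": config.shape.z0_um,
            "r0_um": config.shape.r0_um,
            "r1_um": config.shape.r1_um,
            "rho2_um": config.shape.rho2_um,
            "alpha_deg": config.shape.alpha_rad / DEG,
        },
        "activity": {
            "lambda1_per_um": config.activity.lambda1_per_um,
            "lambda2_per_um": config.activity.lambda2_per_um,
            "beta_deg": config.activity.beta_rad / DEG,
            "xi_um": config.activity.xi_um,
            "xi3_um": config.activity.xi3_um,
            "z0p_um": config.activity.z0p_um,
            **(
                {"lambda_cap_per_um": config.activity.lambda_cap_per_um}
                if config.activity.lambda_cap_per_um is not None
                else {}
            ),
        },
        "solver": {
            "zeta": config.solver.zeta,
            "h_um": config.solver.h_um,
            "penalty": config.solver.penalty,
            "tol": config.solver.tol,
        },
        "analysis": asdict(config.analysis),
        "run": {"seed": config.seed},
    }
    lines = []
    for name, body in sections.items():
        lines.append(f"[{name}]")
        lines += [f"{k} = {_fmt(v)}" for k, v in body.items()]
        lines.append("")
    Path(path).write_text("\n".join(lines))


def load_config(path) -> RunConfig:
    """Read a TOML configuration; missing keys fall back to defaults."""
    raw = tomllib.loads(Path(path).read_text())
    g = raw.get("geometry", {})
    a = raw.get("activity", {})
    s = raw.get("solver", {})
    an = raw.get("analysis", {})
    shape_kw = {k + "_um": g[k + "_um"] for k in ("z0", "r0", "r1", "rho2") if k + "_um" in g}
    if "alpha_deg" in g:
        shape_kw["alpha_rad"] = g["alpha_deg"] * DEG
    act_kw = {k: a[k] for k in ("lambda1_per_um", "lambda2_per_um", "xi_um", "xi3_um",
                                "z0p_um", "lambda_cap_per_um") if k in a}
    if "beta_deg" in a:
        act_kw["beta_rad"] = a["beta_deg"] * DEG
    solver_kw = {k: s[k] for k in ("zeta", "h_um", "penalty", "tol") if k in s}
    return RunConfig(
        shape=CellShapeParams(**shape_kw),
        activity=ActivityParams(**act_kw),
        solver=SolverConfig(**solver_kw),
        analysis=AnalysisConfig(**an),
        seed=int(raw.get("run", {}).get("seed", 0)),
    )
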