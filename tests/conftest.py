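"""Shared fixtures: reference parameters and pre-solved flow fields."""

from __future__ import annotations

import numpy as np
import pytest

from chiroflow import ActivityParams, CellShapeParams, SolverConfig, solve


@pytest.fixture(scope="session")
def shape() -> CellShapeParams:
    """Reference cell shape (35 µm radius, 8.2 µm height, 7° contact angle)."""
    return CellShapeParams()


@pytest.fixture(scope="session")
def activity() -> ActivityParams:
    """Reference concentric-ring activity parameters."""
    return ActivityParams()


@pytest.fixture(scope="session")
def coarse_solution(shape, activity):
    """Flow solution on a coarse (0.7 µm) mesh: fast, right sign structure."""
    return solve(shape, activity, SolverConfig(h_um=0.7))


@pytest.fixture(scope="session")
def default_solution(shape, activity):
    """Flow solution at the default 0.35 µm resolution."""
    return solve(shape, activity, SolverConfig())


def perturbed_shape_sets(n: int = 20, rel: float = 0.2, seed: int = 42):
    """Valid cell-shape parameter sets within ±rel of the reference values."""
    rng = np.random.default_rng(seed)
    ref = CellShapeParams()
    out = []
    while len(out) < n:
        f = 1.0 + rel * rng.uniform(-1.0, 1.0, size=5)
        try:
            p = CellShapeParams(
                z0_um=ref.z0_um * f[0],
                r0_um=ref.r0_um * f[1],
                r1_um=ref.r1_um * f[2],
                rho2_um=ref.rho2_um * f[3],
                alpha_rad=ref.alpha_rad * f[4],
            )
            from chiroflow import derive_shape

            derive_shape(p)  # keep only sets with a valid tangent shoulder
            out.append(p)
        except ValueError:
            continue
    return out
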