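"""Synthetic inputs and analytic oracles.

Everything the test-suite consumes is generated here at run time:
seeded uniform particle ensembles emulating the uniformly distributed
initial cell suspension of the trap-simulation scenario, closed-form
field solutions used as solver and integrator oracles, and the packaged
default configuration.

Random numbers come from one named algorithm — numpy's PCG64 behind
``numpy.random.default_rng`` — always seeded explicitly; no global
state is touched, so every generator is a pure function of its spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from deptrap.field_solver import (
    DeviceGeometry,
    FieldSolution,
    GridSpec,
    solve_potential,
)
from deptrap.dielectrics import DriveSignal
from deptrap.transport import ParticleState


@dataclass(frozen=True)
class EnsembleSpec:
    """Uniform particle ensemble: count, axis-aligned region (m), seed.

    ``region`` is ``(x_min, x_max, y_min, y_max, z_min, z_max)``.  The
    default region spans the channel cross-section around the trap with
    5 um wall clearance, mirroring an initially uniform cell
    suspension; y is pinned to 0 so the ensemble lives in the (x, z)
    cross-sectional plane the trap is usually visualised in.
    """

    count: int = 50
    region: tuple[float, float, float, float, float, float] = (
        -120e-6, 120e-6, 0.0, 0.0, 5e-6, 35e-6
    )
    seed: int = 42

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("ensemble count must be >= 0")
        x0, x1, y0, y1, z0, z1 = self.region
        if not (x0 <= x1 and y0 <= y1 and z0 <= z1):
            raise ValueError("region bounds must be ordered min <= max")


def gen_uniform_ensemble(
    spec: EnsembleSpec,
    geometry: DeviceGeometry | None = None,
    cell_radius: float = 5e-6,
) -> list[ParticleState]:
    """Draw ``spec.count`` particle states uniformly over ``spec.region``.

    Reproducible per seed; every state satisfies the wall-clearance
    invariant ``R <= z <= channel_height - R`` (a region violating it is
    rejected outright).
    """
    geometry = geometry or DeviceGeometry()
    x0, x1, y0, y1, z0, z1 = spec.region
    if z0 < cell_radius or z1 > geometry.channel_height - cell_radius:
        raise ValueError(
            "ensemble region violates wall clearance: need "
            f"{cell_radius:g} <= z <= {geometry.channel_height - cell_radius:g}"
        )
    rng = np.random.default_rng(spec.seed)
    pts = rng.uniform(
        low=[x0, y0, z0], high=[x1, y1, z1], size=(spec.count, 3)
    )
    return [ParticleState(float(p[0]), float(p[1]), float(p[2]), 0.0) for p in pts]


def analytic_parallel_plate(
    voltage: float,
    height: float,
    radius: float = 125e-6,
    spacing: float = 2.5e-6,
) -> FieldSolution:
    """Closed-form uniform capacitor field as a ``FieldSolution``.

    Potential drops linearly from ``voltage`` at the floor to 0 at the
    ceiling: ``|E| = voltage/height`` everywhere and ``grad(E^2) = 0``.
    Usable anywhere a solved ``FieldSolution`` is.
    """
    if height <= 0:
        raise ValueError("height must be > 0")
    nr = int(round(radius / spacing)) + 1
    nz = int(round(height / spacing)) + 1
    r = np.linspace(0.0, radius, nr)
    z = np.linspace(0.0, height, nz)
    e = voltage / height
    sol = FieldSolution(
        r=r,
        z=z,
        phi=np.tile(voltage * (1.0 - z / height), (nr, 1)),
        er=np.zeros((nr, nz)),
        ez=np.full((nr, nz), e),
        e2=np.full((nr, nz), e * e),
        ge2_r=np.zeros((nr, nz)),
        ge2_z=np.zeros((nr, nz)),
    )
    return sol


class LinearTrapField:
    """Synthetic restoring force ``F = -k (pos - center)``.

    The overdamped closed form is exponential relaxation toward the
    centre with time constant ``6 pi eta R / k``, which makes this the
    integrator's convergence oracle.
    """

    def __init__(self, stiffness: float, center: tuple[float, float, float] = (0.0, 0.0, 0.0)):
        if stiffness <= 0:
            raise ValueError("stiffness must be > 0")
        self.stiffness = stiffness
        self.center = center

    def __call__(self, x: float, y: float, z: float) -> tuple[float, float, float]:
        k = self.stiffness
        cx, cy, cz = self.center
        return (-k * (x - cx), -k * (y - cy), -k * (z - cz))

    def relaxation_time(self, cell_radius: float, viscosity: float) -> float:
        return 6.0 * math.pi * viscosity * cell_radius / self.stiffness

    def closed_form(
        self,
        initial: ParticleState,
        cell_radius: float,
        viscosity: float,
        t: float,
    ) -> ParticleState:
        """Exact overdamped trajectory point at time ``t``."""
        tau = self.relaxation_time(cell_radius, viscosity)
        decay = math.exp(-(t - initial.time) / tau)
        cx, cy, cz = self.center
        return ParticleState(
            cx + (initial.x - cx) * decay,
            cy + (initial.y - cy) * decay,
            cz + (initial.z - cz) * decay,
            t,
        )


def linear_trap_oracle(
    stiffness: float, center: tuple[float, float, float] = (0.0, 0.0, 0.0)
) -> LinearTrapField:
    """Build the linear restoring-force oracle field."""
    return LinearTrapField(stiffness, center)


def paper_defaults_path():
    """Path-like handle to the packaged default configuration file."""
    return resources.files("deptrap") / "data" / "paper_defaults.yaml"


@lru_cache(maxsize=4)
def coarse_demo_field(spacing: float = 2.0e-6) -> FieldSolution:
    """Ring-trap field pre-solved on a coarse grid, cached for fast tests.

    Same geometry and drive as the defaults (8 Vpp), just a coarser
    mesh; adequate wherever only the field topology matters.
    """
    return solve_potential(
        DeviceGeometry(),
        DriveSignal(vpp=8.0, frequency=1e7),
        GridSpec(spacing=spacing),
    )
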