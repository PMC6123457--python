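"""Declarative experiment runner for ring-trap simulations.

A :class:`TrapExperimentConfig` fully describes one simulated trapping
experiment — device geometry, AC drive, medium and cell dielectrics,
channel flow, solver grid, integration window and the seeded particle
ensemble — in human units (um, V, Hz, uL/min).  Configs are loaded from
YAML/JSON text, validated field-by-field (unknown keys are errors) and
converted to SI exactly once at load time.

``run_trap_experiment`` solves the field once, integrates every
ensemble particle, classifies outcomes and captures snapshot ensembles;
``frequency_sweep`` reuses the single field solve across frequencies,
which is exact because the DEP force factorises into a geometry term
(grad E^2, fixed) and a dielectric term (Re[f_CM], frequency-dependent).
Runs are bit-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time as _time
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from deptrap import dielectrics as dx
from deptrap.dielectrics import DielectricMedium, DriveSignal, HomogeneousCell, ShelledCell
from deptrap.field_solver import (
    DeviceGeometry,
    FieldSolution,
    GridSpec,
    solve_potential,
    write_field_csv,
)
from deptrap.synthetic import EnsembleSpec, gen_uniform_ensemble
from deptrap.transport import (
    DepForceField,
    FlowModel,
    ParticleState,
    Trajectory,
    TransportContext,
    classify_outcome,
    gravity_force,
    integrate_trajectory,
)

logger = logging.getLogger("deptrap")

UL_PER_MIN = 1e-9 / 60.0  # m^3/s per uL/min


class ConfigError(ValueError):
    """Configuration failed validation; the message names the field."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Section):
    ring_inner_radius_um: float = Field(20.0, gt=0)
    ring_outer_radius_um: float = Field(40.0, gt=0)
    counter_inner_radius_um: float = Field(60.0, gt=0)
    domain_radius_um: float = Field(125.0, gt=0)
    channel_height_um: float = Field(40.0, gt=0)
    channel_width_um: float = Field(250.0, gt=0)
    channel_length_um: float = Field(30000.0, gt=0)

    def to_si(self) -> DeviceGeometry:
        return DeviceGeometry(
            ring_inner_radius=self.ring_inner_radius_um * 1e-6,
            ring_outer_radius=self.ring_outer_radius_um * 1e-6,
            counter_inner_radius=self.counter_inner_radius_um * 1e-6,
            domain_radius=self.domain_radius_um * 1e-6,
            channel_height=self.channel_height_um * 1e-6,
            channel_width=self.channel_width_um * 1e-6,
            channel_length=self.channel_length_um * 1e-6,
        )


class DriveConfig(_Section):
    vpp: float = Field(8.0, ge=0)
    frequency_hz: float = Field(1.0e7, gt=0)

    def to_si(self) -> DriveSignal:
        return DriveSignal(vpp=self.vpp, frequency=self.frequency_hz)


class MediumConfig(_Section):
    permittivity_f_per_m: float = Field(7.1e-10, gt=0)
    conductivity_s_per_m: float = Field(1.5, ge=0)
    viscosity_pa_s: float = Field(1.0e-3, gt=0)
    density_kg_per_m3: float = Field(1000.0, gt=0)

    def to_si(self) -> DielectricMedium:
        return DielectricMedium(
            permittivity=self.permittivity_f_per_m,
            conductivity=self.conductivity_s_per_m,
            viscosity=self.viscosity_pa_s,
            density=self.density_kg_per_m3,
        )


class CellConfig(_Section):
    model: Literal["shelled", "homogeneous"] = "shelled"
    radius_um: float = Field(5.0, gt=0)
    density_kg_per_m3: float = Field(1050.0, gt=0)
    # shelled model
    membrane_thickness_nm: float = Field(5.0, gt=0)
    membrane_permittivity_f_per_m: float = Field(1.8e-12, gt=0)
    membrane_conductivity_s_per_m: float = Field(1.0e-7, ge=0)
    cytoplasm_permittivity_f_per_m: float = Field(7.1e-10, gt=0)
    cytoplasm_conductivity_s_per_m: float = Field(0.75, ge=0)
    # homogeneous model
    relative_permittivity: float = Field(80.0, gt=0)
    conductivity_s_per_m: float = Field(0.1, ge=0)

    def to_si(self) -> ShelledCell | HomogeneousCell:
        r = self.radius_um * 1e-6
        if self.model == "shelled":
            return ShelledCell(
                radius=r,
                membrane_thickness=self.membrane_thickness_nm * 1e-9,
                membrane_permittivity=self.membrane_permittivity_f_per_m,
                membrane_conductivity=self.membrane_conductivity_s_per_m,
                cytoplasm_permittivity=self.cytoplasm_permittivity_f_per_m,
                cytoplasm_conductivity=self.cytoplasm_conductivity_s_per_m,
            )
        return HomogeneousCell(
            radius=r,
            permittivity=self.relative_permittivity * dx.VACUUM_PERMITTIVITY,
            conductivity=self.conductivity_s_per_m,
        )


class FlowConfig(_Section):
    volumetric_rate_ul_min: float = Field(2.5, ge=0)
    enabled: bool = False

    def to_si(self) -> FlowModel:
        return FlowModel(
            volumetric_rate=self.volumetric_rate_ul_min * UL_PER_MIN,
            enabled=self.enabled,
        )


class GravityConfig(_Section):
    # The trap scenario mirrors a DEP-only trajectory model: over the 2 s
    # window sedimentation (~2.7 um/s for a 5 um cell at 5% density excess)
    # is negligible against DEP drift and the repelled particles rise.
    # Enable for plate-down / settling studies (drive off).
    enabled: bool = False


class GridConfig(_Section):
    spacing_um: float = Field(0.5, gt=0)
    solver_tolerance: float = Field(1e-8, gt=0)
    max_iterations: int = Field(10_000, gt=0)

    def to_si(self) -> GridSpec:
        return GridSpec(
            spacing=self.spacing_um * 1e-6,
            solver_tolerance=self.solver_tolerance,
            max_iterations=self.max_iterations,
        )


class IntegrationConfig(_Section):
    dt_s: float = Field(1.0e-4, gt=0)
    t_end_s: float = Field(2.0, gt=0)
    snapshot_times_s: list[float] = Field(default_factory=lambda: [0.3, 1.0, 2.0])
    export_stride: int = Field(100, gt=0)

    @model_validator(mode="after")
    def _snapshots_covered(self) -> "IntegrationConfig":
        if self.snapshot_times_s and max(self.snapshot_times_s) > self.t_end_s + 1e-12:
            raise ValueError("snapshot_times_s must not exceed t_end_s")
        return self


class EnsembleConfig(_Section):
    count: int = Field(50, ge=0)
    seed: int = 42
    x_um: tuple[float, float] = (-120.0, 120.0)
    y_um: tuple[float, float] = (0.0, 0.0)
    z_um: tuple[float, float] = (5.0, 35.0)

    def to_si(self) -> EnsembleSpec:
        return EnsembleSpec(
            count=self.count,
            region=(
                self.x_um[0] * 1e-6, self.x_um[1] * 1e-6,
                self.y_um[0] * 1e-6, self.y_um[1] * 1e-6,
                self.z_um[0] * 1e-6, self.z_um[1] * 1e-6,
            ),
            seed=self.seed,
        )


class TrapExperimentConfig(_Section):
    """Full declarative description of one simulated trapping experiment."""

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    drive: DriveConfig = Field(default_factory=DriveConfig)
    medium: MediumConfig = Field(default_factory=MediumConfig)
    cell: CellConfig = Field(default_factory=CellConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    gravity: GravityConfig = Field(default_factory=GravityConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    integration: IntegrationConfig = Field(default_factory=IntegrationConfig)
    ensemble: EnsembleConfig = Field(default_factory=EnsembleConfig)

    @model_validator(mode="after")
    def _cross_field(self) -> "TrapExperimentConfig":
        g = self.geometry
        if not (
            g.ring_inner_radius_um
            < g.ring_outer_radius_um
            < g.counter_inner_radius_um
            < g.domain_radius_um
        ):
            raise ValueError(
                "geometry: radii must increase ring_inner < ring_outer "
                "< counter_inner < domain"
            )
        if self.grid.spacing_um > g.ring_inner_radius_um / 4:
            raise ValueError("grid.spacing_um: must be <= ring_inner_radius_um/4")
        r = self.cell.radius_um
        z0, z1 = self.ensemble.z_um
        if z0 < r or z1 > g.channel_height_um - r:
            raise ValueError(
                "ensemble.z_um: region violates wall clearance for the cell radius"
            )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def re_fcm(self, frequency: float | None = None) -> float:
        """Re[f_CM] of the configured cell/medium at ``frequency`` (default: drive)."""
        f = self.drive.frequency_hz if frequency is None else frequency
        return dx.cm_factor_at(self.cell.to_si(), self.medium.to_si(), f).real


def _format_pydantic_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path | None = None) -> TrapExperimentConfig:
    """Load and validate a YAML/JSON experiment config.

    Missing sections take the documented defaults; an empty file (or
    ``None``) yields the all-defaults configuration.  Unknown keys and
    invariant violations raise :class:`ConfigError` naming the
    offending field.  All unit conversion to SI happens downstream of
    this single entry point.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    try:
        return TrapExperimentConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_pydantic_error(exc)) from exc


def paper_defaults() -> TrapExperimentConfig:
    """The packaged default configuration (fixture ``paper_defaults``)."""
    from importlib.resources import as_file

    from deptrap.synthetic import paper_defaults_path

    with as_file(paper_defaults_path()) as p:
        return load_config(p)


@dataclass
class TrapExperimentResult:
    """Everything one experiment run produced."""

    config: TrapExperimentConfig
    field: FieldSolution
    trajectories: list[Trajectory]
    outcomes: list[str]
    outcome_counts: dict[str, int]
    snapshots: dict[float, list[ParticleState]]
    re_fcm: float
    provenance: dict = dc_field(default_factory=dict)

    def trajectory_frame(self, stride: int | None = None) -> pd.DataFrame:
        """Long-format trajectory table ``particle_id,t_s,x_um,y_um,z_um,outcome``.

        ``stride`` thins the recorded states for export (the final state
        is always kept); default comes from the config.
        """
        stride = stride or self.config.integration.export_stride
        frames = []
        for pid, (traj, outcome) in enumerate(zip(self.trajectories, self.outcomes)):
            sel = np.arange(0, len(traj), stride)
            if sel[-1] != len(traj) - 1:
                sel = np.append(sel, len(traj) - 1)
            frames.append(
                pd.DataFrame(
                    {
                        "particle_id": pid,
                        "t_s": traj.t[sel],
                        "x_um": traj.x[sel] * 1e6,
                        "y_um": traj.y[sel] * 1e6,
                        "z_um": traj.z[sel] * 1e6,
                        "outcome": outcome,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["particle_id", "t_s", "x_um", "y_um", "z_um", "outcome"]
            )
        return pd.concat(frames, ignore_index=True)

    def snapshot_frame(self) -> pd.DataFrame:
        rows = []
        for t, states in sorted(self.snapshots.items()):
            for pid, s in enumerate(states):
                rows.append(
                    {
                        "snapshot_s": t,
                        "particle_id": pid,
                        "x_um": s.x * 1e6,
                        "y_um": s.y * 1e6,
                        "z_um": s.z * 1e6,
                    }
                )
        return pd.DataFrame(
            rows, columns=["snapshot_s", "particle_id", "x_um", "y_um", "z_um"]
        )

    def write_artifacts(self, out_dir: str | Path) -> dict:
        """Write trajectory/snapshot/field CSVs plus a checksum manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trajectories.csv": out / "trajectories.csv",
            "snapshots.csv": out / "snapshots.csv",
            "outcomes.csv": out / "outcomes.csv",
            "field.csv": out / "field.csv",
        }
        self.trajectory_frame().to_csv(
            paths["trajectories.csv"], index=False, float_format="%.10g"
        )
        self.snapshot_frame().to_csv(
            paths["snapshots.csv"], index=False, float_format="%.10g"
        )
        pd.DataFrame(
            sorted(self.outcome_counts.items()), columns=["outcome", "count"]
        ).to_csv(paths["outcomes.csv"], index=False)
        write_field_csv(self.field, paths["field.csv"])
        manifest = {
            "provenance": self.provenance,
            "files": {
                name: {
                    "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                    "bytes": p.stat().st_size,
                }
                for name, p in paths.items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _build_context(
    config: TrapExperimentConfig,
    solution: FieldSolution,
    re_fcm: float,
) -> TransportContext:
    medium = config.medium.to_si()
    geometry = config.geometry.to_si()
    radius = config.cell.radius_um * 1e-6
    grav = (
        gravity_force(radius, config.cell.density_kg_per_m3, medium.density)
        if config.gravity.enabled
        else 0.0
    )
    return TransportContext(
        force_field=DepForceField(solution, radius, medium, re_fcm),
        cell_radius=radius,
        viscosity=medium.viscosity,
        geometry=geometry,
        flow=config.flow.to_si(),
        gravity_fz=grav,
        lateral_limit=geometry.domain_radius,
    )


def simulate_particle(
    config: TrapExperimentConfig,
    solution: FieldSolution,
    initial: ParticleState,
    re_fcm: float | None = None,
) -> tuple[Trajectory, str]:
    """Integrate and classify a single particle against a solved field."""
    fcm = config.re_fcm() if re_fcm is None else re_fcm
    ctx = _build_context(config, solution, fcm)
    integ = config.integration
    traj = integrate_trajectory(
        initial, ctx, t_end=integ.t_end_s, dt=integ.dt_s,
        snapshot_times=integ.snapshot_times_s,
    )
    outcome = traj.outcome or classify_outcome(
        traj,
        ctx.geometry,
        field_on=config.drive.vpp > 0,
        cell_radius=ctx.cell_radius,
    )
    return traj, outcome


def run_trap_experiment(
    config: TrapExperimentConfig,
    solution: FieldSolution | None = None,
    re_fcm: float | None = None,
) -> TrapExperimentResult:
    """Run one full ensemble experiment.

    Solves the field once (or reuses ``solution``), integrates every
    ensemble particle, classifies outcomes and collects the snapshot
    ensembles.  Deterministic for a fixed config: the ensemble seed is
    part of the config.
    """
    t0 = _time.perf_counter()
    geometry = config.geometry.to_si()
    drive = config.drive.to_si()
    if solution is None:
        solution = solve_potential(geometry, drive, config.grid.to_si())
    fcm = config.re_fcm() if re_fcm is None else re_fcm

    states = gen_uniform_ensemble(
        config.ensemble.to_si(), geometry, config.cell.radius_um * 1e-6
    )
    trajectories: list[Trajectory] = []
    outcomes: list[str] = []
    for pid, s in enumerate(states):
        try:
            traj, outcome = simulate_particle(config, solution, s, re_fcm=fcm)
        except Exception as exc:  # re-raise with particle context
            raise RuntimeError(f"particle {pid} failed: {exc}") from exc
        trajectories.append(traj)
        outcomes.append(outcome)

    counts: dict[str, int] = {}
    for o in outcomes:
        counts[o] = counts.get(o, 0) + 1

    snapshots: dict[float, list[ParticleState]] = {}
    for t in config.integration.snapshot_times_s:
        snapshots[t] = [traj.snapshot(t) for traj in trajectories]

    from deptrap import __version__

    provenance = {
        "config_sha256": config.config_hash(),
        "seed": config.ensemble.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": __version__,
        "re_fcm": fcm,
        "solver_residual": solution.residual,
        "wall_time_s": round(_time.perf_counter() - t0, 3),
    }
    logger.info(
        "run_trap_experiment: hash=%s seed=%d re_fcm=%.4f particles=%d "
        "residual=%.2e wall=%.2fs",
        provenance["config_sha256"][:12], provenance["seed"], fcm,
        len(states), solution.residual, provenance["wall_time_s"],
    )
    return TrapExperimentResult(
        config=config,
        field=solution,
        trajectories=trajectories,
        outcomes=outcomes,
        outcome_counts=counts,
        snapshots=snapshots,
        re_fcm=fcm,
        provenance=provenance,
    )


def frequency_sweep(
    config: TrapExperimentConfig, frequencies: Sequence[float]
) -> pd.DataFrame:
    """Run the ensemble experiment at each frequency, sharing one field solve.

    The geometry-dependent ``grad E^2`` field is voltage- and
    geometry-fixed across the sweep, so only the dielectric factor
    Re[f_CM] changes: the DEP force factorises exactly.  Each row holds
    ``frequency_hz, re_fcm, trapped_count, repelled_count`` plus the
    remaining outcome counts; the ensemble seed is shared, so rows are
    directly comparable.
    """
    if not len(frequencies):
        raise ValueError("frequency list must be non-empty")
    solution = solve_potential(
        config.geometry.to_si(), config.drive.to_si(), config.grid.to_si()
    )
    rows = []
    for f in frequencies:
        fcm = config.re_fcm(f)
        result = run_trap_experiment(config, solution=solution, re_fcm=fcm)
        rows.append(
            {
                "frequency_hz": float(f),
                "re_fcm": fcm,
                "trapped_count": result.outcome_counts.get("trapped", 0),
                "repelled_count": result.outcome_counts.get("repelled", 0),
                "advected_count": result.outcome_counts.get("advected", 0),
                "settled_count": result.outcome_counts.get("settled", 0),
            }
        )
    return pd.DataFrame(rows)
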