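"""Overdamped particle transport in the trap channel.

At the micron scale the particle Reynolds and Stokes numbers are tiny
(Re_p ~ 1e-2, momentum relaxation ~ 1e-5 s for a 5 um cell in water), so
inertia is neglected and velocity balances force through Stokes drag:

    dx/dt = u_flow(z) x_hat + (F_DEP + F_gravity) / (6 pi eta R).

The imposed flow is plane-Poiseuille between the channel floor and
ceiling (the channel is much wider than tall); gravity enters as the
buoyancy-corrected weight, which is what lets a trapped, levitating cell
plate down onto the substrate once the field is switched off.
Trajectories are integrated with a fixed-step classical 4th-order
Runge-Kutta scheme; the floor and ceiling are treated as hard walls for
the particle centre (normal velocity is absorbed, sliding is allowed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from deptrap.dielectrics import DielectricMedium
from deptrap.field_solver import (
    DeviceGeometry,
    FieldSolution,
    dep_force_prefactor,
    field_and_gradients,
)

STANDARD_GRAVITY = 9.81  # m/s^2

Outcome = str  # "trapped" | "repelled" | "advected" | "settled"


@dataclass(frozen=True)
class FlowModel:
    """Imposed channel flow (volumetric rate in m^3/s)."""

    volumetric_rate: float = 2.5e-9 / 60.0  # 2.5 uL/min
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.volumetric_rate < 0:
            raise ValueError("volumetric_rate must be >= 0")


@dataclass(frozen=True)
class ParticleState:
    """Particle centre position (m) and time (s).

    ``x`` runs along the flow, ``y`` across it, ``z`` up from the
    electrode plane; the trap axis is at x = y = 0.
    """

    x: float
    y: float
    z: float
    time: float = 0.0

    @property
    def lateral_distance(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass
class Trajectory:
    """Time-stamped particle states with snapshot extraction."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    snapshot_times: tuple[float, ...] = ()
    outcome: Outcome | None = None
    exited: bool = False

    def __post_init__(self) -> None:
        if len(self.t) == 0:
            raise ValueError("trajectory must contain at least one state")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> ParticleState:
        return ParticleState(
            float(self.x[i]), float(self.y[i]), float(self.z[i]), float(self.t[i])
        )

    @property
    def initial(self) -> ParticleState:
        return self.state(0)

    @property
    def final(self) -> ParticleState:
        return self.state(len(self.t) - 1)

    def snapshot(self, time: float) -> ParticleState:
        """State recorded at the snapshot time closest to ``time``."""
        i = int(np.argmin(np.abs(self.t - time)))
        return self.state(i)

    @property
    def final_speed(self) -> float:
        """Speed over the last recorded step (0 for a single-state trajectory)."""
        if len(self.t) < 2:
            return 0.0
        dt = float(self.t[-1] - self.t[-2])
        return (
            math.hypot(
                float(self.x[-1] - self.x[-2]),
                float(self.y[-1] - self.y[-2]),
            )
            ** 2
            + float(self.z[-1] - self.z[-2]) ** 2
        ) ** 0.5 / dt


def flow_velocity(z: float, flow: FlowModel, geometry: DeviceGeometry) -> float:
    """Plane-Poiseuille axial velocity u(z) = 6 u_mean (z/h)(1 - z/h).

    ``u_mean = Q / (h w)``; no-slip at floor and ceiling.  ``z`` must
    lie within the channel.
    """
    h = geometry.channel_height
    if not 0.0 <= z <= h:
        raise ValueError(f"z={z:g} outside channel [0, {h:g}]")
    if not flow.enabled or flow.volumetric_rate == 0.0:
        return 0.0
    u_mean = flow.volumetric_rate / (h * geometry.channel_width)
    zh = z / h
    return 6.0 * u_mean * zh * (1.0 - zh)


def drift_velocity(force: np.ndarray, cell_radius: float, viscosity: float) -> np.ndarray:
    """Terminal velocity of a Stokes sphere: v = F / (6 pi eta R)."""
    if cell_radius <= 0 or viscosity <= 0:
        raise ValueError("cell_radius and viscosity must be > 0")
    return np.asarray(force, dtype=float) / (6.0 * math.pi * viscosity * cell_radius)


def gravity_force(
    cell_radius: float, cell_density: float, medium_density: float
) -> float:
    """Buoyancy-corrected weight, signed along z (N): negative = sinking."""
    if cell_radius <= 0:
        raise ValueError("cell_radius must be > 0")
    return (
        -(4.0 / 3.0)
        * math.pi
        * cell_radius**3
        * (cell_density - medium_density)
        * STANDARD_GRAVITY
    )


class DepForceField:
    """DEP force field over 3-D positions, backed by an axisymmetric solve.

    Maps (x, y, z) to the force ``2 pi R^3 eps_m Re[f_CM] grad(E_rms^2)``
    evaluated at (rho, z) with rho the distance from the trap axis; the
    azimuthal component is zero by symmetry.  Sampling is bilinear on the
    solver grid; beyond the solved radial extent the field is taken as
    zero (far field).
    """

    def __init__(
        self,
        solution: FieldSolution,
        cell_radius: float,
        medium: DielectricMedium,
        re_fcm: float,
    ) -> None:
        if solution.ge2_r is None:
            field_and_gradients(solution)
        self.solution = solution
        self.prefactor = dep_force_prefactor(cell_radius, medium, re_fcm)
        self._gr = solution.ge2_r
        self._gz = solution.ge2_z
        self._e2 = solution.e2
        self._r0 = float(solution.r[0])
        self._z0 = float(solution.z[0])
        self._inv_h = 1.0 / solution.spacing
        self._nr = len(solution.r)
        self._nz = len(solution.z)
        self._r_max = float(solution.r[-1])
        self._z_max = float(solution.z[-1])

    def _weights(self, rho: float, z: float):
        fi = (rho - self._r0) * self._inv_h
        fj = (z - self._z0) * self._inv_h
        i = int(fi)
        j = int(fj)
        if i > self._nr - 2:
            i = self._nr - 2
        if j > self._nz - 2:
            j = self._nz - 2
        return i, j, fi - i, fj - j

    def _sample(self, arr: np.ndarray, rho: float, z: float) -> float:
        i, j, tr, tz = self._weights(rho, z)
        return (
            arr[i, j] * (1.0 - tr) * (1.0 - tz)
            + arr[i + 1, j] * tr * (1.0 - tz)
            + arr[i, j + 1] * (1.0 - tr) * tz
            + arr[i + 1, j + 1] * tr * tz
        )

    def e2_at(self, x: float, y: float, z: float) -> float:
        """E_rms^2 at a 3-D position (0 outside the solved extent)."""
        rho = math.hypot(x, y)
        if rho > self._r_max:
            return 0.0
        z = min(max(z, self._z0), self._z_max)
        return float(self._sample(self._e2, rho, z))

    def __call__(self, x: float, y: float, z: float) -> tuple[float, float, float]:
        rho = math.hypot(x, y)
        if rho > self._r_max:
            return (0.0, 0.0, 0.0)
        z = min(max(z, self._z0), self._z_max)
        i, j, tr, tz = self._weights(rho, z)
        w00 = (1.0 - tr) * (1.0 - tz)
        w10 = tr * (1.0 - tz)
        w01 = (1.0 - tr) * tz
        w11 = tr * tz
        gr = self._gr
        gz = self._gz
        g_r = (
            gr[i, j] * w00 + gr[i + 1, j] * w10
            + gr[i, j + 1] * w01 + gr[i + 1, j + 1] * w11
        )
        g_z = (
            gz[i, j] * w00 + gz[i + 1, j] * w10
            + gz[i, j + 1] * w01 + gz[i + 1, j + 1] * w11
        )
        f_r = self.prefactor * g_r
        f_z = self.prefactor * g_z
        if rho > 0.0:
            c = x / rho
            s = y / rho
            return (f_r * c, f_r * s, f_z)
        return (0.0, 0.0, f_z)


@dataclass
class TransportContext:
    """Everything the integrator needs besides the initial state.

    ``force_field`` maps (x, y, z) in metres to a force tuple in
    newtons; ``gravity_fz`` is a constant vertical force (N) added to
    it.  ``lateral_limit`` (m) is the radial extent beyond which a
    particle counts as having left the modelled domain; ``None``
    disables the check (oracle problems).
    """

    force_field: Callable[[float, float, float], tuple[float, float, float]]
    cell_radius: float
    viscosity: float
    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    flow: FlowModel | None = None
    gravity_fz: float = 0.0
    lateral_limit: float | None = None


def integrate_trajectory(
    initial: ParticleState,
    context: TransportContext,
    t_end: float,
    dt: float,
    snapshot_times: Sequence[float] = (),
) -> Trajectory:
    """Integrate one overdamped trajectory with fixed-step classical RK4.

    Every step is recorded.  The particle centre is confined to
    ``R <= z <= channel_height - R`` (wall-normal velocity is absorbed
    at contact; sliding is free).  A step carrying the particle beyond
    ``lateral_limit`` truncates the trajectory and pre-labels its
    outcome ``advected``.  Snapshot times must coincide with recorded
    times (multiples of ``dt``) to within half a step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if snapshot_times and t_end < max(snapshot_times) - 1e-12:
        raise ValueError("t_end must cover every snapshot time")

    geom = context.geometry
    radius = context.cell_radius
    z_lo = radius
    z_hi = geom.channel_height - radius
    if not z_lo <= initial.z <= z_hi:
        raise ValueError("initial z violates the wall-clearance invariant")

    mobility = 1.0 / (6.0 * math.pi * context.viscosity * radius)
    force = context.force_field
    grav = context.gravity_fz
    flow = context.flow
    h = geom.channel_height
    if flow is not None and flow.enabled and flow.volumetric_rate > 0.0:
        u6 = 6.0 * flow.volumetric_rate / (h * geom.channel_width)
    else:
        u6 = 0.0

    def velocity(x: float, y: float, z: float) -> tuple[float, float, float]:
        ze = z_lo if z < z_lo else (z_hi if z > z_hi else z)
        fx, fy, fz = force(x, y, ze)
        vx = fx * mobility
        if u6:
            zh = ze / h
            vx += u6 * zh * (1.0 - zh)
        return (vx, fy * mobility, (fz + grav) * mobility)

    n_steps = int(round((t_end - initial.time) / dt))
    ts = np.empty(n_steps + 1)
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    zs = np.empty(n_steps + 1)
    ts[0], xs[0], ys[0], zs[0] = initial.time, initial.x, initial.y, initial.z

    x, y, z = initial.x, initial.y, initial.z
    t = initial.time
    half = 0.5 * dt
    sixth = dt / 6.0
    limit = context.lateral_limit
    exited = False
    n_rec = n_steps + 1

    for k in range(1, n_steps + 1):
        k1 = velocity(x, y, z)
        k2 = velocity(x + half * k1[0], y + half * k1[1], z + half * k1[2])
        k3 = velocity(x + half * k2[0], y + half * k2[1], z + half * k2[2])
        k4 = velocity(x + dt * k3[0], y + dt * k3[1], z + dt * k3[2])
        x += sixth * (k1[0] + 2.0 * (k2[0] + k3[0]) + k4[0])
        y += sixth * (k1[1] + 2.0 * (k2[1] + k3[1]) + k4[1])
        z += sixth * (k1[2] + 2.0 * (k2[2] + k3[2]) + k4[2])
        # hard walls: absorb the normal velocity component, allow sliding
        if z < z_lo:
            z = z_lo
        elif z > z_hi:
            z = z_hi
        t = initial.time + k * dt
        ts[k], xs[k], ys[k], zs[k] = t, x, y, z
        if limit is not None and math.hypot(x, y) > limit:
            exited = True
            n_rec = k + 1
            break

    snaps = []
    for s in snapshot_times:
        i = int(round((s - initial.time) / dt))
        if i >= n_rec or abs(ts[i] - s) > 0.5 * dt:
            continue  # truncated before this snapshot
        snaps.append(float(ts[i]))

    traj = Trajectory(
        t=ts[:n_rec],
        x=xs[:n_rec],
        y=ys[:n_rec],
        z=zs[:n_rec],
        snapshot_times=tuple(snaps),
        exited=exited,
    )
    if exited:
        traj.outcome = "advected"
    return traj


def classify_outcome(
    trajectory: Trajectory,
    geometry: DeviceGeometry,
    field_on: bool = True,
    cell_radius: float = 5e-6,
    trapped_speed: float = 1e-6,
    repelled_rise: float = 5e-6,
) -> Outcome:
    """Label a trajectory ``trapped``, ``advected``, ``repelled`` or ``settled``.

    Precedence: trapped > advected > repelled > settled.

    * trapped — field on, ends within the ring interior (lateral
      distance below the ring inner radius) at speed below
      ``trapped_speed``;
    * advected — left the modelled domain downstream;
    * repelled — ends at least ``repelled_rise`` above its start while
      laterally outside the ring;
    * settled — resting on the channel floor with the field off.

    A trajectory matching none of the rules is still labelled by its
    tendency: rising -> repelled, floor contact -> settled, otherwise
    advected.
    """
    final = trajectory.final
    lateral = final.lateral_distance
    if (
        field_on
        and lateral < geometry.ring_inner_radius
        and trajectory.final_speed < trapped_speed
    ):
        return "trapped"
    if trajectory.exited:
        return "advected"
    if (
        final.z - trajectory.initial.z > repelled_rise
        and lateral >= geometry.ring_outer_radius
    ):
        return "repelled"
    at_floor = final.z <= cell_radius * (1.0 + 1e-9)
    if at_floor and not field_on:
        return "settled"
    if final.z > trajectory.initial.z:
        return "repelled"
    return "settled" if at_floor else "advected"
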