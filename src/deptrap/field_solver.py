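"""Electro-quasistatic field of the ring-shaped trap electrode.

The trap is a planar annular electrode (driven at +Vrms) surrounded,
beyond an insulating gap, by a grounded counter plane, all at the floor
of a shallow microfluidic channel.  Because the electrode is a ring, the
potential is modelled as cylindrically symmetric and solved on a uniform
(r, z) grid from the axisymmetric Laplace equation

    (1/r) d/dr (r dphi/dr) + d2phi/dz2 = 0

with Dirichlet values on the electrode strips at z = 0, homogeneous
Neumann (electrical insulation) on every other boundary, and the
regularised stencil dphi/dr = 0 on the symmetry axis r = 0.  The
discretisation is the standard second-order 5-point stencil; the sparse
system is solved directly.

The potential is stored at its rms amplitude, so the derived field
``E = -grad phi`` is E_rms and ``e2 = |E_rms|^2`` feeds straight into the
time-averaged DEP force

    F_DEP = 2 pi R^3 eps_m Re[f_CM] grad(E_rms^2).

Under nDEP (Re[f_CM] < 0) the force points down the gradient of E^2: the
field minimum at the ring centre is the trap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from deptrap.dielectrics import DielectricMedium, DriveSignal


class SolverError(RuntimeError):
    """Raised when the linear solve fails to reach the requested residual."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Ring-trap and channel dimensions (SI).

    Defaults describe a trap with 40 um internal diameter, 20 um
    electrode width and a 20 um gap to the grounded counter plane, in a
    40 um x 250 um x 3 cm channel.  The axisymmetric solve domain spans
    half the channel width; a single ring is modelled (neighbouring
    traps in the array are far enough apart that cross-coupling is
    neglected).
    """

    ring_inner_radius: float = 20e-6
    ring_outer_radius: float = 40e-6
    counter_inner_radius: float = 60e-6
    domain_radius: float = 125e-6
    channel_height: float = 40e-6
    channel_width: float = 250e-6
    channel_length: float = 3e-2

    def __post_init__(self) -> None:
        ok = (
            0
            < self.ring_inner_radius
            < self.ring_outer_radius
            < self.counter_inner_radius
            < self.domain_radius
        )
        if not ok:
            raise ValueError(
                "geometry must satisfy 0 < ring_inner < ring_outer "
                "< counter_inner < domain_radius"
            )
        if self.channel_height <= 0:
            raise ValueError("channel_height must be > 0")


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid spacing and linear-solver controls."""

    spacing: float = 0.5e-6
    solver_tolerance: float = 1e-8
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be > 0")


@dataclass
class FieldSolution:
    """Discretised potential and derived DEP drive fields on an (r, z) grid.

    ``phi`` holds the rms potential amplitude; ``er``/``ez`` the rms
    field components; ``e2 = er^2 + ez^2``; ``ge2_r``/``ge2_z`` the
    gradient of ``e2``.  Arrays are indexed ``[i_r, i_z]``.
    """

    r: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    geometry: DeviceGeometry | None = None
    drive: DriveSignal | None = None
    grid: GridSpec | None = None
    residual: float = 0.0
    er: np.ndarray | None = None
    ez: np.ndarray | None = None
    e2: np.ndarray | None = None
    ge2_r: np.ndarray | None = None
    ge2_z: np.ndarray | None = None
    _ge2_stack: np.ndarray | None = field(default=None, repr=False)

    @property
    def spacing(self) -> float:
        return float(self.r[1] - self.r[0])

    def contains(self, r: float, z: float) -> bool:
        return (
            self.r[0] <= r <= self.r[-1] and self.z[0] <= z <= self.z[-1]
        )


def _bilinear(axis_r: np.ndarray, axis_z: np.ndarray, arr: np.ndarray,
              r: float, z: float) -> float:
    """Textbook bilinear interpolation on a uniform grid, exact at nodes."""
    hr = axis_r[1] - axis_r[0]
    hz = axis_z[1] - axis_z[0]
    fi = (r - axis_r[0]) / hr
    fj = (z - axis_z[0]) / hz
    i = min(int(fi), arr.shape[0] - 2)
    j = min(int(fj), arr.shape[1] - 2)
    tr = fi - i
    tz = fj - j
    return float(
        arr[i, j] * (1 - tr) * (1 - tz)
        + arr[i + 1, j] * tr * (1 - tz)
        + arr[i, j + 1] * (1 - tr) * tz
        + arr[i + 1, j + 1] * tr * tz
    )


def solve_axisymmetric_laplace(
    r: np.ndarray,
    z: np.ndarray,
    dirichlet_mask: np.ndarray,
    dirichlet_values: np.ndarray,
    tolerance: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Solve the axisymmetric Laplace equation on a uniform (r, z) grid.

    Nodes flagged in ``dirichlet_mask`` are pinned to
    ``dirichlet_values``; all other boundary nodes get homogeneous
    Neumann (mirror-ghost) closure, and the r = 0 axis uses the
    regularised stencil (4/h^2 toward the first off-axis node).

    Returns ``(phi, relative_residual)``.  This low-level entry point is
    also the hook for solving oracle problems with custom boundary data.
    """
    nr, nz = len(r), len(z)
    h = float(r[1] - r[0])
    if not math.isclose(float(z[1] - z[0]), h, rel_tol=1e-9):
        raise ValueError("grid must be uniform with equal r and z spacing")
    n = nr * nz
    # PDE rows are scaled by h^2 so all matrix coefficients are O(1);
    # the residual check is then meaningful relative to the Dirichlet data.
    inv_h2 = 1.0

    idx = np.arange(n).reshape(nr, nz)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(n)

    dir_flat = dirichlet_mask.reshape(-1)
    val_flat = dirichlet_values.reshape(-1)

    # Dirichlet rows: identity
    d = np.nonzero(dir_flat)[0]
    rows.append(d)
    cols.append(d)
    vals.append(np.ones(d.size))
    rhs[d] = val_flat[d]

    # Free rows, assembled by neighbour direction with Neumann mirroring.
    free = ~dirichlet_mask
    ii, jj = np.nonzero(free)
    centre = idx[ii, jj]

    diag = np.zeros(centre.size)

    # r-direction
    on_axis = ii == 0
    # axis nodes: regularised stencil 4*(phi_1 - phi_0)/h^2
    a = np.nonzero(on_axis)[0]
    if a.size:
        rows.append(centre[a])
        cols.append(idx[1, jj[a]])
        vals.append(np.full(a.size, 4.0 * inv_h2))
        diag[a] -= 4.0 * inv_h2
    off = np.nonzero(~on_axis)[0]
    if off.size:
        ri = r[ii[off]]
        c_plus = (1.0 + h / (2.0 * ri)) * inv_h2
        c_minus = (1.0 - h / (2.0 * ri)) * inv_h2
        at_rmax = ii[off] == nr - 1
        # inner neighbour always exists
        rows.append(centre[off])
        cols.append(idx[ii[off] - 1, jj[off]])
        # at r = rmax the ghost outer node mirrors the inner one
        vals.append(np.where(at_rmax, c_minus + c_plus, c_minus))
        inner = np.nonzero(~at_rmax)[0]
        rows.append(centre[off[inner]])
        cols.append(idx[ii[off[inner]] + 1, jj[off[inner]]])
        vals.append(c_plus[inner])
        diag[off] -= c_plus + c_minus

    # z-direction
    at_z0 = jj == 0
    at_zmax = jj == nz - 1
    mid = ~(at_z0 | at_zmax)
    for sel, lo_c, hi_c in (
        (np.nonzero(mid)[0], inv_h2, inv_h2),
        (np.nonzero(at_z0)[0], 0.0, 2.0 * inv_h2),
        (np.nonzero(at_zmax)[0], 2.0 * inv_h2, 0.0),
    ):
        if not sel.size:
            continue
        if lo_c:
            rows.append(centre[sel])
            cols.append(idx[ii[sel], jj[sel] - 1])
            vals.append(np.full(sel.size, lo_c))
        if hi_c:
            rows.append(centre[sel])
            cols.append(idx[ii[sel], jj[sel] + 1])
            vals.append(np.full(sel.size, hi_c))
        diag[sel] -= 2.0 * inv_h2

    rows.append(centre)
    cols.append(centre)
    vals.append(diag)

    a_mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    phi = spsolve(a_mat.tocsc(), rhs)
    scale = max(np.abs(rhs).max(), 1.0)
    residual = float(np.linalg.norm(a_mat @ phi - rhs, ord=np.inf) / scale)
    if residual > tolerance:
        raise SolverError(
            f"linear solve did not reach tolerance {tolerance:g}; "
            f"final relative residual {residual:g}"
        )
    return phi.reshape(nr, nz), residual


def _grid_axes(geometry: DeviceGeometry, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    h = grid.spacing
    if h > geometry.ring_inner_radius / 4:
        raise ValueError(
            "grid spacing must be <= ring_inner_radius/4 to resolve the trap"
        )
    # axes are built from whole cells at the exact spacing; the domain
    # extents snap to the nearest multiple of h (the outer rim and the
    # ceiling are far from the trap, so a fraction of a cell is immaterial)
    nr = max(int(round(geometry.domain_radius / h)), 1)
    nz = max(int(round(geometry.channel_height / h)), 1)
    r = h * np.arange(nr + 1)
    z = h * np.arange(nz + 1)
    return r, z


def solve_potential(
    geometry: DeviceGeometry,
    drive: DriveSignal,
    grid: GridSpec,
    layout: str = "ring",
    ring_potential: float | None = None,
    counter_potential: float = 0.0,
    compute_gradients: bool = True,
) -> FieldSolution:
    """Solve the trap potential and (by default) its DEP drive fields.

    ``layout="ring"`` pins the ring annulus at z = 0 to the drive's rms
    amplitude (override with ``ring_potential``) and the counter plane
    (r >= counter_inner_radius, z = 0) to ``counter_potential``; the
    inner disc, the gap, the channel ceiling, the outer rim and the
    symmetry axis are insulating.  ``layout="parallel_plate"`` instead
    pins the whole floor to Vrms and the whole ceiling to 0 — the
    closed-form capacitor field used as a solver oracle.
    """
    r, z = _grid_axes(geometry, grid)
    v_hi = drive.vrms if ring_potential is None else ring_potential
    mask = np.zeros((len(r), len(z)), dtype=bool)
    values = np.zeros_like(mask, dtype=float)

    if layout == "ring":
        on_ring = (r >= geometry.ring_inner_radius - 1e-15) & (
            r <= geometry.ring_outer_radius + 1e-15
        )
        on_counter = r >= geometry.counter_inner_radius - 1e-15
        mask[on_ring, 0] = True
        values[on_ring, 0] = v_hi
        mask[on_counter, 0] = True
        values[on_counter, 0] = counter_potential
    elif layout == "parallel_plate":
        mask[:, 0] = True
        values[:, 0] = v_hi
        mask[:, -1] = True
        values[:, -1] = counter_potential
    else:
        raise ValueError(f"unknown electrode layout: {layout!r}")

    phi, residual = solve_axisymmetric_laplace(
        r, z, mask, values, tolerance=grid.solver_tolerance
    )
    sol = FieldSolution(
        r=r, z=z, phi=phi, geometry=geometry, drive=drive, grid=grid,
        residual=residual,
    )
    return field_and_gradients(sol) if compute_gradients else sol


def field_and_gradients(solution: FieldSolution) -> FieldSolution:
    """Populate E = -grad(phi), e2 = |E|^2 and grad(e2) on the grid.

    Gradients are central differences in the interior and one-sided at
    the boundaries (``numpy.gradient``).  Returns the same solution
    object with the derived fields filled in.
    """
    dphi_dr, dphi_dz = np.gradient(
        solution.phi, solution.r, solution.z, edge_order=2
    )
    solution.er = -dphi_dr
    solution.ez = -dphi_dz
    solution.e2 = solution.er**2 + solution.ez**2
    ge2_r, ge2_z = np.gradient(
        solution.e2, solution.r, solution.z, edge_order=2
    )
    solution.ge2_r = ge2_r
    solution.ge2_z = ge2_z
    solution._ge2_stack = np.stack([ge2_r, ge2_z])
    return solution


def sample_field(
    solution: FieldSolution, point: tuple[float, float]
) -> tuple[float, np.ndarray]:
    """Bilinearly interpolate ``(e2, grad e2)`` at an (r, z) point (m).

    Exact at grid nodes; raises ``ValueError`` outside the solved
    domain.
    """
    r, z = point
    if not solution.contains(r, z):
        raise ValueError(f"point (r={r:g}, z={z:g}) is outside the solved domain")
    if solution.e2 is None:
        field_and_gradients(solution)
    e2 = _bilinear(solution.r, solution.z, solution.e2, r, z)
    g = np.array(
        [
            _bilinear(solution.r, solution.z, solution.ge2_r, r, z),
            _bilinear(solution.r, solution.z, solution.ge2_z, r, z),
        ]
    )
    return e2, g


def dep_force_at(
    point: tuple[float, float],
    cell_radius: float,
    medium: DielectricMedium,
    re_fcm: float,
    solution: FieldSolution,
) -> np.ndarray:
    """Time-averaged DEP force (N) on a sphere at an (r, z) point.

    ``F = 2 pi R^3 eps_m Re[f_CM] grad(E_rms^2)``: antiparallel to the
    gradient of E^2 in the nDEP regime (``re_fcm < 0``).
    """
    _, g = sample_field(solution, point)
    return 2.0 * math.pi * cell_radius**3 * medium.permittivity * re_fcm * g


def dep_force_prefactor(
    cell_radius: float, medium: DielectricMedium, re_fcm: float
) -> float:
    """Scalar ``2 pi R^3 eps_m Re[f_CM]`` multiplying grad(E^2) in the force."""
    return 2.0 * math.pi * cell_radius**3 * medium.permittivity * re_fcm


def write_field_csv(solution: FieldSolution, path) -> None:
    """Export the solution as CSV rows ``r_um,z_um,phi_v,er_vpm,ez_vpm,e2,ge2_r,ge2_z``."""
    if solution.e2 is None:
        field_and_gradients(solution)
    rr, zz = np.meshgrid(solution.r, solution.z, indexing="ij")
    cols = np.column_stack(
        [
            rr.ravel() * 1e6,
            zz.ravel() * 1e6,
            solution.phi.ravel(),
            solution.er.ravel(),
            solution.ez.ravel(),
            solution.e2.ravel(),
            solution.ge2_r.ravel(),
            solution.ge2_z.ravel(),
        ]
    )
    header = "r_um,z_um,phi_v,er_vpm,ez_vpm,e2,ge2_r,ge2_z"
    np.savetxt(path, cols, delimiter=",", header=header, comments="", fmt="%.10g")
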