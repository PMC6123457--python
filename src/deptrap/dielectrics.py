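"""Frequency-domain dielectric response of cells in suspension.

A polarizable sphere in a non-uniform AC field experiences a
dielectrophoretic force whose sign and magnitude are set by the real part
of the Clausius–Mossotti (CM) factor

    f_CM(w) = (e*_p - e*_m) / (e*_p + 2 e*_m),

with complex permittivities ``e* = e - j s/w`` combining the dielectric
(``e``, F/m) and conductive (``s``, S/m) response at angular frequency
``w``.  ``Re[f_CM]`` is bounded in ``[-0.5, 1]`` for physical inputs; a
negative value (particle less polarizable than the medium) drives the
particle toward field-intensity minima (negative DEP, nDEP), the regime
used to hold live cells in high-conductivity culture media.

Cells are modelled either as homogeneous dielectric spheres or via the
standard single-shell reduction: a conductive cytoplasm sphere coated by
a thin, poorly conducting membrane, collapsed to an equivalent
homogeneous sphere before the CM factor is evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class DielectricMedium:
    """Suspending fluid: dielectric, conductive and hydrodynamic properties.

    Parameters
    ----------
    permittivity:
        Absolute permittivity (F/m).
    conductivity:
        Electrical conductivity (S/m).
    viscosity:
        Dynamic viscosity (Pa s); used by the transport module.
    density:
        Mass density (kg/m^3); used by the transport module.
    """

    permittivity: float
    conductivity: float
    viscosity: float = 1.0e-3
    density: float = 1000.0

    def __post_init__(self) -> None:
        _require(self.permittivity > 0, "medium permittivity must be > 0")
        _require(self.conductivity >= 0, "medium conductivity must be >= 0")
        _require(self.viscosity > 0, "medium viscosity must be > 0")
        _require(self.density > 0, "medium density must be > 0")


@dataclass(frozen=True)
class HomogeneousCell:
    """Homogeneous dielectric sphere of radius ``radius`` (m)."""

    radius: float
    permittivity: float  # absolute, F/m
    conductivity: float  # S/m

    def __post_init__(self) -> None:
        _require(self.radius > 0, "cell radius must be > 0")
        _require(self.permittivity > 0, "cell permittivity must be > 0")
        _require(self.conductivity >= 0, "cell conductivity must be >= 0")


@dataclass(frozen=True)
class ShelledCell:
    """Single-shell cell: cytoplasm sphere coated by a thin membrane.

    ``radius`` is the outer radius including the membrane.  Membrane
    thickness is not a quantity that optical measurements of cell size
    provide; the default used elsewhere in the package is 5 nm, typical
    of a lipid bilayer.
    """

    radius: float
    membrane_thickness: float
    membrane_permittivity: float
    membrane_conductivity: float
    cytoplasm_permittivity: float
    cytoplasm_conductivity: float

    def __post_init__(self) -> None:
        _require(self.radius > 0, "cell radius must be > 0")
        _require(
            0 < self.membrane_thickness < self.radius,
            "membrane thickness must satisfy 0 < d < radius",
        )
        _require(self.membrane_permittivity > 0, "membrane permittivity must be > 0")
        _require(self.membrane_conductivity >= 0, "membrane conductivity must be >= 0")
        _require(self.cytoplasm_permittivity > 0, "cytoplasm permittivity must be > 0")
        _require(self.cytoplasm_conductivity >= 0, "cytoplasm conductivity must be >= 0")


Cell = Union[HomogeneousCell, ShelledCell]


@dataclass(frozen=True)
class DriveSignal:
    """Sinusoidal AC drive, specified peak-to-peak.

    ``amplitude = vpp/2``, ``vrms = vpp/(2*sqrt(2))`` and
    ``angular_frequency = 2*pi*frequency``.
    """

    vpp: float
    frequency: float

    def __post_init__(self) -> None:
        _require(self.vpp >= 0, "vpp must be >= 0")
        _require(self.frequency > 0, "frequency must be > 0")

    @property
    def amplitude(self) -> float:
        return self.vpp / 2.0

    @property
    def vrms(self) -> float:
        return self.vpp / (2.0 * math.sqrt(2.0))

    @property
    def angular_frequency(self) -> float:
        return 2.0 * math.pi * self.frequency


def complex_permittivity(
    permittivity: float, conductivity: float, angular_frequency: float
) -> complex:
    """Complex permittivity ``e* = e - j s/w`` (F/m).

    Parameters are the absolute permittivity (F/m), conductivity (S/m)
    and angular frequency (rad/s, must be positive).
    """
    if np.any(np.asarray(angular_frequency) <= 0):
        raise ValueError("angular_frequency must be > 0")
    return permittivity - 1j * conductivity / angular_frequency


def cm_factor(particle_eps_star: complex, medium_eps_star: complex) -> complex:
    """Clausius–Mossotti factor ``(e*_p - e*_m) / (e*_p + 2 e*_m)``.

    The real part lies in ``[-0.5, 1]`` for physical inputs and sets the
    DEP direction: positive toward field maxima (pDEP), negative toward
    minima (nDEP).
    """
    denom = particle_eps_star + 2.0 * medium_eps_star
    if np.any(np.abs(np.asarray(denom)) == 0):
        raise ZeroDivisionError("CM factor undefined: e*_p + 2 e*_m vanishes")
    return (particle_eps_star - medium_eps_star) / denom


def effective_cell_permittivity(cell: ShelledCell, angular_frequency: float) -> complex:
    """Equivalent homogeneous complex permittivity of a single-shell cell.

    The cytoplasm sphere (radius ``R - d``) coated by the membrane shell
    is replaced by one homogeneous sphere of radius ``R`` with

        e*_eff = e*_mem * (g^3 + 2 K) / (g^3 - K),
        g = R / (R - d),
        K = (e*_cyt - e*_mem) / (e*_cyt + 2 e*_mem),

    the radius-ratio-cubed Maxwell–Garnett form.  The result feeds
    directly into :func:`cm_factor`.
    """
    eps_cyt = complex_permittivity(
        cell.cytoplasm_permittivity, cell.cytoplasm_conductivity, angular_frequency
    )
    eps_mem = complex_permittivity(
        cell.membrane_permittivity, cell.membrane_conductivity, angular_frequency
    )
    gamma = cell.radius / (cell.radius - cell.membrane_thickness)
    g3 = gamma**3
    k = (eps_cyt - eps_mem) / (eps_cyt + 2.0 * eps_mem)
    return eps_mem * (g3 + 2.0 * k) / (g3 - k)


def particle_complex_permittivity(cell: Cell, angular_frequency: float) -> complex:
    """Complex permittivity of either cell model at ``angular_frequency``."""
    if isinstance(cell, ShelledCell):
        return effective_cell_permittivity(cell, angular_frequency)
    return complex_permittivity(cell.permittivity, cell.conductivity, angular_frequency)


def cm_factor_at(cell: Cell, medium: DielectricMedium, frequency: float) -> complex:
    """CM factor of ``cell`` in ``medium`` at drive frequency ``frequency`` (Hz)."""
    _require(frequency > 0, "frequency must be > 0")
    omega = 2.0 * math.pi * frequency
    eps_p = particle_complex_permittivity(cell, omega)
    eps_m = complex_permittivity(medium.permittivity, medium.conductivity, omega)
    return cm_factor(eps_p, eps_m)


def re_cm_spectrum(
    cell: Cell, medium: DielectricMedium, frequencies: Sequence[float]
) -> pd.DataFrame:
    """Tabulate the CM factor over ``frequencies``.

    Returns a DataFrame with columns ``frequency_hz``, ``re_fcm``,
    ``im_fcm`` (one row per input frequency, input order preserved).
    An empty frequency list yields an empty table.
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size and np.any(freqs <= 0):
        raise ValueError("all frequencies must be > 0")
    values = [cm_factor_at(cell, medium, f) for f in freqs]
    return pd.DataFrame(
        {
            "frequency_hz": freqs,
            "re_fcm": [v.real for v in values],
            "im_fcm": [v.imag for v in values],
        }
    )


def crossover_frequency(
    cell: Cell, medium: DielectricMedium, f_low: float, f_high: float
) -> float | None:
    """Frequency in ``[f_low, f_high]`` where ``Re[f_CM]`` changes sign.

    Returns the bracketing root (relative tolerance 1e-6) or ``None`` if
    the real part has the same sign at both bracket ends.  The bracket
    must satisfy ``0 < f_low < f_high``.
    """
    _require(0 < f_low < f_high, "bracket must satisfy 0 < f_low < f_high")

    def re_fcm(f: float) -> float:
        return cm_factor_at(cell, medium, f).real

    lo, hi = re_fcm(f_low), re_fcm(f_high)
    if lo == 0.0:
        return f_low
    if hi == 0.0:
        return f_high
    if math.copysign(1.0, lo) == math.copysign(1.0, hi):
        return None
    # root-find in log-frequency: Re[f_CM] varies on decade scales
    root = brentq(
        lambda u: re_fcm(math.exp(u)),
        math.log(f_low),
        math.log(f_high),
        rtol=1e-9,
        xtol=1e-12,
    )
    return math.exp(root)
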