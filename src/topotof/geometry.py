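"""Idealized reflectron ToF-SIMS flight physics.

Secondary ions sputtered from the sample are accelerated by a uniform
electric field across the gap between the sample surface and a biased
extractor, then drift through the analyzer (the reflectron is assumed to
compensate the exit-velocity deficit exactly).  An ion emitted from a
feature of height ``dh`` above the substrate travels a shorter
acceleration path, so it spends less time in the gap and arrives early.
That early arrival is the topography-induced peak shift every other
module in this package measures, corrects, or inverts.

Three laws live here and are shared by the whole package:

* acceleration time in the gap,
  ``t_ac(m, dh) = sqrt(2 h_ex^2 m / (U_ex e)) * sqrt((h_ex - dh)/h_ex)``;
* the total time of flight ``T(m, dh) = T(m, 0) - t_ac(m, 0)(1 - sqrt((h_ex - dh)/h_ex))``
  with the substrate-level TOF anchored to a calibration ion,
  ``T(m, 0) = T_cal sqrt(m / m_cal)``;
* the quadratic TOF↔mass calibration ``m = m_cal ((t - t0)/(T_cal - t0))^2``.

All functions accept scalars or numpy arrays for ``mass`` and ``dh`` and
broadcast in the usual way.  SI units internally (seconds, meters,
volts); ion masses in unified atomic mass units (u).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

#: 1 unified atomic mass unit in kg (CODATA 2018).
ATOMIC_MASS_KG = 1.66053906660e-27
#: Elementary charge in C (exact, SI 2019).
ELEMENTARY_CHARGE = 1.602176634e-19

# Monoisotopic masses (u) of the species tracked in this package.
K_MONOISOTOPIC = 38.9637
CA_MONOISOTOPIC = 39.9626
NA_MONOISOTOPIC = 22.9898
MG_MONOISOTOPIC = 23.9850
SI_MONOISOTOPIC = 27.9769
SI2_MONOISOTOPIC = 55.9539
CS_MONOISOTOPIC = 132.9055
CS2_MONOISOTOPIC = 265.8109
#: Standard atomic weight of potassium; the printed 30.2 ns acceleration
#: time corresponds to this value rather than to the monoisotopic mass.
K_ATOMIC_WEIGHT = 39.098


@dataclass(frozen=True)
class InstrumentGeometry:
    """Extraction-gap geometry and timing of the spectrometer.

    Parameters
    ----------
    U_ex
        Extractor potential in volts.
    h_ex
        Sample-to-extractor gap in meters.
    T_cal
        Total substrate-level time of flight of the calibration ion, in
        seconds (default: K+ at 20.545 µs).
    m_cal
        Calibration ion mass in u (default: monoisotopic 39K).
    tof_bin
        Detector time-to-digital bin width in seconds.
    t_window
        Acquisition window in seconds.
    H_ef
        Effective drift path in meters; informational only — the flight
        model is anchored to ``T_cal``, not to an explicit drift length.
    z
        Ion charge state in elementary charges; fixed at 1.
    """

    U_ex: float = 2000.0
    h_ex: float = 1.5e-3
    T_cal: float = 20.545e-6
    m_cal: float = K_MONOISOTOPIC
    tof_bin: float = 50e-12
    t_window: float = 100e-6
    H_ef: float = 2.0
    z: int = 1

    def __post_init__(self) -> None:
        for name in ("U_ex", "h_ex", "T_cal", "m_cal", "tof_bin", "t_window", "H_ef"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.z != 1:
            raise ValueError("only singly charged ions are modelled (z = 1)")
        if not self.tof_bin < self.t_window:
            raise ValueError("tof_bin must be smaller than t_window")
        if not self.T_cal < self.t_window:
            raise ValueError("T_cal must lie inside the acquisition window")
        if not acceleration_time(self.m_cal, self) < self.T_cal:
            raise ValueError("acceleration time must be a small fraction of T_cal")

    @property
    def n_bins(self) -> int:
        """Number of raw time bins in the acquisition window."""
        return int(round(self.t_window / self.tof_bin))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentGeometry":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "InstrumentGeometry":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class IonSpecies:
    """A secondary-ion species identified by label and mass (u)."""

    label: str
    mass: float
    charge: int = 1

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        if self.charge != 1:
            raise ValueError("only singly charged ions are modelled")


def _check_mass_dh(mass: ArrayLike, dh: ArrayLike, geom: InstrumentGeometry) -> None:
    mass = np.asarray(mass, dtype=float)
    dh = np.asarray(dh, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("ion mass must be positive")
    if np.any(dh < 0):
        raise ValueError("emission height dh must be non-negative")
    if np.any(dh >= geom.h_ex):
        raise ValueError("emission height dh must lie below the extractor gap h_ex")


def acceleration_time(
    mass: ArrayLike, geom: InstrumentGeometry, dh: ArrayLike = 0.0
) -> ArrayLike:
    """Time an ion of ``mass`` u spends in the uniform extraction field.

    ``t_ac(m, 0) = sqrt(2 h_ex^2 m / (U_ex e))``; emission at height
    ``dh`` shortens the path, scaling the time by
    ``sqrt((h_ex - dh)/h_ex)``.  With the default geometry and the
    atomic weight of potassium this evaluates to ≈30.2 ns.
    """
    _check_mass_dh(mass, dh, geom)
    mass = np.asarray(mass, dtype=float)
    dh = np.asarray(dh, dtype=float)
    t0 = np.sqrt(
        2.0 * geom.h_ex**2 * mass * ATOMIC_MASS_KG / (geom.U_ex * ELEMENTARY_CHARGE)
    )
    out = t0 * np.sqrt((geom.h_ex - dh) / geom.h_ex)
    return out if out.ndim else float(out)


def total_tof(mass: ArrayLike, dh: ArrayLike, geom: InstrumentGeometry) -> ArrayLike:
    """Total time of flight of an ion emitted at height ``dh``.

    The substrate-level TOF follows the square-root mass law anchored at
    the calibration ion, ``T(m, 0) = T_cal * sqrt(m / m_cal)``; elevated
    emission subtracts the acceleration-time deficit
    ``t_ac(m, 0) * (1 - sqrt((h_ex - dh)/h_ex))``.
    """
    _check_mass_dh(mass, dh, geom)
    mass = np.asarray(mass, dtype=float)
    t_sub = geom.T_cal * np.sqrt(mass / geom.m_cal)
    out = t_sub - tof_shift(mass, dh, geom)
    return out if np.ndim(out) else float(out)


def tof_shift(mass: ArrayLike, dh: ArrayLike, geom: InstrumentGeometry) -> ArrayLike:
    """Topography-induced TOF reduction ``T(m, 0) - T(m, dh)`` (≥ 0)."""
    _check_mass_dh(mass, dh, geom)
    dh = np.asarray(dh, dtype=float)
    t0 = acceleration_time(mass, geom)
    out = t0 * (1.0 - np.sqrt((geom.h_ex - dh) / geom.h_ex))
    return out if np.ndim(out) else float(out)


def tof_from_mass(
    mass: ArrayLike, geom: InstrumentGeometry, t0: float = 0.0
) -> ArrayLike:
    """Substrate-level TOF of ``mass`` u under the quadratic calibration."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("ion mass must be positive")
    out = t0 + (geom.T_cal - t0) * np.sqrt(mass / geom.m_cal)
    return out if np.ndim(out) else float(out)


def mass_from_tof(t: ArrayLike, geom: InstrumentGeometry, t0: float = 0.0) -> ArrayLike:
    """Invert the quadratic calibration: ``m = m_cal ((t - t0)/(T_cal - t0))^2``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= t0):
        raise ValueError("time of flight must exceed the calibration offset t0")
    out = geom.m_cal * ((t - t0) / (geom.T_cal - t0)) ** 2
    return out if np.ndim(out) else float(out)


def height_from_shift(
    dt: ArrayLike, mass: float, geom: InstrumentGeometry
) -> ArrayLike:
    """Closed-form inverse of :func:`tof_shift`.

    ``dh = h_ex * (1 - ((t_ac(0) - dt)/t_ac(0))^2)`` recovers the
    emission height that produces a TOF shift ``dt`` for an ion of the
    given mass.  For ``dt`` equal to one detector bin (50 ps) and a K+
    ion this gives the ≈5 µm minimum detectable feature height.
    """
    dt = np.asarray(dt, dtype=float)
    t0 = acceleration_time(mass, geom)
    if np.any(dt >= t0):
        raise ValueError("shift dt must be smaller than the acceleration time")
    if np.any(dt < 0):
        raise ValueError("shift dt must be non-negative")
    out = geom.h_ex * (1.0 - ((t0 - dt) / t0) ** 2)
    return out if np.ndim(out) else float(out)
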