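"""Forward model of soft jamming: entry time, transit time, frequency.

The passage of a particle through the pore decomposes into two independent
durations:

* ``tau1(C)`` — the entry time, gated by the Langmuir occupancy of the pore
  entrance by clog-bound particles:
  ``tau1 = (1/k_off_clog) * C / (C + Kd_clog)``.
* ``tau2(C, P)`` — the transit time through the channel, set by the
  competition between wall adhesion (on-rate ``k_on_pore``) and advection:
  ``tau2 = (1/k) * (P_c/P) * exp(P_c/P)`` with prefactor
  ``k = pi * k_on_pore * C * L * R^2`` and critical pressure
  ``P_c = 8 eta k_on_pore L^2 / R^2``.

The translocation frequency is ``f = 1 / (tau1 + tau2)``.  Its limits
reproduce the bead controls: ``C -> 0`` gives purely advective linear
transport (carboxyl beads), ``Kd -> inf`` with ``k_on > 0`` gives a critical
pressure with no plateau (amino beads).

``k`` and ``P_c`` are always derived from the fundamental triple
``(k_on_pore, k_off_clog, Kd_clog)`` plus geometry — they are never stored,
which rules out inconsistent states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, OutOfDomainError
from .physics import FluidEnv, PoreGeometry, flow_speed


@dataclass(frozen=True)
class JammingParams:
    """Interaction parameters of the jamming model.

    Parameters
    ----------
    kon_pore:
        Characteristic on-rate (1/s) at which a particle sticks to the pore
        central channel.
    koff_clog:
        Characteristic off-rate (1/s) at which a particle detaches from the
        clog.
    Kd_clog:
        Dissociation constant between a free particle and the clog, in
        particles/m^3 (use :func:`softjam.units.molar_to_per_m3` for molar
        input).
    """

    kon_pore: float
    koff_clog: float
    Kd_clog: float

    def __post_init__(self) -> None:
        for name in ("kon_pore", "koff_clog", "Kd_clog"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value}"
                )


@dataclass(frozen=True)
class OperatingPoint:
    """Applied pressure (Pa) and upstream particle concentration (1/m^3)."""

    pressure: float
    concentration: float

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise InvalidParameterError(f"pressure must be >= 0, got {self.pressure}")
        if self.concentration < 0:
            raise InvalidParameterError(
                f"concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class MasterCurvePoint:
    """One point of the data collapse: x = C/(C+Kd), y = rescaled excess time."""

    x: float
    y: float
    alpha: float


def critical_pressure(params: JammingParams, geom: PoreGeometry, fluid: FluidEnv) -> float:
    """Critical pressure ``P_c = 8 eta k_on_pore L^2 / R^2`` (Pa).

    Below P_c, wall adhesion wins over advection and exit is exponentially
    suppressed.
    """
    return 8.0 * fluid.viscosity * params.kon_pore * geom.length**2 / geom.radius**2


def kon_from_critical_pressure(Pc: float, geom: PoreGeometry, fluid: FluidEnv) -> float:
    """Invert the critical-pressure relation: ``k_on = P_c R^2 / (8 eta L^2)``."""
    if Pc <= 0:
        raise InvalidParameterError(f"Pc must be > 0, got {Pc}")
    return Pc * geom.radius**2 / (8.0 * fluid.viscosity * geom.length**2)


def prefactor_k(params: JammingParams, op: OperatingPoint, geom: PoreGeometry) -> float:
    """Flux prefactor ``k = pi k_on_pore C L R^2`` (1/s); linear in C.

    Returns 0 (with a warning) at zero concentration, where the transit time
    is undefined.
    """
    if op.concentration == 0:
        warnings.warn(
            "prefactor k is 0 at zero concentration; tau2 is undefined there",
            stacklevel=2,
        )
        return 0.0
    return math.pi * params.kon_pore * op.concentration * geom.length * geom.radius**2


def tau1(params: JammingParams, op: OperatingPoint) -> float:
    """Entry time ``(1/k_off_clog) * C/(C+Kd_clog)`` (s).

    Monotonically increasing in C from 0 toward the saturation value
    ``1/k_off_clog``; independent of pressure.
    """
    occupancy = op.concentration / (op.concentration + params.Kd_clog)
    return occupancy / params.koff_clog


def _alpha(Pc: float, pressure: float) -> float:
    return (Pc / pressure) * math.exp(Pc / pressure)


def tau2(
    params: JammingParams, op: OperatingPoint, geom: PoreGeometry, fluid: FluidEnv
) -> float:
    """Transit time ``(1/k) (P_c/P) exp(P_c/P)`` (s); strictly decreasing in P."""
    if op.pressure <= 0:
        raise OutOfDomainError("transit time diverges at zero pressure")
    if op.concentration <= 0:
        raise OutOfDomainError("transit time is undefined at zero concentration")
    k = prefactor_k(params, op, geom)
    Pc = critical_pressure(params, geom, fluid)
    return _alpha(Pc, op.pressure) / k


def frequency(
    params: JammingParams, op: OperatingPoint, geom: PoreGeometry, fluid: FluidEnv
) -> float:
    """Translocation frequency ``f = 1/(tau1 + tau2)`` (1/s).

    Increasing in pressure at fixed concentration; the high-pressure plateau
    ``1/tau1 = k_off_clog (C + Kd)/C`` decreases with concentration — the
    hallmark of jamming.
    """
    return 1.0 / (tau1(params, op) + tau2(params, op, geom, fluid))


def frequency_grid(
    params: JammingParams,
    pressures: np.ndarray,
    concentrations: np.ndarray,
    geom: PoreGeometry,
    fluid: FluidEnv,
) -> np.ndarray:
    """Vectorised ``frequency`` over broadcastable pressure/concentration arrays."""
    P = np.asarray(pressures, dtype=float)
    C = np.asarray(concentrations, dtype=float)
    if np.any(P <= 0) or np.any(C <= 0):
        raise OutOfDomainError("frequency_grid requires P > 0 and C > 0")
    Pc = critical_pressure(params, geom, fluid)
    k = math.pi * params.kon_pore * C * geom.length * geom.radius**2
    t1 = (C / (C + params.Kd_clog)) / params.koff_clog
    # cap the exponent: beyond ~500 the transit time dwarfs any entry time
    # and the frequency is zero to machine precision anyway; the cap keeps
    # intermediate products finite for optimizer excursions
    t2 = (Pc / P) * np.exp(np.minimum(Pc / P, 500.0)) / k
    return 1.0 / (t1 + t2)


def pore_concentration_profile(
    params: JammingParams,
    op: OperatingPoint,
    geom: PoreGeometry,
    fluid: FluidEnv,
    x: float,
) -> float:
    """Steady-state in-pore concentration ``C exp(-k_on_pore x / v)`` (1/m^3).

    Adhesion depletes the advected population exponentially along the channel;
    at ``x = L`` the survival factor equals ``exp(-P_c/P)``, the same factor
    that suppresses exit in the transit time.
    """
    if not 0 <= x <= geom.length:
        raise OutOfDomainError(f"x={x} outside the pore [0, {geom.length}]")
    if op.pressure <= 0:
        raise OutOfDomainError("profile requires pressure > 0")
    v = flow_speed(op.pressure, geom, fluid)
    return op.concentration * math.exp(-params.kon_pore * x / v)


def amino_bead_frequency(
    kon_pore: float, op: OperatingPoint, geom: PoreGeometry, fluid: FluidEnv
) -> float:
    """Wall-interaction-only frequency ``f = 1/tau2 = k (P/P_c) exp(-P_c/P)``.

    Models particles that stick to the pore wall but not to each other
    (amino-functionalised beads): a critical pressure followed by a linear
    regime, with no plateau.
    """
    params = JammingParams(kon_pore=kon_pore, koff_clog=1.0, Kd_clog=1.0)
    return 1.0 / tau2(params, op, geom, fluid)


def carboxyl_bead_frequency(
    op: OperatingPoint, geom: PoreGeometry, fluid: FluidEnv
) -> float:
    """Non-interacting advective flux ``f = C v pi R^2``: linear in P and C."""
    v = flow_speed(op.pressure, geom, fluid)
    return op.concentration * v * math.pi * geom.radius**2


def master_transform(
    pressures: Sequence[float],
    concentrations: Sequence[float],
    frequencies: Sequence[float],
    params: JammingParams,
    geom: PoreGeometry,
    fluid: FluidEnv,
) -> list[MasterCurvePoint]:
    """Map measured (P, C, f) triples onto the model's master coordinates.

    With ``tau = 1/f``, ``alpha = (P_c/P) exp(P_c/P)`` and
    ``x = C/(C+Kd_clog)``, the rescaled excess time
    ``y = (k_off_clog/k) (k tau - alpha)`` equals ``x`` exactly for noiseless
    model data, so heterogeneous datasets collapse onto the identity line.
    Points with non-positive frequency are rejected with a warning.
    """
    Pc = critical_pressure(params, geom, fluid)
    points: list[MasterCurvePoint] = []
    for P, C, f in zip(pressures, concentrations, frequencies, strict=True):
        if f <= 0:
            warnings.warn(
                f"rejecting master-curve point with non-positive frequency f={f}",
                stacklevel=2,
            )
            continue
        x = C / (C + params.Kd_clog)
        if C == 0:
            points.append(MasterCurvePoint(x=0.0, y=0.0, alpha=_alpha(Pc, P)))
            continue
        k = math.pi * params.kon_pore * C * geom.length * geom.radius**2
        alpha = _alpha(Pc, P)
        tau = 1.0 / f
        y = (params.koff_clog / k) * (k * tau - alpha)
        points.append(MasterCurvePoint(x=x, y=y, alpha=alpha))
    return points
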