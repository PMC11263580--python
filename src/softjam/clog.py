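"""Clog geometry probing and transient clog formation.

A formed clog is probed with double-stranded DNA, whose flow-driven
translocation follows the suction model
``f_DNA = f_suc (P/P_suc) exp(-P_suc/P)``: translocation is a barrier
crossing, and the critical suction pressure ``P_suc`` scales with the pore's
hydraulic resistance.  Comparing ``P_suc`` for a naked and a clogged pore
therefore measures the open lumen of the clogged pore and hence the
thickness ``R_e`` of the particle layer lining the wall:

    ``R_e = R (1 - (P_suc_virus / P_suc_naked)^(-1/4))``

assuming a compact annular layer with an open cylindrical lumen.

Clog build-up after flushing is tracked through the frequency contrast
``(f(t) - f_inf)/(f_0 - f_inf)``, modelled as a single decaying exponential
``exp(-t/t_clog)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .physics import FluidEnv, PoreGeometry, VirusParams, hydraulic_resistance
from .units import BOLTZMANN


@dataclass(frozen=True)
class SuctionParams:
    """Suction-model parameters: prefactor f_suc (1/s) and critical pressure
    P_suc (Pa).

    ``f_suc`` is a pure fit parameter; the model value of the frequency at
    ``P = P_suc`` is ``f_suc / e``.
    """

    f_suc: float
    P_suc: float

    def __post_init__(self) -> None:
        if self.f_suc <= 0 or self.P_suc <= 0:
            raise InvalidParameterError(
                f"f_suc and P_suc must be > 0, got ({self.f_suc}, {self.P_suc})"
            )


@dataclass(frozen=True)
class ClogStructure:
    """Annular particle layer of thickness ``layer_thickness`` (R_e) lining a
    pore of radius ``pore_radius`` (R)."""

    layer_thickness: float
    pore_radius: float

    def __post_init__(self) -> None:
        if not 0 <= self.layer_thickness < self.pore_radius:
            raise InvalidParameterError(
                f"need 0 <= R_e < R, got R_e={self.layer_thickness}, "
                f"R={self.pore_radius}"
            )

    @property
    def relative_thickness(self) -> float:
        """R_e / R, in [0, 1)."""
        return self.layer_thickness / self.pore_radius


@dataclass(frozen=True)
class ClogTrace:
    """Frequency-contrast transient after clog removal.

    ``contrast[i] = (f(times[i]) - f_inf) / (f_0 - f_inf)`` starts near 1 and
    decays toward 0 as the clog re-forms.
    """

    times: np.ndarray
    contrast: np.ndarray
    f0: float
    f_inf: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise InvalidParameterError("times and contrast must be equal-length 1-D")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be non-negative, strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "contrast", c)


def dna_frequency(p: SuctionParams, pressure: float) -> float:
    """Suction-model DNA frequency ``f_suc (P/P_suc) exp(-P_suc/P)``.

    Strictly increasing in pressure; extended continuously to 0 at P = 0.
    """
    if pressure < 0:
        raise InvalidParameterError(f"pressure must be >= 0, got {pressure}")
    if pressure == 0:
        return 0.0
    return p.f_suc * (pressure / p.P_suc) * math.exp(-p.P_suc / pressure)


def p_suc_from_geometry(geom: PoreGeometry, fluid: FluidEnv) -> float:
    """Geometric prediction ``P_suc = J_c R_h`` with critical flow
    ``J_c = k_B T / eta``.

    The viscosity cancels: ``P_suc = 8 k_B T L / (pi R^4)``.
    """
    Jc = BOLTZMANN * fluid.temperature / fluid.viscosity
    return Jc * hydraulic_resistance(geom, fluid)


def clog_thickness(
    P_suc_naked: float, P_suc_virus: float, geom: PoreGeometry
) -> ClogStructure:
    """Layer thickness from the naked/clogged critical-pressure ratio.

    ``R_e = R (1 - (P_suc_virus/P_suc_naked)^(-1/4))``; a ratio of 16 gives
    ``R_e = R/2``.  A ratio below 1 is rejected: a clogged pore cannot have
    a lower hydraulic resistance than the naked one.
    """
    if P_suc_naked <= 0:
        raise InvalidParameterError(f"P_suc_naked must be > 0, got {P_suc_naked}")
    ratio = P_suc_virus / P_suc_naked
    if ratio < 1:
        raise InvalidParameterError(
            f"P_suc_virus/P_suc_naked = {ratio:.4g} < 1: a clogged pore cannot "
            "have lower resistance than a naked one"
        )
    Re = geom.radius * (1.0 - ratio**-0.25)
    return ClogStructure(layer_thickness=Re, pore_radius=geom.radius)


def suction_ratio_from_thickness(clog: ClogStructure) -> float:
    """Inverse of :func:`clog_thickness`: the pressure ratio implied by R_e."""
    return (1.0 - clog.relative_thickness) ** -4


def effective_pore_concentration(
    clog: ClogStructure, virus: VirusParams, geom: PoreGeometry
) -> float:
    """Particle concentration inside the clogged pore (1/m^3).

    The annular layer occupies a fraction ``1 - (1 - R_e/R)^2`` of the pore
    volume; dividing by the particle volume gives
    ``C_n = (1 - (1 - R_e/R)^2) / ((4/3) pi R_virus^3)``.  Pore radius and
    length cancel — only the relative thickness and the particle size matter.
    """
    fraction = 1.0 - (1.0 - clog.relative_thickness) ** 2
    particle_volume = (4.0 / 3.0) * math.pi * virus.hydrodynamic_radius**3
    return fraction / particle_volume


def corrected_kd(Kd_clog: float, upstream_C: float, pore_C: float) -> float:
    """Rescale an apparent dissociation constant to in-pore conditions.

    The dissociation constant inferred from upstream concentrations
    understates the true local value by the ratio of in-pore to upstream
    concentration: ``Kd_corrected = Kd_clog * (pore_C / upstream_C)``.
    Units of ``Kd_clog`` are preserved (molar in, molar out).
    """
    if Kd_clog <= 0 or upstream_C <= 0 or pore_C <= 0:
        raise InvalidParameterError("all arguments must be > 0")
    return Kd_clog * (pore_C / upstream_C)


def adhesion_energy_barrier(
    kon_pore: float, attempt_rate: float = 1.0e3, fluid: FluidEnv | None = None
) -> float:
    """Adhesion barrier in units of k_B T from ``k_on ~ nu exp(-dF*/k_B T)``.

    The attempt rate ``nu`` is not measurable here; the default 1e3 1/s is a
    configurable convention and every reported barrier must be quoted together
    with the attempt rate used.  An attempt rate below the on-rate yields a
    negative barrier, which is flagged with a warning rather than an error.
    """
    if kon_pore <= 0:
        raise InvalidParameterError(f"kon_pore must be > 0, got {kon_pore}")
    if attempt_rate <= 0:
        raise InvalidParameterError(f"attempt_rate must be > 0, got {attempt_rate}")
    if attempt_rate < kon_pore:
        warnings.warn(
            "attempt_rate < kon_pore gives a negative adhesion barrier",
            stacklevel=2,
        )
    return math.log(attempt_rate / kon_pore)


def clog_formation_model(t: float | np.ndarray, t_clog: float) -> float | np.ndarray:
    """Frequency contrast during clog build-up: ``exp(-t/t_clog)``."""
    if t_clog <= 0:
        raise InvalidParameterError(f"t_clog must be > 0, got {t_clog}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    out = np.exp(-t / t_clog)
    return float(out) if out.ndim == 0 else out
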