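"""Pore hydraulics and transport timescales.

A cylindrical nanochannel of radius ``R`` and length ``L`` driven by a
pressure difference ``P`` in the long-channel (Poiseuille) regime:

* hydraulic resistance  ``R_h = 8 eta L / (pi R^4)``
* mean flow speed       ``v = P / (pi R^2 R_h) = P R^2 / (8 eta L)``
* advection time        ``t_adv = L / v``
* Stokes-Einstein diffusion and the diffusive timescale ``t_diff = L^2 / D``
* Peclet number         ``Pe = t_diff / t_adv = v L / D``

All quantities are strict SI.  The Peclet number uses the pore length as its
length scale because the advection/diffusion comparison of interest is over
the full channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError
from .units import BOLTZMANN


@dataclass(frozen=True)
class FluidEnv:
    """Carrier fluid: dynamic viscosity (Pa s) and temperature (K).

    Defaults are water at room temperature.
    """

    viscosity: float = 1.0e-3
    temperature: float = 295.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise InvalidParameterError(f"viscosity must be > 0, got {self.viscosity}")
        if self.temperature <= 0:
            raise InvalidParameterError(
                f"temperature must be > 0, got {self.temperature}"
            )


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical pore: radius and length in metres.

    ``length >= radius`` is enforced because the Poiseuille description
    assumes a long channel.
    """

    radius: float
    length: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidParameterError(f"radius must be > 0, got {self.radius}")
        if self.length <= 0:
            raise InvalidParameterError(f"length must be > 0, got {self.length}")
        if self.length < self.radius:
            raise InvalidParameterError(
                "long-channel regime requires length >= radius "
                f"(got R={self.radius}, L={self.length})"
            )


@dataclass(frozen=True)
class VirusParams:
    """A viral particle reduced to its hydrodynamic radius (m) plus a label."""

    hydrodynamic_radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.hydrodynamic_radius <= 0:
            raise InvalidParameterError(
                f"hydrodynamic_radius must be > 0, got {self.hydrodynamic_radius}"
            )


def hydraulic_resistance(geom: PoreGeometry, fluid: FluidEnv) -> float:
    """Poiseuille hydraulic resistance ``8 eta L / (pi R^4)`` in Pa s m^-3."""
    return 8.0 * fluid.viscosity * geom.length / (math.pi * geom.radius**4)


def flow_speed(pressure: float, geom: PoreGeometry, fluid: FluidEnv) -> float:
    """Mean (flux-averaged) flow speed ``P R^2 / (8 eta L)`` in m/s.

    Linear in pressure; zero pressure gives zero speed.
    """
    if pressure < 0:
        raise InvalidParameterError(f"pressure must be >= 0, got {pressure}")
    return pressure * geom.radius**2 / (8.0 * fluid.viscosity * geom.length)


def advection_time(pressure: float, geom: PoreGeometry, fluid: FluidEnv) -> float:
    """Time to advect over the pore length, ``L / v = 8 eta L^2 / (P R^2)``."""
    if pressure <= 0:
        raise InvalidParameterError(
            f"advection time requires pressure > 0, got {pressure}"
        )
    return geom.length / flow_speed(pressure, geom, fluid)


def diffusion_coefficient(virus: VirusParams, fluid: FluidEnv) -> float:
    """Stokes-Einstein diffusion coefficient ``k_B T / (6 pi eta R_virus)``."""
    return BOLTZMANN * fluid.temperature / (
        6.0 * math.pi * fluid.viscosity * virus.hydrodynamic_radius
    )


def diffusion_time(geom: PoreGeometry, virus: VirusParams, fluid: FluidEnv) -> float:
    """Diffusive timescale over the pore length, ``L^2 / D_virus``."""
    return geom.length**2 / diffusion_coefficient(virus, fluid)


def peclet_number(
    pressure: float, geom: PoreGeometry, virus: VirusParams, fluid: FluidEnv
) -> float:
    """Peclet number ``v L / D = t_diff / t_adv`` over the pore length."""
    if pressure <= 0:
        raise InvalidParameterError(f"Peclet number requires pressure > 0, got {pressure}")
    v = flow_speed(pressure, geom, fluid)
    return v * geom.length / diffusion_coefficient(virus, fluid)
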