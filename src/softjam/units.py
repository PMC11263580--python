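"""Unit conversions between user-facing units and the internal SI system.

Everything inside the package is strict SI: Pa, m, s, K, particles per m^3.
Bench-side quantities (nm, um, particles/mL, molar) are converted at the
boundary by the helpers below, so no module ever mixes unit systems.
"""

from __future__ import annotations

from scipy.constants import Avogadro, Boltzmann

BOLTZMANN: float = Boltzmann  # J/K
AVOGADRO: float = Avogadro  # 1/mol

#: litres per cubic metre, used in molar conversions
_L_PER_M3 = 1.0e3
#: millilitres per cubic metre
_ML_PER_M3 = 1.0e6


def nm(value: float) -> float:
    """Nanometres to metres."""
    return value * 1.0e-9


def um(value: float) -> float:
    """Micrometres to metres."""
    return value * 1.0e-6


def per_ml_to_per_m3(conc: float) -> float:
    """Particles/mL to particles/m^3 (x 1e6)."""
    return conc * _ML_PER_M3


def per_m3_to_per_ml(conc: float) -> float:
    """Particles/m^3 to particles/mL."""
    return conc / _ML_PER_M3


def molar_to_per_m3(conc_molar: float) -> float:
    """Molar concentration (mol/L) to particles/m^3 via Avogadro's number."""
    return conc_molar * AVOGADRO * _L_PER_M3


def per_m3_to_molar(conc: float) -> float:
    """Particles/m^3 to molar (mol/L)."""
    return conc / (AVOGADRO * _L_PER_M3)
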