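"""Probing the clog geometry with DNA suction curves.

Generates a naked/clogged pair of DNA translocation curves (the clogged
pore's critical suction pressure is 16x the naked one's), fits both with
the suction model, and converts the shift into the thickness of the virus
layer lining the pore, the effective in-pore concentration, and the
adhesion energy barrier.
"""

import numpy as np

import softjam as sj
from softjam.units import per_m3_to_molar, per_m3_to_per_ml

geom = sj.PoreGeometry(radius=100e-9, length=10e-6)
water = sj.FluidEnv()

P_suc_naked = sj.p_suc_from_geometry(geom, water)
print(f"geometric critical suction pressure (naked pore): {P_suc_naked:.0f} Pa")

pressures = np.geomspace(200, 3e5, 14)
naked, clogged = sj.generate_dna_curves(
    P_suc_naked, resistance_ratio=16.0, f_suc=10.0, pressures=pressures,
    sigma=0.05, seed=4,
)
fit_naked = sj.fit_suction(naked, seed=4)
fit_clogged = sj.fit_suction(clogged, seed=4)
print(f"fitted P_suc naked   : {fit_naked.estimates['P_suc']:.0f} Pa")
print(f"fitted P_suc clogged : {fit_clogged.estimates['P_suc']:.0f} Pa")

layer = sj.clog_thickness(
    fit_naked.estimates["P_suc"], fit_clogged.estimates["P_suc"], geom
)
print(f"virus layer thickness: R_e/R = {layer.relative_thickness:.3f}")

virus = sj.VirusParams(hydrodynamic_radius=50e-9)
C_pore = sj.effective_pore_concentration(layer, virus, geom)
print(f"effective in-pore concentration: {per_m3_to_per_ml(C_pore):.2e} /mL")

# Rescaling the apparent dissociation constant by the in-pore/upstream
# concentration ratio moves it into the protein-protein interaction range.
Kd_apparent = 1.5e-13  # M, from the frequency fits
upstream = 1e14  # 1e8 /mL in SI
print(f"corrected Kd_clog: {sj.corrected_kd(Kd_apparent, upstream, C_pore):.2e} M")

dF = sj.adhesion_energy_barrier(0.625, attempt_rate=1e3)
print(f"adhesion barrier (attempt rate 1e3/s): {dF:.1f} kBT")
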