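"""Transport timescales in a pressure-driven nanopore.

Computes the hydraulic resistance, mean flow speed, and the advective and
diffusive timescales for an HIV-sized particle in a 200 nm diameter,
10 um long track-etched pore at 800 Pa.
"""

import softjam as sj

geom = sj.PoreGeometry(radius=100e-9, length=10e-6)
water = sj.FluidEnv()  # 1 mPa s, 295 K
virus = sj.VirusParams(hydrodynamic_radius=83e-9, label="HIV")
P = 800.0  # Pa

print(f"hydraulic resistance : {sj.hydraulic_resistance(geom, water):.3e} Pa s/m^3")
print(f"mean flow speed      : {sj.flow_speed(P, geom, water):.3e} m/s")
print(f"advection time       : {sj.advection_time(P, geom, water):.3f} s")
print(f"diffusion time       : {sj.diffusion_time(geom, virus, water):.1f} s")
print(f"Peclet number        : {sj.peclet_number(P, geom, virus, water):.0f}")

# The 0.1 s advection time cannot explain the ~38 s clog-formation
# transient, while the diffusive timescale over the pore length can; the
# large Peclet number confirms that steady transport is advection-dominated.
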