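"""Clog-formation transient: fitting the frequency contrast.

After flushing the pore at high pressure, the translocation frequency
relaxes exponentially as the clog re-forms.  This script generates a noisy
contrast trace with a 38 s time constant and recovers it.
"""

import numpy as np

import softjam as sj

t = np.linspace(0.0, 300.0, 30)
trace = sj.generate_clog_trace(t_clog=38.0, f0=1.0, f_inf=0.0, times=t,
                               sigma=0.05, seed=11)
result = sj.fit_clog_dynamics(trace, seed=11)
print(f"recovered t_clog = {result.estimates['t_clog']:.1f} "
      f"+/- {result.stderrs['t_clog']:.1f} s (truth 38 s)")

geom = sj.PoreGeometry(radius=100e-9, length=10e-6)
water = sj.FluidEnv()
virus = sj.VirusParams(hydrodynamic_radius=83e-9)
print(f"diffusive timescale L^2/D = {sj.diffusion_time(geom, virus, water):.1f} s")
print(f"advective timescale at 800 Pa = {sj.advection_time(800.0, geom, water):.2f} s")
# The clog builds on the diffusive timescale, not the advective one: the
# layer grows by particles exploring the channel, not by plug flow.
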