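"""Why R2/eta tracks molecular size: the hydrodynamic chain of reasoning.

Walks the Stokes–Einstein–Debye relations for an oleic-acid-sized
molecule: viscosity and radius set the tumbling rate, its inverse is the
rotational correlation time, and the correlation time (in the fast-motion
regime) sets the transverse relaxation rate linearly.
"""

from relaxochain import (
    BPPParams,
    fast_motion_r2,
    rotational_diffusion,
    tau_c_sed,
    tumbling_rate,
)
from relaxochain.hydrodynamics import sphere_volume

radius_m = 0.5e-9        # ~oleic acid hydrodynamic radius
viscosity_cp = 17.6      # oleic acid at 20 C
temperature_k = 293.0

rate = tumbling_rate(radius_m, viscosity_cp, temperature_k)
tau_c = tau_c_sed(sphere_volume(radius_m), viscosity_cp, temperature_k)
d_r = rotational_diffusion(radius_m, viscosity_cp, temperature_k)
print(f"tumbling rate 1/tau_c = {rate:.3e} 1/s  ->  tau_c = {tau_c:.3e} s")
print(f"rotational diffusion D_r = {d_r:.3e} 1/s (tau_c * D_r = {tau_c * d_r:.4f})")

params = BPPParams(larmor_frequency_mhz=23.0)
x = params.omega0 * tau_c
print(f"omega0 * tau_c = {x:.2f}: below the T1 minimum at 0.616, on the "
      "fast-motion branch where R2 grows with tau_c and T1 is close to T2")

m2 = params.dipolar_prefactor * 3 / 20
r2 = fast_motion_r2(tau_c, m2)
print(f"fast-motion R2 = {r2:.2f} 1/s for this tau_c")
print("doubling viscosity doubles tau_c, hence doubles R2 — dividing "
      "R2 by viscosity isolates the molecular-size factor")
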