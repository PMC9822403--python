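"""T1-T2 correlation map of a two-component oil mixture.

Simulates an inversion-recovery CPMG series for a viscous short-T2
component plus a free fluid, inverts it to a T1-T2 map, classifies the
peaks, and demonstrates the gel-formation diagnostic (T1 up, T2 flat).
"""

import numpy as np

from relaxochain import (
    classify_map,
    gel_shift_diagnostic,
    invert_t1t2,
    simulate_ir_cpmg,
)

tinv = np.logspace(0, np.log10(5000.0), 16)

# glycerol-like viscous component + free oil, weights 1 : 2
series = simulate_ir_cpmg(
    [(10.0, 8.0, 1.0), (600.0, 500.0, 2.0)],
    tinv, n_echoes=1000, noise_sigma=0.004, seed=7,
)
t1t2 = invert_t1t2(series, lambda_reg=1e-2)
print(f"inverted in {t1t2.n_iterations} iterations, "
      f"residual {t1t2.residual:.3g}")
for peak, label in classify_map(t1t2)["per_peak"]:
    print(f"  peak T1 = {peak.t1_ms:7.1f} ms, T2 = {peak.t2_ms:7.1f} ms, "
          f"mass = {peak.mass:.2f}  ->  {label}")
print("mass ratios approximate component weights; labels follow the "
      "T2 < 10 ms and T1/T2 > 2 rules")

# gelation: the network immobilises little mass, so T2 stays while T1 grows
before = invert_t1t2(
    simulate_ir_cpmg([(200.0, 150.0, 1.0)], tinv, n_echoes=500), lambda_reg=1e-4
)
after = invert_t1t2(
    simulate_ir_cpmg([(600.0, 150.0, 1.0)], tinv, n_echoes=500), lambda_reg=1e-4
)
report = gel_shift_diagnostic(before, after)
print(f"gel diagnostic: dT1 = {report.delta_t1_rel:+.0%}, "
      f"dT2 = {report.delta_t2_rel:+.0%} -> "
      f"rigid network formation: {report.rigid_network_formation}")
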