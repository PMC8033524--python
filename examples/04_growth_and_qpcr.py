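"""Tumour growth kinetics, relative expression, and ChIP recovery.

Shows the calliper volume formula, the log-linear fit that extracts the
time for a tumour to reach 250 mm^3, the 2^-ddCt fold change, and the
percent-input quantification of a ChIP-qPCR signal.
"""

import math

import numpy as np

import pbscreen as pb

# calliper pairs -> volumes: V = 0.5 x large x small^2
print(f"volume of a 10 x 5 mm tumour: {pb.tumour_volume(10, 5):.1f} mm^3")

# noisy exponential growth, fitted on the log scale
rng = np.random.default_rng(0)
days = list(range(0, 24, 3))
volumes = [10 * math.exp(0.3 * t) * math.exp(rng.normal(0, 0.2))
           for t in days]
fit = pb.time_to_threshold(pb.GrowthSeries("mouse_1", days, volumes),
                           V_star=250)
truth = math.log(25) / 0.3
print(f"time to 250 mm^3: {fit.t_threshold:.2f} days "
      f"(noise-free truth {truth:.2f}), R^2 = {fit.r_squared:.3f}, "
      f"growth rate {fit.slope:.3f}/day")

# relative expression: one extra cycle of the control = 2-fold change
sample = pb.QpcrMeasurement(ct_target=24.0, ct_housekeeping=20.0)
control = pb.QpcrMeasurement(ct_target=25.0, ct_housekeeping=20.0)
print(f"2^-ddCt fold change: {pb.ddct_fold_change(sample, control):.2f} "
      "(ddCt = -1 doubles the estimate)")

# ChIP-qPCR: IP Ct equal to a 1% input aliquot's Ct means ~1% recovery
pct = pb.percent_input(ct_ip=30.0, ct_input=30.0, input_fraction=0.01)
print(f"percent input at equal Ct with a 1% aliquot: {pct:.2f}%")
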