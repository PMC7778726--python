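"""Typical single-dose profiles of the five study treatments.

Evaluates the closed-form two-compartment model at the published typical
values and prints the peak, its time, and total exposure per treatment.
The phosphate/acetate suspension (C) shows the flip-flop tail: a lower
peak but drug still measurable weeks later.
"""

import numpy as np

from cortipk import TREATMENTS, auc_to_infinity, cmax_tmax, concentration, \
    population_for

for code, trt in TREATMENTS.items():
    theta = population_for(trt.drug).theta
    doses = trt.dose_events()
    cmax, tmax = cmax_tmax(theta, doses, grid_step=0.1)
    auc = auc_to_infinity(theta, doses)
    cp336 = concentration(theta, doses, [336.0]).cp[0]
    print(f"{code} ({trt.label:22s}): Cmax {cmax:6.1f} ng/mL at {tmax:4.1f} h, "
          f"AUCinf {auc:6.0f} ng*h/mL, Cp(14 d) {cp336:.3f} ng/mL")

print("\nAll treatments deliver 6 mg; only the acetate depot (C) is still")
print("quantifiable (>= 0.1 ng/mL) at the 14-day mark.")
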