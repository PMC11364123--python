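"""Run a global 3D gamma analysis of a perturbed delivery against the plan.

A planned dose is rendered for a synthetic plan; a 'delivered' dose is
re-rendered with speed-proportional MLC positioning errors and sampled at a
helical diode array.  The detector readings (never interpolated) are then
compared to the planned grid at the four standard criteria.
"""

import numpy as np

from complexiqa import (NoiseConfig, build_layout, gamma_analysis_multi,
                        generate_plan, sample_dose, toy_dose)
from complexiqa.cohort import render_delivery

plan = generate_plan("head_and_neck", m=0.7, seed=7)
planned = toy_dose(plan)

noise = NoiseConfig()
delivered = render_delivery(plan, noise, np.random.default_rng(1))

layout = build_layout("helical")          # 1386 diodes on the cylinder
readings = sample_dose(delivered, layout)

results = gamma_analysis_multi(layout.points, readings, planned)
print(f"{layout.n_points} diodes, {results[(3.0, 3.0)].n_evaluated} above "
      "the 10% dose threshold")
for crit, res in results.items():
    print(f"  {crit[0]:.0f}%/{crit[1]:.0f}mm: GPR = {res.gpr:6.2f}%")

# The passing rate decreases monotonically from 3%/3mm to 1%/1mm: stricter
# criteria expose the MLC positioning errors injected into the delivery.
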