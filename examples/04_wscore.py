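"""W-score normalization of patient expansion maps.

Fits the per-vertex control model (expansion ~ age + ICV), converts each
patient's map to W-scores (unitless deviations from the control
expectation), and shows the calibration: control-model scores are
standard-normal-like, so +1.65 marks the 95th percentile.
"""

import numpy as np

from ventmorph import CohortConfig, fit_control_model, generate_cohort
from ventmorph.synthetic import common_frame_expansion
from ventmorph.wscore import wscore_matrix

cohort = generate_cohort(CohortConfig(seed=1, cortex_resolution=2))
expansion = common_frame_expansion(cohort)["left"]
table = cohort.table
ctrl = table.group == "control"
inph = table.group == "INPH"

model = fit_control_model(expansion[ctrl.to_numpy()], table[ctrl],
                          covariate_names=("age", "icv_mm3"))
w_inph = wscore_matrix(expansion[inph.to_numpy()], table[inph], model)
w_ctrl = wscore_matrix(expansion[ctrl.to_numpy()], table[ctrl], model)

print(f"control W-scores: mean {w_ctrl.mean():+.3f}, SD {w_ctrl.std():.3f} "
      "(0 and ~1 by construction)")
print(f"patient W-scores: mean {w_inph.mean():+.2f}, "
      f"95th percentile {np.percentile(w_inph, 95):.1f}")
frac = (w_inph > 1.65).mean()
print(f"fraction of patient vertex scores above +1.65: {100 * frac:.1f}% "
      "(values above +1.65 exceed the control 95th percentile)")
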