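"""Vertex-wise group comparison of ventricular expansion.

Computes per-vertex expansion distances against the control average shape
and runs the ANCOVA (group + age + ICV) with Bonferroni correction at
family alpha 0.01 over both sides.  Nearly all vertices in the planted
expansion zones should be significant and none in the untouched inferior
body.
"""

import numpy as np

from ventmorph import CohortConfig, generate_cohort, vertexwise_ancova
from ventmorph.synthetic import VENTRICLE_EXPANSION_ZONES, common_frame_expansion

cohort = generate_cohort(CohortConfig(seed=1, cortex_resolution=2))
expansion = common_frame_expansion(cohort)
n_family = sum(expansion[s].shape[1] for s in expansion)

for side in ("left", "right"):
    res = vertexwise_ancova(expansion[side], cohort.table, n_tests=n_family)
    lab = cohort.ventricle_labels[side]
    core = lab.core_mask(VENTRICLE_EXPANSION_ZONES, 0.8)
    inferior = lab.mask("inferior_body")
    print(f"{side:5s}: {res.significant.sum():4d}/{res.n_vertices} significant "
          f"vertices | zone cores {100 * res.significant[core].mean():5.1f}% | "
          f"inferior body {100 * res.significant[inferior].mean():4.1f}% | "
          f"max group effect {res.effect.max():.1f} mm")
print("\nA high zone-core percentage with an empty inferior body means the "
      "planted expansion pattern was localized correctly.")
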