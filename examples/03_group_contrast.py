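"""Voxel-wise group contrast with permutation cluster inference.

Plants a strong group difference (Cohen's d = 2) inside a 4x4x4 cube,
fits the voxel-wise GLM and reports clusters whose size beats the
permutation null of the maximum cluster size.
"""

import numpy as np
import pandas as pd

from neurocoloc.contrast import permutation_cluster_inference
from neurocoloc.imaging import ScalarMap

rng = np.random.default_rng(5)
n_per_group = 12
effect = np.zeros((10, 10, 10))
effect[3:7, 3:7, 3:7] = 2.0  # patients lose signal here

subjects = pd.DataFrame({"group": ["control"] * n_per_group + ["patient"] * n_per_group})
maps = [ScalarMap(rng.standard_normal((10, 10, 10))) for _ in range(n_per_group)]
maps += [ScalarMap(rng.standard_normal((10, 10, 10)) - effect) for _ in range(n_per_group)]

clusters = permutation_cluster_inference(
    maps, subjects, covariates=[], contrast="control>patient",
    n_perm=500, voxel_p=0.001, cluster_p=0.05, seed=9,
)
print(clusters.to_string(index=False))
print("\nThe top cluster sits inside the planted cube (voxels 3-6 on each axis); "
      "its p is the fraction of label permutations whose largest cluster "
      "was at least as big.")
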