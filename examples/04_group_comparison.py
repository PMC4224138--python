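"""Two-group comparison with maximal-cluster-size permutation FWER control.

The full recovery experiment: an 8-vs-8 phantom cohort with a planted
posterior connectivity reduction in the aged group is pushed through the
resting-state route (trim, filter, concatenate, threshold, prune, degree,
Z-normalize) and the voxelwise permutation cluster test. The planted block
should return as a significant degree-decrease cluster.
"""

import numpy as np

from voxnet import PhantomSpec, dice_overlap
from voxnet.experiments import rest_degree_group_comparison

spec = PhantomSpec(
    grid_shape=(16, 16, 6),
    group_sizes={"young": 8, "aged": 8},
    effect_table={
        "young": {"posterior": 1.0, "anterior": 0.35},
        "aged": {"posterior": 0.35, "anterior": 1.0},
    },
    seed=42,
)
report = rest_degree_group_comparison(spec, alpha=1e-25, n_perm=500, seed=7)

print(f"voxels entering the test (>=90% presence in both groups): "
      f"{int(report.mask.sum())}")
print(f"permutations: {report.n_permutations} "
      f"(exact enumeration: {report.exact})")
print(f"significant cluster size threshold: {report.size_threshold}")
for c in report.clusters:
    direction = "young > aged" if c.sign > 0 else "aged > young"
    print(f"  cluster: {direction}, size {c.size}, "
          f"FWER p = {report.cluster_p(c.size):.4f}")

planted = {tuple(v) for v in np.argwhere(spec.region_masks()["posterior"])}
decrease = {tuple(v) for c in report.significant if c.sign > 0 for v in c.voxels}
print(f"\nDice overlap of the significant degree-decrease cluster with the "
      f"planted posterior block: {dice_overlap(decrease, planted):.2f}")
print("A positive-sign cluster means lower Z-degree in the aged group there "
      "— the planted posterior reduction, recovered with familywise error "
      "control from the permutation null of the maximal cluster size.")
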