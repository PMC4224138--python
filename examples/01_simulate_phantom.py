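"""Generate a synthetic cohort and inspect the planted connectivity shift.

The phantom plants two voxel blocks — "posterior" and "anterior" — whose
within-block signal coherence is scaled per group. Aged-like groups get a
reduced posterior multiplier and an increased anterior one, so mean
within-block correlation should fall (posterior) and rise (anterior) from
young to aged.
"""

import numpy as np

from voxnet import PhantomSpec, generate_cohort

spec = PhantomSpec(
    grid_shape=(12, 12, 6),
    n_sessions=1,
    group_sizes={"young": 4, "aged": 4},
    effect_table={
        "young": {"posterior": 1.0, "anterior": 0.35},
        "aged": {"posterior": 0.35, "anterior": 1.0},
    },
    seed=7,
)
cohort = generate_cohort(spec)
blocks = spec.region_masks()
print(f"cohort: {len(cohort)} subjects on a {spec.grid_shape} grid, "
      f"TR {spec.tr} s, {spec.images_per_session} acquisitions/session")
print(f"planted blocks: posterior={int(blocks['posterior'].sum())} voxels, "
      f"anterior={int(blocks['anterior'].sum())} voxels")

for region in ("posterior", "anterior"):
    print(f"\nmean within-{region} pairwise correlation (session 1):")
    for group in spec.group_sizes:
        rs = []
        for subj in cohort:
            if subj.group_label != group:
                continue
            series = subj.sessions[0].data[blocks[region]]
            corr = np.corrcoef(series)
            rs.append(corr[np.triu_indices(corr.shape[0], k=1)].mean())
        print(f"  {group:6s}: {np.mean(rs):+.3f}")

print("\nHigher multiplier -> stronger shared signal -> higher within-block "
      "correlation; the young/aged contrast flips between the two blocks, "
      "which is the planted posterior-anterior shift.")
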