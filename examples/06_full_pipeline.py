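"""The whole analysis in one call: phantom -> prep -> networks -> metrics
-> permutation statistics -> cross-space comparison.

run_pipeline() executes every stage for each group pair, space (native and
normalize-then-resample "standard"), and correlation threshold, and writes
NIfTI t-maps, cluster tables, network densities, regional summaries and a
JSON manifest under the configured output directory.
"""

from voxnet import PhantomSpec, PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/example_pipeline",
    phantom=PhantomSpec(
        grid_shape=(10, 10, 4),
        n_sessions=2,
        images_per_session=32,
        trials_per_session=3,
        trial_len=8,
        group_sizes={"young": 3, "aged": 3},
        effect_table={
            "young": {"posterior": 1.0, "anterior": 0.35},
            "aged": {"posterior": 0.35, "anterior": 1.0},
        },
        seed=5,
    ),
    flavors=("rest",),
    alphas={"rest": [1e-3]},
    measures=("degree", "clustering"),
    n_perm=200,
    seed=9,
)

bundle = run_pipeline(config)
manifest = bundle["manifest"]
print(f"analyses run: {manifest['analyses']} "
      f"(groups {manifest['groups']}, seed {manifest['seed']})")

clusters = bundle["clusters"]
print(f"clusters found: {len(clusters)}, significant: "
      f"{int(clusters['significant'].sum()) if len(clusters) else 0}")
if len(clusters):
    print(clusters[["space", "measure", "sign", "size", "p_fwer", "significant"]]
          .to_string(index=False))

density = bundle["density"].groupby("space")["density"].mean()
print("\nmean network density by space:")
print(density.to_string())
print("\nStandard-space density exceeding native density is the "
      "normalization-order effect: interpolation smoothing manufactures "
      "spatial correlation and therefore extra suprathreshold edges.")
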