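"""Self-contained validation experiments on synthetic data.

Each function runs one calibration or parameter-recovery experiment end to
end — generating its own inputs, executing the analysis, and measuring the
result — so the statistical behaviour of the pipeline can be quantified
without any external data:

- :func:`empirical_fwer`: familywise error rate of the maximal-cluster-size
  permutation procedure on null metric images;
- :func:`edge_threshold_rejection_rate`: type-I error of the derived
  correlation edge threshold on independent Gaussian series;
- :func:`rest_degree_group_comparison`: the full resting-state route
  (trim, filter, concatenate, mask, threshold, prune, degree, Z-normalize,
  permutation cluster test) on a phantom cohort;
- :func:`recovery_experiment`: repeated planted-effect recovery with Dice
  overlap against the planted block;
- :func:`density_inflation_fraction`: how often spatial normalization
  inflates network density at a fixed edge threshold.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .compare import dice_overlap
from .metrics import MetricImage, degree_map, z_normalize
from .network import alpha_to_r, build_network, correlation_matrix, network_density, prune_components
from .phantom import PhantomSpec, generate_cohort, generate_null_metric_images
from .prep import (
    apply_tissue_mask,
    concatenate_sessions,
    highpass_filter,
    normalize_then_resample,
    resample_labels,
    trim_volume,
)
from .stats import ClusterReport, GroupSample, permutation_cluster_test


def empirical_fwer(
    n_replicates: int = 200,
    n_per_group: tuple[int, int] = (8, 8),
    grid_shape: tuple[int, int, int] = (24, 24, 8),
    n_perm: int = 500,
    t_thresh: float = 3.0,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Fraction of null replicates yielding any significant cluster.

    Each replicate draws two groups of i.i.d. Gaussian metric images (no
    group difference by construction) and runs the full cluster-size
    permutation procedure. Under exchangeability the fraction is bounded by
    ``cluster_alpha`` up to Monte-Carlo error.
    """
    root = np.random.SeedSequence(seed)
    gen_seeds, test_seeds = root.spawn(2)
    gen_streams = gen_seeds.spawn(n_replicates)
    test_streams = test_seeds.spawn(n_replicates)
    hits = 0
    for g_ss, t_ss in zip(gen_streams, test_streams):
        g1, g2 = generate_null_metric_images(
            n_per_group, grid_shape, seed=np.random.default_rng(g_ss).integers(2**31)
        )
        report = permutation_cluster_test(
            GroupSample(images=g1, group_label="g1"),
            GroupSample(images=g2, group_label="g2"),
            n_perm=n_perm,
            t_thresh=t_thresh,
            cluster_alpha=cluster_alpha,
            seed=int(np.random.default_rng(t_ss).integers(2**31)),
        )
        hits += bool(report.significant)
    fwer = hits / n_replicates
    mc_se = float(np.sqrt(cluster_alpha * (1 - cluster_alpha) / n_replicates))
    return {
        "fwer": fwer,
        "n_replicates": n_replicates,
        "nominal": cluster_alpha,
        "mc_se": mc_se,
    }


def edge_threshold_rejection_rate(
    alpha: float = 1e-2,
    n_samples: int = 8,
    n_pairs: int = 100_000,
    seed: int | None = None,
) -> dict:
    """Two-tailed rejection rate of the derived correlation threshold on
    independent Gaussian series pairs; should equal ``alpha``."""
    r_crit = alpha_to_r(alpha, n_samples)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_pairs, n_samples))
    y = rng.standard_normal((n_pairs, n_samples))
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    num = (x * y).sum(axis=1)
    denom = np.linalg.norm(x, axis=1) * np.linalg.norm(y, axis=1)
    r = num / denom
    rate = float((np.abs(r) >= r_crit).mean())
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_pairs))
    return {"rate": rate, "alpha": alpha, "r_crit": r_crit, "n_pairs": n_pairs,
            "mc_se": mc_se}


def rest_degree_images(
    spec: PhantomSpec,
    alpha: float = 1e-25,
    trim: tuple[int, int] = (4, 4),
    cutoff_hz: float = 1.0 / 42.88,
) -> dict[str, list[MetricImage]]:
    """Z-normalized degree images from the resting-state route, per group.

    Subjects whose thresholded network is empty (or too small to normalize)
    contribute an all-missing image; downstream presence filtering then
    excludes the affected voxels.
    """
    cohort = generate_cohort(spec)
    out: dict[str, list[MetricImage]] = {}
    for subj in cohort:
        sessions = [
            highpass_filter(trim_volume(s, *trim), cutoff_hz) for s in subj.sessions
        ]
        rest = concatenate_sessions(sessions)
        included = apply_tissue_mask(rest, subj.tissue_mask, ("gm", "wm"))
        r_crit = alpha_to_r(alpha, rest.n_timepoints)
        corr = correlation_matrix(rest, included)
        net = prune_components(
            build_network(corr, r_crit, included, grid_shape=rest.grid_shape)
        )
        img = degree_map(net)
        if img.n_present >= 2 and img.present_values().std() > 0:
            img = z_normalize(img)
        out.setdefault(subj.group_label, []).append(img)
    return out


def rest_degree_group_comparison(
    spec: PhantomSpec,
    alpha: float = 1e-25,
    n_perm: int = 500,
    seed: int | None = None,
) -> ClusterReport:
    """Full resting-state degree comparison between the spec's two groups."""
    groups = list(spec.group_sizes)
    if len(groups) != 2:
        raise ValueError("recovery experiment expects exactly two groups")
    images = rest_degree_images(spec, alpha=alpha)
    samples = [
        GroupSample(images=images[g], group_label=g, voxel_size=spec.voxel_size)
        for g in groups
    ]
    return permutation_cluster_test(samples[0], samples[1], n_perm=n_perm, seed=seed)


def recovery_experiment(
    base_spec: PhantomSpec,
    n_runs: int = 20,
    alpha: float = 1e-25,
    n_perm: int = 500,
    dice_threshold: float = 0.5,
    seed: int | None = None,
) -> dict:
    """Planted-effect recovery rate over seeded phantom replicates.

    A run succeeds when the comparison (first group minus second) yields a
    significant positive cluster whose Dice overlap with the planted
    posterior block is at least ``dice_threshold`` — i.e. the planted
    posterior connectivity reduction in the second ("aged-like") group is
    recovered as a degree-decrease cluster in the right place.
    """
    root = np.random.SeedSequence(seed)
    spec_seeds = np.random.default_rng(root).integers(2**31, size=2 * n_runs)
    planted = {tuple(v) for v in np.argwhere(base_spec.region_masks()["posterior"])}
    successes = 0
    dices = []
    for run in range(n_runs):
        spec = replace(base_spec, seed=int(spec_seeds[2 * run]))
        report = rest_degree_group_comparison(
            spec, alpha=alpha, n_perm=n_perm, seed=int(spec_seeds[2 * run + 1])
        )
        found = {
            tuple(v) for c in report.significant if c.sign > 0 for v in c.voxels
        }
        d = dice_overlap(found, planted) if found else 0.0
        dices.append(d)
        successes += d >= dice_threshold
    return {
        "recovery_rate": successes / n_runs,
        "n_runs": n_runs,
        "dice": dices,
        "mean_dice": float(np.mean(dices)),
    }


def null_effect_spec(base_spec: PhantomSpec) -> PhantomSpec:
    """Copy of a spec with every effect multiplier set to 0 (no planted
    structure anywhere)."""
    table = {g: {r: 0.0 for r in regions} for g, regions in base_spec.effect_table.items()}
    return replace(base_spec, effect_table=table)


def density_inflation_fraction(
    n_subjects: int = 20,
    grid_shape: tuple[int, int, int] = (12, 12, 6),
    alpha: float = 1e-25,
    seed: int | None = None,
) -> dict:
    """Fraction of phantom subjects whose standard-space network is denser
    than the matched native-space network at the same edge threshold.

    Uses the resting-state route in both spaces; the double interpolation of
    the normalize-then-resample round trip induces spatial correlations that
    inflate density.
    """
    half = max(1, n_subjects // 2)
    spec = PhantomSpec(
        grid_shape=grid_shape,
        group_sizes={"g1": half, "g2": n_subjects - half},
        effect_table={
            "g1": {"posterior": 1.0, "anterior": 0.35},
            "g2": {"posterior": 0.35, "anterior": 1.0},
        },
        seed=0 if seed is None else int(seed),
    )
    cohort = generate_cohort(spec)
    r_crit = None
    higher = 0
    pairs = []
    for subj in cohort:
        sessions = [
            highpass_filter(trim_volume(s, 4, 4), 1.0 / 42.88) for s in subj.sessions
        ]
        rest = concatenate_sessions(sessions)
        if r_crit is None:
            r_crit = alpha_to_r(alpha, rest.n_timepoints)
        warped = normalize_then_resample(rest, subj.affine)
        wmask = resample_labels(subj.tissue_mask, subj.affine)
        inc_nat = apply_tissue_mask(rest, subj.tissue_mask, ("gm", "wm"))
        inc_std = apply_tissue_mask(warped, wmask, ("gm", "wm"))
        d_nat = network_density(
            build_network(correlation_matrix(rest, inc_nat), r_crit, inc_nat,
                          grid_shape=grid_shape)
        )
        d_std = network_density(
            build_network(correlation_matrix(warped, inc_std), r_crit, inc_std,
                          grid_shape=grid_shape)
        )
        pairs.append((d_nat, d_std))
        higher += d_std > d_nat
    return {
        "fraction_denser": higher / len(cohort),
        "n_subjects": len(cohort),
        "densities": pairs,
        "r_crit": r_crit,
    }
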