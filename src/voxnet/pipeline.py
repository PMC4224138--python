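"""End-to-end pipeline: phantom -> prep -> networks -> metrics -> statistics.

Orchestrates the full analysis for each group pair, space, and correlation
threshold, writing NIfTI/CSV artifacts plus a JSON manifest of every
parameter and seed. Reruns with an identical config are bit-reproducible:
all randomness flows from one master seed, expanded deterministically per
stage.

By construction the "standard" grid here has the same voxel counts as the
native grid (the spatially normalized volumes are resampled back to the
acquisition resolution), so native- and standard-space images can be
compared voxel for voxel without a further resampling step.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    AtlasLabels,
    dice_overlap,
    regional_summary,
    t_image_correlation,
)
from .metrics import (
    FragmentedNetworkError,
    MetricImage,
    metric_map,
    save_metric_image,
    z_normalize,
)
from .network import alpha_to_r, build_network, correlation_matrix, network_density, prune_components
from .phantom import PhantomSpec, block_atlas, generate_cohort
from .prep import (
    NATIVE,
    STANDARD,
    apply_tissue_mask,
    average_trials,
    concatenate_sessions,
    highpass_filter,
    normalize_then_resample,
    resample_labels,
    trim_volume,
)
from .stats import GroupSample, impute_missing, permutation_cluster_test

def _maybe_path(source):
    """Treat ``source`` as a filesystem path when it plausibly is one."""
    from pathlib import Path

    if isinstance(source, Path):
        return source
    s = str(source)
    if "\n" not in s and len(s) < 4096:
        p = Path(s)
        try:
            if p.exists():
                return p
        except OSError:
            return None
    return None


#: measures dropped for a subject whose network is fragmented
FRAGMENT_SENSITIVE = {"clustering", "pathlength"}

DEFAULT_ALPHAS = {
    "task": [1e-2, 1e-3, 1e-5],
    "rest": [1e-25, 1e-38, 1e-58],
}


@dataclass
class PipelineConfig:
    """Serializable parameterization of a full pipeline run."""

    out_dir: str = "voxnet_out"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    flavors: tuple[str, ...] = ("task", "rest")
    space_mode: str = "both"  # native | standard | both
    alphas: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ALPHAS.items()})
    trim_head: int = 4
    trim_tail: int = 4
    cutoff_hz: float = 1.0 / 42.88
    major_fraction: float = 0.75
    measures: tuple[str, ...] = ("degree", "clustering", "pathlength", "localeff")
    t_thresh: float = 3.0
    n_perm: int = 10000
    cluster_alpha: float = 0.05
    connectivity: int = 26
    presence_fraction: float = 0.9
    impute: bool = True
    radius_mm: float = 10.0
    n_samples: int = 5
    min_present: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.space_mode not in (NATIVE, STANDARD, "both"):
            raise ValueError("space_mode must be native, standard, or both")
        for flavor in self.flavors:
            if flavor not in ("task", "rest"):
                raise ValueError(f"unknown flavor {flavor!r}")
            for a in self.alphas.get(flavor, []):
                if not 0 < a < 1:
                    raise ValueError(f"alpha {a} outside (0, 1)")
        if self.trim_head < 0 or self.trim_tail < 0:
            raise ValueError("trim counts must be non-negative")
        if not 0 < self.major_fraction <= 1:
            raise ValueError("major_fraction must lie in (0, 1]")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must lie in (0, 1]")
        if self.t_thresh <= 0:
            raise ValueError("t_thresh must be positive")

    @property
    def spaces(self) -> tuple[str, ...]:
        return (NATIVE, STANDARD) if self.space_mode == "both" else (self.space_mode,)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["phantom"] = yaml.safe_load(self.phantom.to_yaml())
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        p = _maybe_path(source)
        text = p.read_text() if p is not None else str(source)
        d = yaml.safe_load(text)
        if "phantom" in d:
            d["phantom"] = PhantomSpec.from_yaml(
                yaml.safe_dump(d["phantom"], sort_keys=False)
            )
        for key in ("flavors", "measures"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _prepare_subject(subj, config: PipelineConfig) -> dict:
    """Trim, filter, and assemble task/rest volumes in the requested spaces."""
    sessions = []
    for sess in subj.sessions:
        v = trim_volume(sess, config.trim_head, config.trim_tail)
        sessions.append(highpass_filter(v, config.cutoff_hz))
    rest = concatenate_sessions(sessions)
    spec = config.phantom
    per_session = [o - config.trim_head for o in spec.trial_onsets()]
    sess_len = sessions[0].n_timepoints
    onsets = [
        s * sess_len + o for s in range(len(sessions)) for o in per_session
    ]
    task = average_trials(rest, onsets, spec.trial_len)
    out = {"volumes": {}, "included": {}}
    for flavor, vol in (("task", task), ("rest", rest)):
        if flavor not in config.flavors:
            continue
        if NATIVE in config.spaces:
            out["volumes"][(flavor, NATIVE)] = vol
            out["included"][(flavor, NATIVE)] = apply_tissue_mask(
                vol, subj.tissue_mask, ("gm", "wm")
            )
        if STANDARD in config.spaces:
            warped = normalize_then_resample(vol, subj.affine)
            wmask = resample_labels(subj.tissue_mask, subj.affine)
            out["volumes"][(flavor, STANDARD)] = warped
            out["included"][(flavor, STANDARD)] = apply_tissue_mask(
                warped, wmask, ("gm", "wm")
            )
    return out


def _subject_metric_images(
    prepared: dict, subj, config: PipelineConfig
) -> tuple[dict, dict, dict]:
    """Per (flavor, space, alpha, measure): a Z-normalized MetricImage, or an
    exclusion. Returns (images, excluded, densities)."""
    images: dict = {}
    excluded: dict = {}
    densities: dict = {}
    for (flavor, space), vol in prepared["volumes"].items():
        included = prepared["included"][(flavor, space)]
        corr = correlation_matrix(vol, included)
        for alpha in config.alphas.get(flavor, []):
            r_crit = alpha_to_r(alpha, vol.n_timepoints)
            net = build_network(
                corr,
                r_crit,
                included,
                grid_shape=vol.grid_shape,
                provenance={
                    "subject": subj.subject_id,
                    "space_tag": space,
                    "alpha": alpha,
                    "r_crit": r_crit,
                },
            )
            net = prune_components(net, config.major_fraction)
            densities[(flavor, space, alpha)] = (
                network_density(net) if net.n >= 2 else 0.0
            )
            for measure in config.measures:
                key = (flavor, space, alpha, measure)
                if net.fragmented and measure in FRAGMENT_SENSITIVE:
                    excluded[key] = "fragmented"
                    continue
                if net.n == 0:
                    excluded[key] = "empty network"
                    continue
                try:
                    img = metric_map(net, measure)
                except FragmentedNetworkError:
                    excluded[key] = "fragmented"
                    continue
                try:
                    img = z_normalize(img)
                except ValueError as err:
                    excluded[key] = f"not normalizable ({err})"
                    continue
                images[key] = img
    return images, excluded, densities


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config`` and write all artifacts
    under ``config.out_dir``. Returns a result bundle with the cluster
    reports, cross-space comparison table, regional summaries and manifest.
    """
    config.validate()
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    cohort = generate_cohort(config.phantom)
    groups = sorted({s.group_label for s in cohort})

    # Per-subject metric images (correlation matrices computed once per
    # subject/flavor/space and shared across alphas).
    subj_images: dict = {}
    subj_excluded: dict = {}
    density_rows = []
    for subj in cohort:
        prepared = _prepare_subject(subj, config)
        images, excluded, densities = _subject_metric_images(prepared, subj, config)
        subj_images[subj.subject_id] = images
        subj_excluded[subj.subject_id] = excluded
        for (flavor, space, alpha), d in densities.items():
            density_rows.append(
                {
                    "subject": subj.subject_id,
                    "group": subj.group_label,
                    "flavor": flavor,
                    "space": space,
                    "alpha": alpha,
                    "density": d,
                }
            )
    density_table = pd.DataFrame(density_rows)
    density_table.to_csv(out_dir / "network_density.csv", index=False)

    # Group statistics.
    seed_root = np.random.SeedSequence(config.seed)
    reports: dict = {}
    cluster_rows = []
    grid = config.phantom.grid_shape
    by_group = {
        g: [s for s in cohort if s.group_label == g] for g in groups
    }
    analyses = [
        (flavor, space, alpha, measure, pair)
        for flavor in config.flavors
        for space in config.spaces
        for alpha in config.alphas.get(flavor, [])
        for measure in config.measures
        for pair in itertools.combinations(groups, 2)
    ]
    streams = seed_root.spawn(len(analyses))
    for stream, (flavor, space, alpha, measure, pair) in zip(streams, analyses):
        key = (flavor, space, alpha, measure)
        samples = []
        ok = True
        for glabel in pair:
            imgs, flags = [], []
            for subj in by_group[glabel]:
                img = subj_images[subj.subject_id].get(key)
                if img is None:
                    # keep a placeholder so df bookkeeping sees the exclusion
                    imgs.append(
                        MetricImage(
                            values=np.full(grid, np.nan),
                            missing_mask=np.ones(grid, dtype=bool),
                            measure=measure,
                            subject=subj.subject_id,
                            space_tag=space,
                        )
                    )
                    flags.append(True)
                else:
                    imgs.append(img)
                    flags.append(False)
            if sum(not f for f in flags) < 2:
                ok = False
            samples.append(
                GroupSample(
                    images=imgs,
                    group_label=glabel,
                    excluded=flags,
                    voxel_size=config.phantom.voxel_size,
                )
            )
        rkey = key + (pair,)
        if not ok:
            reports[rkey] = None
            continue
        rng_ints = np.random.default_rng(stream).integers(2**31, size=2)
        if config.impute and space == STANDARD:
            samples = [
                impute_missing(
                    s,
                    radius_mm=config.radius_mm,
                    n_samples=config.n_samples,
                    min_present=config.min_present,
                    seed=int(rng_ints[0]) + i,
                )
                for i, s in enumerate(samples)
            ]
        report = permutation_cluster_test(
            samples[0],
            samples[1],
            n_perm=config.n_perm,
            t_thresh=config.t_thresh,
            cluster_alpha=config.cluster_alpha,
            connectivity=config.connectivity,
            min_fraction=config.presence_fraction,
            seed=int(rng_ints[1]),
        )
        reports[rkey] = report
        _write_report(out_dir, rkey, report, config)
        for c in report.clusters:
            cluster_rows.append(
                {
                    "flavor": flavor,
                    "space": space,
                    "alpha": alpha,
                    "measure": measure,
                    "pair": f"{pair[0]}_vs_{pair[1]}",
                    "sign": c.sign,
                    "size": c.size,
                    "p_fwer": report.cluster_p(c.size),
                    "significant": c.size >= report.size_threshold,
                }
            )
    pd.DataFrame(cluster_rows).to_csv(out_dir / "clusters.csv", index=False)

    comparison_table = _cross_space_comparisons(reports, config)
    comparison_table.to_csv(out_dir / "cross_space.csv", index=False)
    regional = _regional_tables(reports, config)
    regional.to_csv(out_dir / "regional_summary.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
        "groups": {g: len(v) for g, v in by_group.items()},
        "analyses": len(analyses),
        "excluded": {
            sid: {" / ".join(map(str, k)): v for k, v in ex.items()}
            for sid, ex in subj_excluded.items()
            if ex
        },
        "runtime_s": round(time.time() - t0, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "reports": reports,
        "clusters": pd.DataFrame(cluster_rows),
        "cross_space": comparison_table,
        "regional": regional,
        "density": density_table,
        "manifest": manifest,
    }


def _write_report(out_dir: Path, rkey, report, config: PipelineConfig) -> None:
    flavor, space, alpha, measure, pair = rkey
    tag = f"{flavor}_{space}_a{alpha:g}_{measure}_{pair[0]}-{pair[1]}"
    import nibabel as nib

    vox = config.phantom.voxel_size
    aff = np.diag(list(vox) + [1.0])
    nib.save(
        nib.Nifti1Image(np.asarray(report.t_image, dtype=np.float32), aff),
        str(out_dir / f"tmap_{tag}.nii.gz"),
    )
    labels = np.zeros(report.t_image.shape, dtype=np.int16)
    for i, c in enumerate(report.significant, start=1):
        labels[tuple(c.voxels.T)] = i * c.sign
    nib.save(
        nib.Nifti1Image(labels, aff), str(out_dir / f"sigclusters_{tag}.nii.gz")
    )


def _cross_space_comparisons(reports: dict, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    if config.space_mode != "both":
        return pd.DataFrame(rows)
    for rkey, rep_nat in reports.items():
        flavor, space, alpha, measure, pair = rkey
        if space != NATIVE or rep_nat is None:
            continue
        rep_std = reports.get((flavor, STANDARD, alpha, measure, pair))
        if rep_std is None:
            continue
        both_defined = (
            np.isfinite(rep_nat.t_image).sum() >= 3
            and np.isfinite(rep_std.t_image).sum() >= 3
        )
        try:
            r = (
                t_image_correlation(rep_nat.t_image, rep_std.t_image)
                if both_defined
                else np.nan
            )
        except ValueError:
            r = np.nan
        import warnings as _w

        sets_nat = rep_nat.significant_voxel_sets()
        sets_std = rep_std.significant_voxel_sets()
        all_nat = sets_nat["increase"] | sets_nat["decrease"]
        all_std = sets_std["increase"] | sets_std["decrease"]
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            dice = dice_overlap(all_nat, all_std)
        rows.append(
            {
                "flavor": flavor,
                "alpha": alpha,
                "measure": measure,
                "pair": f"{pair[0]}_vs_{pair[1]}",
                "t_correlation": r,
                "dice": dice,
                "n_sig_native": len(all_nat),
                "n_sig_standard": len(all_std),
            }
        )
    return pd.DataFrame(rows)


def _regional_tables(reports: dict, config: PipelineConfig) -> pd.DataFrame:
    atlas = AtlasLabels(labels=block_atlas(config.phantom.grid_shape))
    frames = []
    keys_by_test: dict = {}
    for rkey, rep in reports.items():
        if rep is None:
            continue
        flavor, space, alpha, measure, pair = rkey
        keys_by_test.setdefault((flavor, space, measure, pair), []).append(
            (alpha, rep)
        )
    for (flavor, space, measure, pair), items in keys_by_test.items():
        sig_sets = [rep.significant_voxel_sets() for _, rep in items]
        # Figure-style summary pools significant voxels across thresholds;
        # the "at least two thresholds" consistency sets are also recorded.
        union = {
            "increase": set().union(*(s["increase"] for s in sig_sets)),
            "decrease": set().union(*(s["decrease"] for s in sig_sets)),
        }
        table = regional_summary(union, atlas)
        table.insert(0, "flavor", flavor)
        table.insert(1, "space", space)
        table.insert(2, "measure", measure)
        table.insert(3, "pair", f"{pair[0]}_vs_{pair[1]}")
        frames.append(table)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
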