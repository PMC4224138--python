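"""Synthetic phantom cohorts for voxelwise network analysis.

The generator emulates the acquisition and cohort structure the analysis
assumes — 64x64x16 grids of 3.75x3.75x8 mm voxels, TR 2.68 s, four
sessions of 128 acquisitions, 15 trials of 8 acquisitions per session with
linearly summating haemodynamic responses — and plants a posterior-anterior
connectivity shift: "aged-like" groups get a reduced connectivity
multiplier in a posterior voxel block and an increased one in an anterior
block.

Signal model per voxel, per session::

    y(t) = baseline
         + m_region * (shared_amp * S_region(t) + coherence_amp * C_sub(t))
         + background_amp * B(t)          (brain voxels)
         + noise_sd * eps(t)

``S_region`` mixes the task response (HRF-convolved stimulus train) with a
slow region-wide fluctuation; ``C_sub`` is a slow fluctuation shared by a
contiguous sub-block, which keeps every block voxel connected even when the
group multiplier ``m_region`` is small — the multiplier then controls how
strongly sub-blocks bind together, i.e. node degree. A multiplier of 0
removes the block structure entirely, leaving pure noise.

Blocks are contiguous voxel boxes rather than anatomy: sufficient for
parameter-recovery experiments, not for realism.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import yaml
from scipy import fft as sp_fft

from .metrics import MetricImage
from .network import FunctionalNetwork
from .prep import (
    DEFAULT_LEGEND,
    NATIVE,
    BoldVolume,
    TissueMask,
    save_bold,
    save_mask,
)


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


def _rotation_z(degrees: float, center: np.ndarray) -> np.ndarray:
    th = math.radians(degrees)
    R = np.eye(4)
    R[0, 0] = math.cos(th)
    R[0, 1] = -math.sin(th)
    R[1, 0] = math.sin(th)
    R[1, 1] = math.cos(th)
    shift = np.eye(4)
    shift[:3, 3] = -center
    unshift = np.eye(4)
    unshift[:3, 3] = center
    return unshift @ R @ shift


def default_affine(grid_shape=(64, 64, 16)) -> np.ndarray:
    """A known, mildly non-trivial native-to-standard voxel affine:
    a 3 degree in-plane rotation about the grid centre plus a sub-voxel
    translation."""
    center = (np.asarray(grid_shape, dtype=float) - 1) / 2.0
    A = _rotation_z(3.0, center)
    A[:3, 3] += np.array([0.6, 0.4, 0.3])
    return A


@dataclass
class HRFParams:
    """Double-gamma haemodynamic response parameters (seconds)."""

    peak_delay: float = 5.0
    dispersion: float = 1.0
    undershoot_delay: float = 15.0
    undershoot_ratio: float = 1.0 / 6.0

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak response evaluated at times ``t`` (zero for t < 0)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]

        def gamma_pdf(x, mode):
            shape = mode / self.dispersion + 1.0
            scale = self.dispersion
            return (
                x ** (shape - 1)
                * np.exp(-x / scale)
                / (math.gamma(shape) * scale ** shape)
            )

        out[pos] = gamma_pdf(tp, self.peak_delay) - self.undershoot_ratio * gamma_pdf(
            tp, self.undershoot_delay
        )
        fine = np.linspace(1e-3, self.undershoot_delay + 20, 4000)
        peak = (
            gamma_pdf(fine, self.peak_delay)
            - self.undershoot_ratio * gamma_pdf(fine, self.undershoot_delay)
        ).max()
        return out / peak


def hrf_response(
    stim_onsets, n_acq: int, tr: float, hrf_params: HRFParams | None = None
) -> np.ndarray:
    """Linearly summating haemodynamic response sampled at the TR.

    Each stimulus contributes one fixed unit-peak response shifted to its
    onset (seconds); the response to several stimuli is exactly the sum of
    the responses to each alone. An empty onset list gives an all-zero
    signal.
    """
    if n_acq < 1:
        raise ValueError("n_acq must be positive")
    if tr <= 0:
        raise ValueError("tr must be positive")
    hrf = hrf_params or HRFParams()
    times = np.arange(n_acq) * tr
    signal = np.zeros(n_acq)
    for onset in stim_onsets:
        onset = float(onset)
        if onset < 0:
            raise ValueError("stimulus onsets must be non-negative")
        if onset >= n_acq * tr:
            raise ValueError("stimulus onset beyond the recording window")
        signal = signal + hrf.kernel(times - onset)
    return signal


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic cohort.

    ``effect_table`` maps group label -> region -> connectivity amplitude
    multiplier. The defaults plant the posterior-anterior shift: relative to
    the young group, aged-like groups have a reduced posterior multiplier
    and an increased anterior one, with the AD-like group accentuating both.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (3.75, 3.75, 8.0)
    tr: float = 2.68
    n_sessions: int = 4
    images_per_session: int = 128
    trials_per_session: int = 15
    trial_len: int = 8
    first_trial_offset: int = 4  # acquisitions before the first trial
    group_sizes: dict = field(
        default_factory=lambda: {"young": 14, "aged": 14, "aged_ad": 11}
    )
    effect_table: dict = field(
        default_factory=lambda: {
            "young": {"posterior": 1.0, "anterior": 0.35},
            "aged": {"posterior": 0.35, "anterior": 1.0},
            "aged_ad": {"posterior": 0.2, "anterior": 1.15},
        }
    )
    noise_sd: float = 1.0
    shared_amp: float = 2.4
    coherence_amp: float = 2.0
    background_amp: float = 0.25
    baseline: float = 100.0
    n_subblocks: int = 4
    two_stim_fraction: float = 0.5
    stim_gap_acq: int = 2  # second stimulus follows the first by 2 acquisitions
    hrf: HRFParams = field(default_factory=HRFParams)
    affine: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if self.affine is None:
            self.affine = default_affine(self.grid_shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ValueError("grid_shape must be three counts of at least 2")
        for name in (
            "tr", "n_sessions", "images_per_session", "trials_per_session",
            "trial_len", "noise_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trial_len * self.trials_per_session > self.images_per_session:
            raise ValueError("trials do not fit in a session")
        if (
            self.first_trial_offset + self.trial_len * self.trials_per_session
            > self.images_per_session
        ):
            raise ValueError("trials overrun the session given the first-trial offset")
        if len(self.group_sizes) < 2:
            raise ValueError("need at least 2 groups")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for g in self.group_sizes:
            if g not in self.effect_table:
                raise ValueError(f"group {g!r} missing from effect_table")

    # -- geometry ----------------------------------------------------------

    def trial_onsets(self) -> list[int]:
        """Acquisition index of each trial onset within one raw session."""
        return [
            self.first_trial_offset + k * self.trial_len
            for k in range(self.trials_per_session)
        ]

    def region_masks(self) -> dict[str, np.ndarray]:
        """Planted posterior/anterior blocks as boolean masks (fractional
        boxes on the grid; posterior = low y, anterior = high y)."""
        nx_, ny_, nz_ = self.grid_shape

        def box(xf, yf, zf):
            m = np.zeros(self.grid_shape, dtype=bool)
            xs = slice(max(0, round(xf[0] * nx_)), max(1, round(xf[1] * nx_)))
            ys = slice(max(0, round(yf[0] * ny_)), max(1, round(yf[1] * ny_)))
            zs = slice(max(0, round(zf[0] * nz_)), max(1, round(zf[1] * nz_)))
            m[xs, ys, zs] = True
            return m

        return {
            "posterior": box((0.30, 0.70), (0.10, 0.35), (0.25, 0.75)),
            "anterior": box((0.30, 0.70), (0.65, 0.90), (0.25, 0.75)),
        }

    def subblock_labels(self, region_mask: np.ndarray) -> np.ndarray:
        """Split a block into ``n_subblocks`` contiguous slabs along x;
        returns an int array with 0 outside the block and 1..n inside."""
        out = np.zeros(self.grid_shape, dtype=int)
        xs = np.unique(np.argwhere(region_mask)[:, 0])
        slabs = np.array_split(xs, self.n_subblocks)
        for i, slab in enumerate(slabs, start=1):
            for x in slab:
                out[x][region_mask[x]] = i
        return out

    def tissue_mask(self) -> TissueMask:
        """Synthetic brain: a grey-matter ellipsoid with a white-matter core
        and a small CSF pocket; planted blocks are forced to grey matter."""
        grid = np.indices(self.grid_shape, dtype=float)
        center = (np.asarray(self.grid_shape) - 1) / 2.0
        semi = np.asarray(self.grid_shape) * 0.45
        d2 = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
        labels = np.zeros(self.grid_shape, dtype=np.int16)
        labels[d2 <= 1.0] = 2  # GM
        labels[d2 <= 0.12] = 3  # WM core
        labels[d2 <= 0.02] = 1  # CSF pocket
        for mask in self.region_masks().values():
            labels[mask] = 2
        return TissueMask(labels=labels, legend=dict(DEFAULT_LEGEND))

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["affine"] = np.asarray(self.affine).tolist()
        d["hrf"] = asdict(self.hrf)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PhantomSpec":
        p = _maybe_path(source)
        text = p.read_text() if p is not None else str(source)
        d = yaml.safe_load(text)
        if "hrf" in d:
            d["hrf"] = HRFParams(**d["hrf"])
        if d.get("affine") is not None:
            d["affine"] = np.asarray(d["affine"], dtype=float)
        for key in ("grid_shape", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SubjectRecording:
    """One subject's raw sessions plus mask, group label and affine."""

    subject_id: str
    group_label: str
    sessions: list[BoldVolume]
    tissue_mask: TissueMask
    affine: np.ndarray

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("subject has no sessions")
        shape = self.sessions[0].grid_shape
        tr = self.sessions[0].tr
        for s in self.sessions:
            if s.grid_shape != shape or s.tr != tr:
                raise ValueError("sessions disagree on grid or TR")
        if self.tissue_mask.grid_shape != shape:
            raise ValueError("tissue mask grid does not match sessions")


def _slow_latent(
    rng: np.random.Generator,
    n: int,
    tr: float,
    f_lo: float = 0.025,
    f_hi: float = 0.10,
) -> np.ndarray:
    """Unit-SD resting fluctuation band-limited to [f_lo, f_hi] Hz.

    Built from random DCT coefficients restricted to the band, so the
    fluctuation occupies the low-frequency range typical of resting-state
    signal while sitting safely above the analysis high-pass cutoff.
    """
    freqs = np.arange(n) / (2.0 * n * tr)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any():  # degenerate short series: fall back to white noise
        x = rng.standard_normal(n)
        return x / x.std()
    coeffs = np.zeros(n)
    coeffs[band] = rng.standard_normal(int(band.sum()))
    x = sp_fft.idct(coeffs, type=2, norm="ortho")
    return x / x.std()


def _session_task_regressor(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    onsets_acq = spec.trial_onsets()
    onsets_s: list[float] = []
    for o in onsets_acq:
        onsets_s.append(o * spec.tr)
        if rng.random() < spec.two_stim_fraction:
            onsets_s.append((o + spec.stim_gap_acq) * spec.tr)
    d = hrf_response(onsets_s, spec.images_per_session, spec.tr, spec.hrf)
    sd = d.std()
    return d / sd if sd > 0 else d


def generate_subject(
    spec: PhantomSpec, group: str, rng: np.random.Generator, subject_id: str
) -> SubjectRecording:
    regions = spec.region_masks()
    sub_labels = {r: spec.subblock_labels(m) for r, m in regions.items()}
    mask = spec.tissue_mask()
    brain = mask.binary({"gm", "wm", "csf"})
    nt = spec.images_per_session
    sessions = []
    for _ in range(spec.n_sessions):
        data = spec.noise_sd * rng.standard_normal(spec.grid_shape + (nt,))
        data = data.astype(np.float32)
        background = spec.background_amp * _slow_latent(rng, nt, spec.tr)
        data[brain] += background.astype(np.float32)
        task = _session_task_regressor(spec, rng)
        for region, rmask in regions.items():
            m = float(spec.effect_table[group].get(region, 0.0))
            shared = math.sqrt(0.5) * (task + _slow_latent(rng, nt, spec.tr))
            labs = sub_labels[region]
            for s in range(1, spec.n_subblocks + 1):
                coher = _slow_latent(rng, nt, spec.tr)
                smask = labs == s
                if not smask.any():
                    continue
                contrib = m * (
                    spec.shared_amp * shared + spec.coherence_amp * coher
                )
                data[smask] += contrib.astype(np.float32)
        data += np.float32(spec.baseline)
        sessions.append(
            BoldVolume(
                data=data,
                voxel_size=spec.voxel_size,
                tr=spec.tr,
                space_tag=NATIVE,
                affine=spec.affine,
            )
        )
    return SubjectRecording(
        subject_id=subject_id,
        group_label=group,
        sessions=sessions,
        tissue_mask=mask,
        affine=np.asarray(spec.affine, dtype=float),
    )


def generate_cohort(spec: PhantomSpec) -> list[SubjectRecording]:
    """Generate every subject of the cohort; identical specs (including the
    seed) produce bit-identical cohorts."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    subjects = []
    streams = root.spawn(sum(spec.group_sizes.values()))
    i = 0
    for group, size in spec.group_sizes.items():
        for k in range(size):
            rng = np.random.default_rng(streams[i])
            subjects.append(
                generate_subject(spec, group, rng, f"{group}_{k:02d}")
            )
            i += 1
    return subjects


def generate_null_metric_images(
    n_per_group: tuple[int, int],
    grid_shape: tuple[int, int, int],
    seed: int | None = None,
    measure: str = "degree",
) -> tuple[list[MetricImage], list[MetricImage]]:
    """Two groups of i.i.d. standard-Gaussian metric images with no group
    difference by construction (for type-I-error experiments)."""
    n1, n2 = int(n_per_group[0]), int(n_per_group[1])
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    none_missing = np.zeros(grid_shape, dtype=bool)

    def draw(group, count):
        return [
            MetricImage(
                values=rng.standard_normal(grid_shape),
                missing_mask=none_missing,
                measure=measure,
                subject=f"{group}_{i:02d}",
            )
            for i in range(count)
        ]

    return draw("g1", n1), draw("g2", n2)


# ---------------------------------------------------------------------------
# toy graph fixtures
# ---------------------------------------------------------------------------


def toy_graph(name: str) -> FunctionalNetwork:
    """Deterministic named graph fixtures on synthetic voxel coordinates.

    Recognized names: ``K<n>`` (complete), ``path<n>``, ``ring<n>``,
    ``star<n>`` (a centre plus n leaves), ``triangle``,
    ``two_components_<a>_<b>`` (two disjoint rings), and ``er<n>_<p%>``
    (seeded Erdos-Renyi, p in percent).
    """
    import re

    if name == "triangle":
        return FunctionalNetwork.from_graph(nx.cycle_graph(3))
    m = re.fullmatch(r"K(\d+)", name)
    if m:
        return FunctionalNetwork.from_graph(nx.complete_graph(int(m.group(1))))
    m = re.fullmatch(r"path(\d+)", name)
    if m:
        return FunctionalNetwork.from_graph(nx.path_graph(int(m.group(1))))
    m = re.fullmatch(r"ring(\d+)", name)
    if m:
        return FunctionalNetwork.from_graph(nx.cycle_graph(int(m.group(1))))
    m = re.fullmatch(r"star(\d+)", name)
    if m:
        return FunctionalNetwork.from_graph(nx.star_graph(int(m.group(1))))
    m = re.fullmatch(r"two_components_(\d+)_(\d+)", name)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        g = nx.disjoint_union(nx.cycle_graph(a), nx.cycle_graph(b))
        return FunctionalNetwork.from_graph(g)
    m = re.fullmatch(r"er(\d+)_(\d+)", name)
    if m:
        n, pct = int(m.group(1)), int(m.group(2))
        g = nx.gnp_random_graph(n, pct / 100.0, seed=0)
        return FunctionalNetwork.from_graph(g)
    raise ValueError(f"unknown toy graph {name!r}")


def block_atlas(grid_shape, splits=(2, 2, 1)) -> "np.ndarray":
    """Synthetic integer atlas partitioning the grid into labelled boxes
    (label 0 is background-free here: every voxel belongs to a region)."""
    labels = np.zeros(grid_shape, dtype=np.int16)
    xs = np.array_split(np.arange(grid_shape[0]), splits[0])
    ys = np.array_split(np.arange(grid_shape[1]), splits[1])
    zs = np.array_split(np.arange(grid_shape[2]), splits[2])
    lab = 1
    for xb in xs:
        for yb in ys:
            for zb in zs:
                labels[np.ix_(xb, yb, zb)] = lab
                lab += 1
    return labels


# ---------------------------------------------------------------------------
# cohort on disk
# ---------------------------------------------------------------------------


def write_cohort(spec: PhantomSpec, out_dir) -> Path:
    """Write a cohort as NIfTI volumes plus a subject table CSV; returns the
    path of the table. Subjects are generated and written one at a time."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec.to_yaml(out / "phantom_spec.yaml")
    np.savetxt(out / "native_to_standard.txt", spec.affine)
    rows = []
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(sum(spec.group_sizes.values()))
    i = 0
    for group, size in spec.group_sizes.items():
        for k in range(size):
            rng = np.random.default_rng(streams[i])
            subj = generate_subject(spec, group, rng, f"{group}_{k:02d}")
            sdir = out / subj.subject_id
            sdir.mkdir(exist_ok=True)
            paths = []
            for snum, sess in enumerate(subj.sessions):
                p = sdir / f"session_{snum}.nii.gz"
                save_bold(sess, p)
                paths.append(p)
            mask_path = sdir / "tissue_mask.nii.gz"
            save_mask(subj.tissue_mask, mask_path, spec.voxel_size)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": group,
                    "mask": str(mask_path),
                    "sessions": ";".join(str(p) for p in paths),
                }
            )
            i += 1
    table = out / "subjects.csv"
    with open(table, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return table
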