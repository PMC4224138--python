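"""Voxelwise two-group comparison with permutation cluster-size FWER control.

The procedure, applied to per-subject metric images of one measure:

1. optionally impute missing voxels by *mean replacement by random neighbor
   selection* (standard-space images only);
2. presence filtering: a voxel enters the test only if at least 90% of the
   subjects in *each* group carry a value there;
3. a pooled-variance two-sample t image over included voxels, with degrees
   of freedom adjusted for excluded subjects;
4. cluster forming at ``|t| >= 3.0`` (26-neighbourhood, both signs) and a
   null distribution of the *maximal* cluster size over random permutations
   of group labels; clusters whose size reaches the top ``alpha`` tail of
   that distribution are familywise significant.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .metrics import MetricImage
from .prep import STANDARD


@dataclass
class GroupSample:
    """A group of per-subject metric images entering one statistical test.

    ``excluded`` marks subjects dropped for this measure (e.g. fragmented
    networks for path length); excluded subjects carry no values into tests
    and reduce the degrees of freedom.
    """

    images: list[MetricImage]
    group_label: str = ""
    excluded: list[bool] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (3.75, 3.75, 8.0)

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("group has no images")
        shape = self.images[0].grid_shape
        measure = self.images[0].measure
        for img in self.images[1:]:
            if img.grid_shape != shape:
                raise ValueError("images do not share a grid")
            if img.measure != measure:
                raise ValueError("images mix measures")
        if not self.excluded:
            self.excluded = [False] * len(self.images)
        if len(self.excluded) != len(self.images):
            raise ValueError("excluded flags do not match image count")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.images[0].grid_shape

    @property
    def measure(self) -> str:
        return self.images[0].measure

    @property
    def space_tag(self) -> str:
        return self.images[0].space_tag

    def active_images(self) -> list[MetricImage]:
        return [img for img, ex in zip(self.images, self.excluded) if not ex]

    def stacked(self) -> np.ndarray:
        """(n_active, x, y, z) array with NaN at missing voxels."""
        active = self.active_images()
        if not active:
            raise ValueError("all subjects excluded")
        return np.stack([img.values for img in active], axis=0)


def presence_filter(
    s1: GroupSample, s2: GroupSample, min_fraction: float = 0.9
) -> np.ndarray:
    """Boolean mask of voxels with a value in >= ``min_fraction`` of the
    (non-excluded) subjects of *both* groups."""
    if s1.grid_shape != s2.grid_shape:
        raise ValueError("groups do not share a grid")
    out = np.ones(s1.grid_shape, dtype=bool)
    for s in (s1, s2):
        x = s.stacked()
        frac = (~np.isnan(x)).sum(axis=0) / x.shape[0]
        out &= frac >= min_fraction - 1e-12
    return out


def _sphere_offsets(radius_mm: float, voxel_size: Sequence[float]) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float)
    lim = np.floor(radius_mm / vs).astype(int)
    offs = []
    for dx in range(-lim[0], lim[0] + 1):
        for dy in range(-lim[1], lim[1] + 1):
            for dz in range(-lim[2], lim[2] + 1):
                if np.linalg.norm(np.array([dx, dy, dz]) * vs) <= radius_mm:
                    offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=int)


def impute_missing(
    s: GroupSample,
    radius_mm: float = 10.0,
    n_samples: int = 5,
    min_present: float = 0.9,
    seed: int | None = None,
) -> GroupSample:
    """Mean replacement by random neighbor selection, within one group.

    For each missing voxel of each subject, up to ``n_samples`` candidate
    (other-subject, voxel) pairs are drawn uniformly without replacement
    from the sphere of ``radius_mm`` (world coordinates) centred at the
    missing voxel, over the images of all *other* subjects in the group.
    If the fraction of drawn candidates that hold a value is at least
    ``min_present`` the missing value is replaced by the mean of the drawn
    present values; otherwise it stays missing. Non-missing values are
    never altered, and candidate values are always read from the original
    (pre-imputation) images.
    """
    if s.space_tag != STANDARD:
        raise ValueError("imputation applies to standard-space images only")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    active_idx = [i for i, ex in enumerate(s.excluded) if not ex]
    if len(active_idx) < 2:
        warnings.warn("no other subjects in group; nothing imputed", stacklevel=2)
        return replace(s, images=list(s.images))
    rng = np.random.default_rng(seed)
    offs = _sphere_offsets(radius_mm, s.voxel_size)
    shape = np.asarray(s.grid_shape)
    originals = {i: s.images[i] for i in active_idx}
    new_images = list(s.images)
    for i in active_idx:
        img = s.images[i]
        others = [j for j in active_idx if j != i]
        miss_coords = np.argwhere(img.missing_mask)
        if miss_coords.size == 0:
            continue
        values = img.values.copy()
        missing = img.missing_mask.copy()
        for vox in miss_coords:
            locs = vox[None, :] + offs
            inside = np.all((locs >= 0) & (locs < shape), axis=1)
            locs = locs[inside]
            n_cand = len(others) * len(locs)
            if n_cand == 0:
                continue
            take = min(n_samples, n_cand)
            picks = rng.choice(n_cand, size=take, replace=False)
            subj = np.array(others)[picks // len(locs)]
            where = locs[picks % len(locs)]
            vals = np.array(
                [originals[j].values[tuple(w)] for j, w in zip(subj, where)]
            )
            present = np.isfinite(vals)
            if present.sum() / take >= min_present - 1e-12:
                values[tuple(vox)] = vals[present].mean()
                missing[tuple(vox)] = False
        new_images[i] = replace(img, values=values, missing_mask=missing)
    return replace(s, images=new_images)


def _t_from_stack(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t (group1 - group2) along axis 0, NaN-aware.

    Returns (t, df) arrays over the trailing axes; voxels with fewer than 2
    values in a group or zero pooled variance come out NaN.
    """
    p1, p2 = ~np.isnan(x1), ~np.isnan(x2)
    n1, n2 = p1.sum(axis=0), p2.sum(axis=0)
    z1 = np.where(p1, x1, 0.0)
    z2 = np.where(p2, x2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = z1.sum(axis=0) / n1
        m2 = z2.sum(axis=0) / n2
        ss1 = (z1 ** 2).sum(axis=0) - n1 * m1 ** 2
        ss2 = (z2 ** 2).sum(axis=0) - n2 * m2 ** 2
        df = n1 + n2 - 2
        pooled = (ss1 + ss2) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    return t, np.where(bad, np.nan, df)


def t_map(
    s1: GroupSample, s2: GroupSample, mask: np.ndarray | None = None
) -> np.ndarray:
    """Voxelwise pooled-variance t image (group1 - group2).

    Voxels outside ``mask`` (default: the 90% presence filter) are NaN.
    Degrees of freedom follow the non-excluded subject counts; at voxels
    where some included subjects are still missing, the available values
    are used and the per-voxel df shrinks accordingly. Zero-variance voxels
    are dropped with a warning.
    """
    if mask is None:
        mask = presence_filter(s1, s2)
    x1, x2 = s1.stacked(), s2.stacked()
    t, _df = _t_from_stack(x1, x2)
    undefined = mask & np.isnan(t)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} voxel(s) dropped (undefined t)", stacklevel=2
        )
    return np.where(mask, t, np.nan)


@dataclass
class Cluster:
    sign: int
    voxels: np.ndarray  # (k, 3) coordinates
    size: int


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def clusters_from_tmap(
    t_img: np.ndarray, t_thresh: float = 3.0, connectivity: int = 26
) -> list[Cluster]:
    """Signed suprathreshold clusters of a 3D t image.

    Positive clusters are connected components of ``t >= t_thresh``,
    negative clusters of ``t <= -t_thresh``; NaN voxels never enter a
    cluster.
    """
    t_img = np.asarray(t_img, dtype=float)
    if t_img.ndim != 3:
        raise ValueError("t image must be 3D")
    struct = _structure(connectivity)
    out: list[Cluster] = []
    for sign in (+1, -1):
        with np.errstate(invalid="ignore"):
            supra = (sign * t_img) >= t_thresh
        labels, n = ndimage.label(supra, structure=struct)
        for lab in range(1, n + 1):
            voxels = np.argwhere(labels == lab)
            out.append(Cluster(sign=sign, voxels=voxels, size=voxels.shape[0]))
    out.sort(key=lambda c: -c.size)
    return out


def _max_cluster_size(
    flat_t: np.ndarray, mask_idx: tuple, shape: tuple, t_thresh: float,
    struct: np.ndarray, scratch: np.ndarray,
) -> int:
    scratch.fill(0.0)
    scratch[mask_idx] = flat_t
    best = 0
    for sign in (+1, -1):
        supra = (sign * scratch) >= t_thresh
        if not supra.any():
            continue
        labels, n = ndimage.label(supra, structure=struct)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            best = max(best, int(sizes.max()))
    return best


@dataclass
class ClusterReport:
    """Observed signed clusters, the permutation null of the maximal cluster
    size, and the familywise significance calls."""

    clusters: list[Cluster]
    null_max_sizes: np.ndarray
    size_threshold: int
    significant: list[Cluster]
    n_permutations: int
    seed: int | None
    exact: bool = False
    t_image: np.ndarray | None = None
    mask: np.ndarray | None = None

    def cluster_p(self, size: int) -> float:
        """Max-statistic familywise p-value of a cluster of ``size``."""
        null = np.asarray(self.null_max_sizes)
        return float((null >= size).sum() / null.size)

    def significant_voxel_sets(self) -> dict[str, set]:
        out = {"increase": set(), "decrease": set()}
        for c in self.significant:
            key = "increase" if c.sign > 0 else "decrease"
            out[key] |= {tuple(v) for v in c.voxels}
        return out


def permutation_cluster_test(
    s1: GroupSample,
    s2: GroupSample,
    n_perm: int = 10000,
    t_thresh: float = 3.0,
    cluster_alpha: float = 0.05,
    connectivity: int = 26,
    min_fraction: float = 0.9,
    seed: int | None = None,
) -> ClusterReport:
    """Maximal-cluster-size permutation test between two groups.

    Group labels are permuted uniformly (with replacement across
    permutations); the identity labeling is always a member of the null
    distribution, so the smallest attainable familywise p is
    ``1/n_perm``. When the number of distinct relabelings does not exceed
    ``n_perm`` the null is enumerated exactly and the result does not
    depend on the seed. A cluster is significant when the fraction of null
    maxima at least as large as its size is at most ``cluster_alpha``.
    """
    x1, x2 = s1.stacked(), s2.stacked()
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 non-excluded subjects per group")
    if x1.shape[1:] != x2.shape[1:]:
        raise ValueError("groups do not share a grid")
    mask = presence_filter(s1, s2, min_fraction)
    shape = x1.shape[1:]
    struct = _structure(connectivity)

    if not mask.any():
        # Nothing to test: every voxel failed the presence filter.
        null = np.zeros(max(n_perm, 1), dtype=int)
        t_full = np.full(shape, np.nan)
        return ClusterReport(
            clusters=[], null_max_sizes=null, size_threshold=1, significant=[],
            n_permutations=len(null), seed=seed, exact=True,
            t_image=t_full, mask=mask,
        )

    data = np.concatenate([x1, x2], axis=0)[:, mask]  # (n, V)
    n = n1 + n2
    n_distinct = math.comb(n, n1)
    exact = n_distinct <= n_perm
    if exact:
        assignments = np.zeros((n_distinct, n), dtype=bool)
        for row, combo in enumerate(itertools.combinations(range(n), n1)):
            assignments[row, list(combo)] = True
    else:
        rng = np.random.default_rng(seed)
        assignments = np.zeros((n_perm, n), dtype=bool)
        assignments[0, :n1] = True  # identity labeling
        base = np.zeros(n, dtype=bool)
        base[:n1] = True
        for row in range(1, n_perm):
            assignments[row] = rng.permutation(base)

    present = ~np.isnan(data)
    zdata = np.where(present, data, 0.0)
    sq = zdata ** 2

    mask_idx = np.nonzero(mask)
    scratch = np.zeros(shape)
    null_max = np.empty(assignments.shape[0], dtype=int)
    chunk = 200
    for start in range(0, assignments.shape[0], chunk):
        G = assignments[start : start + chunk].astype(float)  # (B, n)
        H = 1.0 - G
        c1, c2 = G @ present, H @ present
        s1v, s2v = G @ zdata, H @ zdata
        q1, q2 = G @ sq, H @ sq
        with np.errstate(divide="ignore", invalid="ignore"):
            m1, m2 = s1v / c1, s2v / c2
            ss1 = q1 - c1 * m1 ** 2
            ss2 = q2 - c2 * m2 ** 2
            df = c1 + c2 - 2
            se = np.sqrt((ss1 + ss2) / df * (1.0 / c1 + 1.0 / c2))
            tvals = (m1 - m2) / se
        tvals = np.where((c1 < 2) | (c2 < 2) | ~np.isfinite(tvals), 0.0, tvals)
        for b in range(G.shape[0]):
            null_max[start + b] = _max_cluster_size(
                tvals[b], mask_idx, shape, t_thresh, struct, scratch
            )

    # Observed t image and clusters from the identity labeling.
    t_obs, _ = _t_from_stack(x1, x2)
    t_obs = np.where(mask, t_obs, np.nan)
    clusters = clusters_from_tmap(t_obs, t_thresh, connectivity)

    # Smallest cluster size whose max-statistic p-value is <= alpha.
    n_null = null_max.size
    size_threshold = int(null_max.max()) + 1
    for s in range(1, int(null_max.max()) + 2):
        if (null_max >= s).sum() / n_null <= cluster_alpha:
            size_threshold = s
            break
    significant = [c for c in clusters if c.size >= size_threshold]
    return ClusterReport(
        clusters=clusters,
        null_max_sizes=null_max,
        size_threshold=size_threshold,
        significant=significant,
        n_permutations=n_null,
        seed=seed,
        exact=exact,
        t_image=t_obs,
        mask=mask,
    )
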