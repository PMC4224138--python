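"""Cross-space correspondence and regional summaries of significant voxels.

Used to compare results computed on the native acquisition grid with
results computed after spatial normalization: voxelwise Pearson correlation
of t images, Dice overlap of significant-voxel sets, consistency of calls
across correlation thresholds, and per-region proportions of significant
voxels against an integer atlas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DIRECTIONS = ("increase", "decrease")


def as_voxel_set(voxels) -> set[tuple[int, int, int]]:
    """Normalize a boolean mask, coordinate array, or iterable of coordinate
    triples into a set of (x, y, z) tuples."""
    if isinstance(voxels, np.ndarray) and voxels.dtype == bool:
        return {tuple(v) for v in np.argwhere(voxels)}
    return {tuple(int(c) for c in v) for v in voxels}


def t_image_correlation(t_a: np.ndarray, t_b: np.ndarray) -> float:
    """Pearson correlation between two t images over the voxels where both
    are defined (non-NaN)."""
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    if t_a.shape != t_b.shape:
        raise ValueError("t images do not share a grid")
    both = np.isfinite(t_a) & np.isfinite(t_b)
    if both.sum() < 3:
        raise ValueError("need at least 3 voxels defined in both images")
    a, b = t_a[both], t_b[both]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("zero variance in one of the t images")
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def dice_overlap(sig_a, sig_b) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) between significant-voxel sets.

    Two empty sets are defined to overlap with coefficient 0; a warning is
    emitted to flag the degenerate case.
    """
    a, b = as_voxel_set(sig_a), as_voxel_set(sig_b)
    if not a and not b:
        warnings.warn("both voxel sets empty; Dice defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


@dataclass
class AtlasLabels:
    """3D integer atlas with a label -> region-name map."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer typed")
        present = {int(v) for v in np.unique(self.labels) if v != 0}
        unnamed = present - set(self.names)
        if unnamed:
            self.names = dict(self.names)
            for lab in sorted(unnamed):
                self.names[lab] = f"region_{lab}"

    @property
    def region_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v != 0}


def regional_summary(
    significant: Mapping[str, Iterable], atlas: AtlasLabels
) -> pd.DataFrame:
    """Per-region proportion of significant voxels, normalized by region
    size, separately for each direction of change.

    ``significant`` maps a direction name (``"increase"``/``"decrease"`` in
    the first group relative to the second) to a voxel set / boolean mask.
    """
    sizes = atlas.region_sizes
    rows = []
    sets = {d: as_voxel_set(v) for d, v in significant.items()}
    for lab, size in sorted(sizes.items()):
        region_vox = as_voxel_set(atlas.labels == lab)
        for direction in DIRECTIONS:
            hits = len(region_vox & sets.get(direction, set()))
            rows.append(
                {
                    "region_id": lab,
                    "region_name": atlas.names.get(lab, str(lab)),
                    "direction": direction,
                    "n_significant": hits,
                    "region_size": size,
                    "proportion": hits / size,
                }
            )
    return pd.DataFrame(rows)


def consistency_mask(
    sig_by_threshold: Sequence[Mapping[str, Iterable]], min_count: int = 2
) -> dict[str, set]:
    """Voxels significant in the same direction at >= ``min_count`` of the
    per-threshold results."""
    if len(sig_by_threshold) < 2:
        raise ValueError("need results for at least 2 thresholds")
    out: dict[str, set] = {}
    for direction in DIRECTIONS:
        counts: dict[tuple, int] = {}
        for result in sig_by_threshold:
            for vox in as_voxel_set(result.get(direction, set())):
                counts[vox] = counts.get(vox, 0) + 1
        out[direction] = {v for v, c in counts.items() if c >= min_count}
    return out
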