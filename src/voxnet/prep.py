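"""Temporal and spatial preparation of 4D BOLD volumes.

This module covers the deterministic preprocessing that sits between raw
4D acquisitions and network construction: discarding edge acquisitions,
high-pass temporal filtering, trial averaging (event-related designs with
linearly summating responses), session concatenation, tissue masking, and
the "normalize then resample" round trip used to study the effect of
spatial-normalization order on downstream network density.

Head-motion correction, slice timing, tissue segmentation and template
registration are out of scope: inputs are assumed already corrected, and
synthetic data (see :mod:`voxnet.phantom`) carries known masks and a known
native-to-standard affine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

NATIVE = "native"
STANDARD = "standard"

#: canonical tissue legend used throughout the package
DEFAULT_LEGEND = {0: "background", 1: "csf", 2: "gm", 3: "wm"}


def _identity_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class BoldVolume:
    """A 4D BOLD signal volume with grid geometry and affine provenance.

    Parameters
    ----------
    data:
        ``(x, y, z, t)`` signal array.
    voxel_size:
        Voxel edge lengths in millimetres per axis.
    tr:
        Repetition time (seconds between successive whole-volume
        acquisitions).
    space_tag:
        ``"native"`` (acquisition grid) or ``"standard"`` (template grid).
    affine:
        4x4 matrix mapping native voxel coordinates to standard voxel
        coordinates. Must be invertible.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.75, 3.75, 8.0)
    tr: float = 2.68
    space_tag: str = NATIVE
    affine: np.ndarray = field(default_factory=_identity_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.data.shape[-1] < 1:
            raise ValueError("volume must contain at least one time point")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.space_tag not in (NATIVE, STANDARD):
            raise ValueError(f"space_tag must be {NATIVE!r} or {STANDARD!r}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def with_data(self, data: np.ndarray, **overrides) -> "BoldVolume":
        kwargs = dict(
            voxel_size=self.voxel_size,
            tr=self.tr,
            space_tag=self.space_tag,
            affine=self.affine,
        )
        kwargs.update(overrides)
        return BoldVolume(data=data, **kwargs)


@dataclass
class TissueMask:
    """3D integer tissue-label volume with a label legend."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not described in legend")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def binary(self, keep: Iterable[str]) -> np.ndarray:
        """Boolean mask of voxels whose tissue name is in ``keep``."""
        keep = set(keep)
        unknown = keep - set(self.legend.values())
        if unknown:
            raise ValueError(f"unknown tissue names: {sorted(unknown)}")
        values = [lab for lab, name in self.legend.items() if name in keep]
        return np.isin(self.labels, values)


# ---------------------------------------------------------------------------
# temporal operations
# ---------------------------------------------------------------------------


def trim_volume(v: BoldVolume, n_head: int, n_tail: int) -> BoldVolume:
    """Discard ``n_head`` leading and ``n_tail`` trailing acquisitions."""
    if n_head < 0 or n_tail < 0:
        raise ValueError("trim counts must be non-negative")
    if v.n_timepoints <= n_head + n_tail:
        raise ValueError(
            f"cannot trim {n_head}+{n_tail} acquisitions from a volume of "
            f"{v.n_timepoints} time points"
        )
    stop = v.n_timepoints - n_tail
    return v.with_data(v.data[..., n_head:stop])


def highpass_filter(v: BoldVolume, cutoff_hz: float) -> BoldVolume:
    """High-pass filter each voxel time series.

    The filter is a discrete-cosine projection: DCT-II basis functions with
    frequency below ``cutoff_hz`` (including the DC term) are removed. This
    realization is exactly linear, phase-free, and removes the per-voxel mean.
    The component with index ``k`` on ``N`` samples has frequency
    ``k / (2 N TR)`` Hz.
    """
    nt = v.n_timepoints
    if nt < 4:
        raise ValueError("need at least 4 time points to filter")
    nyquist = 0.5 / v.tr
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist:.4f}) Hz"
        )
    coeffs = sp_fft.dct(np.asarray(v.data, dtype=float), type=2, norm="ortho", axis=-1)
    freqs = np.arange(nt) / (2.0 * nt * v.tr)
    drop = freqs < cutoff_hz
    drop[0] = True  # DC always removed
    coeffs[..., drop] = 0.0
    out = sp_fft.idct(coeffs, type=2, norm="ortho", axis=-1)
    return v.with_data(out)


def average_trials(
    v: BoldVolume, trial_onsets: Sequence[int], trial_len: int
) -> BoldVolume:
    """Average identically shaped trial windows into a single short volume.

    ``trial_onsets`` are acquisition indices; each window
    ``[onset, onset + trial_len)`` must lie inside the volume. Output sample
    ``s`` is the arithmetic mean over trials of within-trial sample ``s``.
    """
    onsets = [int(o) for o in trial_onsets]
    if trial_len < 1:
        raise ValueError("trial_len must be at least 1")
    if not onsets:
        raise ValueError("need at least one trial onset")
    for o in onsets:
        if o < 0 or o + trial_len > v.n_timepoints:
            raise ValueError(f"trial window [{o}, {o + trial_len}) out of range")
    spans = sorted((o, o + trial_len) for o in onsets)
    if any(b0 < a1 for (_, a1), (b0, _) in zip(spans, spans[1:])):
        warnings.warn("trial windows overlap", stacklevel=2)
    stacked = np.stack([v.data[..., o : o + trial_len] for o in onsets], axis=0)
    return v.with_data(stacked.mean(axis=0))


def concatenate_sessions(vs: Sequence[BoldVolume]) -> BoldVolume:
    """Concatenate sessions along time, preserving order."""
    if not vs:
        raise ValueError("need at least one session")
    first = vs[0]
    for v in vs[1:]:
        if v.grid_shape != first.grid_shape:
            raise ValueError("sessions have mismatched grids")
        if v.voxel_size != first.voxel_size or v.tr != first.tr:
            raise ValueError("sessions have mismatched geometry or TR")
        if v.space_tag != first.space_tag:
            raise ValueError("sessions have mismatched space tags")
    if len(vs) == 1:
        return first.with_data(first.data.copy())
    return first.with_data(np.concatenate([v.data for v in vs], axis=-1))


def apply_tissue_mask(
    v: BoldVolume, m: TissueMask, keep: Iterable[str] = ("gm", "wm")
) -> np.ndarray:
    """Return the ``(k, 3)`` voxel coordinates whose tissue label is kept.

    Coordinates are sorted in raster order with x varying fastest, then y,
    then z (0-based indices).
    """
    if m.grid_shape != v.grid_shape:
        raise ValueError(
            f"mask grid {m.grid_shape} does not match volume grid {v.grid_shape}"
        )
    return mask_to_coords(m.binary(keep))


def mask_to_coords(mask: np.ndarray) -> np.ndarray:
    """Coordinates of True voxels in x-fastest raster order, shape (k, 3)."""
    mask = np.asarray(mask, dtype=bool)
    # argwhere on the transposed array orders rows by (z, y, x) lexicographically,
    # i.e. x varies fastest; flip columns back to (x, y, z).
    return np.argwhere(mask.transpose(2, 1, 0))[:, ::-1].astype(np.intp)


# ---------------------------------------------------------------------------
# spatial normalization order
# ---------------------------------------------------------------------------


def _warp3d(
    frame: np.ndarray,
    matrix: np.ndarray,
    out_shape: tuple[int, int, int],
    order: int,
) -> np.ndarray:
    return ndimage.affine_transform(
        frame,
        matrix[:3, :3],
        offset=matrix[:3, 3],
        output_shape=tuple(out_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )


def normalize_then_resample(
    v: BoldVolume,
    affine: np.ndarray | None = None,
    standard_shape: tuple[int, int, int] | None = None,
    back_shape: tuple[int, int, int] | None = None,
) -> BoldVolume:
    """Warp a native volume to the standard grid, then resample it back.

    ``affine`` maps native voxel coordinates to standard voxel coordinates
    (defaults to the volume's own affine). Data are interpolated trilinearly
    at both steps; the double interpolation is exactly the smoothing
    mechanism that inflates spatial autocorrelation (and hence network
    density) in standard-space analyses. The result is tagged
    ``space_tag="standard"``.
    """
    A = np.asarray(v.affine if affine is None else affine, dtype=float)
    if A.shape != (4, 4) or abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")
    Ainv = np.linalg.inv(A)
    standard_shape = tuple(standard_shape or v.grid_shape)
    back_shape = tuple(back_shape or v.grid_shape)
    out = np.empty(back_shape + (v.n_timepoints,), dtype=float)
    for t in range(v.n_timepoints):
        std = _warp3d(np.asarray(v.data[..., t], dtype=float), Ainv, standard_shape, 1)
        out[..., t] = _warp3d(std, A, back_shape, 1)
    return v.with_data(out, space_tag=STANDARD, affine=A)


def resample_labels(
    m: TissueMask,
    affine: np.ndarray,
    standard_shape: tuple[int, int, int] | None = None,
    back_shape: tuple[int, int, int] | None = None,
) -> TissueMask:
    """Round-trip a label volume with nearest-neighbour interpolation."""
    A = np.asarray(affine, dtype=float)
    if A.shape != (4, 4) or abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")
    Ainv = np.linalg.inv(A)
    standard_shape = tuple(standard_shape or m.grid_shape)
    back_shape = tuple(back_shape or m.grid_shape)
    std = _warp3d(m.labels.astype(float), Ainv, standard_shape, 0)
    back = _warp3d(std, A, back_shape, 0)
    return TissueMask(labels=np.rint(back).astype(m.labels.dtype), legend=dict(m.legend))


# ---------------------------------------------------------------------------
# NIfTI input/output
# ---------------------------------------------------------------------------


def _vox2world(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_bold(v: BoldVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _vox2world(v.voxel_size))
    img.header.set_zooms(tuple(v.voxel_size) + (v.tr,))
    img.header["descrip"] = f"space={v.space_tag}".encode()
    nib.save(img, str(path))


def load_bold(path, tr: float | None = None, space_tag: str = NATIVE,
              affine: np.ndarray | None = None) -> BoldVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    descrip = bytes(img.header["descrip"]).decode(errors="ignore")
    if "space=standard" in descrip:
        space_tag = STANDARD
    kwargs = {} if affine is None else {"affine": affine}
    return BoldVolume(data=data, voxel_size=voxel_size, tr=tr, space_tag=space_tag, **kwargs)


def save_mask(m: TissueMask, path, voxel_size: Sequence[float] = (3.75, 3.75, 8.0)) -> None:
    img = nib.Nifti1Image(m.labels.astype(np.int16), _vox2world(voxel_size))
    nib.save(img, str(path))


def load_mask(path, legend: dict[int, str] | None = None) -> TissueMask:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    labels = np.rint(labels).astype(np.int16)
    return TissueMask(labels=labels, legend=dict(legend or DEFAULT_LEGEND))
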