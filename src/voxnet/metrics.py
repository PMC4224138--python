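"""Per-node graph measures materialized as 3D metric images.

Four measures are supported, each computed at every node of a pruned
voxel network and written back onto the 3D grid the network came from:

- **degree** ``k``: number of neighbours.
- **clustering** ``c``: density of the subgraph induced by a node's
  neighbours, in [0, 1].
- **pathlength** ``l``: mean shortest-path hop count from a node to every
  other node (connected networks only; fragmented networks are excluded).
- **localeff** ``e``: efficiency of the neighbour-induced subgraph — the
  mean over neighbour pairs of the inverse shortest-path distance within
  that subgraph, with 1/inf = 0.

Voxels that are not nodes of the network carry an explicit missing marker
(NaN plus a boolean mask). Per-subject Z-normalization over the non-missing
voxels accounts for network size and density differences across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import networkx as nx
import numpy as np

from .network import FunctionalNetwork
from .prep import NATIVE

MEASURES = ("degree", "clustering", "pathlength", "localeff")


class FragmentedNetworkError(ValueError):
    """Raised when a measure that requires a connected network is requested
    on a fragmented one; callers treat this as a subject-level exclusion."""


@dataclass
class MetricImage:
    """3D per-voxel map of one graph measure with explicit missingness."""

    values: np.ndarray
    missing_mask: np.ndarray
    measure: str
    normalized: bool = False
    subject: str | None = None
    space_tag: str = NATIVE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan
        present = self.values[~self.missing_mask]
        if present.size and not np.all(np.isfinite(present)):
            raise ValueError("non-missing values must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_present(self) -> int:
        return int((~self.missing_mask).sum())

    def present_values(self) -> np.ndarray:
        return self.values[~self.missing_mask]


def _materialize(
    g: FunctionalNetwork, node_values: Iterable[float], measure: str
) -> MetricImage:
    values = np.full(g.grid_shape, np.nan)
    missing = np.ones(g.grid_shape, dtype=bool)
    for (x, y, z), v in zip(g.coords, node_values):
        values[x, y, z] = v
        missing[x, y, z] = False
    subject = g.provenance.get("subject")
    space = g.provenance.get("space_tag", NATIVE)
    return MetricImage(
        values=values, missing_mask=missing, measure=measure,
        subject=subject, space_tag=space,
    )


def degree_map(g: FunctionalNetwork) -> MetricImage:
    """Edge count of every node, as a 3D image."""
    return _materialize(g, (g.graph.degree[i] for i in range(g.n)), "degree")


def clustering_map(g: FunctionalNetwork) -> MetricImage:
    """Neighbourhood density of every node; degree < 2 yields 0."""
    cl = nx.clustering(g.graph)
    return _materialize(g, (cl[i] for i in range(g.n)), "clustering")


def pathlength_map(g: FunctionalNetwork) -> MetricImage:
    """Mean BFS hop count from each node to all others.

    Requires a connected (non-fragmented) network; fragmented networks are
    refused with :class:`FragmentedNetworkError` so callers can exclude the
    subject and adjust degrees of freedom.
    """
    if g.fragmented:
        raise FragmentedNetworkError("fragmented network excluded from path length")
    if g.n == 0:
        raise FragmentedNetworkError("empty network has no path lengths")
    if g.n > 1 and not nx.is_connected(g.graph):
        raise FragmentedNetworkError("network is not connected")
    vals = np.empty(g.n)
    for i in range(g.n):
        dists = nx.single_source_shortest_path_length(g.graph, i)
        vals[i] = (sum(dists.values())) / (g.n - 1) if g.n > 1 else 0.0
    return _materialize(g, vals, "pathlength")


def _subgraph_efficiency(g: nx.Graph, nodes: list) -> float:
    """Mean inverse shortest-path distance over ordered pairs of ``nodes``
    within their induced subgraph (1/inf = 0)."""
    k = len(nodes)
    if k < 2:
        return 0.0
    sub = g.subgraph(nodes)
    inv_sum = 0.0
    for u in nodes:
        dists = nx.single_source_shortest_path_length(sub, u)
        inv_sum += sum(1.0 / d for v, d in dists.items() if v != u)
    return inv_sum / (k * (k - 1))


def local_efficiency_map(g: FunctionalNetwork) -> MetricImage:
    """Efficiency of each node's neighbour-induced subgraph, in [0, 1]."""
    vals = [
        _subgraph_efficiency(g.graph, list(g.graph.neighbors(i))) for i in range(g.n)
    ]
    return _materialize(g, vals, "localeff")


_MAP_FUNCS = {
    "degree": degree_map,
    "clustering": clustering_map,
    "pathlength": pathlength_map,
    "localeff": local_efficiency_map,
}


def metric_map(g: FunctionalNetwork, measure: str) -> MetricImage:
    """Dispatch to the named measure's map function."""
    try:
        fn = _MAP_FUNCS[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    return fn(g)


def z_normalize(m: MetricImage) -> MetricImage:
    """Z-score the non-missing voxels of a metric image (population SD).

    Normalization is per subject, per measure, per space; it removes the
    effect of varying network size and density before group comparison.
    """
    present = m.present_values()
    if present.size < 2:
        raise ValueError("need at least 2 non-missing voxels to normalize")
    sd = present.std()  # population SD
    if sd == 0:
        raise ValueError("zero spread: cannot Z-normalize")
    values = (m.values - present.mean()) / sd
    return replace(m, values=values, missing_mask=m.missing_mask.copy(), normalized=True)


# ---------------------------------------------------------------------------
# NIfTI round trip (NaN is the missing marker on disk)
# ---------------------------------------------------------------------------


def save_metric_image(m: MetricImage, path, voxel_size=(3.75, 3.75, 8.0)) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(
        m.values.astype(np.float32), np.diag(list(voxel_size) + [1.0])
    )
    img.header["descrip"] = f"measure={m.measure};normalized={m.normalized}".encode()
    nib.save(img, str(path))


def load_metric_image(path, measure: str | None = None,
                      space_tag: str = NATIVE) -> MetricImage:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    descrip = bytes(img.header["descrip"]).decode(errors="ignore")
    normalized = "normalized=True" in descrip
    if measure is None:
        for name in MEASURES:
            if f"measure={name}" in descrip:
                measure = name
                break
        else:
            raise ValueError("measure not recorded in header; pass measure=")
    return MetricImage(
        values=values,
        missing_mask=~np.isfinite(values),
        measure=measure,
        normalized=normalized,
        space_tag=space_tag,
    )
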