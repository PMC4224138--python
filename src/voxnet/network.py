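"""Construction of thresholded, pruned, unweighted voxel networks.

Nodes are voxels; an edge joins two voxels whose Pearson correlation over
time meets or exceeds a critical value derived from a two-tailed
significance level. Only positive correlations form edges. After
thresholding, disconnected nodes are removed and, when one component holds
at least 75% of the remaining nodes, all minor components are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

#: The source study's printed approximate critical correlations, kept purely
#: as reference constants. The exact t-transform values differ slightly
#: (e.g. 0.834 rather than 0.82 for alpha=1e-2 at n=8); r_crit is always
#: derived at runtime from alpha and the actual sample count.
REFERENCE_R = {
    "task": {1e-2: 0.82, 1e-3: 0.90, 1e-5: 0.96},
    "rest": {1e-25: 0.45, 1e-38: 0.54, 1e-58: 0.63},
}


def alpha_to_r(alpha: float, n_samples: int) -> float:
    """Critical Pearson correlation for a two-tailed test at level ``alpha``.

    Uses the exact transform ``t = r sqrt(df) / sqrt(1 - r^2)`` with
    ``df = n_samples - 2``: the returned value is the correlation whose
    two-tailed null p-value equals ``alpha``. Monotone decreasing in both
    ``alpha`` and ``n_samples``.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    df = n_samples - 2
    t = stats.t.isf(alpha / 2.0, df)
    return float(t / np.sqrt(df + t * t))


@dataclass
class CorrelationThreshold:
    """A two-tailed significance level and its derived edge threshold."""

    alpha: float
    n_samples: int
    r_crit: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4")
        if not 0 <= self.r_crit <= 1:
            raise ValueError("r_crit must lie in [0, 1]")

    @classmethod
    def from_alpha(cls, alpha: float, n_samples: int) -> "CorrelationThreshold":
        return cls(alpha=alpha, n_samples=n_samples, r_crit=alpha_to_r(alpha, n_samples))


def correlation_matrix(data_or_volume, included: np.ndarray) -> np.ndarray:
    """Pearson correlation between all pairs of included voxels.

    ``included`` is a ``(k, 3)`` coordinate array (see
    :func:`voxnet.prep.apply_tissue_mask`). Zero-variance voxels cannot
    carry edges: their rows and columns are NaN-flagged and silently ignored
    by :func:`build_network`. Raises if every included voxel has zero
    variance.
    """
    data = getattr(data_or_volume, "data", data_or_volume)
    data = np.asarray(data, dtype=float)
    included = np.asarray(included)
    if included.ndim != 2 or included.shape[1] != 3:
        raise ValueError("included must be a (k, 3) coordinate array")
    if included.shape[0] == 0:
        raise ValueError("included voxel list is empty")
    if data.shape[-1] < 3:
        raise ValueError("need at least 3 time points")
    series = data[included[:, 0], included[:, 1], included[:, 2], :]
    series = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(series, axis=1)
    valid = norms > 0
    if not valid.any():
        raise ValueError("all included voxels have zero variance")
    unit = np.zeros_like(series)
    unit[valid] = series[valid] / norms[valid, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    return corr


@dataclass
class FunctionalNetwork:
    """Undirected unweighted graph whose nodes are voxel coordinates.

    Nodes are indexed ``0..n-1``; ``coords[i]`` is node ``i``'s (x, y, z)
    voxel coordinate on ``grid_shape``. ``fragmented`` is None until the
    network has been pruned.
    """

    coords: np.ndarray
    graph: nx.Graph
    grid_shape: tuple[int, int, int]
    fragmented: bool | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be a (n, 3) array")
        n = self.coords.shape[0]
        if set(self.graph.nodes) != set(range(n)):
            raise ValueError("graph nodes must be exactly 0..n-1")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_graph(
        cls,
        g: nx.Graph,
        coords: np.ndarray | None = None,
        grid_shape: tuple[int, int, int] | None = None,
        **kwargs,
    ) -> "FunctionalNetwork":
        """Wrap an arbitrary networkx graph, laying nodes along the x axis
        when no coordinates are given."""
        nodes = list(g.nodes)
        relabel = {node: i for i, node in enumerate(nodes)}
        h = nx.relabel_nodes(g, relabel, copy=True)
        if coords is None:
            coords = np.array([[i, 0, 0] for i in range(len(nodes))], dtype=np.intp)
        coords = np.asarray(coords)
        if grid_shape is None:
            if len(coords):
                grid_shape = tuple(int(m) + 1 for m in coords.max(axis=0))
            else:
                grid_shape = (1, 1, 1)
        return cls(coords=coords, graph=h, grid_shape=grid_shape, **kwargs)

    def subnetwork(self, keep: Sequence[int]) -> "FunctionalNetwork":
        keep = sorted(int(i) for i in keep)
        relabel = {old: new for new, old in enumerate(keep)}
        h = nx.relabel_nodes(self.graph.subgraph(keep), relabel, copy=True)
        return FunctionalNetwork(
            coords=self.coords[keep],
            graph=h,
            grid_shape=self.grid_shape,
            fragmented=self.fragmented,
            provenance=dict(self.provenance),
        )


def build_network(
    corr: np.ndarray,
    r_crit: float,
    included: np.ndarray,
    grid_shape: tuple[int, int, int] | None = None,
    provenance: dict | None = None,
) -> FunctionalNetwork:
    """Threshold a correlation matrix into an unweighted network.

    An edge (i, j) exists iff ``corr[i, j] >= r_crit`` (ties included) and
    ``i != j``. Negative correlations never create edges; NaN entries
    (zero-variance voxels) are ignored.
    """
    corr = np.asarray(corr, dtype=float)
    included = np.asarray(included, dtype=np.intp)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("corr must be a square matrix")
    if corr.shape[0] != included.shape[0]:
        raise ValueError("corr size does not match included voxel count")
    n = corr.shape[0]
    with np.errstate(invalid="ignore"):
        above = corr >= r_crit
    iu, ju = np.triu_indices(n, k=1)
    sel = above[iu, ju]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[sel].tolist(), ju[sel].tolist()))
    if grid_shape is None:
        grid_shape = tuple(int(m) + 1 for m in included.max(axis=0))
    return FunctionalNetwork(
        coords=included,
        graph=g,
        grid_shape=grid_shape,
        provenance=dict(provenance or {}),
    )


def prune_components(
    g: FunctionalNetwork, major_fraction: float = 0.75
) -> FunctionalNetwork:
    """Remove disconnected nodes and, when possible, minor components.

    Degree-0 nodes are always removed. If the largest remaining component
    holds at least ``major_fraction`` of the remaining nodes, all other
    components are removed and the result is marked ``fragmented=False``;
    otherwise only the isolated nodes are removed and ``fragmented=True``.
    A network in which every node was isolated prunes to an empty network
    (``fragmented=True``).
    """
    if g.n == 0:
        raise ValueError("cannot prune an empty network")
    keep = [i for i in range(g.n) if g.graph.degree[i] > 0]
    if not keep:
        out = g.subnetwork([])
        out.fragmented = True
        return out
    sub = g.graph.subgraph(keep)
    comps = sorted(nx.connected_components(sub), key=len, reverse=True)
    if len(comps[0]) >= major_fraction * len(keep):
        out = g.subnetwork(sorted(comps[0]))
        out.fragmented = False
    else:
        out = g.subnetwork(keep)
        out.fragmented = True
    return out


def network_density(g: FunctionalNetwork) -> float:
    """Fraction of possible edges present: ``m / (n(n-1)/2)``."""
    if g.n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * g.n_edges / (g.n * (g.n - 1))


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------


def save_network(g: FunctionalNetwork, path) -> None:
    """Write a network as a documented plain-text node/edge listing."""
    with open(path, "w") as fh:
        fh.write("# voxnet network v1\n")
        fh.write(f"# grid_shape {g.grid_shape[0]} {g.grid_shape[1]} {g.grid_shape[2]}\n")
        fh.write(f"# fragmented {g.fragmented}\n")
        fh.write(f"# nodes {g.n}\n")
        for i, (x, y, z) in enumerate(g.coords):
            fh.write(f"n {i} {x} {y} {z}\n")
        fh.write(f"# edges {g.n_edges}\n")
        for u, v in sorted(g.graph.edges):
            fh.write(f"e {u} {v}\n")


def load_network(path) -> FunctionalNetwork:
    grid_shape = (1, 1, 1)
    fragmented: bool | None = None
    coords: list[list[int]] = []
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "#":
                if len(parts) >= 5 and parts[1] == "grid_shape":
                    grid_shape = (int(parts[2]), int(parts[3]), int(parts[4]))
                elif len(parts) >= 3 and parts[1] == "fragmented":
                    fragmented = {"True": True, "False": False, "None": None}[parts[2]]
            elif parts[0] == "n":
                coords.append([int(parts[2]), int(parts[3]), int(parts[4])])
            elif parts[0] == "e":
                edges.append((int(parts[1]), int(parts[2])))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(coords)))
    graph.add_edges_from(edges)
    return FunctionalNetwork(
        coords=np.asarray(coords, dtype=np.intp).reshape(-1, 3),
        graph=graph,
        grid_shape=grid_shape,
        fragmented=fragmented,
    )
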