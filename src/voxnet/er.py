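"""Erdős–Rényi reference curves and metric-relationship diagnostics.

For a supercritical G(n, p) random graph, the mean path length follows the
closed form ``l = (ln n - gamma)/ln k + 1/2`` in the mean degree ``k``
(with Euler–Mascheroni ``gamma``), and the mean local efficiency follows an
empirical curve ``e = (w c + x) / (1 + (c/y)^z)`` in the mean clustering
coefficient ``c``. Plotting these curves against joint histograms of
per-node (degree, path length) and (clustering, local efficiency) values
shows how closely the measured relationships track the random-graph
expectation — and why path length and local efficiency add little beyond
degree and clustering for group comparison.

The efficiency-curve constants are fixed published values, not re-fitted
here: the original fit depends on an unstated graph-size range, so
re-estimation is a diagnostic, never a gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .metrics import MetricImage

EULER_GAMMA = 0.5772

#: published constants of the local-efficiency reference curve
EFFICIENCY_CONSTANTS = {"w": 0.5, "x": 0.5, "y": 0.07, "z": -3.9}


def er_pathlength(n: int, k: float, gamma: float = EULER_GAMMA) -> float:
    """Predicted mean path length of an ER graph with ``n`` nodes and mean
    degree ``k``: ``(ln n - gamma)/ln k + 1/2``. Requires ``k > 1``."""
    if n < 2:
        raise ValueError("n must be at least 2")
    if k <= 1:
        raise ValueError("mean degree must exceed 1")
    return float((np.log(n) - gamma) / np.log(k) + 0.5)


def er_local_efficiency(
    c: float,
    w: float = EFFICIENCY_CONSTANTS["w"],
    x: float = EFFICIENCY_CONSTANTS["x"],
    y: float = EFFICIENCY_CONSTANTS["y"],
    z: float = EFFICIENCY_CONSTANTS["z"],
) -> float:
    """Predicted mean local efficiency of an ER graph from its mean
    clustering coefficient ``c``: ``(w c + x) / (1 + (c/y)^z)``.

    With the published constants the curve rises monotonically from 0 at
    ``c -> 0+`` to ~1 at ``c = 1``.
    """
    if not 0 <= c <= 1:
        raise ValueError("c must lie in [0, 1]")
    if c == 0:
        return 0.0  # (c/y)^z diverges for z < 0
    return float((w * c + x) / (1.0 + (c / y) ** z))


@dataclass
class ERReferenceCurve:
    """Bundled reference curves for a fixed network size ``n``."""

    n: int
    gamma: float = EULER_GAMMA
    w: float = EFFICIENCY_CONSTANTS["w"]
    x: float = EFFICIENCY_CONSTANTS["x"]
    y: float = EFFICIENCY_CONSTANTS["y"]
    z: float = EFFICIENCY_CONSTANTS["z"]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        for name in ("gamma", "w", "x", "y", "z"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"constant {name} must be finite")

    def pathlength(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return (np.log(self.n) - self.gamma) / np.log(k) + 0.5

    def local_efficiency(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        out = np.zeros_like(c)
        pos = c > 0
        out[pos] = (self.w * c[pos] + self.x) / (1.0 + (c[pos] / self.y) ** self.z)
        return out

    def table(self, k_grid=None, c_grid=None):
        """Curve values on a grid, as a DataFrame (for CSV export)."""
        import pandas as pd

        k_grid = np.asarray(
            k_grid if k_grid is not None else np.linspace(2.0, 200.0, 100)
        )
        c_grid = np.asarray(
            c_grid if c_grid is not None else np.linspace(0.0, 1.0, 101)
        )
        m = max(len(k_grid), len(c_grid))
        k_pad = np.full(m, np.nan)
        k_pad[: len(k_grid)] = k_grid
        c_pad = np.full(m, np.nan)
        c_pad[: len(c_grid)] = c_grid
        l_pad = np.full(m, np.nan)
        l_pad[: len(k_grid)] = self.pathlength(k_grid)
        e_pad = np.full(m, np.nan)
        e_pad[: len(c_grid)] = self.local_efficiency(c_grid)
        return pd.DataFrame(
            {"k": k_pad, "pathlength": l_pad, "c": c_pad, "local_efficiency": e_pad}
        )


def metric_relationship_histogram(
    image_pairs, n_bins: int = 5000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D joint histogram of paired per-voxel metric values.

    ``image_pairs`` is a sequence of (MetricImage, MetricImage) tuples; for
    each pair, voxels present in both images contribute one count. Bins are
    equal-width and span the observed ranges; the total count equals the
    number of paired voxels. Returns ``(counts, x_edges, y_edges)``.
    """
    xs, ys = [], []
    for a, b in image_pairs:
        if a.grid_shape != b.grid_shape:
            raise ValueError("paired images do not share a grid")
        both = ~(a.missing_mask | b.missing_mask)
        xs.append(a.values[both])
        ys.append(b.values[both])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if x.size == 0:
        raise ValueError("no paired non-missing values")
    # histogram2d degenerates when a range is a single point; widen it.
    def edges(v):
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, n_bins + 1)

    counts, xe, ye = np.histogram2d(x, y, bins=[edges(x), edges(y)])
    return counts, xe, ye


def sampled_mean_path_length(
    g: nx.Graph, n_sources: int | None = None, seed: int | None = None
) -> float:
    """Empirical mean (over sampled source nodes) of each node's mean
    shortest-path length to all other nodes; an unbiased estimate of the
    network mean when sources are sampled uniformly."""
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    if n_sources is not None and n_sources < n:
        rng = np.random.default_rng(seed)
        sources = [nodes[i] for i in rng.choice(n, size=n_sources, replace=False)]
    else:
        sources = nodes
    total = 0.0
    for s in sources:
        dists = nx.single_source_shortest_path_length(g, s)
        if len(dists) < n:
            raise ValueError("graph is not connected")
        total += sum(dists.values()) / (n - 1)
    return total / len(sources)


def simulate_er_pathlength(
    n: int, k: float, n_sources: int = 200, seed: int | None = None
) -> float:
    """Mean path length of one simulated G(n, p) graph with p = k/(n-1),
    estimated from BFS over sampled sources. Retries the draw (new seed
    stream) if the graph comes out disconnected, which is rare in the
    supercritical regime used here."""
    rng = np.random.default_rng(seed)
    p = k / (n - 1)
    for _ in range(10):
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return sampled_mean_path_length(
                g, n_sources=n_sources, seed=int(rng.integers(2**31))
            )
    raise RuntimeError("could not draw a connected ER graph in 10 attempts")


def plot_relationships(
    hist_kl, hist_ce, curve: ERReferenceCurve, out_path
) -> None:
    """Overlay the reference curves on the two joint histograms and save a
    figure. ``hist_kl``/``hist_ce`` are (counts, x_edges, y_edges) tuples
    from :func:`metric_relationship_histogram`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (counts, xe, ye), label in zip(
        axes, (hist_kl, hist_ce), ("degree vs path length", "clustering vs local eff.")
    ):
        masked = np.ma.masked_equal(counts.T, 0)
        ax.pcolormesh(xe, ye, masked, cmap="viridis")
        ax.set_title(label)
    k_grid = np.linspace(max(2.0, hist_kl[1][0]), max(3.0, hist_kl[1][-1]), 200)
    axes[0].plot(k_grid, curve.pathlength(k_grid), "r--")
    c_grid = np.linspace(1e-3, 1.0, 200)
    axes[1].plot(c_grid, curve.local_efficiency(c_grid), "r--")
    axes[0].set_xlabel("degree k")
    axes[0].set_ylabel("path length l")
    axes[1].set_xlabel("clustering c")
    axes[1].set_ylabel("local efficiency e")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
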