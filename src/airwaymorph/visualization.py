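"""Diagnostic graphics: clustered correlation heat maps and p-value plots."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class HeatmapSpec:
    """What to render: a correlation matrix, a display order, and an
    optional symmetric white-out interval [-delta, delta]."""

    corr: pd.DataFrame
    order: np.ndarray | None = None
    whiteout_delta: float | None = None

    def __post_init__(self) -> None:
        n = self.corr.shape[0]
        if self.order is None:
            self.order = np.arange(n)
        self.order = np.asarray(self.order, dtype=int)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of the feature indices")
        if self.whiteout_delta is not None and not 0 <= self.whiteout_delta <= 1:
            raise ValueError("white-out interval half-width must be in [0, 1]")


def cluster_order(corr: pd.DataFrame) -> np.ndarray:
    """Dendrogram leaf order from average-linkage clustering of the
    correlation-profile rows (Euclidean distance); deterministic."""
    A = corr.to_numpy(dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("correlation matrix contains non-finite entries")
    n = A.shape[0]
    if n == 1:
        return np.arange(1)
    Z = hierarchy.linkage(pdist(A, metric="euclidean"), method="average")
    return np.asarray(hierarchy.leaves_list(Z), dtype=int)


def render_heatmap(spec: HeatmapSpec, path: str | Path) -> None:
    """Render the (permuted) correlation matrix as a signed heat map.

    Blue encodes negative and red positive correlation, anchored at -1 and
    +1 regardless of the observed range so runs are visually comparable.
    Cells inside the white-out interval are drawn white.  Output is a PNG
    with deterministic bytes for fixed inputs.
    """
    A = spec.corr.to_numpy(dtype=float)[np.ix_(spec.order, spec.order)]
    if spec.whiteout_delta is not None:
        A = np.ma.masked_inside(A, -spec.whiteout_delta, spec.whiteout_delta)
    cmap = matplotlib.colormaps["RdBu_r"].copy()
    cmap.set_bad(color="white")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(A, cmap=cmap, vmin=-1.0, vmax=1.0, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="Pearson correlation")
    ax.set_xlabel("features")
    ax.set_ylabel("features")
    fig.savefig(path, format="png", dpi=150,
                metadata={"Software": None, "CreationDate": None})
    plt.close(fig)


def low_correlation_counts(corr: pd.DataFrame, delta: float) -> pd.Series:
    """Per-feature count of other features with correlation in [-delta, delta].

    This is the vector plotted against the feature axis in the
    low-correlation count figure, and exactly the quantity the selection
    module thresholds at M_L.
    """
    from .selection import low_correlation_counts as _counts

    return _counts(corr, delta)


def plot_low_correlation_counts(corr: pd.DataFrame, delta: float,
                                path: str | Path) -> None:
    counts = low_correlation_counts(corr, delta)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(np.arange(len(counts)), counts.to_numpy(), lw=0.8)
    ax.set_xlabel("feature index")
    ax.set_ylabel(f"# features with |r| <= {delta:g}")
    fig.tight_layout()
    fig.savefig(path, format="png", dpi=150,
                metadata={"Software": None, "CreationDate": None})
    plt.close(fig)


def plot_p_value_histogram(p_values, path: str | Path, bins: int = 20) -> None:
    from .selection import p_value_histogram

    counts = p_value_histogram(p_values, bins=bins)
    edges = np.linspace(0, 1, bins + 1)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           edgecolor="black")
    ax.set_xlabel("p-value")
    ax.set_ylabel("number of features")
    fig.tight_layout()
    fig.savefig(path, format="png", dpi=150,
                metadata={"Software": None, "CreationDate": None})
    plt.close(fig)
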