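"""Reef-seascape colour dissimilarity via earth mover's distance.

Each reef image is summarized as a colour signature: a 4-regions-per-channel
(4³ = 64 bin) histogram whose occupied bins carry a weight (pixel
proportion) and a mean sRGB colour.  The earth mover's distance (EMD)
between two signatures is the minimum cost of transporting one weight
distribution onto the other, with ground cost the Euclidean distance
between bin colours — the effort required to make one palette resemble the
other.  With a metric ground distance and equal total weights, EMD is a
metric on signatures.

The transportation problem is solved exactly as a linear program (HiGHS).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import linprog
from scipy.spatial.distance import cdist, squareform

from .hue_quant import bin_image, exclude_rare_bins, load_image_pixels
from .iscc_nbs import _to_match_space

__all__ = [
    "ColourSignature",
    "build_signature",
    "signature_from_pixels",
    "emd",
    "distance_matrix",
    "DistanceMatrix",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ColourSignature:
    """A reef's colour palette: bin centroids with unit-sum weights."""

    reef_id: str
    centroids: np.ndarray  # (n_bins, 3) sRGB
    weights: np.ndarray  # (n_bins,) positive, sum 1

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "weights", w)
        if c.ndim != 2 or c.shape[1] != 3 or len(w) != len(c):
            raise ValueError("centroids must be (n, 3) with matching weights")
        if len(w) == 0:
            raise ValueError("empty signature")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights sum to {w.sum()}, expected 1")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise EMD matrix with a similarity-clustered ordering."""

    ids: tuple[str, ...]
    values: np.ndarray
    ordering: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def ordered_ids(self) -> tuple[str, ...]:
        return tuple(self.ids[i] for i in self.ordering)

    def mean_distance(self, reef_id: str) -> float:
        i = self.ids.index(reef_id)
        others = [j for j in range(len(self.ids)) if j != i]
        return float(self.values[i, others].mean())


def signature_from_pixels(
    pixels: np.ndarray,
    reef_id: str,
    bins_per_channel: int = 4,
    threshold: float = 0.01,
) -> ColourSignature:
    """Histogram an (n, 3) pixel array into a unit-weight colour signature."""
    hist = exclude_rare_bins(bin_image(pixels, bins_per_channel), threshold)
    return ColourSignature(
        reef_id=reef_id,
        centroids=hist.centroids,
        weights=hist.proportions / hist.proportions.sum(),
    )


def build_signature(
    path: str | Path,
    reef_id: str | None = None,
    bins_per_channel: int = 4,
    threshold: float = 0.01,
) -> ColourSignature:
    """Read a pre-cropped reef image and build its colour signature."""
    path = Path(path)
    pixels = load_image_pixels(path)
    return signature_from_pixels(
        pixels,
        reef_id=reef_id if reef_id is not None else path.stem,
        bins_per_channel=bins_per_channel,
        threshold=threshold,
    )


def _ground_cost(a: ColourSignature, b: ColourSignature, space: str) -> np.ndarray:
    ca = _to_match_space(a.centroids, space)
    cb = _to_match_space(b.centroids, space)
    return cdist(ca, cb)


def emd(a: ColourSignature, b: ColourSignature, space: str = "srgb") -> float:
    """Earth mover's distance between two unit-weight colour signatures.

    Solves the transportation linear program
    ``min Σ f_ij d(c_i, c_j)  s.t.  Σ_j f_ij = w_i,  Σ_i f_ij = v_j, f >= 0``
    exactly.  ``space`` selects the ground-distance space ("srgb" default,
    "cielab" optional).
    """
    cost = _ground_cost(a, b, space)
    na, nb = cost.shape
    # equality rows: na row-sum constraints + nb column-sum constraints
    # (one is redundant since both sides sum to 1; HiGHS copes)
    A_rows = np.zeros((na, na * nb))
    for i in range(na):
        A_rows[i, i * nb : (i + 1) * nb] = 1.0
    A_cols = np.tile(np.eye(nb), (1, na))
    A_eq = np.vstack([A_rows, A_cols])
    b_eq = np.concatenate([a.weights, b.weights])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS solves all feasible instances
        raise RuntimeError(f"EMD transportation LP failed: {res.message}")
    return max(float(res.fun), 0.0)


def distance_matrix(
    signatures: Sequence[ColourSignature],
    space: str = "srgb",
    linkage_method: str = "average",
) -> DistanceMatrix:
    """All pairwise EMDs plus an agglomerative-clustering leaf ordering.

    The ordering arranges similar reefs adjacently for heatmap display
    (average linkage by default).
    """
    ids = [s.reef_id for s in signatures]
    if len(ids) < 2:
        raise ValueError("need at least 2 signatures")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reef ids")
    n = len(signatures)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = emd(signatures[i], signatures[j], space=space)
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    order = tuple(int(i) for i in leaves_list(Z))
    return DistanceMatrix(ids=tuple(ids), values=D, ordering=order)


def plot_heatmap(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a similarity-ordered heatmap of the distance matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(dm.ordering)
    vals = dm.values[np.ix_(order, order)]
    labels = [dm.ids[i] for i in order]
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(order), 1.0 + 0.6 * len(order)))
    im = ax.imshow(vals, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    for i in range(len(order)):
        for j in range(len(order)):
            ax.text(j, i, f"{vals[i, j]:.0f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="earth mover's distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
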