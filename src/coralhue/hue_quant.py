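"""Discrete colour histograms and ISCC-NBS hue profiles for organism images.

An image's pixels are treated as points in the sRGB cube.  Each channel is
divided into ``bins_per_channel`` equal-width regions, giving
``bins_per_channel ** 3`` possible histogram bins; each occupied bin carries
the proportion of pixels it holds and the mean sRGB colour of those pixels.
Bins holding less than a threshold fraction of the pixels (default 1%) are
discarded as likely artefacts, and the retained bin centroids are classified
into ISCC-NBS categories.  The set of distinct categories is the species'
hue profile — the number of visually distinct colour stimuli in the image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .iscc_nbs import IsccTable, classify_srgb_array

__all__ = [
    "ColourHistogram",
    "HueProfile",
    "load_image_pixels",
    "bin_image",
    "exclude_rare_bins",
    "histogram_to_profile",
    "quantify_image",
    "write_profiles_csv",
    "read_profiles_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColourHistogram:
    """Binned pixel proportions with per-bin mean sRGB centroids.

    ``bins`` maps a (ri, gi, bi) region-index triple to a
    ``(proportion, centroid_srgb)`` pair.  Proportions sum to 1.
    """

    bins_per_channel: int
    bins: dict[tuple[int, int, int], tuple[float, tuple[float, float, float]]]
    n_pixels: int

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for p, _ in self.bins.values()])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c for _, c in self.bins.values()])

    def __len__(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class HueProfile:
    """The set of ISCC-NBS categories present in one species' image(s)."""

    species_id: str
    categories: frozenset[int]
    n_bins_retained: int

    def __len__(self) -> int:
        return len(self.categories)


def load_image_pixels(
    path: str | Path,
    background_sentinel: Sequence[int] | None = None,
) -> np.ndarray:
    """Read an image file into an (n, 3) array of unmasked sRGB pixels.

    Fully transparent pixels (alpha == 0) and pixels equal to the optional
    background sentinel colour are dropped: images are pre-cropped but may
    carry transparent or flat-colour padding.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGBA")
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    pixels = arr.reshape(-1, 4)
    keep = pixels[:, 3] > 0
    rgb = pixels[keep, :3].astype(float)
    if background_sentinel is not None:
        sent = np.asarray(background_sentinel, dtype=float)
        rgb = rgb[~np.all(rgb == sent, axis=1)]
    return rgb


def bin_image(pixels: np.ndarray, bins_per_channel: int = 3) -> ColourHistogram:
    """Partition pixels into an equal-width multidimensional colour histogram.

    Parameters
    ----------
    pixels : (n, 3) array
        sRGB pixel values in [0, 255].
    bins_per_channel : int
        Number of equal regions each channel is divided into; 3 gives the
        3³ = 27-bin histogram used for single-organism images, 4 gives the
        64-bin histogram used for seascape images.

    Each channel's [0, 256) range is split into half-open equal intervals;
    a pixel's bin is the triple of its per-channel region indices.  The bin
    centroid is the mean sRGB of the bin's own pixels, not the geometric bin
    centre.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:
        pixels = pixels.reshape(-1, pixels.shape[-1])[:, :3]
    if pixels.size == 0:
        raise ValueError("image is empty after masking")
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise ValueError("expected an (n, 3) pixel array")
    if bins_per_channel < 2:
        raise ValueError("bins_per_channel must be >= 2")
    width = 256.0 / bins_per_channel
    idx = np.clip((pixels // width).astype(int), 0, bins_per_channel - 1)
    flat = (idx[:, 0] * bins_per_channel + idx[:, 1]) * bins_per_channel + idx[:, 2]
    n = len(pixels)
    bins: dict[tuple[int, int, int], tuple[float, tuple[float, float, float]]] = {}
    for code in np.unique(flat):
        sel = flat == code
        centroid = pixels[sel].mean(axis=0)
        bin_id = (
            int(code // (bins_per_channel**2)),
            int((code // bins_per_channel) % bins_per_channel),
            int(code % bins_per_channel),
        )
        bins[bin_id] = (float(sel.sum()) / n, tuple(float(c) for c in centroid))
    return ColourHistogram(bins_per_channel=bins_per_channel, bins=bins, n_pixels=n)


def exclude_rare_bins(
    hist: ColourHistogram, threshold: float = 0.01
) -> ColourHistogram:
    """Drop bins holding less than ``threshold`` of the pixels; renormalize.

    Guards against small portions of discoloured pixels (compression
    artefacts, residual shadows) inflating the hue profile.  At least one bin
    always survives (the largest bin's proportion is >= 1/len >= threshold
    for any threshold <= 1 only when bins exist; the max bin is kept
    unconditionally if everything falls below threshold).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    kept = {k: v for k, v in hist.bins.items() if v[0] >= threshold}
    if not kept:
        best = max(hist.bins, key=lambda k: hist.bins[k][0])
        kept = {best: hist.bins[best]}
    total = sum(p for p, _ in kept.values())
    kept = {k: (p / total, c) for k, (p, c) in kept.items()}
    return ColourHistogram(
        bins_per_channel=hist.bins_per_channel, bins=kept, n_pixels=hist.n_pixels
    )


def histogram_to_profile(
    hist: ColourHistogram, table: IsccTable, species_id: str
) -> HueProfile:
    """Classify each retained bin centroid and collect the distinct categories."""
    if len(hist) == 0:
        raise ValueError("histogram has no bins")
    cats = classify_srgb_array(np.clip(hist.centroids, 0, 255), table)
    return HueProfile(
        species_id=species_id,
        categories=frozenset(int(c) for c in cats),
        n_bins_retained=len(hist),
    )


def quantify_image(
    path: str | Path,
    table: IsccTable,
    species_id: str | None = None,
    bins_per_channel: int = 3,
    threshold: float = 0.01,
    background_sentinel: Sequence[int] | None = None,
) -> HueProfile:
    """Full per-image pipeline: read, bin, drop rare bins, classify.

    Deterministic composition of :func:`bin_image`,
    :func:`exclude_rare_bins` and :func:`histogram_to_profile`.
    """
    path = Path(path)
    species_id = species_id if species_id is not None else path.stem
    try:
        pixels = load_image_pixels(path, background_sentinel=background_sentinel)
        hist = exclude_rare_bins(bin_image(pixels, bins_per_channel), threshold)
        profile = histogram_to_profile(hist, table, species_id)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    logger.info(
        "quantified %s: %d pixels, %d bins retained, %d categories",
        path, hist.n_pixels, profile.n_bins_retained, len(profile),
    )
    return profile


def profile_record(profile: HueProfile, hist: ColourHistogram | None = None) -> dict:
    """JSON-serialisable record of one profile (optionally with its histogram)."""
    rec = {
        "species_id": profile.species_id,
        "categories": sorted(profile.categories),
        "n_bins_retained": profile.n_bins_retained,
    }
    if hist is not None:
        rec["n_pixels"] = hist.n_pixels
        rec["bins"] = [
            {"bin_id": list(k), "proportion": p, "centroid": list(c)}
            for k, (p, c) in hist.bins.items()
        ]
    return rec


def write_profiles_csv(profiles: Mapping[str, HueProfile], path: str | Path) -> None:
    """Write a batch of profiles as species_id -> semicolon-joined categories."""
    rows = [
        {
            "species_id": p.species_id,
            "categories": ";".join(str(c) for c in sorted(p.categories)),
            "n_bins_retained": p.n_bins_retained,
        }
        for p in profiles.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> dict[str, HueProfile]:
    df = pd.read_csv(path, dtype={"species_id": str, "categories": str})
    out: dict[str, HueProfile] = {}
    for row in df.itertuples():
        cats = frozenset(
            int(c) for c in str(row.categories).split(";") if c not in ("", "nan")
        )
        out[row.species_id] = HueProfile(
            species_id=row.species_id,
            categories=cats,
            n_bins_retained=int(getattr(row, "n_bins_retained", len(cats))),
        )
    return out
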