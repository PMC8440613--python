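"""Level-3 ISCC-NBS colour system: 267 named categories and sRGB classification.

The ISCC-NBS system partitions colour space into 267 named blocks (Level 3),
each with a centroid defined in Munsell space.  This module bundles the
category list with an approximate sRGB rendering of each centroid and assigns
an arbitrary sRGB colour to its nearest category.  The matching space is
CIELAB (D65) by default: nearest-centroid under a perceptually uniform metric
approximates the Munsell-block intent of the system.  A plain sRGB-Euclidean
fallback can be selected via ``colour_space_for_matching``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2lab

__all__ = [
    "IsccCategory",
    "IsccTable",
    "load_iscc_table",
    "srgb_to_hex",
    "hex_to_srgb",
    "classify_srgb",
    "classify_srgb_array",
]

_RESOURCE = "iscc_nbs_level3.csv"
N_CATEGORIES = 267


@dataclass(frozen=True)
class IsccCategory:
    """One ISCC-NBS Level-3 colour category.

    Attributes
    ----------
    index : int
        Category number, 1..267.
    name : str
        Canonical category name, e.g. ``"vivid pink"``.
    centroid_srgb : tuple of int
        The category's reference colour, rendered in sRGB (each channel 0-255).
    achromatic : bool
        True for the neutral axis and the near-neutral "-ish white/gray/black"
        categories.
    """

    index: int
    name: str
    centroid_srgb: tuple[int, int, int]
    achromatic: bool


@dataclass
class IsccTable:
    """The full 267-category table plus the configured matching space."""

    categories: tuple[IsccCategory, ...]
    colour_space_for_matching: str = "cielab"
    _by_index: dict = field(default_factory=dict, repr=False)
    _by_name: dict = field(default_factory=dict, repr=False)
    _match_coords: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.categories) != N_CATEGORIES:
            raise ValueError(
                f"expected {N_CATEGORIES} categories, got {len(self.categories)}"
            )
        self._by_index = {c.index: c for c in self.categories}
        self._by_name = {c.name: c for c in self.categories}
        if len(self._by_index) != N_CATEGORIES or len(self._by_name) != N_CATEGORIES:
            raise ValueError("category indices/names are not unique")
        if set(self._by_index) != set(range(1, N_CATEGORIES + 1)):
            raise ValueError("category indices do not cover 1..267")
        self._match_coords = _to_match_space(
            np.array([c.centroid_srgb for c in self.categories], dtype=float),
            self.colour_space_for_matching,
        )

    def __len__(self) -> int:
        return len(self.categories)

    def by_index(self, index: int) -> IsccCategory:
        return self._by_index[index]

    def by_name(self, name: str) -> IsccCategory:
        return self._by_name[name]

    @property
    def centroids_srgb(self) -> np.ndarray:
        return np.array([c.centroid_srgb for c in self.categories], dtype=float)


def _to_match_space(srgb: np.ndarray, space: str) -> np.ndarray:
    """Map an (n, 3) array of sRGB values in [0, 255] to the matching space."""
    if space == "srgb":
        return np.asarray(srgb, dtype=float)
    if space == "cielab":
        return rgb2lab(np.asarray(srgb, dtype=float)[np.newaxis, :, :] / 255.0)[0]
    raise ValueError(f"unknown matching space {space!r}")


def load_iscc_table(colour_space_for_matching: str = "cielab") -> IsccTable:
    """Load the bundled 267-category ISCC-NBS Level-3 table.

    The bundled centroids are approximate sRGB renderings of the published
    Munsell-space centroids.  Loading is idempotent: two calls return equal
    tables.

    Raises
    ------
    RuntimeError
        If the bundled resource is missing or malformed.
    """
    try:
        with resources.files("coralhue.data").joinpath(_RESOURCE).open("r") as fh:
            df = pd.read_csv(fh)
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise RuntimeError(f"ISCC-NBS resource {_RESOURCE!r} is missing") from exc
    expected = {"index", "name", "r", "g", "b", "achromatic"}
    if set(df.columns) != expected or len(df) != N_CATEGORIES:
        raise RuntimeError(f"ISCC-NBS resource {_RESOURCE!r} is corrupt")
    if df[["r", "g", "b"]].lt(0).any().any() or df[["r", "g", "b"]].gt(255).any().any():
        raise RuntimeError("ISCC-NBS centroid channels outside [0, 255]")
    cats = tuple(
        IsccCategory(
            index=int(row["index"]),
            name=str(row["name"]),
            centroid_srgb=(int(row["r"]), int(row["g"]), int(row["b"])),
            achromatic=bool(row["achromatic"]),
        )
        for row in df.to_dict("records")
    )
    return IsccTable(cats, colour_space_for_matching=colour_space_for_matching)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _validate_rgb(rgb: Sequence[float]) -> tuple[int, int, int]:
    if len(rgb) != 3:
        raise ValueError(f"expected an (r, g, b) triple, got {rgb!r}")
    out = []
    for v in rgb:
        iv = _round_half_up(float(v))
        if not 0 <= iv <= 255:
            raise ValueError(f"channel value {v!r} outside [0, 255]")
        out.append(iv)
    return tuple(out)


def srgb_to_hex(rgb: Sequence[float]) -> str:
    """Encode an sRGB triple as a lowercase 6-digit hex code.

    Non-integer channels are rounded half-up (bin centroids are pixel means
    and rarely integral).
    """
    r, g, b = _validate_rgb(rgb)
    return f"{r:02x}{g:02x}{b:02x}"


def hex_to_srgb(code: str) -> tuple[int, int, int]:
    """Decode a 6-digit hex colour code (with or without leading '#')."""
    code = code.lstrip("#")
    if len(code) != 6:
        raise ValueError(f"expected a 6-digit hex code, got {code!r}")
    return tuple(int(code[i : i + 2], 16) for i in (0, 2, 4))


def classify_srgb_array(rgb: np.ndarray, table: IsccTable) -> np.ndarray:
    """Vectorized nearest-centroid classification of an (n, 3) sRGB array.

    Returns the 1-based category index for each row.  Ties break to the
    lowest category index (argmin on a stable ordering).
    """
    rgb = np.atleast_2d(np.asarray(rgb, dtype=float))
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of sRGB triples")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("sRGB channels must lie in [0, 255]")
    coords = _to_match_space(rgb, table.colour_space_for_matching)
    d2 = ((coords[:, np.newaxis, :] - table._match_coords[np.newaxis, :, :]) ** 2).sum(
        axis=2
    )
    # np.argmin returns the first (lowest-index) minimiser, the tie-break rule
    return np.argmin(d2, axis=1) + 1


def classify_srgb(rgb: Sequence[float], table: IsccTable) -> IsccCategory:
    """Assign one sRGB triple to its nearest ISCC-NBS category.

    Deterministic and total over the sRGB cube; equidistant centroids resolve
    to the lowest category index.
    """
    idx = classify_srgb_array(np.asarray(rgb, dtype=float)[np.newaxis, :], table)[0]
    return table.by_index(int(idx))
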