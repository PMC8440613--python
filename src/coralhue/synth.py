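"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators stand in for the study-scale inputs so every stage is
exercisable offline:

* patch-composed organism images with known colour proportions and known
  ISCC-NBS category sets;
* an ecoregion table in the study's shape — 74 ecoregions, 784 coral
  species, 25 fish families, four ocean regions — where coral richness
  follows a gradient, hue diversity follows a configured saturating
  logistic of coral richness *exactly* (by nested construction), and fish
  richness is drawn from the configured polynomial-plus-hue truth model
  with Gaussian noise;
* meta-analysis comparison tables whose per-class true standardized mean
  difference and heterogeneity are known;
* a reef panel of colourful seascapes plus one achromatic "bleached" scene.

Every generator is a deterministic function of (config, seed).  Fish
richness is rounded to a non-negative integer when noise is present;
in the exact zero-noise regime values are left unrounded so the truth
coefficients remain identifiable to numerical precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .ecoregion import PresenceMatrix
from .hue_quant import HueProfile, write_profiles_csv
from .iscc_nbs import IsccTable, classify_srgb_array, load_iscc_table

__all__ = [
    "SynthConfig",
    "make_coral_image",
    "image_safe_categories",
    "make_ecoregion_dataset",
    "make_regression_table",
    "make_meta_dataset",
    "make_reef_pixel_panel",
    "save_ecoregion_dataset",
]

OCEAN_REGIONS = (
    "Western Pacific",
    "Central and East Pacific",
    "Atlantic",
    "Northern Indian",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped defaults for all generators.

    The regression truth produces fish-richness ranges matching the global
    reef gradient (totals from a few hundred up to ~2500 species) and the
    logistic truth plateaus at 180 unique colours, reached beyond roughly
    300 coral species.
    """

    seed: int = 0
    n_ecoregions: int = 74
    n_coral_species: int = 784
    n_families: int = 25
    image_size: int = 32
    min_coral_richness: int = 20
    # fish_total = b0 + b_hue*hue + b1*coral + b2*coral^2 + N(0, sd)
    regression_truth: tuple[float, float, float, float] = (150.0, 2.0, 3.0, -0.002)
    noise_sd: float = 280.0
    # hue = A / (1 + exp(-k (coral - x0)))
    logistic_truth: tuple[float, float, float] = (180.0, 0.015, 150.0)
    # per response class: (true d, tau2, k comparisons)
    meta_truth: Mapping[str, tuple[float, float, int]] = field(
        default_factory=lambda: {
            "richness": (-0.8, 0.05, 15),
            "abundance": (-0.6, 0.10, 40),
            "recruitment": (-1.2, 0.05, 18),
            "family_abundance": (-0.5, 0.15, 60),
        }
    )
    n_studies: int = 8
    meta_group_n: int = 20


def _logistic(x: np.ndarray, A: float, k: float, x0: float) -> np.ndarray:
    return A / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0)))


def make_coral_image(
    patch_spec: Sequence[tuple[Sequence[int], float]],
    image_size: int,
    path: str | Path,
    contaminants: Sequence[tuple[Sequence[int], float]] = (),
) -> dict:
    """Write a PNG composed of solid vertical stripes with given proportions.

    ``patch_spec`` is a list of ``(srgb_colour, proportion)`` pairs summing
    to 1.  Optional ``contaminants`` are narrow stripes carved out of the
    last patch (intended to sit below the rare-bin threshold).  Returns a
    ground-truth record with the realized pixel proportions per colour.
    """
    props = [p for _, p in patch_spec]
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError(f"patch proportions sum to {sum(props)}, expected 1")
    n_cols = image_size
    widths = [int(round(p * n_cols)) for p in props]
    while sum(widths) > n_cols:
        widths[int(np.argmax(widths))] -= 1
    while sum(widths) < n_cols:
        widths[int(np.argmax(props))] += 1
    img = np.zeros((image_size, n_cols, 3), dtype=np.uint8)
    x = 0
    for (colour, _), w in zip(patch_spec, widths):
        img[:, x : x + w] = np.asarray(colour, dtype=np.uint8)
        x += w
    # contaminants overwrite single pixel-rows at the right edge
    n_pix = image_size * n_cols
    y = 0
    realized_contam = []
    for colour, prop in contaminants:
        rows = max(1, int(round(prop * n_pix)) // 1)
        px = int(round(prop * n_pix))
        col = n_cols - 1
        img[y : y + px, col] = np.asarray(colour, dtype=np.uint8)
        realized_contam.append((tuple(int(c) for c in colour), px / n_pix))
        y += px
    Image.fromarray(img, mode="RGB").save(path)
    counts: dict[tuple, int] = {}
    flat = img.reshape(-1, 3)
    for colour in {tuple(int(c) for c in col) for col, _ in patch_spec} | {
        c for c, _ in realized_contam
    }:
        counts[colour] = int(np.all(flat == np.array(colour), axis=1).sum())
    return {
        "path": str(path),
        "n_pixels": n_pix,
        "proportions": {str(c): n / n_pix for c, n in counts.items()},
        "contaminants": realized_contam,
    }


def image_safe_categories(
    table: IsccTable, bins_per_channel: int = 3
) -> list[int]:
    """Categories usable as exact image ground truth.

    A category qualifies if its centroid classifies back to itself and no
    other qualifying category's centroid shares its histogram bin (so solid
    patches at these colours survive binning as pure, self-classifying
    centroids).  For 3 regions per channel this yields at most 27 categories.
    """
    cents = table.centroids_srgb
    self_cls = classify_srgb_array(cents, table) == np.arange(1, len(table) + 1)
    width = 256.0 / bins_per_channel
    seen_bins: set[tuple[int, ...]] = set()
    safe: list[int] = []
    for cat, (ok, c) in enumerate(zip(self_cls, cents), start=1):
        if not ok:
            continue
        b = tuple(int(v) for v in np.clip(c // width, 0, bins_per_channel - 1))
        if b in seen_bins:
            continue
        seen_bins.add(b)
        safe.append(cat)
    return safe


def _hue_targets(richness: np.ndarray, logistic_truth, max_categories: int) -> np.ndarray:
    t = np.round(_logistic(richness, *logistic_truth)).astype(int)
    return np.clip(t, 1, max_categories)


def make_ecoregion_dataset(
    cfg: SynthConfig,
    zero_noise: bool = False,
    category_pool: Sequence[int] | None = None,
) -> dict:
    """Generate a full ecoregion dataset plus its ground truth.

    Construction: coral richness follows a linear gradient over ecoregions
    from ``min_coral_richness`` to ``n_coral_species``, with a *nested*
    presence structure (the species of a poorer ecoregion are a subset of
    any richer one).  Species are assigned colour categories in nesting
    order so that the cumulative number of unique categories after the
    first r species equals the rounded configured logistic of r — hue
    diversity therefore tracks the logistic truth exactly at every realized
    richness.  Fish richness (total and per family) is drawn from the
    polynomial-plus-hue truth model.

    Returns a dict with ``presence`` (PresenceMatrix), ``profiles``,
    ``fish`` (DataFrame), ``regions`` (Series), and ``truth``.
    """
    rng = np.random.default_rng(cfg.seed)
    A = cfg.logistic_truth[0]
    if category_pool is None:
        if A > 267:
            raise ValueError("logistic asymptote exceeds the 267 ISCC-NBS categories")
        category_pool = list(rng.permutation(np.arange(1, 268))[: int(np.ceil(A)) + 10])
    else:
        category_pool = list(category_pool)
        if A > len(category_pool):
            raise ValueError(
                f"logistic asymptote {A} exceeds the category pool "
                f"({len(category_pool)} categories)"
            )

    n_eco, n_sp = cfg.n_ecoregions, cfg.n_coral_species
    if n_eco > n_sp:
        raise ValueError("cannot give each ecoregion a distinct richness: too few species")
    # strictly increasing richness gradient ending at the full species pool
    richness = np.round(np.linspace(cfg.min_coral_richness, n_sp, n_eco)).astype(int)
    for j in range(1, n_eco):
        richness[j] = max(richness[j], richness[j - 1] + 1)
    richness[-1] = min(richness[-1], n_sp)
    for j in range(n_eco - 2, -1, -1):
        richness[j] = min(richness[j], richness[j + 1] - 1)
    if richness[0] < 1:
        raise ValueError("infeasible richness gradient")

    # cumulative unique-category targets over the nested species order
    per_species_target = _hue_targets(
        np.arange(1, n_sp + 1), cfg.logistic_truth, len(category_pool)
    )
    per_species_target = np.maximum.accumulate(per_species_target)
    profiles: dict[str, HueProfile] = {}
    species_ids = [f"coral_{i:04d}" for i in range(n_sp)]
    used: list[int] = []
    ptr = 0
    for i, sid in enumerate(species_ids):
        target = per_species_target[i]
        new_needed = target - ptr
        cats: set[int] = set()
        if new_needed > 0:
            cats.update(category_pool[ptr : ptr + new_needed])
            ptr += new_needed
        # repeats of already-used categories pad each species to >= 1 colour
        n_repeat = int(rng.integers(1, 3))
        if ptr > 0:
            pool = category_pool[:ptr]
            cats.update(rng.choice(pool, size=min(n_repeat, len(pool)), replace=False))
        profiles[sid] = HueProfile(
            species_id=sid, categories=frozenset(int(c) for c in cats),
            n_bins_retained=len(cats),
        )
        used = category_pool[:ptr]

    eco_ids = [f"eco_{j:02d}" for j in range(n_eco)]
    presence = np.zeros((n_sp, n_eco), dtype=int)
    for j, r in enumerate(richness):
        presence[:r, j] = 1
    matrix = PresenceMatrix(species_ids=species_ids, ecoregion_ids=eco_ids, presence=presence)

    hue = per_species_target[richness - 1].astype(float)
    b0, b_hue, b1, b2 = cfg.regression_truth
    mean_total = b0 + b_hue * hue + b1 * richness + b2 * richness.astype(float) ** 2
    sd = 0.0 if zero_noise else cfg.noise_sd
    fish_total = mean_total + rng.normal(0.0, sd or 0.0, size=n_eco) * (sd > 0)

    fam_names = [f"family_{f:02d}" for f in range(cfg.n_families)]
    fam_scale = np.linspace(0.12, 0.02, cfg.n_families)
    fam_noise = np.linspace(0.2, 2.0, cfg.n_families) * (0.0 if zero_noise else 1.0)
    fam_data = {}
    for f, name in enumerate(fam_names):
        mean_f = fam_scale[f] * mean_total
        vals = mean_f + rng.normal(0.0, fam_noise[f] * max(sd, 1.0), size=n_eco) * (
            fam_noise[f] > 0
        )
        fam_data[name] = vals
    if not zero_noise:
        fish_total = np.maximum(np.round(fish_total), 0)
        for name in fam_names:
            fam_data[name] = np.minimum(
                np.maximum(np.round(fam_data[name]), 0), fish_total
            )
    fish = pd.DataFrame({"fish_total": fish_total}, index=pd.Index(eco_ids, name="ecoregion_id"))
    for name in fam_names:
        fish[f"fish_{name}"] = fam_data[name]

    # contiguous richness blocks per ocean region, richest block = Western Pacific
    region_labels = np.array(
        [OCEAN_REGIONS[min(3, (n_eco - 1 - j) * 4 // max(n_eco, 1))] for j in range(n_eco)]
    )
    regions = pd.Series(region_labels, index=pd.Index(eco_ids, name="ecoregion_id"),
                        name="ocean_region")

    truth = {
        "regression_truth": list(cfg.regression_truth),
        "noise_sd": sd,
        "logistic_truth": list(cfg.logistic_truth),
        "coral_richness": richness.tolist(),
        "hue_diversity": hue.astype(int).tolist(),
        "family_scale": fam_scale.tolist(),
        "family_noise_sd": (fam_noise * max(sd, 1.0)).tolist(),
        "category_pool_used": [int(c) for c in used],
        "species_categories": {
            s: sorted(p.categories) for s, p in profiles.items()
        },
    }
    return {
        "presence": matrix,
        "profiles": profiles,
        "fish": fish,
        "regions": regions,
        "truth": truth,
    }


def save_ecoregion_dataset(dataset: dict, out_dir: str | Path) -> None:
    """Write a generated dataset to CSV files plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset["presence"].to_frame().to_csv(out / "presence.csv", index_label="species_id")
    write_profiles_csv(dataset["profiles"], out / "profiles.csv")
    dataset["fish"].to_csv(out / "fish_richness.csv")
    dataset["regions"].to_frame().to_csv(out / "regions.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset["truth"], fh, indent=1)


def write_species_images(
    dataset: dict, table: IsccTable, out_dir: str | Path, image_size: int = 32
) -> dict[str, Path]:
    """Render each species' category set as a patch image.

    Patches are solid stripes at the categories' centroid colours with equal
    proportions, so quantifying the image recovers exactly the intended
    category set (requires the dataset to have been generated from an
    image-safe category pool; see :func:`image_safe_categories`).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, profile in dataset["profiles"].items():
        cats = sorted(profile.categories)
        spec = [
            (table.by_index(c).centroid_srgb, 1.0 / len(cats)) for c in cats
        ]
        p = out / f"{sid}.png"
        make_coral_image(spec, image_size, p)
        paths[sid] = p
    return paths


def make_regression_table(
    cfg: SynthConfig,
    seed: int | None = None,
    zero_noise: bool = False,
    hue_noise_sd: float = 6.0,
) -> tuple[pd.DataFrame, dict]:
    """Draw an ecoregion-shaped regression table directly from the truth models.

    A lighter companion to :func:`make_ecoregion_dataset` for model-recovery
    simulations: hue diversity is sampled around the logistic truth with
    Gaussian scatter (``hue_noise_sd`` categories, reflecting ecoregion-level
    variation in colour composition at a given coral richness) rather than
    constructed from species colour sets, so the hue predictor varies within
    every ocean region, including on the plateau.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_eco = cfg.n_ecoregions
    richness = np.round(
        np.linspace(cfg.min_coral_richness, cfg.n_coral_species, n_eco)
    ).astype(float)
    hue_mean = _logistic(richness, *cfg.logistic_truth)
    sd_h = 0.0 if zero_noise else hue_noise_sd
    hue = np.maximum(np.round(hue_mean + rng.normal(0.0, sd_h or 1.0, n_eco) * (sd_h > 0)), 1.0)
    b0, b_hue, b1, b2 = cfg.regression_truth
    mean_total = b0 + b_hue * hue + b1 * richness + b2 * richness**2
    sd = 0.0 if zero_noise else cfg.noise_sd
    fish = mean_total + rng.normal(0.0, sd or 1.0, n_eco) * (sd > 0)
    if not zero_noise:
        fish = np.maximum(np.round(fish), 0.0)
    eco_ids = [f"eco_{j:02d}" for j in range(n_eco)]
    region_labels = [
        OCEAN_REGIONS[min(3, (n_eco - 1 - j) * 4 // max(n_eco, 1))] for j in range(n_eco)
    ]
    df = pd.DataFrame(
        {
            "ecoregion_id": eco_ids,
            "ocean_region": region_labels,
            "coral_richness": richness,
            "hue_diversity": hue,
            "fish_total": fish,
        }
    )
    truth = {
        "regression_truth": list(cfg.regression_truth),
        "logistic_truth": list(cfg.logistic_truth),
        "noise_sd": sd,
        "hue_noise_sd": sd_h,
    }
    return df, truth


def make_meta_dataset(cfg: SynthConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a comparisons table with known per-class true effects.

    For each comparison the study-level true effect is drawn as
    ``theta ~ N(d_true, tau2)``; group observations are then sampled as
    ``N(theta, 1)`` (treatment) and ``N(0, 1)`` (control) and summarized,
    so observed effects carry realistic sampling error.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    fam_cycle = [f"family_{f:02d}" for f in range(max(cfg.n_families, 1))]
    idx = 0
    for cls, (d_true, tau2, k) in cfg.meta_truth.items():
        for i in range(k):
            theta = rng.normal(d_true, np.sqrt(tau2))
            n = int(cfg.meta_group_n + rng.integers(-5, 6))
            treat = rng.normal(theta, 1.0, size=n)
            ctrl = rng.normal(0.0, 1.0, size=n)
            rows.append(
                {
                    "study_id": f"study_{idx % cfg.n_studies + 1}",
                    "response_class": cls,
                    "family": fam_cycle[i % len(fam_cycle)]
                    if cls == "family_abundance"
                    else "",
                    "mean_treat": float(treat.mean()),
                    "sd_treat": float(treat.std(ddof=1)),
                    "n_treat": n,
                    "mean_ctrl": float(ctrl.mean()),
                    "sd_ctrl": float(ctrl.std(ddof=1)),
                    "n_ctrl": n,
                }
            )
            idx += 1
    truth = {cls: {"d": d, "tau2": t, "k": k} for cls, (d, t, k) in cfg.meta_truth.items()}
    return pd.DataFrame(rows), truth


def make_reef_pixel_panel(
    seed: int = 0, n_colourful: int = 5, n_pixels: int = 4096
) -> dict[str, np.ndarray]:
    """Pixel arrays for a panel of colourful reefs plus one bleached scene.

    Colourful reefs mix saturated hues drawn from well-separated corners of
    the sRGB cube; the bleached reef concentrates nearly all mass in pale,
    achromatic shades — mirroring the colour homogenization bleaching causes.
    """
    rng = np.random.default_rng(seed)
    saturated = np.array(
        [
            [200, 30, 40], [230, 120, 20], [240, 200, 30], [40, 160, 60],
            [30, 90, 200], [140, 40, 180], [20, 180, 170], [250, 80, 140],
        ],
        dtype=float,
    )
    panel: dict[str, np.ndarray] = {}
    for i in range(n_colourful):
        k = int(rng.integers(4, 7))
        cols = saturated[rng.choice(len(saturated), size=k, replace=False)]
        w = rng.dirichlet(np.ones(k) * 5.0)
        counts = np.maximum((w * n_pixels).astype(int), int(0.02 * n_pixels))
        px = np.vstack(
            [
                np.clip(c + rng.normal(0, 6, size=(m, 3)), 0, 255)
                for c, m in zip(cols, counts)
            ]
        )
        panel[f"reef_{i}"] = px
    pale = np.array([[235, 235, 230], [220, 218, 210], [245, 244, 240]], dtype=float)
    counts = [int(0.5 * n_pixels), int(0.3 * n_pixels), int(0.2 * n_pixels)]
    px = np.vstack(
        [
            np.clip(c + rng.normal(0, 3, size=(m, 3)), 0, 255)
            for c, m in zip(pale, counts)
        ]
    )
    panel["bleached"] = px
    return panel
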