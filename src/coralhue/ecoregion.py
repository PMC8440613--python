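"""Per-ecoregion assembly of coral richness, hue diversity, and fish richness.

An ecoregion is a geographic unit within which coral and fish species
presence is tallied.  Coral richness is the number of coral species present;
hue diversity is the number of unique ISCC-NBS categories contributed by the
corals present (the union of their hue profiles); fish richness is taken
from per-ecoregion tables, both in total and per family.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .hue_quant import HueProfile

__all__ = [
    "PresenceMatrix",
    "coral_richness",
    "ecoregion_hue_diversity",
    "assemble_table",
    "read_presence_csv",
    "read_fish_csv",
    "read_regions_csv",
]

FAMILY_PREFIX = "fish_"


@dataclass
class PresenceMatrix:
    """Binary species x ecoregion presence matrix."""

    species_ids: list[str]
    ecoregion_ids: list[str]
    presence: np.ndarray  # shape (n_species, n_ecoregions), 0/1

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.species_ids), len(self.ecoregion_ids)):
            raise ValueError("presence shape does not match id lists")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if len(set(self.ecoregion_ids)) != len(self.ecoregion_ids):
            raise ValueError("duplicate ecoregion ids")
        self._ecol = {e: j for j, e in enumerate(self.ecoregion_ids)}

    def species_in(self, ecoregion_id: str) -> list[str]:
        """Species present in one ecoregion."""
        j = self._ecol[ecoregion_id]
        return [s for s, p in zip(self.species_ids, self.presence[:, j]) if p]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence, index=self.species_ids, columns=self.ecoregion_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceMatrix":
        return cls(
            species_ids=[str(s) for s in df.index],
            ecoregion_ids=[str(e) for e in df.columns],
            presence=df.to_numpy(dtype=int),
        )


def coral_richness(matrix: PresenceMatrix, ecoregion_id: str) -> int:
    """Number of coral species present in an ecoregion."""
    if ecoregion_id not in matrix._ecol:
        raise KeyError(f"unknown ecoregion {ecoregion_id!r}")
    return int(matrix.presence[:, matrix._ecol[ecoregion_id]].sum())


def ecoregion_hue_diversity(
    matrix: PresenceMatrix,
    profiles: Mapping[str, HueProfile],
    ecoregion_id: str,
) -> int:
    """Number of unique ISCC-NBS categories over the ecoregion's corals.

    The union of the hue profiles of all present species; duplicated colours
    across species count once.
    """
    present = matrix.species_in(ecoregion_id)
    missing = [s for s in present if s not in profiles]
    if missing:
        raise ValueError(
            f"ecoregion {ecoregion_id!r}: species without hue profiles: {missing}"
        )
    cats: set[int] = set()
    for s in present:
        cats |= set(profiles[s].categories)
    return len(cats)


def read_presence_csv(path: str | Path) -> PresenceMatrix:
    """Read a species x ecoregion binary matrix (first column = species id)."""
    df = pd.read_csv(path, index_col=0)
    return PresenceMatrix.from_frame(df)


def read_fish_csv(path: str | Path) -> pd.DataFrame:
    """Read per-ecoregion fish richness: ecoregion_id, fish_total, fish_<family>..."""
    df = pd.read_csv(path, dtype={"ecoregion_id": str}).set_index("ecoregion_id")
    if "fish_total" not in df.columns:
        raise ValueError("fish table must contain a 'fish_total' column")
    return df


def read_regions_csv(path: str | Path) -> pd.Series:
    """Read ecoregion -> ocean region labels."""
    df = pd.read_csv(path, dtype=str)
    return df.set_index("ecoregion_id")["ocean_region"]


def assemble_table(
    matrix: PresenceMatrix,
    profiles: Mapping[str, HueProfile],
    fish: pd.DataFrame,
    regions: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Build the tidy per-ecoregion analysis table.

    Returns a DataFrame with one row per ecoregion and columns
    ``ecoregion_id, ocean_region, coral_richness, hue_diversity, fish_total``
    plus one ``fish_<family>`` column per family in the fish table.

    Raises
    ------
    ValueError
        On any id mismatch between the inputs, listing the offenders.
    """
    regions = pd.Series(dict(regions)) if not isinstance(regions, pd.Series) else regions
    eids = list(matrix.ecoregion_ids)
    problems = []
    missing_fish = [e for e in eids if e not in fish.index]
    if missing_fish:
        problems.append(f"ecoregions missing from fish table: {missing_fish}")
    missing_reg = [e for e in eids if e not in regions.index]
    if missing_reg:
        problems.append(f"ecoregions missing from regions table: {missing_reg}")
    if not problems:
        bad = [e for e in eids if fish.loc[e].isna().any()]
        if bad:
            problems.append(f"fish table has missing values for: {bad}")
        neg = [e for e in eids if (fish.loc[e] < 0).any()]
        if neg:
            problems.append(f"fish table has negative counts for: {neg}")
    if problems:
        raise ValueError("; ".join(problems))

    family_cols = [c for c in fish.columns if c.startswith(FAMILY_PREFIX) and c != "fish_total"]
    rows = []
    for e in eids:
        rec = {
            "ecoregion_id": e,
            "ocean_region": regions[e],
            "coral_richness": coral_richness(matrix, e),
            "hue_diversity": ecoregion_hue_diversity(matrix, profiles, e),
            "fish_total": float(fish.loc[e, "fish_total"]),
        }
        for c in family_cols:
            rec[c] = float(fish.loc[e, c])
        fam_max = max((rec[c] for c in family_cols), default=0)
        if rec["fish_total"] < fam_max:
            raise ValueError(
                f"ecoregion {e!r}: fish_total {rec['fish_total']} below the "
                f"largest family count {fam_max}"
            )
        rows.append(rec)
    return pd.DataFrame(rows)
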