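"""Female-fitness measures from raw reproductive components.

Four per-plant fitness measures are derived from fruit fates and egg
surveys:

* total seeds (with imputation for dehisced fruits and early-collected
  flowers),
* seeds initiated per flower (pollination success, insulated from
  predation),
* proportion of fruits escaping predispersal seed predation,
* fly eggs per flower.

Each measure is then relativized by its grand mean across all plants and
years.  Records whose components make a measure undefined are flagged
missing (never silently zeroed) with a reason string, so downstream
selection models can exclude them pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantReproRecord",
    "FitnessValue",
    "total_seeds",
    "seeds_initiated_per_flower",
    "escape_predation",
    "eggs_per_flower",
    "relativize",
    "fitness_table",
    "records_from_frame",
    "MEASURES",
]

MEASURES = ("total_seeds", "seeds_per_flower", "escape_predation", "eggs_per_flower")


@dataclass
class PlantReproRecord:
    """Raw reproductive components for one plant.

    ``fruits_intact_undehisced`` holds the directly counted seed number of
    each intact, undehisced fruit.  All other fruit fates are counts.
    ``flowers_surveyed`` is the season total of open flowers plus elongated
    buds over the weekly egg surveys.
    """

    plant_id: str
    flowers_total: int
    aborted: int
    fruits_intact_undehisced: Sequence[float] = field(default_factory=list)
    fruits_dehisced: int = 0
    fruits_fly: int = 0
    fruits_caterpillar: int = 0
    flowers_collected_early: int = 0
    eggs_total: int = 0
    flowers_surveyed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.aborted,
            self.fruits_dehisced,
            self.fruits_fly,
            self.fruits_caterpillar,
            self.flowers_collected_early,
            self.eggs_total,
            self.flowers_surveyed,
        )
        if any(c < 0 for c in counts) or any(s < 0 for s in self.fruits_intact_undehisced):
            raise ValueError(f"negative count in record for plant {self.plant_id!r}")
        accounted = (
            self.aborted
            + self.n_intact
            + self.fruits_dehisced
            + self.fruits_fly
            + self.fruits_caterpillar
            + self.flowers_collected_early
        )
        if accounted != self.flowers_total:
            raise ValueError(
                f"flower accounting identity violated for plant {self.plant_id!r}: "
                f"components sum to {accounted}, flowers_total is {self.flowers_total}"
            )

    @property
    def n_intact(self) -> int:
        return len(self.fruits_intact_undehisced)

    @property
    def flowers_at_risk(self) -> int:
        """Flowers that could have set fruit (early collections excluded)."""
        return self.flowers_total - self.flowers_collected_early

    @property
    def nonaborted(self) -> int:
        return self.flowers_at_risk - self.aborted

    @property
    def attacked(self) -> int:
        return self.fruits_fly + self.fruits_caterpillar


@dataclass
class FitnessValue:
    """A fitness measure that may be missing, with the reason recorded."""

    value: float
    missing_reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.missing_reason is not None


def _missing(reason: str) -> FitnessValue:
    return FitnessValue(float("nan"), reason)


def total_seeds(rec: PlantReproRecord) -> FitnessValue:
    """Total seeds produced, imputing dehisced fruits and early collections.

    Dehisced fruits contribute the plant's mean seeds per intact fruit;
    early-collected flowers contribute the mean seeds per flower that was
    allowed to set seed on the plant.  Attacked (eaten) fruits contribute
    zero.
    """
    counted = float(sum(rec.fruits_intact_undehisced))
    if rec.fruits_dehisced > 0:
        if rec.n_intact == 0:
            return _missing("dehisced fruits present but no intact fruit to impute from")
        counted += rec.fruits_dehisced * (
            float(sum(rec.fruits_intact_undehisced)) / rec.n_intact
        )
    if rec.flowers_collected_early > 0:
        allowed = rec.flowers_total - rec.flowers_collected_early
        if allowed == 0:
            return _missing("all flowers collected early; seed imputation impossible")
        counted += rec.flowers_collected_early * (counted / allowed)
    return FitnessValue(counted)


def seeds_initiated_per_flower(rec: PlantReproRecord) -> FitnessValue:
    """Nonaborted fruits per flower at risk times seeds per noneaten fruit."""
    if rec.flowers_at_risk == 0:
        raise ValueError(f"plant {rec.plant_id!r} has zero flowers at risk")
    if rec.nonaborted == 0:
        return FitnessValue(0.0)
    noneaten = rec.n_intact + rec.fruits_dehisced
    if noneaten == 0:
        return _missing("no noneaten fruit to estimate seeds per fruit")
    if rec.n_intact == 0:
        return _missing("noneaten fruits all dehisced; seeds per fruit unknown")
    # dehisced fruits carry the plant-mean imputation, so the mean over
    # noneaten fruits equals the mean over intact fruits
    mean_seeds = float(sum(rec.fruits_intact_undehisced)) / rec.n_intact
    return FitnessValue(rec.nonaborted / rec.flowers_at_risk * mean_seeds)


def escape_predation(rec: PlantReproRecord) -> FitnessValue:
    """1 minus the proportion of nonaborted fruits attacked by flies or caterpillars."""
    if rec.nonaborted < 1:
        return _missing("no nonaborted fruits; attack proportion undefined")
    if rec.attacked > rec.nonaborted:
        raise ValueError(
            f"plant {rec.plant_id!r}: attacked fruits ({rec.attacked}) exceed "
            f"nonaborted fruits ({rec.nonaborted})"
        )
    return FitnessValue(1.0 - rec.attacked / rec.nonaborted)


def eggs_per_flower(rec: PlantReproRecord) -> FitnessValue:
    """Season egg total divided by season total of surveyed flowers and buds."""
    if rec.flowers_surveyed < 1:
        return _missing("no flowers surveyed for eggs")
    return FitnessValue(rec.eggs_total / rec.flowers_surveyed)


def relativize(values: pd.Series | np.ndarray) -> pd.Series:
    """Divide by the grand mean pooled over all plants and years.

    Missing values are ignored in the mean and propagate in the output.
    """
    s = pd.Series(values, dtype=float)
    grand_mean = s.mean(skipna=True)
    if not math.isfinite(grand_mean) or grand_mean <= 0:
        raise ValueError(f"grand mean must be positive, got {grand_mean}")
    return s / grand_mean


def fitness_table(records: Sequence[PlantReproRecord]) -> pd.DataFrame:
    """Compute all four fitness measures, raw and relativized, per plant.

    Returns one row per plant with raw columns, ``*_rel`` relativized
    columns, and a semicolon-joined ``missing_reason`` column.
    """
    rows = []
    for rec in records:
        vals = {
            "total_seeds": total_seeds(rec),
            "seeds_per_flower": seeds_initiated_per_flower(rec),
            "escape_predation": escape_predation(rec),
            "eggs_per_flower": eggs_per_flower(rec),
        }
        reasons = [
            f"{name}: {v.missing_reason}" for name, v in vals.items() if v.is_missing
        ]
        rows.append(
            {
                "plant_id": rec.plant_id,
                **{name: v.value for name, v in vals.items()},
                "missing_reason": "; ".join(reasons) if reasons else "",
            }
        )
    table = pd.DataFrame(rows)
    for name in MEASURES:
        table[name + "_rel"] = relativize(table[name])
    return table


def records_from_frame(frame: pd.DataFrame) -> list[PlantReproRecord]:
    """Build records from a fitness-components table.

    ``intact_seed_counts`` is a semicolon-joined list of per-fruit seed
    counts ("" for none); other columns are integer counts.
    """
    records = []
    for _, row in frame.iterrows():
        raw = str(row.get("intact_seed_counts", "") or "")
        seed_counts = [float(x) for x in raw.split(";") if x.strip() != ""]
        records.append(
            PlantReproRecord(
                plant_id=str(row["plant_id"]),
                flowers_total=int(row["flowers_total"]),
                aborted=int(row["aborted"]),
                fruits_intact_undehisced=seed_counts,
                fruits_dehisced=int(row["fruits_dehisced"]),
                fruits_fly=int(row["fruits_fly"]),
                fruits_caterpillar=int(row["fruits_caterpillar"]),
                flowers_collected_early=int(row["flowers_collected_early"]),
                eggs_total=int(row["eggs_total"]),
                flowers_surveyed=int(row["flowers_surveyed"]),
            )
        )
    return records
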