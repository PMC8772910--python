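"""Cohort arithmetic for the rider:horse bodyweight-ratio study design.

The study rides each of 12 horses under each of 6 riders, the riders being
pre-assigned to light (L), moderate (M) and heavy (H) bodyweight groups.  The
design quantity is the rider:horse bodyweight ratio

    R/H = 100 * (rider bodyweight + saddle weight) / horse bodyweight  [%]

banded as L: 10-12 %, M: >12-15 %, H: >15-18 %.  Rider size is additionally
summarised by BMI (kg/m^2) with the usual WHO bands.  All printed design
quantities are 1-decimal values, so ratios and BMIs are rounded half-up to one
decimal *before* banding and summarising.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RiderRecord",
    "HorseRecord",
    "CombinationRecord",
    "compute_bmi",
    "classify_bmi",
    "compute_rh_ratio",
    "assign_weight_group",
    "build_combination_table",
    "summarize_groups",
    "reference_riders",
    "reference_horses",
    "reference_ratio_grid",
    "read_rider_csv",
    "read_horse_csv",
    "write_combination_csv",
]

WEIGHT_GROUPS = ("L", "M", "H")
OUT_OF_DESIGN = "out-of-design"


def round1(x: float) -> float:
    """Round half-up to one decimal, as in the printed design tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2, rounded half-up to one decimal."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return round1(weight_kg / (height_cm / 100.0) ** 2)


def classify_bmi(bmi: float) -> str:
    """WHO BMI band: underweight (<18.5), normal, overweight, obese (>=30)."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def compute_rh_ratio(rider_bw: float, saddle_bw: float, horse_bw: float) -> float:
    """Rider:horse bodyweight ratio, percent of horse bodyweight, 1 decimal.

    The saddle rides with the rider, so its weight counts toward the load.
    """
    if rider_bw <= 0 or horse_bw <= 0 or saddle_bw < 0:
        raise ValueError("bodyweights must be positive (saddle may be zero)")
    return round1(100.0 * (rider_bw + saddle_bw) / horse_bw)


def assign_weight_group(ratio: float) -> str:
    """Band a 1-decimal ratio into L (10-12), M (>12-15), H (>15-<18).

    Ratios outside [10, 18) are labelled ``out-of-design`` rather than
    rejected, so stress tests may probe the band edges.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if 10.0 <= ratio <= 12.0:
        return "L"
    if 12.0 < ratio <= 15.0:
        return "M"
    if 15.0 < ratio < 18.0:
        return "H"
    return OUT_OF_DESIGN


@dataclass(frozen=True)
class RiderRecord:
    """One rider, weighed with full equestrian equipment."""

    id: str
    bodyweight: float  # kg
    height: float  # cm
    group: str | None = None
    bmi: float = field(init=False)
    bmi_category: str = field(init=False)

    def __post_init__(self) -> None:
        if self.bodyweight <= 0 or self.height <= 0:
            raise ValueError(f"rider {self.id}: bodyweight and height must be positive")
        object.__setattr__(self, "bmi", compute_bmi(self.bodyweight, self.height))
        object.__setattr__(self, "bmi_category", classify_bmi(self.bmi))


@dataclass(frozen=True)
class HorseRecord:
    """One horse with its individually fitted saddle."""

    id: str
    bodyweight: float  # kg
    height_withers: float  # cm
    saddle_weight: float  # kg

    def __post_init__(self) -> None:
        if min(self.bodyweight, self.height_withers, self.saddle_weight) <= 0:
            raise ValueError(f"horse {self.id}: all fields must be positive")
        if self.saddle_weight >= self.bodyweight:
            raise ValueError(f"horse {self.id}: saddle heavier than horse")


@dataclass(frozen=True)
class CombinationRecord:
    """One rider x horse realization of the study design."""

    rider_id: str
    horse_id: str
    ratio: float  # percent of horse bodyweight, 1 decimal
    group: str


def build_combination_table(
    riders: Sequence[RiderRecord], horses: Sequence[HorseRecord]
) -> list[CombinationRecord]:
    """All rider x horse combinations with their ratio and weight group."""
    if not riders or not horses:
        raise ValueError("riders and horses must be non-empty")
    for label, recs in (("rider", riders), ("horse", horses)):
        ids = [r.id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate {label} ids")
    table = []
    for rider in riders:
        for horse in horses:
            ratio = compute_rh_ratio(rider.bodyweight, horse.saddle_weight, horse.bodyweight)
            table.append(
                CombinationRecord(rider.id, horse.id, ratio, assign_weight_group(ratio))
            )
    return table


def summarize_groups(records: Iterable[CombinationRecord]) -> dict[str, dict[str, float | tuple]]:
    """Per-group mean and (min, max) range of the 1-decimal ratios.

    Groups with no members are simply absent from the result.
    """
    by_group: dict[str, list[float]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec.ratio)
    out = {}
    for group, ratios in by_group.items():
        out[group] = {
            "n": len(ratios),
            "mean": round1(sum(ratios) / len(ratios)),
            "range": (min(ratios), max(ratios)),
        }
    return out


def summarize_riders(riders: Sequence[RiderRecord]) -> dict[str, dict[str, float | tuple]]:
    """Per-group rider bodyweight and BMI: mean (1 decimal) and (min, max)."""
    by_group: dict[str, list[RiderRecord]] = {}
    for r in riders:
        by_group.setdefault(r.group or "?", []).append(r)
    out = {}
    for group, recs in by_group.items():
        bw = [r.bodyweight for r in recs]
        bmi = [r.bmi for r in recs]
        out[group] = {
            "n": len(recs),
            "bodyweight_mean": round1(sum(bw) / len(bw)),
            "bodyweight_range": (min(bw), max(bw)),
            "bmi_mean": round1(sum(bmi) / len(bmi)),
            "bmi_range": (min(bmi), max(bmi)),
        }
    return out


# --------------------------------------------------------------------------
# Published reference cohort (riders A-F, horses 1-12) and the ratio grid it
# implies.  These printed values serve as the ground truth for validating the
# design arithmetic and as a ready-made input for report generation.

_RIDERS = (
    ("A", 58, 159, "L"),
    ("B", 60, 160, "L"),
    ("C", 77, 172, "M"),
    ("D", 75, 164, "M"),
    ("E", 91, 172, "H"),
    ("F", 92, 174, "H"),
)

_HORSES = (
    ("1", 585, 166, 4.1),
    ("2", 550, 154, 4.5),
    ("3", 580, 158, 4.2),
    ("4", 575, 164, 4.5),
    ("5", 560, 160, 4.1),
    ("6", 550, 156, 4.4),
    ("7", 560, 162, 4.2),
    ("8", 545, 157, 4.2),
    ("9", 570, 158, 4.4),
    ("10", 580, 162, 4.4),
    ("11", 565, 160, 4.2),
    ("12", 580, 166, 4.2),
)

# Published rider x horse ratio grid (%), rows A-F, columns horses 1-12.
_RATIO_GRID = (
    (10.6, 11.4, 10.7, 10.9, 11.1, 11.3, 11.1, 11.4, 10.9, 10.8, 11.0, 10.7),
    (11.0, 11.7, 11.1, 11.2, 11.4, 11.7, 11.5, 11.8, 11.3, 11.1, 11.4, 11.1),
    (13.9, 14.8, 14.0, 14.2, 14.5, 14.8, 14.5, 14.9, 14.3, 14.0, 14.4, 14.0),
    (13.5, 14.5, 13.7, 13.8, 14.1, 14.4, 14.1, 14.5, 13.9, 13.7, 14.0, 13.7),
    (16.3, 17.4, 16.4, 16.6, 17.0, 17.3, 17.0, 17.5, 16.7, 16.4, 16.8, 16.4),
    (16.4, 17.5, 16.6, 16.8, 17.2, 17.5, 17.2, 17.7, 16.9, 16.6, 17.0, 16.6),
)


def reference_riders() -> list[RiderRecord]:
    """The six published riders (A-F) with their group assignment."""
    return [RiderRecord(i, bw, h, g) for i, bw, h, g in _RIDERS]


def reference_horses() -> list[HorseRecord]:
    """The twelve published horses (1-12) with their saddle weights."""
    return [HorseRecord(i, bw, h, sw) for i, bw, h, sw in _HORSES]


def reference_ratio_grid() -> dict[tuple[str, str], float]:
    """Published ratio per (rider_id, horse_id) pair."""
    return {
        (rider[0], horse[0]): _RATIO_GRID[ri][hi]
        for ri, rider in enumerate(_RIDERS)
        for hi, horse in enumerate(_HORSES)
    }


# --------------------------------------------------------------------------
# CSV interfaces


def read_rider_csv(path: str | Path) -> list[RiderRecord]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        RiderRecord(
            row["rider_id"],
            float(row["bodyweight_kg"]),
            float(row["height_cm"]),
            row.get("group") or None,
        )
        for row in rows
    ]


def read_horse_csv(path: str | Path) -> list[HorseRecord]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        HorseRecord(
            row["horse_id"],
            float(row["bodyweight_kg"]),
            float(row["height_cm"]),
            float(row["saddle_kg"]),
        )
        for row in rows
    ]


def write_combination_csv(records: Sequence[CombinationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rider_id", "horse_id", "ratio_pct", "group"])
        for rec in records:
            writer.writerow([rec.rider_id, rec.horse_id, f"{rec.ratio:.1f}", rec.group])
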