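"""Dose-volume histogram metrics and the three-tier plan classifier.

A plan is graded against a table of dose constraints in which each row has
a *per protocol* (ideal) bound and a looser *variation acceptable* bound.
The overall verdict is:

* ``per_protocol`` — every row meets its per-protocol bound;
* ``acceptable``   — every row meets at least its variation bound;
* ``unacceptable`` — some row misses even the variation bound.

Boundary semantics follow the printed constraints: target rows are
``at_least`` bounds and pass at equality (V ≥ bound); organ-at-risk rows
are ``less_than`` bounds and fail at equality (V < bound).

Metrics are computed exactly from voxel doses (dose-at-voxel-center, no
surface interpolation); the binned DVH curve is for export/plotting only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import yaml

from .dose_engine import DoseGrid
from .grid import Structure

__all__ = [
    "DVHCurve",
    "CriterionRow",
    "CriteriaSet",
    "RowVerdict",
    "PlanEvaluation",
    "PlanClass",
    "cumulative_dvh",
    "metric_v",
    "metric_d",
    "classify_plan",
    "evaluate_plan",
    "load_criteria",
    "save_criteria",
    "default_criteria",
]

PlanClass = Literal["per_protocol", "acceptable", "unacceptable"]


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving ≥ each dose."""

    dose_bins_gy: np.ndarray
    volume_fraction: np.ndarray
    total_volume_cm3: float

    def volume_at(self, dose_gy: float) -> float:
        """Fraction of volume at/above ``dose_gy`` (nearest bin at/below)."""
        idx = int(np.searchsorted(self.dose_bins_gy, dose_gy, side="right")) - 1
        idx = max(idx, 0)
        return float(self.volume_fraction[idx])


def _mask_doses(dose: DoseGrid, mask: Structure) -> np.ndarray:
    if not dose.grid.compatible(mask.grid):
        raise ValueError("dose and structure are on incompatible grids")
    if mask.is_empty:
        raise ValueError(f"structure '{mask.name}' is empty")
    return dose.values[mask.mask]


def cumulative_dvh(
    dose: DoseGrid, mask: Structure, bin_width_gy: float = 0.1
) -> DVHCurve:
    """Cumulative DVH of a structure on dose bins of ``bin_width_gy``."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    d = _mask_doses(dose, mask)
    top = float(d.max()) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(np.sort(d), edges, side="left") / d.size
    return DVHCurve(edges, frac, mask.volume_cm3)


def metric_v(
    dose: DoseGrid,
    mask: Structure,
    dose_level_gy: float,
    mode: Literal["percent", "cm3"] = "percent",
) -> float:
    """V_D: structure volume receiving ≥ ``dose_level_gy``, in % or cm³."""
    d = _mask_doses(dose, mask)
    hit = int((d >= dose_level_gy).sum())
    if mode == "percent":
        return 100.0 * hit / d.size
    if mode == "cm3":
        return hit * mask.grid.voxel_volume_cm3
    raise ValueError(f"unknown mode {mode!r}")


def metric_d(
    dose: DoseGrid, mask: Structure, which: Literal["mean", "1cm3"] = "mean"
) -> float:
    """D_mean or D_1cm³ (minimum dose of the hottest 1 cm³), in Gy."""
    d = _mask_doses(dose, mask)
    if which == "mean":
        return float(d.mean())
    if which == "1cm3":
        voxvol = mask.grid.voxel_volume_cm3
        n_target = 1.0 / voxvol
        d_sorted = np.sort(d)[::-1]
        if n_target >= d.size:
            warnings.warn(
                f"structure '{mask.name}' is smaller than 1 cm³; "
                "D_1cm3 falls back to the structure minimum dose",
                stacklevel=2,
            )
            return float(d_sorted[-1])
        lo = int(np.floor(n_target))
        if lo == n_target:
            return float(d_sorted[lo - 1])
        frac = n_target - lo
        return float((1.0 - frac) * d_sorted[lo - 1] + frac * d_sorted[lo])
    raise ValueError(f"unknown metric {which!r}")


# ---------------------------------------------------------------------------
# criteria table


@dataclass(frozen=True)
class CriterionRow:
    """One constraint row: a DVH metric with per-protocol and variation bounds."""

    structure: str
    metric: Literal["V"]
    dose_level_gy: float
    unit: Literal["percent", "cm3"]
    per_protocol: float
    variation: float
    direction: Literal["at_least", "less_than"]

    def __post_init__(self) -> None:
        # per-protocol must be at least as strict as variation-acceptable
        if self.direction == "at_least" and self.per_protocol < self.variation:
            raise ValueError(
                f"{self.key}: per-protocol bound {self.per_protocol} looser "
                f"than variation bound {self.variation} under 'at_least'"
            )
        if self.direction == "less_than" and self.per_protocol > self.variation:
            raise ValueError(
                f"{self.key}: per-protocol bound {self.per_protocol} looser "
                f"than variation bound {self.variation} under 'less_than'"
            )

    @property
    def key(self) -> str:
        level = f"{self.dose_level_gy:g}".replace(".", "p")
        return f"{self.structure}_v{level}gy"

    def passes(self, value: float, bound: float) -> bool:
        if self.direction == "at_least":
            return value >= bound
        return value < bound

    def verdict(self, value: float) -> str:
        if self.passes(value, self.per_protocol):
            return "per_protocol"
        if self.passes(value, self.variation):
            return "variation"
        return "fail"


@dataclass
class CriteriaSet:
    rows: list[CriterionRow]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate criterion rows")

    def __len__(self) -> int:
        return len(self.rows)

    def structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.structure)
        return list(seen)


@dataclass
class RowVerdict:
    row: CriterionRow
    value: float
    verdict: Literal["per_protocol", "variation", "fail"]


@dataclass
class PlanEvaluation:
    per_row: list[RowVerdict]
    overall: PlanClass

    @property
    def acceptable(self) -> bool:
        return self.overall in ("per_protocol", "acceptable")


def classify_plan(
    values: Mapping[str, float], criteria: CriteriaSet
) -> PlanEvaluation:
    """Grade metric values (keyed by :attr:`CriterionRow.key`) against the table."""
    per_row: list[RowVerdict] = []
    for row in criteria.rows:
        if row.key not in values:
            raise ValueError(f"missing metric value for criterion '{row.key}'")
        v = float(values[row.key])
        per_row.append(RowVerdict(row, v, row.verdict(v)))
    if all(r.verdict == "per_protocol" for r in per_row):
        overall: PlanClass = "per_protocol"
    elif all(r.verdict in ("per_protocol", "variation") for r in per_row):
        overall = "acceptable"
    else:
        overall = "unacceptable"
    return PlanEvaluation(per_row, overall)


def evaluate_plan(
    dose: DoseGrid,
    structures: Mapping[str, Structure],
    criteria: CriteriaSet,
) -> tuple[PlanEvaluation, dict[str, float]]:
    """Compute every criterion metric from a dose and classify the plan."""
    values: dict[str, float] = {}
    for row in criteria.rows:
        if row.structure not in structures:
            raise ValueError(f"no structure '{row.structure}' to evaluate")
        values[row.key] = metric_v(
            dose, structures[row.structure], row.dose_level_gy, row.unit
        )
    return classify_plan(values, criteria), values


# ---------------------------------------------------------------------------
# YAML serialization


def _rows_from_obj(obj: dict) -> CriteriaSet:
    rows = [
        CriterionRow(
            structure=str(r["structure"]),
            metric=r.get("metric", "V"),
            dose_level_gy=float(r["dose_level_gy"]),
            unit=r["unit"],
            per_protocol=float(r["per_protocol"]),
            variation=float(r["variation"]),
            direction=r["direction"],
        )
        for r in obj["criteria"]
    ]
    return CriteriaSet(rows)


def load_criteria(path: str | Path) -> CriteriaSet:
    """Load a criteria table from YAML."""
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    return _rows_from_obj(obj)


def save_criteria(criteria: CriteriaSet, path: str | Path) -> None:
    obj = {
        "criteria": [
            {
                "structure": r.structure,
                "metric": r.metric,
                "dose_level_gy": r.dose_level_gy,
                "unit": r.unit,
                "per_protocol": r.per_protocol,
                "variation": r.variation,
                "direction": r.direction,
            }
            for r in criteria.rows
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def default_criteria() -> CriteriaSet:
    """The default clinical constraint table shipped with the package."""
    ref = resources.files("lorp.data").joinpath("criteria_default.yaml")
    with resources.as_file(ref) as path:
        return load_criteria(path)
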