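"""Resource-use costing from the NHS/personal-social-services perspective.

Per-patient service counts are priced with a unit-cost table (GBP at a stated
price year, default 2014); the therapy itself is costed as contact time times
the clinical-psychologist hourly rate (£138/h including on-costs, overheads
and non-contact time).  Resource use attributable to the index trauma (e.g.
emergency-department attendance, ambulance) can be excluded via a flag in the
table.  All arithmetic is carried out on unrounded values; whole-GBP rounding
is applied only when reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CostingError",
    "UnitCostTable",
    "PatientCostSummary",
    "cost_intervention",
    "aggregate_costs",
    "arm_cost_summary",
    "report_gbp",
    "DEFAULT_THERAPIST_HOURLY_RATE",
]

DEFAULT_THERAPIST_HOURLY_RATE = 138.0


class CostingError(ValueError):
    """A resource category cannot be priced; the message names the category."""


def report_gbp(value: float) -> int:
    """Round to the nearest whole pound (half away from zero) for reporting."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


# Illustrative 2014-price unit costs: the per-category pattern (hospital vs
# community, index-trauma flags) is what matters downstream, not the figures.
_DEFAULT_ROWS = [
    # category, service_class, unit, cost_gbp, index_trauma
    ("outpatient", "hospital", "attendance", 135.0, 0),
    ("emergency_dept", "hospital", "attendance", 124.0, 1),
    ("ambulance", "hospital", "callout", 231.0, 1),
    ("gp_surgery", "community", "visit", 45.0, 0),
    ("gp_home_visit", "community", "visit", 78.0, 0),
    ("practice_nurse", "community", "visit", 14.0, 0),
    ("camhs_worker", "community", "contact", 55.0, 0),
    ("counsellor", "community", "session", 64.0, 0),
    ("social_services", "community", "contact", 53.0, 0),
    ("medications", "community", "item", 9.0, 0),
]


@dataclass
class UnitCostTable:
    """Per-category unit costs plus the therapist hourly rate.

    ``table`` columns: category, service_class ({hospital, community}), unit,
    cost_gbp, index_trauma (0/1 — excludable as index-trauma related).
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            _DEFAULT_ROWS,
            columns=["category", "service_class", "unit", "cost_gbp", "index_trauma"],
        )
    )
    therapist_hourly_rate: float = DEFAULT_THERAPIST_HOURLY_RATE
    price_year: int = 2014

    def __post_init__(self):
        if (self.table["cost_gbp"] < 0).any() or self.therapist_hourly_rate < 0:
            raise CostingError("unit costs must be non-negative")

    def cost_of(self, category: str) -> float:
        row = self.table.loc[self.table["category"] == category, "cost_gbp"]
        if row.empty:
            raise CostingError(f"no unit cost for resource category '{category}'")
        return float(row.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, therapist_hourly_rate=DEFAULT_THERAPIST_HOURLY_RATE,
                 price_year=2014) -> "UnitCostTable":
        return cls(pd.read_csv(path), therapist_hourly_rate, price_year)


@dataclass(frozen=True)
class PatientCostSummary:
    id: int
    arm: str
    hospital_costs: float
    community_costs: float
    intervention_cost: float

    @property
    def total_cost(self) -> float:
        return self.hospital_costs + self.community_costs + self.intervention_cost


def cost_intervention(contact_minutes: float,
                      hourly_rate: float = DEFAULT_THERAPIST_HOURLY_RATE) -> float:
    """Therapy cost = contact time × therapist hourly rate, unrounded GBP.

    E.g. the trial-mean 636.25 minutes at £138/h cost £1463.375, reported
    as £1463 via :func:`report_gbp`.
    """
    if contact_minutes < 0 or hourly_rate < 0:
        raise CostingError("contact minutes and hourly rate must be non-negative")
    return contact_minutes / 60.0 * hourly_rate


def aggregate_costs(
    records: pd.DataFrame,
    unit_costs: UnitCostTable,
    period: str = "followup",
    exclude_index_trauma: bool = True,
) -> pd.DataFrame:
    """Price each patient's resource use for one period.

    Returns a frame (id, arm, hospital_costs, community_costs,
    intervention_cost, total_cost); the intervention is costed in the
    follow-up period only and is identically zero in the control arm.
    Records with missing follow-up counts get NaN costs for that period.
    Unknown ``use_<category>_<period>`` columns raise :class:`CostingError`.
    """
    if period not in ("baseline", "followup"):
        raise ValueError(f"period must be 'baseline' or 'followup'; got {period!r}")
    suffix = f"_{period}"
    use_cols = [c for c in records.columns if c.startswith("use_") and c.endswith(suffix)]
    known = set(unit_costs.table["category"])

    hospital = np.zeros(len(records))
    community = np.zeros(len(records))
    for col in use_cols:
        category = col[len("use_"):-len(suffix)]
        if category not in known:
            raise CostingError(f"no unit cost for resource category '{category}'")
        row = unit_costs.table.loc[unit_costs.table["category"] == category].iloc[0]
        if exclude_index_trauma and row["index_trauma"]:
            continue
        counts = pd.to_numeric(records[col], errors="coerce").to_numpy(dtype=float)
        costs = counts * float(row["cost_gbp"])
        if row["service_class"] == "hospital":
            hospital = hospital + costs
        else:
            community = community + costs

    if period == "followup":
        minutes = records["contact_minutes"].to_numpy(dtype=float)
        intervention = np.array([cost_intervention(m, unit_costs.therapist_hourly_rate)
                                 for m in minutes])
        intervention[records["arm"].to_numpy() != "treatment"] = 0.0
    else:
        intervention = np.zeros(len(records))

    return pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "arm": records["arm"].to_numpy(),
            "hospital_costs": hospital,
            "community_costs": community,
            "intervention_cost": intervention,
            "total_cost": hospital + community + intervention,
        }
    )


def arm_cost_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean and SD of total cost over non-missing records."""
    return (
        summaries.dropna(subset=["total_cost"])
        .groupby("arm")["total_cost"]
        .agg(["mean", "std", "count"])
    )
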