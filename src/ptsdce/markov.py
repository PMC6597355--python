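"""Two-state cohort Markov extrapolation of the trial results.

The model has two health states — PTSD and PTSD-free — and runs in 3-month
cycles over a 3-year horizon (12 cycles).  A cohort enters each arm split
according to the arm's end-of-trial recovery proportion (defaults 71%
PTSD-free for treatment, 27% for usual care).  Cycle 1 stands in for the
trial period itself and accrues the arm's observed trial cost and QALYs.
Natural recovery continues during the remainder of year 1 only (cycles 2–4):
at the start of each such cycle the PTSD occupancy is multiplied by
(1 − 0.129), the 3-month recovery probability obtained from a meta-analytic
9-month probability of 0.34 via the constant-rate conversion

    p_short = 1 − exp(ln(1 − p_long) · t_short / t_long).

PTSD-free is absorbing (relapse after a single acute trauma is considered
very low and is not modelled).  Each cycle accrues the per-cycle state costs
(£549 PTSD / £236 PTSD-free) and QALYs (0.185 / 0.193) weighted by occupancy;
costs and QALYs after the first year are discounted at 3.5% per annum,
applied per year block (year-2 cycles at 1/1.035, year-3 at 1/1.035²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trial_cua import CuaResult, compute_icer

__all__ = [
    "ARMS",
    "StateValueSet",
    "MarkovSpec",
    "CohortTrajectory",
    "convert_probability",
    "discount_factor",
    "run_cohort",
    "model_icer",
]

ARMS = ("treatment", "control")


@dataclass(frozen=True)
class StateValueSet:
    """Per-3-month-cycle cost (GBP) and QALYs for each health state.

    Defaults are the trial-derived cycle values: the PTSD state from all
    children at baseline, the PTSD-free state from children recovered at
    follow-up (therapy cost excluded).
    """

    cost_ptsd: float = 549.0
    cost_free: float = 236.0
    qaly_ptsd: float = 0.185
    qaly_free: float = 0.193

    def __post_init__(self):
        for name in ("cost_ptsd", "cost_free", "qaly_ptsd", "qaly_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _default_initial():
    return {"treatment": 0.71, "control": 0.27}


def _default_trial_cost():
    return {"treatment": 1686.0, "control": 307.0}


def _default_trial_qaly():
    return {"treatment": 0.1979, "control": 0.1823}


@dataclass(frozen=True)
class MarkovSpec:
    """Structure of the two-state cohort model.

    ``recovery_cycles`` are the 1-based cycle indices in which natural
    recovery applies (default cycles 2–4, i.e. the remainder of year 1).
    ``trial_cycle_cost``/``trial_cycle_qaly`` are the per-arm totals accrued
    in cycle 1 in place of state-value accrual (imputed trial results by
    default).  ``discounting`` is ``'year_block'`` (each cycle of year y ≥ 2
    discounted by (1+r)^−(y−1)) or ``'per_cycle'`` (continuous by cycle-end
    time beyond year 1).  ``half_cycle_correction`` averages pre- and
    post-transition occupancy when accruing (off by default).
    """

    cycle_length: float = 0.25
    n_cycles: int = 12
    recovery_prob: float = 0.129
    recovery_cycles: tuple[int, ...] = (2, 3, 4)
    discount_rate: float = 0.035
    initial_ptsd_free: dict = field(default_factory=_default_initial)
    trial_cycle_cost: dict = field(default_factory=_default_trial_cost)
    trial_cycle_qaly: dict = field(default_factory=_default_trial_qaly)
    discounting: str = "year_block"
    half_cycle_correction: bool = False

    def __post_init__(self):
        if not 0.0 <= self.recovery_prob <= 1.0:
            raise ValueError("recovery_prob must be in [0, 1]")
        for arm, p in self.initial_ptsd_free.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"initial_ptsd_free[{arm!r}] must be in [0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.discounting not in ("year_block", "per_cycle"):
            raise ValueError("discounting must be 'year_block' or 'per_cycle'")

    def with_overrides(self, **kwargs) -> "MarkovSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CohortTrajectory:
    """Per-cycle occupancies and (discounted) accruals for one arm.

    ``cycles`` columns: cycle, year, occupancy_ptsd, occupancy_free,
    discount, cost, qaly, cum_cost, cum_qaly.  ``yearly`` holds the
    cumulative totals at each whole-year boundary.
    """

    arm: str
    cycles: pd.DataFrame
    yearly: pd.DataFrame

    def totals_at_year(self, year: int) -> tuple[float, float]:
        row = self.yearly.loc[self.yearly["year"] == year]
        if row.empty:
            raise ValueError(f"no year-{year} boundary in a {len(self.cycles)}-cycle run")
        return float(row["cum_cost"].iloc[0]), float(row["cum_qaly"].iloc[0])

    def to_csv(self, path) -> None:
        self.cycles.to_csv(path, index=False)


def convert_probability(p_long: float, t_long: float, t_short: float) -> float:
    """Re-express a transition probability on a different cycle length.

    Converts via the constant instantaneous rate: the probability ``p_long``
    observed over ``t_long`` corresponds to rate −ln(1−p_long)/t_long, which
    over ``t_short`` gives 1 − exp(ln(1−p_long)·t_short/t_long).  E.g. a
    9-month probability of 0.34 becomes a 3-month probability of 0.129.
    """
    if not 0.0 <= p_long < 1.0:
        raise ValueError(f"p_long must be in [0, 1); got {p_long}")
    if t_long <= 0 or t_short <= 0:
        raise ValueError("durations must be positive")
    return 1.0 - math.exp(math.log1p(-p_long) * t_short / t_long)


def discount_factor(cycle_index: int, cycle_length: float = 0.25,
                    rate: float = 0.035, mode: str = "year_block") -> float:
    """Discount factor for a 1-based cycle index; year 1 is undiscounted.

    ``year_block``: every cycle falling in year y ≥ 2 gets (1+rate)^−(y−1).
    ``per_cycle``: (1+rate)^−max(0, t_end − 1) with t_end the cycle-end time
    in years (a smooth alternative, off by default everywhere).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    t_end = cycle_index * cycle_length
    if mode == "year_block":
        year = math.ceil(t_end - 1e-12)
        return 1.0 if year <= 1 else (1.0 + rate) ** -(year - 1)
    if mode == "per_cycle":
        return (1.0 + rate) ** -max(0.0, t_end - 1.0)
    raise ValueError(f"unknown discounting mode {mode!r}")


def run_cohort(spec: MarkovSpec, values: StateValueSet, arm: str) -> CohortTrajectory:
    """Run the two-state cohort model for one arm.

    Cycle 1 accrues the arm's trial-observed cost and QALYs at the initial
    occupancy.  In each subsequent cycle listed in ``recovery_cycles`` the
    PTSD occupancy is multiplied by (1 − recovery_prob) at the start of the
    cycle; state values then accrue weighted by occupancy and the discount
    factor.  Occupancies always sum to one and the PTSD-free share never
    decreases (absorbing state).
    """
    if arm not in spec.initial_ptsd_free:
        raise ValueError(f"unknown arm {arm!r}")
    free = spec.initial_ptsd_free[arm]
    ptsd = 1.0 - free
    if not 0.0 <= free <= 1.0:
        raise ValueError("initial occupancy outside [0, 1]")

    rows = []
    cum_cost = cum_qaly = 0.0
    for cycle in range(1, spec.n_cycles + 1):
        prev_ptsd, prev_free = ptsd, free
        if cycle in spec.recovery_cycles:
            recovered = ptsd * spec.recovery_prob
            ptsd -= recovered
            free += recovered
        if not (-1e-12 <= ptsd <= 1 + 1e-12 and -1e-12 <= free <= 1 + 1e-12):
            raise ValueError("state occupancy left [0, 1]")

        factor = discount_factor(cycle, spec.cycle_length, spec.discount_rate,
                                 spec.discounting)
        if cycle == 1:
            cost = spec.trial_cycle_cost[arm] * factor
            qaly = spec.trial_cycle_qaly[arm] * factor
        else:
            if spec.half_cycle_correction:
                w_ptsd = 0.5 * (prev_ptsd + ptsd)
                w_free = 0.5 * (prev_free + free)
            else:
                w_ptsd, w_free = ptsd, free
            cost = factor * (w_ptsd * values.cost_ptsd + w_free * values.cost_free)
            qaly = factor * (w_ptsd * values.qaly_ptsd + w_free * values.qaly_free)

        cum_cost += cost
        cum_qaly += qaly
        rows.append(
            {
                "cycle": cycle,
                "year": math.ceil(cycle * spec.cycle_length - 1e-12),
                "occupancy_ptsd": ptsd,
                "occupancy_free": free,
                "discount": factor,
                "cost": cost,
                "qaly": qaly,
                "cum_cost": cum_cost,
                "cum_qaly": cum_qaly,
            }
        )

    cycles = pd.DataFrame(rows)
    boundaries = cycles[np.isclose((cycles["cycle"] * spec.cycle_length) % 1.0, 0.0)]
    yearly = pd.DataFrame(
        {
            "year": (boundaries["cycle"] * spec.cycle_length).round().astype(int),
            "cum_cost": boundaries["cum_cost"],
            "cum_qaly": boundaries["cum_qaly"],
        }
    ).reset_index(drop=True)
    return CohortTrajectory(arm, cycles, yearly)


def model_icer(traj_treatment: CohortTrajectory, traj_control: CohortTrajectory,
               year: int) -> CuaResult:
    """Model-based incremental analysis at a whole-year boundary."""
    if len(traj_treatment.cycles) != len(traj_control.cycles):
        raise ValueError("trajectories have mismatched horizons")
    ct, qt = traj_treatment.totals_at_year(year)
    cc, qc = traj_control.totals_at_year(year)
    dc, dq = ct - cc, qt - qc
    return CuaResult(
        mean_cost={"treatment": ct, "control": cc},
        mean_qaly={"treatment": qt, "control": qc},
        adjusted_cost_diff=dc,
        adjusted_qaly_diff=dq,
        icer=compute_icer(dc, dq),
        analysis_set=f"model_year_{year}",
    )
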