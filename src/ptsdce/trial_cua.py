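"""Trial-horizon incremental cost-utility analysis.

Builds per-patient trial outcomes (total follow-up cost including the
intervention; QALYs over the 11-week window), imputes missing follow-up
values by conditional regression on arm, baseline value, age and gender,
adjusts between-arm differences for baseline imbalance with a linear model,
and summarises cost-effectiveness as an incremental cost-effectiveness ratio
(ICER = ΔCost/ΔQALY) with a cost-effectiveness-plane quadrant/dominance
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .costing import UnitCostTable, aggregate_costs
from .utility_qaly import (
    DEFAULT_COEFFICIENTS,
    SUBSCALES,
    TRIAL_DURATION_YEARS,
    QalyAccrual,
    UtilityMappingCoefficients,
    accrue_qalys,
    map_sdq_to_utility,
)

__all__ = [
    "IcerOutcome",
    "CuaResult",
    "prepare_trial_outcomes",
    "impute_missing",
    "adjust_differences",
    "compute_icer",
    "run_trial_cua",
]


@dataclass(frozen=True)
class IcerOutcome:
    """ICER with its cost-effectiveness-plane classification.

    ``ratio`` is ΔC/ΔE (GBP per QALY) and is ``None`` when ΔE = 0, in which
    case ``defined`` is False and net benefit should be reported instead.
    ``label`` is 'dominant' (cheaper and more effective), 'dominated' (dearer
    and less effective), or the trade-off quadrant 'NE'/'SW'.
    """

    delta_cost: float
    delta_qaly: float
    ratio: float | None
    quadrant: str
    label: str
    defined: bool

    def net_benefit(self, threshold: float) -> float:
        """Net monetary benefit λ·ΔE − ΔC at willingness-to-pay λ."""
        return threshold * self.delta_qaly - self.delta_cost


@dataclass(frozen=True)
class CuaResult:
    mean_cost: dict
    mean_qaly: dict
    adjusted_cost_diff: float
    adjusted_qaly_diff: float
    icer: IcerOutcome
    analysis_set: str


def compute_icer(cost_diff: float, qaly_diff: float) -> IcerOutcome:
    """Classify (ΔC, ΔE) on the cost-effectiveness plane and form the ICER.

    ΔE > 0 with ΔC ≤ 0 is dominance of the intervention; ΔE < 0 with ΔC ≥ 0
    is domination by the comparator.  With ΔE = 0 the ratio is undefined and
    the result signals that net benefit should be used.
    """
    if not (np.isfinite(cost_diff) and np.isfinite(qaly_diff)):
        raise ValueError("cost and QALY differences must be finite")
    if qaly_diff > 0:
        quadrant = "NE" if cost_diff > 0 else "SE"
    elif qaly_diff < 0:
        quadrant = "NW" if cost_diff > 0 else "SW"
    else:
        quadrant = "NE" if cost_diff > 0 else "SW"
    label = {"SE": "dominant", "NW": "dominated"}.get(quadrant, quadrant)
    if qaly_diff == 0:
        return IcerOutcome(cost_diff, qaly_diff, None, quadrant, label, False)
    return IcerOutcome(cost_diff, qaly_diff, cost_diff / qaly_diff, quadrant, label, True)


def prepare_trial_outcomes(
    records: pd.DataFrame,
    unit_costs: UnitCostTable | None = None,
    coeffs: UtilityMappingCoefficients = DEFAULT_COEFFICIENTS,
    duration: float = TRIAL_DURATION_YEARS,
) -> pd.DataFrame:
    """Per-patient analysis frame: costs, utilities and QALYs for the trial.

    Columns: id, arm, age, gender, baseline_cost, followup_cost (total trial
    cost including the intervention), utility_baseline, utility_followup,
    qaly (trapezoid over ``duration`` years), missing_followup.
    """
    unit_costs = unit_costs or UnitCostTable()
    base = aggregate_costs(records, unit_costs, period="baseline")
    follow = aggregate_costs(records, unit_costs, period="followup")

    u_base = map_sdq_to_utility(
        *(records[f"sdq_{s}_baseline"].to_numpy(dtype=float) for s in SUBSCALES),
        coeffs=coeffs,
    )
    sdq_fu = [pd.to_numeric(records[f"sdq_{s}_followup"], errors="coerce") for s in SUBSCALES]
    missing = records["missing_followup"].to_numpy(dtype=bool)
    u_fu = np.full(len(records), np.nan)
    if (~missing).any():
        u_fu[~missing] = map_sdq_to_utility(
            *(col.to_numpy(dtype=float)[~missing] for col in sdq_fu), coeffs=coeffs
        )

    out = pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "arm": records["arm"].to_numpy(),
            "age": records["age"].to_numpy(dtype=float),
            "gender": records["gender"].to_numpy(),
            "baseline_cost": base["total_cost"].to_numpy(),
            "followup_cost": np.where(missing, np.nan, follow["total_cost"].to_numpy()),
            "utility_baseline": np.asarray(u_base, dtype=float),
            "utility_followup": u_fu,
            "missing_followup": missing,
        }
    )
    out["qaly"] = [
        accrue_qalys(QalyAccrual(b, f, duration)) if np.isfinite(f) else np.nan
        for b, f in zip(out["utility_baseline"], out["utility_followup"])
    ]
    return out


_IMPUTE_TARGETS = {"followup_cost": "baseline_cost", "utility_followup": "utility_baseline"}


def impute_missing(outcomes: pd.DataFrame, seed: int | None = None,
                   add_noise: bool = False,
                   duration: float = TRIAL_DURATION_YEARS) -> pd.DataFrame:
    """Conditional-regression imputation of missing follow-up cost and utility.

    Each missing follow-up value is replaced by the prediction of an ordinary
    least-squares regression (fit on complete records) of the follow-up value
    on arm, the corresponding baseline value, age and gender; observed values
    are never altered.  Deterministic by default; ``add_noise=True`` adds a
    seeded draw from the residual distribution.  QALYs are recomputed for
    imputed rows.
    """
    out = outcomes.copy()
    rng = np.random.default_rng(seed)
    for target, baseline in _IMPUTE_TARGETS.items():
        missing = out[target].isna()
        if not missing.any():
            continue
        complete = out.loc[~missing]
        if complete.empty:
            raise ValueError(f"cannot impute '{target}': no complete records")
        for col in (baseline, "age"):
            if complete[col].isna().any():
                raise ValueError(f"predictor '{col}' has missing values")
        model = smf.ols(
            f"{target} ~ C(arm) + {baseline} + age + C(gender)", data=complete
        ).fit()
        pred = model.predict(out.loc[missing])
        if add_noise and model.df_resid > 0:
            pred = pred + rng.normal(0.0, np.sqrt(model.scale), size=len(pred))
        out.loc[missing, target] = pred.to_numpy()
    imputed_rows = out["qaly"].isna()
    out.loc[imputed_rows, "qaly"] = [
        accrue_qalys(QalyAccrual(b, f, duration))
        for b, f in zip(
            out.loc[imputed_rows, "utility_baseline"],
            out.loc[imputed_rows, "utility_followup"],
        )
    ]
    return out


def adjust_differences(outcomes: pd.DataFrame, outcome: str,
                       family: str = "gaussian") -> float:
    """Covariate-adjusted between-arm difference in follow-up cost or QALYs.

    Fits ``followup ~ group + baseline + age + gender`` and returns the group
    (treatment vs control) coefficient.  With the default identity-link
    Gaussian model the coefficient is directly a difference in GBP or QALYs;
    ``family='gamma-log'`` fits a log-link Gamma GLM instead, whose group
    coefficient is a log cost ratio (provided for skew-robustness checks).
    """
    if outcome not in ("cost", "qaly"):
        raise ValueError("outcome must be 'cost' or 'qaly'")
    y, baseline = (
        ("followup_cost", "baseline_cost") if outcome == "cost"
        else ("qaly", "utility_baseline")
    )
    data = outcomes.dropna(subset=[y]).copy()
    if data["arm"].nunique() < 2:
        raise ValueError("both arms must be non-empty")
    data["group"] = (data["arm"] == "treatment").astype(float)
    formula = f"{y} ~ group + {baseline} + age + C(gender)"
    if family == "gaussian":
        model = smf.ols(formula, data=data).fit()
    elif family == "gamma-log":
        model = smf.glm(
            formula, data=data, family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(model.params["group"])


def run_trial_cua(
    records: pd.DataFrame,
    unit_costs: UnitCostTable | None = None,
    analysis_set: str = "imputed",
    seed: int | None = None,
) -> CuaResult:
    """Full trial-horizon analysis on a cohort of patient records."""
    if analysis_set not in ("imputed", "complete_case"):
        raise ValueError("analysis_set must be 'imputed' or 'complete_case'")
    outcomes = prepare_trial_outcomes(records, unit_costs)
    if analysis_set == "imputed":
        outcomes = impute_missing(outcomes, seed=seed)
    else:
        outcomes = outcomes.dropna(subset=["followup_cost", "qaly"])
    mean_cost = outcomes.groupby("arm")["followup_cost"].mean().to_dict()
    mean_qaly = outcomes.groupby("arm")["qaly"].mean().to_dict()
    dc = adjust_differences(outcomes, "cost")
    de = adjust_differences(outcomes, "qaly")
    return CuaResult(mean_cost, mean_qaly, dc, de, compute_icer(dc, de), analysis_set)
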