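"""Probabilistic and one-way sensitivity analysis for the Markov model.

The probabilistic sensitivity analysis (PSA) draws each uncertain model
parameter from its assigned distribution — Beta for the two arm efficacies
(recovery proportions at end of trial) and for the state QALYs, Gamma for the
state costs, Beta for the 9-month natural-remission probability, which is
converted to the 3-month cycle probability per draw — re-runs both arms'
3-year cohorts for every draw, and records the joint distribution of
incremental costs and QALYs at years 1–3.  Cost-effectiveness acceptability
curves (CEACs) report, for each willingness-to-pay threshold λ, the fraction
of draws with positive net monetary benefit λ·ΔE − ΔC.

One-way sensitivity analyses cover therapist-training costs (amortized
straight-line over a service life and annual caseload, added to the
treatment arm's trial-cycle cost) and a complete-case variant of the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import MarkovSpec, StateValueSet, model_icer, run_cohort
from .trial_cua import CuaResult

__all__ = [
    "Beta",
    "Gamma",
    "Fixed",
    "PsaDistributions",
    "default_psa_distributions",
    "sample_psa",
    "ceac",
    "default_thresholds",
    "amortize_training",
    "run_variant",
    "TRAINING_COST_PER_PATIENT",
]

#: Amortized therapist-training cost per treated patient (straight-line over
#: a 5-year service life at the trial's annual caseload of 29).
TRAINING_COST_PER_PATIENT = 186.0


@dataclass(frozen=True)
class Beta:
    a: float
    b: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")
        return rng.beta(self.a, self.b, size=n)

    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class Gamma:
    shape: float
    scale: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma parameters must be positive")
        return rng.gamma(self.shape, self.scale, size=n)

    def mean(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class Fixed:
    """Degenerate (zero-variance) distribution, for collapse checks."""

    value: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.value)

    def mean(self) -> float:
        return self.value


@dataclass(frozen=True)
class PsaDistributions:
    """Parameter distributions for the PSA.

    ``remission`` is the distribution of the 9-month natural-remission
    probability by default (``remission_scale='nine_month'``), moment-matched
    to a mean of 34% with 95% CI 21%–49% and converted to the 3-month cycle
    probability per draw; set ``remission_scale='three_month'`` to treat the
    sampled value as the per-cycle probability directly (e.g. with
    ``Beta(14, 95)``, whose mean ≈ 0.129 is already on the 3-month scale).
    """

    efficacy_treatment: Beta = Beta(19, 7)
    efficacy_control: Beta = Beta(3, 9)
    remission: Beta = Beta(14.614, 28.368)
    remission_scale: str = "nine_month"
    cost_ptsd: Gamma = Gamma(19.532, 28.118)
    cost_free: Gamma = Gamma(10.369, 22.738)
    qaly_ptsd: Beta = Beta(808, 3567)
    qaly_free: Beta = Beta(2618, 10940)

    def __post_init__(self):
        if self.remission_scale not in ("nine_month", "three_month"):
            raise ValueError("remission_scale must be 'nine_month' or 'three_month'")


def default_psa_distributions() -> PsaDistributions:
    """Default PSA distributions, with the state-QALY Betas assigned by mean.

    The source table pairs Beta(2618, 10940) (mean ≈ 0.193) with the PTSD
    state whose stated mean is 0.185, and Beta(808, 3567) (mean ≈ 0.185)
    with the PTSD-free state whose stated mean is 0.193 — an evident swap.
    Each Beta is therefore assigned to the state whose stated mean it
    matches, and a warning is emitted so the choice is visible.
    """
    warnings.warn(
        "state-QALY Beta distributions are assigned to the state matching "
        "their mean (0.185→PTSD, 0.193→PTSD-free), swapping the source "
        "table's printed pairing",
        UserWarning,
        stacklevel=2,
    )
    return PsaDistributions()


def _year_boundary_cycles(spec: MarkovSpec) -> dict[int, int]:
    return {
        int(round(c * spec.cycle_length)): c
        for c in range(1, spec.n_cycles + 1)
        if abs((c * spec.cycle_length) % 1.0) < 1e-9
    }


def _run_arm_vectorized(
    spec: MarkovSpec,
    arm: str,
    eff: np.ndarray,
    recovery: np.ndarray,
    cost_ptsd: np.ndarray,
    cost_free: np.ndarray,
    qaly_ptsd: np.ndarray,
    qaly_free: np.ndarray,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Cohort recursion over all draws at once; returns totals per year."""
    from .markov import discount_factor

    ptsd = 1.0 - eff
    cum_cost = np.zeros_like(ptsd)
    cum_qaly = np.zeros_like(ptsd)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    boundaries = _year_boundary_cycles(spec)
    for cycle in range(1, spec.n_cycles + 1):
        if cycle in spec.recovery_cycles:
            ptsd = ptsd * (1.0 - recovery)
        factor = discount_factor(cycle, spec.cycle_length, spec.discount_rate,
                                 spec.discounting)
        if cycle == 1:
            cum_cost = cum_cost + spec.trial_cycle_cost[arm] * factor
            cum_qaly = cum_qaly + spec.trial_cycle_qaly[arm] * factor
        else:
            free = 1.0 - ptsd
            cum_cost = cum_cost + factor * (ptsd * cost_ptsd + free * cost_free)
            cum_qaly = cum_qaly + factor * (ptsd * qaly_ptsd + free * qaly_free)
        for year, boundary in boundaries.items():
            if cycle == boundary:
                out[year] = (cum_cost.copy(), cum_qaly.copy())
    return out


def _quadrant(dc: np.ndarray, de: np.ndarray) -> np.ndarray:
    quad = np.where(dc > 0, np.where(de > 0, "NE", "NW"), np.where(de > 0, "SE", "SW"))
    return quad


def sample_psa(
    n_draws: int,
    seed: int,
    spec: MarkovSpec | None = None,
    distributions: PsaDistributions | None = None,
) -> pd.DataFrame:
    """Run the PSA: ``n_draws`` parameter vectors, both arms re-run per draw.

    Trial-cycle (cycle 1) costs and QALYs are held fixed at the values in
    ``spec`` — no sampling distribution is assigned to them.  Returns one row
    per draw with the sampled parameters, incremental cost and QALYs at each
    whole-year boundary (``delta_cost_y1`` … ``delta_qaly_y3`` under the
    default 12-cycle horizon), and the 3-year cost-effectiveness-plane
    quadrant.  Identical seed and configuration give identical output.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    spec = spec or MarkovSpec()
    dists = distributions or PsaDistributions()
    rng = np.random.default_rng(seed)

    eff_t = dists.efficacy_treatment.sample(rng, n_draws)
    eff_c = dists.efficacy_control.sample(rng, n_draws)
    remission_raw = dists.remission.sample(rng, n_draws)
    if dists.remission_scale == "nine_month":
        recovery = 1.0 - np.exp(np.log1p(-remission_raw) * 3.0 / 9.0)
    else:
        recovery = remission_raw
    cost_ptsd = dists.cost_ptsd.sample(rng, n_draws)
    cost_free = dists.cost_free.sample(rng, n_draws)
    qaly_ptsd = dists.qaly_ptsd.sample(rng, n_draws)
    qaly_free = dists.qaly_free.sample(rng, n_draws)

    per_arm = {
        arm: _run_arm_vectorized(
            spec, arm, eff, recovery, cost_ptsd, cost_free, qaly_ptsd, qaly_free
        )
        for arm, eff in (("treatment", eff_t), ("control", eff_c))
    }

    data = {
        "draw_id": np.arange(n_draws),
        "efficacy_treatment": eff_t,
        "efficacy_control": eff_c,
        "remission_sampled": remission_raw,
        "recovery_prob_cycle": recovery,
        "cost_ptsd": cost_ptsd,
        "cost_free": cost_free,
        "qaly_ptsd": qaly_ptsd,
        "qaly_free": qaly_free,
    }
    years = sorted(per_arm["treatment"])
    for year in years:
        ct, qt = per_arm["treatment"][year]
        cc, qc = per_arm["control"][year]
        data[f"delta_cost_y{year}"] = ct - cc
        data[f"delta_qaly_y{year}"] = qt - qc
    final = years[-1]
    data["quadrant"] = _quadrant(data[f"delta_cost_y{final}"], data[f"delta_qaly_y{final}"])
    return pd.DataFrame(data)


def default_thresholds() -> np.ndarray:
    """£0–£50,000 per QALY in £500 steps (includes the £20k/£30k anchors)."""
    return np.arange(0.0, 50000.0 + 1, 500.0)


def ceac(draws: pd.DataFrame, thresholds=None, year: int = 3) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA draws.

    For each threshold λ the probability is the fraction of draws whose net
    monetary benefit λ·ΔE − ΔC is positive at the requested year.
    """
    if len(draws) == 0:
        raise ValueError("CEAC requires at least one draw")
    thresholds = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    dc = draws[f"delta_cost_y{year}"].to_numpy()
    de = draws[f"delta_qaly_y{year}"].to_numpy()
    prob = [(lam * de - dc > 0).mean() for lam in thresholds]
    return pd.DataFrame({"threshold": thresholds, "probability": prob})


def amortize_training(total_training_cost: float, years: float,
                      annual_caseload: float) -> float:
    """Straight-line training cost per treated patient: total/(years × caseload)."""
    if total_training_cost < 0:
        raise ValueError("total_training_cost must be non-negative")
    if years <= 0 or annual_caseload <= 0:
        raise ValueError("years and annual_caseload must be positive")
    return total_training_cost / (years * annual_caseload)


@dataclass(frozen=True)
class VariantResult:
    """One sensitivity-analysis scenario: deterministic results plus PSA/CEAC."""

    variant: str
    spec: MarkovSpec
    values: StateValueSet
    deterministic: dict  # year -> CuaResult
    draws: pd.DataFrame
    ceac: pd.DataFrame


def _variant_config(variant: str, spec: MarkovSpec,
                    values: StateValueSet) -> tuple[MarkovSpec, StateValueSet]:
    if variant == "base":
        return spec, values
    if variant == "training_costs":
        cost = dict(spec.trial_cycle_cost)
        cost["treatment"] = cost["treatment"] + TRAINING_COST_PER_PATIENT
        return replace(spec, trial_cycle_cost=cost), values
    if variant == "complete_case":
        # complete-case initial distributions and PTSD-free state values,
        # with the complete-case trial-cycle totals for consistency
        spec_cc = replace(
            spec,
            initial_ptsd_free={"treatment": 0.90, "control": 0.18},
            trial_cycle_cost={"treatment": 1691.0, "control": 351.0},
            trial_cycle_qaly={"treatment": 0.1929, "control": 0.1851},
        )
        values_cc = replace(values, cost_free=264.55, qaly_free=0.2027)
        return spec_cc, values_cc
    raise ValueError(f"unknown variant {variant!r}")


def run_variant(
    variant: str,
    n_draws: int = 5000,
    seed: int = 0,
    spec: MarkovSpec | None = None,
    values: StateValueSet | None = None,
    distributions: PsaDistributions | None = None,
    thresholds=None,
) -> VariantResult:
    """Deterministic model + PSA + CEAC under one sensitivity scenario.

    ``variant`` is 'base' (primary analysis), 'training_costs' (adds the
    amortized £186 per treated patient to the treatment arm's trial-cycle
    cost) or 'complete_case' (complete-case initial distributions 90%/18%,
    PTSD-free cycle values £264.55/0.2027, complete-case trial-cycle totals).
    """
    spec = spec or MarkovSpec()
    values = values or StateValueSet()
    spec_v, values_v = _variant_config(variant, spec, values)
    trajs = {arm: run_cohort(spec_v, values_v, arm) for arm in ("treatment", "control")}
    deterministic: dict[int, CuaResult] = {
        year: model_icer(trajs["treatment"], trajs["control"], year)
        for year in trajs["treatment"].yearly["year"]
    }
    draws = sample_psa(n_draws, seed, spec_v, distributions)
    curve = ceac(draws, thresholds)
    return VariantResult(variant, spec_v, values_v, deterministic, draws, curve)
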