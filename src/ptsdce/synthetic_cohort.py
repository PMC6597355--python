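"""Seeded synthetic trial cohorts for the early-PTSD cost-utility pipeline.

Emulates the statistical structure of a small two-arm randomized trial of
early cognitive therapy for child/adolescent PTSD against a waitlist control:
every child enters with PTSD, follow-up recovery is Bernoulli per arm
(defaults 71% treatment vs 27% control), SDQ subscale scores are drawn
conditionally on recovery status so recovered children carry higher mapped
utilities, resource-use counts are zero-heavy and right-skewed, therapist
contact minutes exist only in the treatment arm, and follow-up blocks go
missing completely at random (default 20%).

Cohorts are plain :class:`pandas.DataFrame` objects with a documented column
schema (see :data:`sdq_columns` / :func:`resource_columns`); rows can be
viewed as typed :class:`PatientRecord` values.  Identical configuration
(including seed) reproduces the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .utility_qaly import SUBSCALES, map_sdq_to_utility

__all__ = [
    "ConfigError",
    "CategoryParams",
    "CohortConfig",
    "PatientRecord",
    "DEFAULT_CATEGORY_PARAMS",
    "generate_cohort",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
    "sdq_columns",
    "resource_columns",
]


class ConfigError(ValueError):
    """A cohort configuration field is invalid; the message names the field."""


@dataclass(frozen=True)
class CategoryParams:
    """Zero-inflated gamma model for one resource-use category's counts.

    A count is 0 with probability ``zero_prob``; otherwise it is a rounded
    Gamma(``gamma_shape``, scale = mean_nonzero/shape) draw floored at 1.
    The resulting per-category cost distribution (count × unit cost) is the
    zero-heavy, right-skewed shape typical of child mental-health service use.
    """

    zero_prob: float
    mean_nonzero: float
    gamma_shape: float = 1.5


#: Default per-category count models, loosely calibrated so that priced
#: totals sit at the few-hundred-GBP level with many exact zeros.
DEFAULT_CATEGORY_PARAMS: dict[str, CategoryParams] = {
    "outpatient": CategoryParams(0.75, 2.0),
    "emergency_dept": CategoryParams(0.80, 1.2),
    "ambulance": CategoryParams(0.85, 1.1),
    "gp_surgery": CategoryParams(0.40, 2.2),
    "gp_home_visit": CategoryParams(0.85, 1.5),
    "practice_nurse": CategoryParams(0.70, 1.5),
    "camhs_worker": CategoryParams(0.85, 1.5),
    "counsellor": CategoryParams(0.75, 1.8),
    "social_services": CategoryParams(0.85, 1.4),
    "medications": CategoryParams(0.70, 2.5),
}


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic trial generator, seed included.

    ``baseline_utility_mean`` / ``recovered_utility_mean`` set the target mean
    mapped CHU-9D utility for children in the PTSD state and for recovered
    children; the generator back-solves the emotional-problems subscale mean
    so the linear crosswalk lands near the targets.
    """

    n_treatment: int = 14
    n_control: int = 15
    recovery_prob_treatment: float = 0.71
    recovery_prob_control: float = 0.27
    baseline_utility_mean: float = 0.734
    recovered_utility_mean: float = 0.91
    followup_missing_prob: float = 0.2
    contact_minutes_mean: float = 636.25
    contact_minutes_range: tuple[float, float] = (195.0, 755.0)
    cost_category_params: Mapping[str, CategoryParams] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PARAMS)
    )
    cost_outcome_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "recovery_prob_treatment",
            "recovery_prob_control",
            "followup_missing_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]; got {p}")
        for name in ("n_treatment", "n_control"):
            n = getattr(self, name)
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise ConfigError(f"{name} must be an integer >= 1; got {n}")
        lo, hi = self.contact_minutes_range
        if not lo <= hi:
            raise ConfigError(
                f"contact_minutes_range bounds must be ordered; got {self.contact_minutes_range}"
            )
        if not lo <= self.contact_minutes_mean <= hi:
            raise ConfigError(
                "contact_minutes_mean must lie inside contact_minutes_range; "
                f"got {self.contact_minutes_mean}"
            )
        for cat, params in self.cost_category_params.items():
            if not 0.0 <= params.zero_prob <= 1.0:
                raise ConfigError(f"cost_category_params[{cat!r}].zero_prob not in [0, 1]")
            if params.mean_nonzero < 0:
                raise ConfigError(f"cost_category_params[{cat!r}].mean_nonzero negative")
        for name in ("baseline_utility_mean", "recovered_utility_mean"):
            u = getattr(self, name)
            if not 0.51 <= u <= 0.93:
                raise ConfigError(
                    f"{name} must lie in the mapping range [0.51, 0.93]; got {u}"
                )
        if not -1.0 <= self.cost_outcome_correlation <= 1.0:
            raise ConfigError("cost_outcome_correlation must lie in [-1, 1]")

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["cost_category_params"] = {
            cat: dataclasses.asdict(p) for cat, p in self.cost_category_params.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "seed" not in payload:
            raise ConfigError("seed is mandatory in a cohort configuration file")
        payload["cost_category_params"] = {
            cat: CategoryParams(**p) for cat, p in payload["cost_category_params"].items()
        }
        payload["contact_minutes_range"] = tuple(payload["contact_minutes_range"])
        return cls(**payload)


@dataclass(frozen=True)
class PatientRecord:
    """Typed view of one cohort row (see :func:`generate_cohort` for schema)."""

    id: int
    arm: str
    age: int
    gender: str
    ptsd_baseline: bool
    ptsd_followup: bool | None
    sdq_baseline: tuple
    sdq_followup: tuple | None
    resource_use_baseline: dict
    resource_use_followup: dict | None
    contact_minutes: float
    missing_followup: bool

    @classmethod
    def from_row(cls, row: pd.Series, categories) -> "PatientRecord":
        missing = bool(row["missing_followup"])
        sdq_fu = None if missing else tuple(int(row[f"sdq_{s}_followup"]) for s in SUBSCALES)
        use_fu = None if missing else {c: int(row[f"use_{c}_followup"]) for c in categories}
        return cls(
            id=int(row["id"]),
            arm=row["arm"],
            age=int(row["age"]),
            gender=row["gender"],
            ptsd_baseline=bool(row["ptsd_baseline"]),
            ptsd_followup=None if missing else bool(row["ptsd_followup"]),
            sdq_baseline=tuple(int(row[f"sdq_{s}_baseline"]) for s in SUBSCALES),
            sdq_followup=sdq_fu,
            resource_use_baseline={c: int(row[f"use_{c}_baseline"]) for c in categories},
            resource_use_followup=use_fu,
            contact_minutes=float(row["contact_minutes"]),
            missing_followup=missing,
        )


def sdq_columns(period: str) -> list[str]:
    return [f"sdq_{s}_{period}" for s in SUBSCALES]


def resource_columns(categories, period: str) -> list[str]:
    return [f"use_{c}_{period}" for c in categories]


# Reference subscale-mean profiles (emotion, conduct, hyper, peer, prosocial).
# The emotion mean is shifted to hit the configured target utility; the other
# four stay fixed, keeping the conduct/peer/prosocial pattern of each state.
_PTSD_PROFILE = (6.0, 3.0, 3.0, 2.0, 4.0)  # maps to 0.740
_RECOVERED_PROFILE = (0.5, 0.5, 1.0, 0.5, 9.0)  # maps to 0.906
_SDQ_SD = 1.0


def _profile_for(target_utility: float, base: tuple) -> np.ndarray:
    means = np.array(base, dtype=float)
    base_u = map_sdq_to_utility(*means)
    means[0] = np.clip(means[0] + (base_u - target_utility) / 0.019, 0.0, 10.0)
    return means


def _draw_sdq(rng: np.random.Generator, means: np.ndarray, n: int) -> np.ndarray:
    raw = rng.normal(loc=means, scale=_SDQ_SD, size=(n, 5))
    return np.clip(np.rint(raw), 0, 10).astype(int)


def _draw_counts(rng: np.random.Generator, params: CategoryParams, n: int) -> np.ndarray:
    nonzero = rng.random(n) >= params.zero_prob
    counts = np.zeros(n, dtype=int)
    if params.mean_nonzero > 0 and nonzero.any():
        scale = params.mean_nonzero / params.gamma_shape
        draws = rng.gamma(params.gamma_shape, scale, size=int(nonzero.sum()))
        counts[nonzero] = np.maximum(1, np.rint(draws).astype(int))
    return counts


def _draw_contact_minutes(rng: np.random.Generator, config: CohortConfig, n: int) -> np.ndarray:
    """Contact minutes on [lo, hi] from a Beta scaled to hit the target mean."""
    lo, hi = config.contact_minutes_range
    if hi == lo:
        return np.full(n, lo)
    m = (config.contact_minutes_mean - lo) / (hi - lo)
    m = min(max(m, 1e-6), 1 - 1e-6)
    concentration = 6.0  # left-skewed for m > 0.5, matching a ceiling of full attendance
    return lo + (hi - lo) * rng.beta(m * concentration, (1 - m) * concentration, size=n)


def generate_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Generate one synthetic trial dataset.

    Returns a DataFrame with one row per child and columns::

        id, arm, age, gender, ptsd_baseline, ptsd_followup,
        sdq_<subscale>_{baseline,followup}   (five subscales, integers 0-10)
        use_<category>_{baseline,followup}   (resource-use counts)
        contact_minutes, missing_followup

    Follow-up recovery is Bernoulli per arm; follow-up SDQ scores are drawn
    from the recovered profile for recovered children and the PTSD profile
    otherwise, so recovered children carry higher mapped utility.  Follow-up
    blocks are then masked missing-completely-at-random at the configured
    rate.  The same config (seed included) always returns an identical frame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    categories = list(config.cost_category_params)

    n = config.n_treatment + config.n_control
    arm = np.array(["treatment"] * config.n_treatment + ["control"] * config.n_control)
    recovery_p = np.where(
        arm == "treatment", config.recovery_prob_treatment, config.recovery_prob_control
    )
    recovered = rng.random(n) < recovery_p

    ptsd_profile = _profile_for(config.baseline_utility_mean, _PTSD_PROFILE)
    rec_profile = _profile_for(config.recovered_utility_mean, _RECOVERED_PROFILE)

    sdq_base = _draw_sdq(rng, ptsd_profile, n)
    sdq_fu = np.where(
        recovered[:, None], _draw_sdq(rng, rec_profile, n), _draw_sdq(rng, ptsd_profile, n)
    )

    data: dict = {
        "id": np.arange(n),
        "arm": arm,
        "age": rng.integers(8, 18, size=n),
        "gender": rng.choice(["female", "male"], size=n),
        "ptsd_baseline": np.ones(n, dtype=bool),
        "ptsd_followup": ~recovered,
    }
    for j, s in enumerate(SUBSCALES):
        data[f"sdq_{s}_baseline"] = sdq_base[:, j]
        data[f"sdq_{s}_followup"] = sdq_fu[:, j]
    for cat in categories:
        params = config.cost_category_params[cat]
        data[f"use_{cat}_baseline"] = _draw_counts(rng, params, n)
        # recovered children use fewer services at follow-up
        fu = _draw_counts(rng, params, n)
        fu[recovered] = _draw_counts(
            rng,
            CategoryParams(
                min(1.0, params.zero_prob + 0.5 * (1 - params.zero_prob)),
                params.mean_nonzero,
                params.gamma_shape,
            ),
            int(recovered.sum()),
        )
        data[f"use_{cat}_followup"] = fu
    data["contact_minutes"] = np.where(
        arm == "treatment", _draw_contact_minutes(rng, config, n), 0.0
    )

    frame = pd.DataFrame(data)
    mask_seed = int(rng.integers(0, 2**31 - 1))
    return apply_missingness(frame, config.followup_missing_prob, mask_seed)


def apply_missingness(records: pd.DataFrame, prob: float, seed: int) -> pd.DataFrame:
    """Mask each record's follow-up block independently with probability ``prob``.

    Baseline fields are never touched; masked records get NA in every
    follow-up column and ``missing_followup=True``.
    """
    if not 0.0 <= prob <= 1.0:
        raise ConfigError(f"followup_missing_prob must be in [0, 1]; got {prob}")
    out = records.copy()
    rng = np.random.default_rng(seed)
    masked = rng.random(len(out)) < prob
    followup_cols = [
        c for c in out.columns if c.endswith("_followup") and c != "missing_followup"
    ]
    for col in followup_cols:
        out[col] = out[col].astype(object)
        out.loc[masked, col] = pd.NA
    out["missing_followup"] = masked
    return out


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort as CSV; missing values become empty fields."""
    records.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "missing_followup" in frame.columns:
        frame["missing_followup"] = frame["missing_followup"].astype(bool)
    return frame
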