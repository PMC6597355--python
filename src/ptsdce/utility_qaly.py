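"""SDQ → CHU-9D utility mapping and QALY accrual.

Children's health-related quality of life is scored with the parent-completed
Strengths and Difficulties Questionnaire (SDQ): five subscales (emotion,
conduct, hyperactivity, peer problems, prosocial behaviour), each an integer
0–10.  A published linear crosswalk converts the five subscale scores into a
Child Health Utility 9D (CHU-9D) preference weight:

    utility = 0.88 − 0.019·emotion − 0.009·conduct − 0.001·hyper
                   − 0.008·peer    + 0.005·prosocial

Over the valid SDQ domain the mapping spans [0.51, 0.93] exactly, so no
clamping is ever required; out-of-domain scores are rejected rather than
clipped.  QALYs are accrued as the trapezoidal area under the utility line
between two assessment points (survival time × utility weight).
"""

from __future__ import annotations

from dataclasses import astuple, dataclass

import numpy as np

__all__ = [
    "SUBSCALES",
    "TRIAL_DURATION_YEARS",
    "UtilityMappingCoefficients",
    "QalyAccrual",
    "SdqDomainError",
    "map_sdq_to_utility",
    "accrue_qalys",
]

SUBSCALES = ("emotion", "conduct", "hyper", "peer", "prosocial")

#: Trial follow-up window: 11 weeks expressed in average-length years.
TRIAL_DURATION_YEARS = 11.0 / 52.18


class SdqDomainError(ValueError):
    """An SDQ subscale score lies outside the instrument's 0–10 range."""


@dataclass(frozen=True)
class UtilityMappingCoefficients:
    """Coefficients of the linear SDQ→CHU-9D crosswalk.

    Defaults are the published mapping estimated in a sample of caregivers of
    young people attending child and adolescent mental health services; they
    can be overridden to explore alternative tariffs.
    """

    intercept: float = 0.88
    emotion: float = -0.019
    conduct: float = -0.009
    hyper: float = -0.001
    peer: float = -0.008
    prosocial: float = 0.005


DEFAULT_COEFFICIENTS = UtilityMappingCoefficients()


@dataclass(frozen=True)
class QalyAccrual:
    """Utility at two assessment points and the time between them (years)."""

    utility_baseline: float
    utility_followup: float
    duration: float


def map_sdq_to_utility(
    emotion,
    conduct,
    hyper,
    peer,
    prosocial,
    coeffs: UtilityMappingCoefficients = DEFAULT_COEFFICIENTS,
):
    """Map five SDQ subscale scores to a CHU-9D utility weight.

    Accepts scalars or numpy arrays (broadcast elementwise).  Scores must lie
    in [0, 10]; the result is the raw linear combination, never clamped.

    Raises
    ------
    SdqDomainError
        If any score falls outside [0, 10]; the message names the subscale.
    """
    scores = (emotion, conduct, hyper, peer, prosocial)
    for name, score in zip(SUBSCALES, scores):
        arr = np.asarray(score, dtype=float)
        if np.any(np.isnan(arr)) or np.any(arr < 0) or np.any(arr > 10):
            raise SdqDomainError(
                f"SDQ subscale '{name}' must lie in [0, 10]; got {score!r}"
            )
    _, *weights = astuple(coeffs)
    out = coeffs.intercept + sum(
        w * np.asarray(s, dtype=float) for w, s in zip(weights, scores)
    )
    return float(out) if np.ndim(out) == 0 else out


def accrue_qalys(accrual: QalyAccrual) -> float:
    """QALYs between two assessments: trapezoidal area under the utility line.

    ``duration × (u_baseline + u_followup) / 2`` — e.g. two years lived at a
    constant utility of 0.5 yield one QALY.
    """
    if not accrual.duration > 0:
        raise ValueError(f"duration must be positive; got {accrual.duration}")
    if not (np.isfinite(accrual.utility_baseline) and np.isfinite(accrual.utility_followup)):
        raise ValueError("utilities must be finite")
    return accrual.duration * (accrual.utility_baseline + accrual.utility_followup) / 2.0
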