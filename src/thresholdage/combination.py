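"""Combine the third molar with exactly one skeletal indicator.

Dental and skeletal maturation are assumed conditionally independent given
age, so the joint stage probability factorises:

    P(S_s = s_s, S_t = s_t | A) = P(S_s = s_s | A) * P(S_t = s_t | A),

and the combined age posterior follows by the same uniform-prior Bayes
inversion as for a single indicator.  The independence assumption is *not*
made between skeletal indicators — combining two skeletal sites is rejected.

Combined prior supports differ from the single-indicator ones:

- clavicle + third molar: upper limit 26.0 years (the dental data are
  truncated there), lower 10;
- hand/wrist + third molar: 7-21 years for both sexes;
- distal femur + third molar: 15-21 years, with the dental stages
  restricted to Demirjian D-H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CombinationError, SchemaError
from .ordinal import FittedOrdinalModel
from .posterior import (
    DEFAULT_GRID_STEP,
    AgeGrid,
    AgePosterior,
    posterior_from_curve,
)
from .reference import PriorSupport, default_support

__all__ = [
    "CombinationQuery",
    "combined_support",
    "joint_stage_given_age",
    "posterior_combined",
    "FEMUR_COMBO_DENTAL_STAGES",
]

DENTAL_INDICATOR = "third_molar"
SKELETAL_INDICATORS = ("hand_wrist", "distal_femur", "clavicle")

#: Demirjian stages admissible in the distal femur + third molar combination.
FEMUR_COMBO_DENTAL_STAGES = ("D", "E", "F", "G", "H")

_COMBINED_UPPER = {
    "clavicle": {"male": 26.0, "female": 26.0},
    "hand_wrist": {"male": 21.0, "female": 21.0},
    "distal_femur": {"male": 21.0, "female": 21.0},
}


def combined_support(skeletal_indicator: str, sex: str) -> PriorSupport:
    """Uniform-prior support for the third molar + one skeletal indicator.

    Upper limits follow the combination rules above; the lower bound is the
    larger of the two single-indicator lower bounds (which makes the distal
    femur combination exactly 15-21).
    """
    if skeletal_indicator not in SKELETAL_INDICATORS:
        raise CombinationError(
            f"{skeletal_indicator!r} is not a skeletal indicator that can be "
            "combined with the third molar"
        )
    dental = default_support(DENTAL_INDICATOR, sex)
    skeletal = default_support(skeletal_indicator, sex)
    lower = max(dental.lower, skeletal.lower)
    upper = _COMBINED_UPPER[skeletal_indicator][sex]
    return PriorSupport(skeletal_indicator, sex, lower, upper)


@dataclass(frozen=True)
class CombinationQuery:
    """One dental stage plus one skeletal stage for the same individual."""

    sex: str
    dental_stage: str
    skeletal_indicator: str
    skeletal_stage: str
    support: PriorSupport | None = None

    def __post_init__(self) -> None:
        if self.skeletal_indicator == DENTAL_INDICATOR:
            raise CombinationError("the skeletal indicator cannot be the third molar")
        if self.skeletal_indicator not in SKELETAL_INDICATORS:
            raise CombinationError(
                f"unknown skeletal indicator {self.skeletal_indicator!r}"
            )
        if (
            self.skeletal_indicator == "distal_femur"
            and str(self.dental_stage) not in FEMUR_COMBO_DENTAL_STAGES
        ):
            raise CombinationError(
                f"the distal femur + third molar combination covers Demirjian "
                f"stages {'-'.join((FEMUR_COMBO_DENTAL_STAGES[0], FEMUR_COMBO_DENTAL_STAGES[-1]))}; "
                f"got {self.dental_stage!r}"
            )
        if self.support is None:
            object.__setattr__(
                self, "support", combined_support(self.skeletal_indicator, self.sex)
            )


def _check_pair(
    dental_model: FittedOrdinalModel, skeletal_model: FittedOrdinalModel
) -> None:
    if (
        dental_model.indicator in SKELETAL_INDICATORS
        and skeletal_model.indicator in SKELETAL_INDICATORS
    ):
        raise CombinationError(
            "conditional independence is not assumed between skeletal "
            "indicators; combining "
            f"{dental_model.indicator!r} with {skeletal_model.indicator!r} "
            "is not allowed"
        )
    if dental_model.indicator != DENTAL_INDICATOR:
        raise CombinationError(
            f"first model must be a {DENTAL_INDICATOR} model, got "
            f"{dental_model.indicator!r}"
        )
    if skeletal_model.indicator not in SKELETAL_INDICATORS:
        raise CombinationError(
            "conditional independence is not assumed between skeletal "
            "indicators; only the third molar can be combined with a "
            f"skeletal site (got {skeletal_model.indicator!r})"
        )
    if dental_model.sex != skeletal_model.sex:
        raise CombinationError(
            f"models are for different sexes: {dental_model.sex!r} vs "
            f"{skeletal_model.sex!r}"
        )


def joint_stage_given_age(
    dental_model: FittedOrdinalModel,
    skeletal_model: FittedOrdinalModel,
    dental_stage: str,
    skeletal_stage: str,
    age,
) -> np.ndarray:
    """P(S_s = s_s, S_t = s_t | a) under conditional independence."""
    _check_pair(dental_model, skeletal_model)
    jt = dental_model.scheme.index(dental_stage)
    js = skeletal_model.scheme.index(skeletal_stage)
    ages = np.atleast_1d(age)
    p = (
        dental_model.stage_probabilities(ages)[:, jt]
        * skeletal_model.stage_probabilities(ages)[:, js]
    )
    return float(p[0]) if np.isscalar(age) else p


def posterior_combined(
    query: CombinationQuery,
    dental_model: FittedOrdinalModel,
    skeletal_model: FittedOrdinalModel,
    grid_step: float = DEFAULT_GRID_STEP,
) -> AgePosterior:
    """Bayes-invert the joint stage probability over the combined support.

    Both fitted stage-given-age curves are evaluated over the combined
    support (the dental curves extend above the single-indicator upper
    limit where the combination requires it, e.g. to 26.0 years with the
    clavicle), multiplied, and normalised to integrate to one.
    """
    _check_pair(dental_model, skeletal_model)
    support = query.support
    grid = AgeGrid(support.lower, support.upper, grid_step)
    curve = joint_stage_given_age(
        dental_model, skeletal_model, query.dental_stage, query.skeletal_stage,
        grid.ages,
    )
    return posterior_from_curve(
        grid.ages,
        curve,
        grid,
        {
            DENTAL_INDICATOR: str(query.dental_stage),
            query.skeletal_indicator: str(query.skeletal_stage),
        },
        query.sex,
    )
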