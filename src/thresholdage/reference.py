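"""Domain types for staged developmental data and the uniform age priors.

The package models four maturity indicators read from medical images:

- ``hand_wrist``  — Greulich & Pyle skeletal-age grades (radiography),
- ``third_molar`` — Demirjian crown/root stages C–H of the lower wisdom
  tooth (radiography),
- ``distal_femur`` — Krämer knee epiphysis, dichotomised open/closed (MRI),
- ``clavicle``    — Schmeling stages 1–5 of the medial clavicular
  epiphysis (CT).

Each observation pairs an ordinal stage with a known chronological age in
decimal years.  Age-given-stage inference uses a uniform prior on a bounded,
indicator- and sex-specific age interval (:class:`PriorSupport`); the default
bounds are chosen so that the prior covers the ages over which the indicator
is still developing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, SchemaError

INDICATORS = ("hand_wrist", "third_molar", "distal_femur", "clavicle")
SEXES = ("male", "female")

_INDIVIDUAL_COLUMNS = ("subject_id", "sex", "indicator", "stage", "age")


@dataclass(frozen=True)
class StageScheme:
    """An ordered set of developmental stage labels for one indicator.

    Labels are stored as strings so that Demirjian letters, Schmeling
    integers and Greulich & Pyle skeletal-age labels (including female
    half-year grades) can coexist in one representation.
    """

    indicator: str
    stage_labels: tuple[str, ...]
    sex_specific: bool = False

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise SchemaError(f"unknown indicator {self.indicator!r}")
        labels = tuple(str(s) for s in self.stage_labels)
        object.__setattr__(self, "stage_labels", labels)
        if len(labels) < 2:
            raise SchemaError("a stage scheme needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise SchemaError("duplicate stage labels")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def index(self, label: str) -> int:
        try:
            return self.stage_labels.index(str(label))
        except ValueError:
            raise SchemaError(
                f"stage {label!r} is not in the {self.indicator} scheme "
                f"{self.stage_labels}"
            ) from None

    def __contains__(self, label: object) -> bool:
        return str(label) in self.stage_labels


#: Default staging schemes.  The hand/wrist grades are skeletal-age labels
#: compared against the Greulich & Pyle atlas; an alternative female
#: half-year grid is provided below.
DEFAULT_SCHEMES: dict[str, StageScheme] = {
    "hand_wrist": StageScheme(
        "hand_wrist", tuple(str(a) for a in range(12, 20)), sex_specific=True
    ),
    "third_molar": StageScheme("third_molar", ("C", "D", "E", "F", "G", "H")),
    "distal_femur": StageScheme("distal_femur", ("open", "closed")),
    "clavicle": StageScheme("clavicle", ("1", "2", "3", "4", "5")),
}

#: Female Greulich & Pyle plates include half-year grades between 13.5 and 18.
FEMALE_HAND_WRIST_HALFYEAR_SCHEME = StageScheme(
    "hand_wrist",
    tuple(f"{x / 2:g}" for x in range(27, 37)),  # 13.5, 14, ..., 18
    sex_specific=True,
)


@dataclass(frozen=True)
class PriorSupport:
    """Bounded support ``[lower, upper]`` of the uniform age prior, in years."""

    indicator: str
    sex: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if not self.lower < self.upper:
            raise SchemaError("prior support needs lower < upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower


#: Default prior supports per (indicator, sex).  Hand/wrist and third molar
#: start at 7 years; the hand/wrist upper bound is the end of the
#: second-to-last skeletal-age grade (20 female / 21 male); the third molar
#: is capped at 21 for both sexes (age at which half the population reaches
#: stage H); the clavicle spans 10-30 (female) / 10-32 (male); the
#: dichotomous distal femur model uses 15-21 for both sexes.
DEFAULT_SUPPORTS: dict[tuple[str, str], PriorSupport] = {
    ("hand_wrist", "male"): PriorSupport("hand_wrist", "male", 7.0, 21.0),
    ("hand_wrist", "female"): PriorSupport("hand_wrist", "female", 7.0, 20.0),
    ("third_molar", "male"): PriorSupport("third_molar", "male", 7.0, 21.0),
    ("third_molar", "female"): PriorSupport("third_molar", "female", 7.0, 21.0),
    ("clavicle", "male"): PriorSupport("clavicle", "male", 10.0, 32.0),
    ("clavicle", "female"): PriorSupport("clavicle", "female", 10.0, 30.0),
    ("distal_femur", "male"): PriorSupport("distal_femur", "male", 15.0, 21.0),
    ("distal_femur", "female"): PriorSupport("distal_femur", "female", 15.0, 21.0),
}


def default_support(indicator: str, sex: str) -> PriorSupport:
    """Return the default uniform-prior support for an indicator and sex."""
    try:
        return DEFAULT_SUPPORTS[(indicator, sex)]
    except KeyError:
        raise SchemaError(f"no default support for ({indicator!r}, {sex!r})") from None


@dataclass(frozen=True)
class StagedObservation:
    """One individual: sex, indicator, ordinal stage and chronological age."""

    subject_id: str
    sex: str
    indicator: str
    stage: str
    age: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if self.indicator not in INDICATORS:
            raise SchemaError(f"unknown indicator {self.indicator!r}")
        if not np.isfinite(self.age) or self.age < 0:
            raise SchemaError(f"age must be a finite non-negative number, got {self.age}")
        object.__setattr__(self, "stage", str(self.stage))
        object.__setattr__(self, "subject_id", str(self.subject_id))


@dataclass(frozen=True)
class Population:
    """A homogeneous set of staged observations (one indicator, one sex)."""

    observations: tuple[StagedObservation, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        if not obs:
            raise SchemaError("a population must contain at least one observation")
        indicators = {o.indicator for o in obs}
        sexes = {o.sex for o in obs}
        if len(indicators) != 1 or len(sexes) != 1:
            raise SchemaError(
                "a population must hold a single indicator and a single sex; "
                f"got indicators {sorted(indicators)} and sexes {sorted(sexes)}"
            )

    @property
    def indicator(self) -> str:
        return self.observations[0].indicator

    @property
    def sex(self) -> str:
        return self.observations[0].sex

    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def ages(self) -> np.ndarray:
        return np.array([o.age for o in self.observations], dtype=float)

    @property
    def stages(self) -> list[str]:
        return [o.stage for o in self.observations]

    def observed_stages(self) -> list[str]:
        """Distinct stages present, in first-appearance order."""
        seen: dict[str, None] = {}
        for o in self.observations:
            seen.setdefault(o.stage, None)
        return list(seen)


def read_individual_table(
    path: str | Path,
    scheme: StageScheme | None = None,
) -> Population:
    """Read an individual-level staged table (CSV) into a :class:`Population`.

    The file must carry the header ``subject_id,sex,indicator,stage,age``.
    Stage labels are validated against *scheme* (default: the package scheme
    for the table's indicator); an invalid label raises a :class:`SchemaError`
    naming the offending row.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"subject_id": str, "stage": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: no observations (empty file)") from None
    missing = [c for c in _INDIVIDUAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise SchemaError(f"{path}: no observations")
    ages = pd.to_numeric(frame["age"], errors="coerce")
    bad = frame.index[ages.isna()]
    if len(bad):
        raise ParseError(
            f"{path}: non-numeric age {frame.loc[bad[0], 'age']!r} in row {bad[0] + 2}"
        )
    observations = []
    for row_idx, row in frame.iterrows():
        row_scheme = scheme or DEFAULT_SCHEMES.get(str(row["indicator"]))
        if row_scheme is not None and str(row["stage"]) not in row_scheme:
            raise SchemaError(
                f"{path}: row {row_idx + 2}: stage {row['stage']!r} is not a "
                f"valid {row['indicator']} label "
                f"(expected one of {row_scheme.stage_labels})"
            )
        observations.append(
            StagedObservation(
                subject_id=str(row["subject_id"]),
                sex=str(row["sex"]),
                indicator=str(row["indicator"]),
                stage=str(row["stage"]),
                age=float(ages.loc[row_idx]),
            )
        )
    return Population(tuple(observations), provenance=str(path))


def write_individual_table(pop: Population, path: str | Path) -> None:
    """Write a population to CSV; ``read(write(pop))`` round-trips exactly.

    Ages are serialised with :func:`repr`-level precision so the full stored
    float value survives the round trip.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in pop.observations],
            "sex": [o.sex for o in pop.observations],
            "indicator": [o.indicator for o in pop.observations],
            "stage": [o.stage for o in pop.observations],
            "age": [repr(float(o.age)) for o in pop.observations],
        }
    )
    frame.to_csv(path, index=False)


def age_cohort_counts(
    ages: Iterable[float], cohort_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Counts per half-open age cohort ``[k*w, (k+1)*w)`` spanning the data.

    Interior cohorts with zero observations are kept so a uniformity test
    sees the gaps.
    """
    a = np.asarray(list(ages), dtype=float)
    idx = np.floor(a / cohort_width).astype(int)
    lo, hi = idx.min(), idx.max()
    edges = np.arange(lo, hi + 2)
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    return edges[:-1] * cohort_width, counts


def chisq_uniform_age(
    pop: Population, cohort_width: float = 1.0
) -> tuple[float, float]:
    """Pearson chi-square screen for an uneven age distribution.

    Observed integer-age-cohort counts are compared against a uniform
    expectation across the cohorts spanned by the data; the p-value uses the
    chi-square distribution with (cohorts - 1) degrees of freedom.  Used as
    an inclusion screen: reference studies whose age distribution departs
    strongly from uniform carry a high risk of age mimicry.
    """
    _, counts = age_cohort_counts(pop.ages, cohort_width)
    if len(counts) < 2:
        raise SchemaError("chi-square uniformity screen needs at least 2 age cohorts")
    statistic, p_value = stats.chisquare(counts)
    return float(statistic), float(p_value)
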