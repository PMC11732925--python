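"""Ground-truth generators for end-to-end testing without external data.

A :class:`GenerativeTruth` pairs a known stage-given-age model with an age
distribution over a bounded support; drawing ages and then stages from the
model yields individual-level populations whose true stage-transition law is
known exactly.  The inverse of every recreation routine is provided by
:func:`summarize`, which collapses a population into any of the four
published summary formats, so recreation fidelity can be checked as a round
trip.  :func:`generate_age_mimicry_pair` produces two populations sharing
one stage-transition truth but different age distributions — the fixture for
demonstrating that stage-given-age modelling plus uniform-prior inversion is
robust to the age make-up of the reference study (age mimicry).

The indicator presets below are plausible hand-tuned coefficient sets with
the right number of stages per indicator; they are fixtures for testing, not
estimates from any reference population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import SchemaError
from .ordinal import FittedOrdinalModel, ModelSpec, model_from_coefficients
from .recreation import (
    Cohort4,
    Stage3a,
    Stage3b,
    SummaryDataset,
    Type2Summary,
    Type3aSummary,
    Type3bSummary,
    Type4Summary,
)
from .reference import (
    DEFAULT_SCHEMES,
    Population,
    PriorSupport,
    StagedObservation,
    default_support,
)

__all__ = [
    "AgeDistribution",
    "GenerativeTruth",
    "preset_truth",
    "generate_population",
    "summarize",
    "generate_age_mimicry_pair",
]


@dataclass(frozen=True)
class AgeDistribution:
    """An age law on [lower, upper]: uniform, triangular or a 2-uniform mixture.

    ``kind`` is one of ``uniform``, ``triangular`` (with ``mode``) or
    ``mixture`` (two uniforms split at ``mode``, with weight ``weight`` on
    the lower piece) — the latter two emulate the skewed study-age profiles
    that cause age mimicry.
    """

    lower: float
    upper: float
    kind: str = "uniform"
    mode: float | None = None
    weight: float = 0.5

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise SchemaError("age distribution needs lower < upper")
        if self.kind not in ("uniform", "triangular", "mixture"):
            raise SchemaError(f"unknown age distribution kind {self.kind!r}")
        if self.kind in ("triangular", "mixture"):
            m = self.mode if self.mode is not None else 0.5 * (self.lower + self.upper)
            if not self.lower < m < self.upper:
                raise SchemaError("mode must lie strictly inside the support")
            object.__setattr__(self, "mode", m)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lower, self.upper, size=n)
        if self.kind == "triangular":
            return rng.triangular(self.lower, self.mode, self.upper, size=n)
        low = rng.random(n) < self.weight
        out = np.empty(n)
        out[low] = rng.uniform(self.lower, self.mode, size=int(low.sum()))
        out[~low] = rng.uniform(self.mode, self.upper, size=int((~low).sum()))
        return out


@dataclass(frozen=True)
class GenerativeTruth:
    """A known stage-transition model plus an age law and a sample size."""

    model: FittedOrdinalModel
    age_distribution: AgeDistribution
    n: int
    seed: int | None = None

    @property
    def indicator(self) -> str:
        return self.model.indicator

    @property
    def sex(self) -> str:
        return self.model.sex

    @property
    def support(self) -> PriorSupport:
        return PriorSupport(
            self.indicator, self.sex,
            self.age_distribution.lower, self.age_distribution.upper,
        )


# Hand-tuned continuation-ratio logit coefficients per indicator.  Each
# boundary hazard h_j(a) = expit(alpha_j + beta_j * a) crosses 1/2 at age
# -alpha_j / beta_j, so the pairs below place the stage transitions at
# plausible ages with moderate spread.
_PRESET_TRANSITIONS: dict[str, tuple[tuple[float, float], ...]] = {
    # (transition age in years, |slope|) per stage boundary
    "hand_wrist": tuple(
        (t, s) for t, s in zip((12.0, 13.2, 14.2, 15.2, 16.2, 17.2, 18.4),
                               (1.6, 1.6, 1.7, 1.7, 1.6, 1.5, 1.4))
    ),
    "third_molar": tuple(
        (t, s) for t, s in zip((11.5, 13.0, 14.5, 16.2, 18.5),
                               (1.1, 1.1, 1.0, 0.9, 0.8))
    ),
    "distal_femur": ((18.0, 1.2),),
    "clavicle": tuple(
        (t, s) for t, s in zip((17.0, 19.5, 22.0, 25.5), (0.9, 0.8, 0.7, 0.7))
    ),
}


def preset_truth(
    indicator: str,
    sex: str = "male",
    n: int = 5000,
    seed: int | None = 0,
    spec: ModelSpec = ModelSpec("continuation_ratio", "logit", "non_parallel"),
    age_distribution: AgeDistribution | None = None,
) -> GenerativeTruth:
    """A ready-made generative truth for one indicator.

    The default age distribution is uniform on the indicator's prior
    support, which is also the regime where stage distributions within a
    stage are approximately normal and age mimicry is absent.
    """
    scheme = DEFAULT_SCHEMES[indicator]
    trans = _PRESET_TRANSITIONS[indicator]
    if len(trans) != scheme.n_stages - 1:
        raise SchemaError("preset transitions do not match the scheme")
    slopes = tuple(-s for _, s in trans)
    intercepts = tuple(s * t for (t, s) in trans)
    if spec.slope == "parallel":
        mean_slope = float(np.mean(slopes))
        slopes = (mean_slope,)
        intercepts = tuple(-mean_slope * t for t, _ in trans)
    model = model_from_coefficients(spec, scheme, sex, intercepts, slopes)
    if age_distribution is None:
        sup = default_support(indicator, sex)
        age_distribution = AgeDistribution(sup.lower, sup.upper)
    return GenerativeTruth(model, age_distribution, n, seed)


def generate_population(
    truth: GenerativeTruth, seed: int | None = None
) -> Population:
    """Draw ages from the age law and stages from the stage-given-age model."""
    if truth.n < 1:
        raise SchemaError("generative truth needs n >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ages = truth.age_distribution.sample(truth.n, rng)
    P = truth.model.stage_probabilities(ages)  # (n, J)
    u = rng.random(truth.n)
    idx = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
    labels = truth.model.scheme.stage_labels
    obs = tuple(
        StagedObservation(f"syn-{i:06d}", truth.sex, truth.indicator,
                          labels[j], float(a))
        for i, (a, j) in enumerate(zip(ages, idx))
    )
    return Population(obs, provenance=f"synthetic:{truth.indicator}:{truth.sex}")


def _stage_value_grid(scheme) -> dict[str, float]:
    """Map stage labels to numeric skeletal-age style values.

    Numeric labels map to themselves; otherwise labels map to their rank,
    the simplest invertible convention.
    """
    grid = {}
    for i, s in enumerate(scheme.stage_labels):
        try:
            grid[s] = float(s)
        except ValueError:
            grid[s] = float(i)
    return grid


def summarize(
    pop: Population,
    as_type: str,
    include_ranges: bool = False,
) -> SummaryDataset:
    """Collapse an individual-level population into a published-summary format.

    ``as_type`` is one of ``type2``, ``type3a``, ``type3b`` or ``type4``.
    For type 3a, ``include_ranges=True`` additionally records each stage's
    observed age min/max as its truncation range.  Stages with a single
    member cannot report an SD and are emitted with ``sd=nan`` flagged via
    ``n == 1``.  Type 4 derives a skeletal-age value per observation from
    the stage label grid and reports a single whole-study cohort.
    """
    ages = pop.ages
    stages = np.array(pop.stages)
    scheme = DEFAULT_SCHEMES[pop.indicator]
    order = [s for s in scheme.stage_labels if s in set(stages)]
    if as_type == "type2":
        cohorts: dict[int, dict[str, int]] = {}
        ks = np.floor(ages).astype(int)
        for k in range(ks.min(), ks.max() + 1):
            sel = ks == k
            if not sel.any():
                continue
            cohorts[k] = {
                s: int(np.sum(stages[sel] == s))
                for s in order
                if np.sum(stages[sel] == s) > 0
            }
        return Type2Summary(pop.indicator, pop.sex, cohorts, source_id=pop.provenance)
    if as_type == "type3a":
        recs = {}
        for s in order:
            a = ages[stages == s]
            recs[s] = Stage3a(
                n=len(a),
                mean=float(a.mean()),
                sd=float(a.std(ddof=1)) if len(a) > 1 else float("nan"),
                age_range=(float(a.min()), float(a.max())) if include_ranges else None,
            )
        return Type3aSummary(pop.indicator, pop.sex, recs, source_id=pop.provenance)
    if as_type == "type3b":
        recs3b = {}
        for s in order:
            a = ages[stages == s]
            mn, q1, med, q3, mx = np.percentile(a, [0, 25, 50, 75, 100])
            recs3b[s] = Stage3b(len(a), float(mn), float(q1), float(med),
                                float(q3), float(mx))
        return Type3bSummary(pop.indicator, pop.sex, recs3b, source_id=pop.provenance)
    if as_type == "type4":
        grid = _stage_value_grid(scheme)
        sa = np.array([grid[s] for s in stages], dtype=float)
        r = float(np.corrcoef(ages, sa)[0, 1]) if len(ages) > 1 else 0.0
        cohort = Cohort4(
            n=len(ages),
            mean_ca=float(ages.mean()),
            sd_ca=float(ages.std(ddof=1)),
            mean_sa=float(sa.mean()),
            sd_sa=float(sa.std(ddof=1)),
            r=r,
        )
        return Type4Summary(
            pop.indicator, pop.sex, (cohort,), grid, source_id=pop.provenance
        )
    raise SchemaError(f"unknown summary type {as_type!r}")


def generate_age_mimicry_pair(
    truth: GenerativeTruth,
    skewed_age_distribution: AgeDistribution,
    seed: int | None = None,
) -> tuple[Population, Population]:
    """Two populations with one stage-transition truth, two age laws.

    The first population uses the truth's own age distribution, the second
    the skewed one; both draw stages from the same model.  Because the
    two-step procedure models stage given age and then inverts under a
    uniform prior, posteriors inferred from the two populations should
    agree up to sampling error, whatever the study-age profile.
    """
    base_seed = truth.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed).spawn(2)
    pop_a = generate_population(truth, seed=ss[0])
    skewed = replace(truth, age_distribution=skewed_age_distribution)
    pop_b = generate_population(skewed, seed=ss[1])
    return pop_a, pop_b
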