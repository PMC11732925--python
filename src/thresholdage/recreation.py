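"""Recreate individual-level (age, stage) populations from published summaries.

Reference studies rarely publish one row per individual.  Four aggregate
formats are supported, mirroring how the literature reports staged data:

- **type 2** — stage counts (or fractions plus totals) within integer age
  cohorts, optionally with a global age range per stage;
- **type 3a** — per-stage sample size, mean and SD of chronological age,
  optionally with a truncation range;
- **type 3b** — per-stage five-number summary (min, Q1, median, Q3, max);
- **type 4** — cohort means/SDs of chronological and skeletal age plus a
  Pearson correlation, from which (age, stage) pairs are drawn via a
  bivariate normal.

Each format has a ``recreate_*`` operation that draws a synthetic population
consistent with the summary.  Repeating the recreation many times produces
an ensemble of plausible reference populations; downstream statistics are
taken as percentiles across that ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .errors import (
    DegenerateSpreadError,
    FitError,
    FitInfeasibleError,
    ParseError,
    SchemaError,
)
from .reference import Population, StagedObservation

__all__ = [
    "Type2Summary",
    "Stage3a",
    "Type3aSummary",
    "Stage3b",
    "Type3bSummary",
    "Cohort4",
    "Type4Summary",
    "TruncNormFit",
    "fit_truncnorm_moments",
    "fit_truncnorm_quantiles",
    "recreate_type2",
    "recreate_type3",
    "recreate_type4",
    "recreate",
    "simulate_population_ensemble",
    "read_summary",
    "write_summary",
]


# ---------------------------------------------------------------------------
# Summary dataclasses


@dataclass(frozen=True)
class Type2Summary:
    """Stage counts per integer age cohort.

    ``cohort_counts`` maps the cohort's lower integer bound ``k`` (the
    half-open interval ``[k, k+1)``) to a ``{stage: count}`` mapping.
    ``stage_ranges`` optionally restricts a stage's ages to a global
    ``[min, max]`` interval across all cohorts.
    """

    indicator: str
    sex: str
    cohort_counts: Mapping[int, Mapping[str, int]]
    stage_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self) -> None:
        for k, counts in self.cohort_counts.items():
            for s, c in counts.items():
                if c < 0:
                    raise SchemaError(f"negative count for cohort {k}, stage {s!r}")

    @classmethod
    def from_fractions(
        cls,
        indicator: str,
        sex: str,
        cohort_fractions: Mapping[int, Mapping[str, float]],
        cohort_totals: Mapping[int, int],
        **kwargs,
    ) -> "Type2Summary":
        """Build from per-cohort stage fractions and cohort totals."""
        counts: dict[int, dict[str, int]] = {}
        for k, fracs in cohort_fractions.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise SchemaError(
                    f"cohort {k}: stage fractions sum to {total}, expected 1"
                )
            counts[k] = {s: int(round(f * cohort_totals[k])) for s, f in fracs.items()}
        return cls(indicator, sex, counts, **kwargs)

    @property
    def n(self) -> int:
        return sum(c for d in self.cohort_counts.values() for c in d.values())


@dataclass(frozen=True)
class Stage3a:
    n: int
    mean: float
    sd: float
    age_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SchemaError("stage n must be non-negative")
        if self.n > 1 and not self.sd > 0:
            raise SchemaError("stage SD must be positive when n > 1")


@dataclass(frozen=True)
class Type3aSummary:
    """Per-stage sample size, mean age and SD (optionally truncated)."""

    indicator: str
    sex: str
    stages: Mapping[str, Stage3a]
    source_id: str = ""


@dataclass(frozen=True)
class Stage3b:
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def __post_init__(self) -> None:
        q = (self.minimum, self.q1, self.median, self.q3, self.maximum)
        if any(b < a for a, b in zip(q, q[1:])):
            raise SchemaError(f"five-number summary not ordered: {q}")

    @property
    def five_numbers(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q1, self.median, self.q3, self.maximum)


@dataclass(frozen=True)
class Type3bSummary:
    """Per-stage five-number summary of chronological age."""

    indicator: str
    sex: str
    stages: Mapping[str, Stage3b]
    source_id: str = ""


@dataclass(frozen=True)
class Cohort4:
    n: int
    mean_ca: float
    sd_ca: float
    mean_sa: float
    sd_sa: float
    r: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise SchemaError(f"Pearson correlation out of [-1, 1]: {self.r}")
        if self.n > 1 and (self.sd_ca <= 0 or self.sd_sa <= 0):
            raise SchemaError("cohort SDs must be positive")


@dataclass(frozen=True)
class Type4Summary:
    """Bivariate (chronological age, skeletal age) summaries per cohort.

    ``label_grid`` maps each stage label to the skeletal-age value it
    represents (e.g. Greulich & Pyle grade "14" -> 14.0 years); conditional
    skeletal-age draws are discretised to the nearest grid value.
    """

    indicator: str
    sex: str
    cohorts: tuple[Cohort4, ...]
    label_grid: Mapping[str, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        if not self.label_grid:
            raise SchemaError("type-4 summary needs a non-empty stage label grid")


SummaryDataset = Type2Summary | Type3aSummary | Type3bSummary | Type4Summary


# ---------------------------------------------------------------------------
# Truncated-normal fitting


@dataclass(frozen=True)
class TruncNormFit:
    """A (possibly truncated) normal age model for one stage."""

    mu: float
    sigma: float
    lower: float
    upper: float
    objective_value: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise FitError(f"sigma must be positive, got {self.sigma}")
        if not self.lower < self.upper:
            raise FitError("truncation range needs lower < upper")

    def _frozen(self):
        a = (self.lower - self.mu) / self.sigma
        b = (self.upper - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def mean_sd(self) -> tuple[float, float]:
        d = self._frozen()
        return float(d.mean()), float(d.std())

    def ppf(self, p) -> np.ndarray:
        return self._frozen().ppf(p)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)


def _is_unbounded(age_range: tuple[float, float] | None) -> bool:
    if age_range is None:
        return True
    lo, hi = age_range
    return not (np.isfinite(lo) or np.isfinite(hi))


def fit_truncnorm_moments(
    n: int,
    mean: float,
    sd: float,
    age_range: tuple[float, float] | None = None,
) -> TruncNormFit:
    """Find (mu, sigma) whose truncated mean/SD match the reported values.

    With no (or an unbounded) range this is the identity fit mu = mean,
    sigma = sd.  With a finite range the two moment equations are solved
    numerically; the achieved moments match the reported ones to 1e-6 or a
    :class:`FitInfeasibleError` is raised.  Note a truncated normal on
    ``[a, b]`` cannot have an SD at or above the uniform limit
    ``(b - a)/sqrt(12)``.
    """
    if not sd > 0:
        raise SchemaError("sd must be positive")
    if _is_unbounded(age_range):
        return TruncNormFit(float(mean), float(sd), -np.inf, np.inf, 0.0)
    lo, hi = float(age_range[0]), float(age_range[1])
    if not lo < hi:
        raise SchemaError("age_range needs lower < upper")
    if not lo < mean < hi:
        raise FitInfeasibleError(
            f"reported mean {mean} outside the truncation range [{lo}, {hi}]"
        )
    if sd >= (hi - lo) / math.sqrt(12.0):
        raise FitInfeasibleError(
            f"reported SD {sd} is not attainable on [{lo}, {hi}] "
            f"(uniform limit {(hi - lo) / math.sqrt(12.0):.4f})"
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(max(v, 0.0)) - sd])

    sol = optimize.least_squares(
        residuals, x0=np.array([mean, math.log(sd)]), xtol=1e-14, ftol=1e-14
    )
    if np.max(np.abs(sol.fun)) > 1e-6:
        raise FitInfeasibleError(
            f"could not match mean={mean}, sd={sd} on [{lo}, {hi}] "
            f"(residual {np.max(np.abs(sol.fun)):.2e})"
        )
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    return TruncNormFit(mu, sigma, lo, hi, float(np.sum(sol.fun**2)))


def fit_truncnorm_quantiles(
    q: Sequence[float],
    age_range: tuple[float, float] | None = None,
    n_obs: int | None = None,
    include_extremes: bool = True,
) -> TruncNormFit:
    """Fit (mu, sigma) to a reported five-number summary by least squares.

    *q* is ``(min, Q1, median, Q3, max)``.  The objective is the sum of
    squared differences between the theoretical quantiles of the truncated
    normal and the reported values, at probabilities 0.25/0.5/0.75 and — by
    default — at the expected order-statistic positions ``1/(n+1)`` and
    ``n/(n+1)`` of the reported extremes (``include_extremes=False``
    restricts the objective to the quartiles).  When no truncation range is
    reported, the reported min/max serve as the truncation bounds.
    """
    q = tuple(float(v) for v in q)
    if len(q) != 5:
        raise SchemaError("expected a five-number summary (min, Q1, median, Q3, max)")
    mn, q1, med, q3, mx = q
    if any(b < a for a, b in zip(q, q[1:])):
        raise SchemaError(f"five-number summary not ordered: {q}")
    if q3 - q1 <= 0:
        raise DegenerateSpreadError(f"zero interquartile spread in {q}")
    if age_range is None:
        lo, hi = mn, mx
        if not lo < hi:
            raise DegenerateSpreadError("degenerate range: min equals max")
    else:
        lo, hi = float(age_range[0]), float(age_range[1])

    probs = [0.25, 0.5, 0.75]
    targets = [q1, med, q3]
    if include_extremes:
        n_eff = int(n_obs) if n_obs else 20
        probs = [1.0 / (n_eff + 1)] + probs + [n_eff / (n_eff + 1.0)]
        targets = [mn] + targets + [mx]
    probs_arr = np.asarray(probs)
    targets_arr = np.asarray(targets)

    def objective(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = math.exp(min(log_sigma, 20.0))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        qq = stats.truncnorm.ppf(probs_arr, a, b, loc=mu, scale=sigma)
        if not np.all(np.isfinite(qq)):
            return 1e12
        return float(np.sum((qq - targets_arr) ** 2))

    sigma0 = max((q3 - q1) / 1.349, 1e-3)
    starts = [np.array([med, math.log(sigma0)])]
    jitter_rng = np.random.default_rng(0)
    starts += [
        starts[0] + jitter_rng.normal(scale=[0.5, 0.3]) for _ in range(3)
    ]
    best = None
    for x0 in starts:
        sol = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or sol.fun < best.fun:
            best = sol
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"quantile fit failed for summary {q}")
    mu, sigma = float(best.x[0]), float(math.exp(best.x[1]))
    return TruncNormFit(mu, sigma, lo, hi, float(best.fun))


# ---------------------------------------------------------------------------
# Recreation operations


def _make_obs(indicator, sex, stage, ages, prefix) -> list[StagedObservation]:
    return [
        StagedObservation(f"{prefix}{i:05d}", sex, indicator, stage, float(a))
        for i, a in enumerate(ages)
    ]


def recreate_type2(summary: Type2Summary, seed: int | None = None) -> Population:
    """Draw one individual-level population from a type-2 summary.

    Each count ``c`` in cohort ``[k, k+1)`` yields ``c`` observations whose
    ages are uniform on the cohort interval, intersected with the stage's
    global age range when one is reported.
    """
    rng = np.random.default_rng(seed)
    observations: list[StagedObservation] = []
    counter = 0
    for k in sorted(summary.cohort_counts):
        for stage, count in summary.cohort_counts[k].items():
            if count == 0:
                continue
            lo, hi = float(k), float(k) + 1.0
            if stage in summary.stage_ranges:
                smin, smax = summary.stage_ranges[stage]
                lo, hi = max(lo, smin), min(hi, smax)
                if not lo < hi:
                    raise SchemaError(
                        f"stage {stage!r} range [{smin}, {smax}] is disjoint "
                        f"from cohort [{k}, {k + 1})"
                    )
            ages = rng.uniform(lo, hi, size=count)
            observations += _make_obs(
                summary.indicator, summary.sex, stage, ages, f"t2-{counter:04d}-"
            )
            counter += 1
    if not observations:
        raise SchemaError("type-2 summary has no positive counts")
    return Population(
        tuple(observations),
        provenance=f"{summary.source_id or 'type2'}:recreated:seed={seed}",
    )


def _stage_fits_type3(summary: Type3aSummary | Type3bSummary) -> dict[str, tuple[int, TruncNormFit]]:
    fits: dict[str, tuple[int, TruncNormFit]] = {}
    for stage, rec in summary.stages.items():
        if rec.n == 0:
            continue
        if isinstance(summary, Type3aSummary):
            fits[stage] = (rec.n, fit_truncnorm_moments(rec.n, rec.mean, rec.sd, rec.age_range))
        else:
            fits[stage] = (
                rec.n,
                fit_truncnorm_quantiles(rec.five_numbers, n_obs=rec.n),
            )
    return fits


def recreate_type3(
    summary: Type3aSummary | Type3bSummary, seed: int | None = None
) -> Population:
    """Draw a population from per-stage (truncated) normal age models.

    Type 3a stages use the moment fit; type 3b stages use the quantile fit.
    Stages with n = 0 are absent from the output.
    """
    rng = np.random.default_rng(seed)
    observations: list[StagedObservation] = []
    for i, (stage, (n, fit)) in enumerate(_stage_fits_type3(summary).items()):
        ages = fit.rvs(n, rng)
        observations += _make_obs(
            summary.indicator, summary.sex, stage, ages, f"t3-{i:04d}-"
        )
    if not observations:
        raise SchemaError("type-3 summary has no stages with n > 0")
    return Population(
        tuple(observations),
        provenance=f"{summary.source_id or 'type3'}:recreated:seed={seed}",
    )


def recreate_type4(summary: Type4Summary, seed: int | None = None) -> Population:
    """Draw a population from bivariate-normal (CA, skeletal age) summaries.

    Two-step sampling per cohort: chronological age from
    ``N(mean_ca, sd_ca)``, then skeletal age from the conditional normal
    given CA (mean shifted by ``r * sd_sa / sd_ca * (CA - mean_ca)``, SD
    ``sd_sa * sqrt(1 - r^2)``); the skeletal-age draw is discretised to the
    nearest label on the grid.
    """
    rng = np.random.default_rng(seed)
    labels = list(summary.label_grid)
    grid = np.array([summary.label_grid[s] for s in labels], dtype=float)
    observations: list[StagedObservation] = []
    for i, c in enumerate(summary.cohorts):
        if abs(c.r) >= 1.0:
            raise FitError(
                f"cohort {i}: |r| = 1 gives a degenerate conditional distribution"
            )
        ca = rng.normal(c.mean_ca, c.sd_ca, size=c.n)
        cond_mean = c.mean_sa + c.r * (c.sd_sa / c.sd_ca) * (ca - c.mean_ca)
        cond_sd = c.sd_sa * math.sqrt(1.0 - c.r**2)
        sa = rng.normal(cond_mean, cond_sd)
        nearest = np.argmin(np.abs(sa[:, None] - grid[None, :]), axis=1)
        for j, (a, s_idx) in enumerate(zip(ca, nearest)):
            observations.append(
                StagedObservation(
                    f"t4-{i:04d}-{j:05d}",
                    summary.sex,
                    summary.indicator,
                    labels[s_idx],
                    float(max(a, 0.0)),
                )
            )
    if not observations:
        raise SchemaError("type-4 summary has no cohorts with n > 0")
    return Population(
        tuple(observations),
        provenance=f"{summary.source_id or 'type4'}:recreated:seed={seed}",
    )


def recreate(summary: SummaryDataset, seed: int | None = None) -> Population:
    """Dispatch to the recreation routine matching the summary type."""
    if isinstance(summary, Type2Summary):
        return recreate_type2(summary, seed)
    if isinstance(summary, (Type3aSummary, Type3bSummary)):
        return recreate_type3(summary, seed)
    if isinstance(summary, Type4Summary):
        return recreate_type4(summary, seed)
    raise SchemaError(f"not a summary dataset: {type(summary).__name__}")


def simulate_population_ensemble(
    source: SummaryDataset | Population,
    n_pops: int = 10_000,
    seed: int | None = None,
) -> list[Population]:
    """Simulate an ensemble of recreated populations from one summary.

    Individual-level (type 1) data need no recreation: passing a
    :class:`Population` returns ``n_pops`` references to it unchanged.
    Per-population seeds are spawned deterministically from the master seed.
    """
    if n_pops < 1:
        raise SchemaError("n_pops must be at least 1")
    if isinstance(source, Population):
        return [source] * n_pops
    children = np.random.SeedSequence(seed).spawn(n_pops)
    return [recreate(source, c) for c in children]


# ---------------------------------------------------------------------------
# Summary document I/O (YAML/JSON with a "type" discriminator)


def write_summary(summary: SummaryDataset, path: str | Path) -> None:
    """Serialise a summary dataset to a YAML document."""
    doc: dict = {"indicator": summary.indicator, "sex": summary.sex}
    if summary.source_id:
        doc["source_id"] = summary.source_id
    if isinstance(summary, Type2Summary):
        doc["type"] = "type2"
        doc["cohorts"] = {
            int(k): {str(s): int(c) for s, c in counts.items()}
            for k, counts in summary.cohort_counts.items()
        }
        if summary.stage_ranges:
            doc["stage_ranges"] = {
                str(s): [float(a), float(b)] for s, (a, b) in summary.stage_ranges.items()
            }
    elif isinstance(summary, Type3aSummary):
        doc["type"] = "type3a"
        doc["stages"] = {
            str(s): {
                "n": int(r.n),
                "mean": float(r.mean),
                "sd": float(r.sd),
                **(
                    {"range": [float(r.age_range[0]), float(r.age_range[1])]}
                    if r.age_range is not None
                    else {}
                ),
            }
            for s, r in summary.stages.items()
        }
    elif isinstance(summary, Type3bSummary):
        doc["type"] = "type3b"
        doc["stages"] = {
            str(s): {
                "n": int(r.n),
                "min": float(r.minimum),
                "q1": float(r.q1),
                "median": float(r.median),
                "q3": float(r.q3),
                "max": float(r.maximum),
            }
            for s, r in summary.stages.items()
        }
    elif isinstance(summary, Type4Summary):
        doc["type"] = "type4"
        doc["cohorts"] = [
            {
                "n": int(c.n),
                "mean_ca": float(c.mean_ca),
                "sd_ca": float(c.sd_ca),
                "mean_sa": float(c.mean_sa),
                "sd_sa": float(c.sd_sa),
                "r": float(c.r),
            }
            for c in summary.cohorts
        ]
        doc["label_grid"] = {str(s): float(v) for s, v in summary.label_grid.items()}
    else:
        raise SchemaError(f"not a summary dataset: {type(summary).__name__}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_summary(path: str | Path) -> SummaryDataset:
    """Read a summary dataset document written by :func:`write_summary`."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "type" not in doc:
        raise SchemaError(f"{path}: not a summary document (missing 'type' field)")
    kind = doc["type"]
    common = dict(
        indicator=doc.get("indicator", ""),
        sex=doc.get("sex", ""),
        source_id=doc.get("source_id", ""),
    )
    try:
        if kind == "type2":
            return Type2Summary(
                cohort_counts={
                    int(k): {str(s): int(c) for s, c in v.items()}
                    for k, v in doc["cohorts"].items()
                },
                stage_ranges={
                    str(s): (float(a), float(b))
                    for s, (a, b) in doc.get("stage_ranges", {}).items()
                },
                **common,
            )
        if kind == "type3a":
            return Type3aSummary(
                stages={
                    str(s): Stage3a(
                        n=int(r["n"]),
                        mean=float(r["mean"]),
                        sd=float(r["sd"]),
                        age_range=tuple(r["range"]) if "range" in r else None,
                    )
                    for s, r in doc["stages"].items()
                },
                **common,
            )
        if kind == "type3b":
            return Type3bSummary(
                stages={
                    str(s): Stage3b(
                        n=int(r["n"]),
                        minimum=float(r["min"]),
                        q1=float(r["q1"]),
                        median=float(r["median"]),
                        q3=float(r["q3"]),
                        maximum=float(r["max"]),
                    )
                    for s, r in doc["stages"].items()
                },
                **common,
            )
        if kind == "type4":
            return Type4Summary(
                cohorts=tuple(
                    Cohort4(
                        n=int(c["n"]),
                        mean_ca=float(c["mean_ca"]),
                        sd_ca=float(c["sd_ca"]),
                        mean_sa=float(c["mean_sa"]),
                        sd_sa=float(c["sd_sa"]),
                        r=float(c["r"]),
                    )
                    for c in doc["cohorts"]
                ),
                label_grid={str(s): float(v) for s, v in doc["label_grid"].items()},
                **common,
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed {kind} document ({exc})") from exc
    raise SchemaError(f"{path}: unknown summary type {kind!r}")
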