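"""Threshold classification and reliability metrics on independent data.

An individual's posterior probability of being below a legal age threshold
is turned into a below/above statement by a cutoff on that probability
(default 0.35): probabilities *above* the cutoff classify the individual as
below the threshold, probabilities below it as above.  The asymmetric
cutoff deliberately trades specificity for fewer type-1 errors (minors
classified as adults).  Against observations of known chronological age the
usual diagnostic metrics are reported per threshold, with "above the
threshold" as the positive class:

- sensitivity  = TP / (TP + FN)   (above identified as above)
- specificity  = TN / (TN + FP)   (below identified as below)
- PPV          = TP / (TP + FP)
- NPV          = TN / (TN + FN)
- accuracy     = (TP + TN) / total

Zero-denominator ratios are reported as undefined (``None``), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import SchemaError
from .ordinal import FittedOrdinalModel
from .posterior import DEFAULT_GRID_STEP, posterior_age_given_stage, prob_below
from .reference import Population, PriorSupport

__all__ = [
    "DEFAULT_CUTOFF",
    "classify",
    "ConfusionCounts",
    "ReliabilityReport",
    "evaluate",
    "min_validation_sample_size",
    "roc_points",
]

DEFAULT_CUTOFF = 0.35


def classify(prob_below_threshold: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Classify ``below``/``above`` a threshold from P(A < threshold).

    A probability exactly at the cutoff classifies as ``above`` (ties are
    measure-zero; the low cutoff itself already biases statements toward
    ``below``).
    """
    if not 0.0 <= prob_below_threshold <= 1.0:
        raise SchemaError(f"probability out of [0, 1]: {prob_below_threshold}")
    return "below" if prob_below_threshold > cutoff else "above"


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with "above the threshold" as the positive class."""

    tp: int  # above, classified above
    fn: int  # above, classified below
    tn: int  # below, classified below
    fp: int  # below, classified above

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-threshold diagnostic metrics; undefined ratios are ``None``."""

    metrics: Mapping[float, Mapping[str, float | None]]

    def __getitem__(self, threshold: float) -> Mapping[str, float | None]:
        return self.metrics[threshold]


def _metrics(c: ConfusionCounts) -> dict[str, float | None]:
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "accuracy": _ratio(c.tp + c.tn, c.total),
    }


def evaluate(
    validation_pop: Population,
    model: FittedOrdinalModel,
    support: PriorSupport,
    thresholds: Sequence[float] = (15.0, 18.0, 21.0),
    cutoff: float = DEFAULT_CUTOFF,
    grid_step: float = DEFAULT_GRID_STEP,
) -> tuple[dict[float, ConfusionCounts], ReliabilityReport]:
    """Classify every observation by its true stage and score against true age.

    For each observation the posterior P(A < threshold) given its observed
    stage is computed from the fitted model (cached per stage), classified
    at the cutoff, and compared with whether the individual's chronological
    age actually lies below the threshold (ages exactly at the threshold
    count as above).
    """
    if validation_pop.n == 0:
        raise SchemaError("empty validation set")
    stage_probs: dict[str, dict[float, float]] = {}
    for stage in validation_pop.observed_stages():
        if stage not in model.scheme:
            raise SchemaError(
                f"validation stage {stage!r} is not in the model scheme"
            )
        post = posterior_age_given_stage(model, stage, support, grid_step)
        stage_probs[stage] = {t: prob_below(post, t) for t in thresholds}

    counts: dict[float, ConfusionCounts] = {}
    for t in thresholds:
        tp = fn = tn = fp = 0
        for obs in validation_pop.observations:
            predicted = classify(stage_probs[obs.stage][t], cutoff)
            truly_above = obs.age >= t
            if truly_above and predicted == "above":
                tp += 1
            elif truly_above:
                fn += 1
            elif predicted == "below":
                tn += 1
            else:
                fp += 1
        counts[t] = ConfusionCounts(tp, fn, tn, fp)
    report = ReliabilityReport({t: _metrics(c) for t, c in counts.items()})
    return counts, report


def min_validation_sample_size(
    prevalence: float, margin: float, z: float = 1.96
) -> int:
    """Minimum validation sample size for a binary-outcome precision target.

    ``n = (z / margin)^2 * prevalence * (1 - prevalence)``, truncated to an
    integer.  With a 15% expected misclassification rate, a 5% margin and
    z = 1.96 this gives 195 individuals.
    """
    if not 0.0 < prevalence < 1.0:
        raise SchemaError("prevalence must be strictly between 0 and 1")
    if not 0.0 < margin < 1.0:
        raise SchemaError("margin must be strictly between 0 and 1")
    return int((z / margin) ** 2 * prevalence * (1.0 - prevalence))


def roc_points(
    probs_below: Sequence[float], truly_below: Sequence[bool]
) -> np.ndarray:
    """Optional ROC sweep of the classification cutoff.

    Returns an array of (cutoff, true-positive rate, false-positive rate)
    rows, with "below the threshold" as the positive class scored by
    P(A < threshold).  The operating cutoff of the model remains 0.35; this
    is a diagnostic report only.
    """
    p = np.asarray(probs_below, dtype=float)
    y = np.asarray(truly_below, dtype=bool)
    cutoffs = np.unique(np.concatenate([[0.0], np.sort(p), [1.0]]))
    rows = []
    for c in cutoffs:
        pred_below = p > c
        tp = int(np.sum(pred_below & y))
        fp = int(np.sum(pred_below & ~y))
        tpr = tp / max(int(np.sum(y)), 1)
        fpr = fp / max(int(np.sum(~y)), 1)
        rows.append((float(c), tpr, fpr))
    return np.array(rows)
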