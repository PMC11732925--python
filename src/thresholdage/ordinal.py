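"""Ordinal stage-given-age models: likelihoods, fitting and AIC selection.

The developmental stage ``S`` of an indicator is modelled conditionally on
chronological age ``A`` with one of two ordinal regression families:

- **cumulative** (proportional-odds style):
  ``P(S <= j | a) = F(alpha_j + beta_j * a)`` for boundaries
  ``j = 1..J-1``; category probabilities are successive differences.
- **continuation ratio** (CR), ascending form: the boundary hazards
  ``h_j(a) = P(S = j | S >= j, a) = F(alpha_j + beta_j * a)`` give
  ``P(S = j | a) = h_j(a) * prod_{k<j} (1 - h_k(a))``, with the latest
  stage taking the remaining mass.

``F`` is either the logistic CDF (logit link) or the standard normal CDF
(probit link); slopes are shared across boundaries (*parallel*) or free per
boundary (*non-parallel*).  With exactly two stages every combination
collapses to plain binary regression.

Maximisation is quasi-Newton (L-BFGS-B) on the negative log-likelihood with
age standardised internally for conditioning; non-parallel cumulative models
can imply negative category probabilities, so the objective adds a smooth
penalty keeping probabilities above 1e-12 at the observed ages, and
evaluation floors at zero and renormalises.  Candidate models are compared
by AIC; across an ensemble of recreated populations the winner is the
specification with the lowest median AIC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtr, ndtri

from .errors import FitError, SchemaError
from .reference import Population, StageScheme, DEFAULT_SCHEMES

__all__ = [
    "ModelSpec",
    "CANDIDATE_SPECS",
    "FittedOrdinalModel",
    "stage_probabilities",
    "stage_given_age",
    "fit",
    "select_model",
    "model_from_coefficients",
    "save_model",
    "load_model",
]

FAMILIES = ("cumulative", "continuation_ratio")
LINKS = ("logit", "probit")
SLOPES = ("parallel", "non_parallel")

_PENALTY_FLOOR = 1e-12
_PENALTY_WEIGHT = 1e6


@dataclass(frozen=True)
class ModelSpec:
    """Family/link/slope structure of a candidate ordinal model."""

    family: str
    link: str
    slope: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SchemaError(f"unknown family {self.family!r}")
        if self.link not in LINKS:
            raise SchemaError(f"unknown link {self.link!r}")
        if self.slope not in SLOPES:
            raise SchemaError(f"unknown slope structure {self.slope!r}")

    @property
    def label(self) -> str:
        return f"{self.family}/{self.link}/{self.slope}"


#: All eight candidate specifications.
CANDIDATE_SPECS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(f, l, s) for f, l, s in product(FAMILIES, LINKS, SLOPES)
)


def _cdf(link: str, eta: np.ndarray) -> np.ndarray:
    return expit(eta) if link == "logit" else ndtr(eta)


def _cdf_inv(link: str, p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    if link == "logit":
        return np.log(p / (1 - p))
    return ndtri(p)


def _raw_probabilities(
    spec: ModelSpec,
    intercepts: np.ndarray,
    slopes: np.ndarray,
    ages: np.ndarray,
) -> np.ndarray:
    """Category probabilities, shape (n_ages, J); cumulative non-parallel
    models may return (small) negative values here."""
    ages = np.asarray(ages, dtype=float).ravel()
    intercepts = np.asarray(intercepts, dtype=float).ravel()
    n_bound = intercepts.size
    b = np.asarray(slopes, dtype=float).ravel()
    if b.size == 1:
        b = np.full(n_bound, b[0])
    eta = intercepts[:, None] + b[:, None] * ages[None, :]
    F = _cdf(spec.link, eta)  # (J-1, n)
    n = ages.size
    if spec.family == "cumulative":
        stacked = np.vstack([np.zeros((1, n)), F, np.ones((1, n))])
        P = np.diff(stacked, axis=0)
    else:
        one_minus = 1.0 - F
        surv = np.vstack([np.ones((1, n)), np.cumprod(one_minus, axis=0)])
        hazards = np.vstack([F, np.ones((1, n))])
        P = hazards * surv
    return P.T


def stage_probabilities(
    spec: ModelSpec,
    intercepts: Sequence[float],
    slopes: Sequence[float],
    ages,
) -> np.ndarray:
    """Evaluate P(S = s | a) for each stage at the given age(s).

    Returns a (n_ages, J) matrix of probabilities, each row non-negative
    and summing to one (cumulative non-parallel probabilities are floored
    at zero and renormalised).
    """
    P = _raw_probabilities(
        spec, np.asarray(intercepts, float), np.asarray(slopes, float),
        np.atleast_1d(ages),
    )
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass(frozen=True)
class FittedOrdinalModel:
    """A fitted (or externally specified) stage-given-age model."""

    spec: ModelSpec
    scheme: StageScheme
    sex: str
    intercepts: tuple[float, ...]
    slopes: tuple[float, ...]
    log_likelihood: float = float("nan")
    n_params: int = 0
    aic: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        n_bound = self.scheme.n_stages - 1
        if len(self.intercepts) != n_bound:
            raise SchemaError(
                f"expected {n_bound} intercepts for {self.scheme.n_stages} stages"
            )
        n_slopes = 1 if self.spec.slope == "parallel" else n_bound
        if len(self.slopes) != n_slopes:
            raise SchemaError(f"expected {n_slopes} slope(s), got {len(self.slopes)}")

    @property
    def indicator(self) -> str:
        return self.scheme.indicator

    def stage_probabilities(self, ages) -> np.ndarray:
        return stage_probabilities(self.spec, self.intercepts, self.slopes, ages)


def model_from_coefficients(
    spec: ModelSpec,
    scheme: StageScheme,
    sex: str,
    intercepts: Sequence[float],
    slopes: Sequence[float],
) -> FittedOrdinalModel:
    """Build a model directly from coefficients (no data involved)."""
    return FittedOrdinalModel(
        spec, scheme, sex, tuple(float(a) for a in intercepts),
        tuple(float(b) for b in slopes),
    )


def stage_given_age(model: FittedOrdinalModel, age) -> np.ndarray:
    """Probability vector over stages at a given age (or matrix for an array)."""
    P = model.stage_probabilities(age)
    return P[0] if np.isscalar(age) else P


# ---------------------------------------------------------------------------
# Fitting


def _initial_params(
    spec: ModelSpec, y: np.ndarray, n_stages: int
) -> np.ndarray:
    """Moment-based start: intercepts from marginal boundary proportions
    (in standardised-age space), slopes at zero."""
    counts = np.bincount(y, minlength=n_stages).astype(float)
    n = counts.sum()
    if spec.family == "cumulative":
        cum = np.cumsum(counts)[:-1] / n
        alpha0 = _cdf_inv(spec.link, cum)
    else:
        remaining = n - np.concatenate([[0.0], np.cumsum(counts)[:-1]])
        hazard = counts[:-1] / np.maximum(remaining[:-1], 1.0)
        alpha0 = _cdf_inv(spec.link, hazard)
    n_slopes = 1 if spec.slope == "parallel" else n_stages - 1
    return np.concatenate([alpha0, np.zeros(n_slopes)])


def _nll_grad(params, spec, y, z, n_stages):
    """Negative log-likelihood and its analytic gradient.

    Cumulative models add a smooth quadratic penalty whenever a category
    probability at an observed age drops below ``_PENALTY_FLOOR`` (the
    continuation-ratio construction cannot go negative, so it needs none).
    """
    B = n_stages - 1
    alpha = params[:B]
    beta = params[B:]
    b = np.full(B, beta[0]) if beta.size == 1 else beta
    eta = alpha[None, :] + b[None, :] * z[:, None]  # (n, B)
    if spec.link == "logit":
        F = expit(eta)
        f = F * (1.0 - F)
    else:
        F = ndtr(eta)
        f = np.exp(-0.5 * eta**2) / np.sqrt(2.0 * np.pi)
    n = len(y)
    rows = np.arange(n)
    G = np.zeros((n, B))  # d(nll)/d(eta)
    if spec.family == "cumulative":
        Fpad = np.hstack([np.zeros((n, 1)), F, np.ones((n, 1))])
        P = np.diff(Fpad, axis=1)  # (n, J)
        p_obs = np.clip(P[rows, y], 1e-300, None)
        nll = -float(np.sum(np.log(p_obs)))
        m = y <= B - 1
        G[rows[m], y[m]] -= f[rows[m], y[m]] / p_obs[m]
        m = y >= 1
        G[rows[m], y[m] - 1] += f[rows[m], y[m] - 1] / p_obs[m]
        deficit = np.clip(_PENALTY_FLOOR - P, 0.0, None)
        nll += _PENALTY_WEIGHT * float(np.sum(deficit**2))
        G -= 2.0 * _PENALTY_WEIGHT * f * (deficit[:, :B] - deficit[:, 1:])
    else:
        logF = np.log(np.clip(F, 1e-300, None))
        log1mF = np.log(np.clip(1.0 - F, 1e-300, None))
        cum = np.hstack([np.zeros((n, 1)), np.cumsum(log1mF, axis=1)])
        ll = cum[rows, y].copy()
        m = y <= B - 1
        ll[m] += logF[rows[m], y[m]]
        nll = -float(np.sum(ll))
        ratio_in = f / np.clip(F, 1e-300, None)
        ratio_out = f / np.clip(1.0 - F, 1e-300, None)
        G[rows[m], y[m]] -= ratio_in[rows[m], y[m]]
        G += ratio_out * (np.arange(B)[None, :] < y[:, None])
    grad_alpha = G.sum(axis=0)
    if beta.size == 1:
        grad_beta = np.array([float(np.sum(G * z[:, None]))])
    else:
        grad_beta = (G * z[:, None]).sum(axis=0)
    return nll, np.concatenate([grad_alpha, grad_beta])


def _nll(params, spec, y, z, n_stages):
    return _nll_grad(params, spec, y, z, n_stages)[0]


def fit(
    spec: ModelSpec,
    pop: Population,
    scheme: StageScheme | None = None,
) -> FittedOrdinalModel:
    """Maximum-likelihood fit of an ordinal model to one population.

    Age is standardised internally for numerical conditioning and the
    coefficients mapped back to the age scale.  Raises :class:`FitError`
    when fewer than two stages are observed or no start converges; a fit
    whose slope hits the optimisation bounds (complete separation) is
    returned with a warning and capped coefficients.
    """
    scheme = scheme or DEFAULT_SCHEMES[pop.indicator]
    y = np.array([scheme.index(s) for s in pop.stages])
    if len(np.unique(y)) < 2:
        raise FitError(
            f"population has a single observed stage; the model is unidentifiable"
        )
    ages = pop.ages
    mu_a, sd_a = float(ages.mean()), float(ages.std())
    sd_a = sd_a if sd_a > 0 else 1.0
    z = (ages - mu_a) / sd_a
    J = scheme.n_stages
    n_bound = J - 1

    x0 = _initial_params(spec, y, J)
    nll0 = _nll(x0, spec, y, z, J)
    rng = np.random.default_rng(12345)
    best = None
    for attempt in range(4):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.5, size=len(x0))
        if spec.family == "cumulative":
            start[:n_bound] = np.sort(start[:n_bound])
        res = optimize.minimize(
            _nll_grad, start, args=(spec, y, z, J), method="L-BFGS-B", jac=True,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if (
            best is not None
            and best.fun <= nll0 + 1e-9
            and np.max(np.abs(best.jac)) < 1e-3
        ):
            break
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"{spec.label}: optimisation failed to converge")

    # complete separation drives standardised-age coefficients off to
    # saturation; cap them at a value far outside any identifiable fit
    cap = 200.0
    params = best.x
    if np.any(np.abs(params) > cap):
        warnings.warn(
            f"{spec.label}: runaway coefficients suggest complete "
            "separation; coefficients capped",
            RuntimeWarning,
            stacklevel=2,
        )
        params = np.clip(params, -cap, cap)
    alpha_z = params[:n_bound]
    beta_z = params[n_bound:]
    # map back from standardised age: eta = alpha_z + beta_z * (a - mu)/sd
    slopes = beta_z / sd_a
    if spec.slope == "parallel":
        intercepts = alpha_z - beta_z[0] * mu_a / sd_a
    else:
        intercepts = alpha_z - beta_z * mu_a / sd_a
    ll = -_nll(params, spec, y, z, J)
    k = len(params)
    return FittedOrdinalModel(
        spec=spec,
        scheme=scheme,
        sex=pop.sex,
        intercepts=tuple(float(a) for a in intercepts),
        slopes=tuple(float(b) for b in slopes),
        log_likelihood=float(ll),
        n_params=k,
        aic=float(2 * k - 2 * ll),
        converged=bool(best.success),
    )


def select_model(
    specs: Iterable[ModelSpec],
    ensemble: Sequence[Population],
    scheme: StageScheme | None = None,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Median-AIC model selection over an ensemble of populations.

    Every candidate is fitted to every population; per candidate the median
    AIC across the converged fits is computed and the specification with the
    lowest median wins.  The returned table records, per candidate, the
    median AIC and the number of populations where the fit failed.
    """
    specs = list(specs)
    if not specs or not ensemble:
        raise SchemaError("model selection needs at least one spec and one population")
    rows = []
    for spec in specs:
        aics = []
        n_failed = 0
        for pop in ensemble:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    aics.append(fit(spec, pop, scheme).aic)
            except FitError:
                n_failed += 1
        rows.append(
            {
                "family": spec.family,
                "link": spec.link,
                "slope": spec.slope,
                "median_aic": float(np.median(aics)) if aics else float("nan"),
                "n_failed": n_failed,
                "n_fitted": len(aics),
            }
        )
    table = pd.DataFrame(rows)
    if table["median_aic"].isna().all():
        raise FitError("all candidate specifications failed on every population")
    best_idx = int(table["median_aic"].idxmin())
    return specs[best_idx], table


# ---------------------------------------------------------------------------
# Serialisation


def save_model(model: FittedOrdinalModel, path: str | Path) -> None:
    """Write a fitted model to JSON so posteriors can be rebuilt without refitting."""
    doc = {
        "spec": {
            "family": model.spec.family,
            "link": model.spec.link,
            "slope": model.spec.slope,
        },
        "indicator": model.scheme.indicator,
        "stage_labels": list(model.scheme.stage_labels),
        "sex_specific": model.scheme.sex_specific,
        "sex": model.sex,
        "intercepts": list(model.intercepts),
        "slopes": list(model.slopes),
        "log_likelihood": model.log_likelihood,
        "n_params": model.n_params,
        "aic": model.aic,
        "converged": model.converged,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> FittedOrdinalModel:
    doc = json.loads(Path(path).read_text())
    return FittedOrdinalModel(
        spec=ModelSpec(**doc["spec"]),
        scheme=StageScheme(
            doc["indicator"], tuple(doc["stage_labels"]), doc.get("sex_specific", False)
        ),
        sex=doc["sex"],
        intercepts=tuple(doc["intercepts"]),
        slopes=tuple(doc["slopes"]),
        log_likelihood=float(doc.get("log_likelihood", float("nan"))),
        n_params=int(doc.get("n_params", 0)),
        aic=float(doc.get("aic", float("nan"))),
        converged=bool(doc.get("converged", True)),
    )
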