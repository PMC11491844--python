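"""Categorical-perception psychometrics.

Forced-choice responses along the morph continuum are modelled with the
logistic function

    p(x) = 1 / (1 + exp(-(x - mu) / s)),

where ``mu`` is the point of subjective equality (the morph percentage at
which either response is equally likely) and ``s`` sets the steepness. The
*slope* reported throughout is the steepness beta = 1/s, so that a
shallower psychometric curve (reduced discriminability) yields a smaller
slope. The behavioural integration index is the pre-training slope minus
the post-training slope: positive = integration.

Fits are penalized maximum likelihood (a weak ridge on beta stabilizes
near-separation); the post-training fit clamps mu to its pre-training value
and estimates the slope alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, minimize

from .synthetic_data import BehaviouralDataset, logistic_response_probability

SLOPE_BOUND = 10.0  # cap on beta under complete separation
RIDGE = 1e-6


@dataclass
class PsychometricModel:
    mu: float
    slope: float  # beta = 1/s
    loglik: float
    fixed_mu: bool
    separation_flag: bool
    converged: bool

    @property
    def s(self) -> float:
        """The scale parameterization s = 1/beta (inf for a flat curve)."""
        return np.inf if self.slope == 0 else 1.0 / self.slope

    def predict(self, x) -> np.ndarray:
        return logistic_response_probability(x, self.mu, self.slope)


@dataclass
class BehaviouralIntegration:
    """Pre/post slopes and their difference, per axis."""

    slope_s1: dict[str, float]
    slope_s5: dict[str, float]

    def index(self, axis: str) -> float:
        return self.slope_s1[axis] - self.slope_s5[axis]

    @property
    def contrast(self) -> float:
        return self.index("trained") - self.index("untrained")


def _aggregate(responses: "pd.DataFrame | BehaviouralDataset") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse trials to (morph level, successes, trials) triples.

    Fractional success counts are accepted, which lets noise-free expected
    data be fitted exactly.
    """
    if isinstance(responses, BehaviouralDataset):
        responses = responses.frame
    g = responses.groupby("morph")["response"]
    x = np.array(sorted(responses["morph"].unique()), dtype=float)
    k = g.sum().reindex(x).to_numpy(dtype=float)
    n = g.count().reindex(x).to_numpy(dtype=float)
    return x, k, n


def _is_separated(k: np.ndarray, n: np.ndarray) -> bool:
    """Complete separation: every morph level answered unanimously.

    The Bernoulli likelihood then has no interior optimum in the slope, so
    the fitted steepness is only meaningful up to its cap.
    """
    return bool(np.all((k == 0) | (k == n)))


def _nll(mu: float, beta: float, x: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    z = np.clip(beta * (x - mu), -500, 500)
    # log p = -log(1+e^-z); log(1-p) = -z - log(1+e^-z)
    log_p = -np.logaddexp(0.0, -z)
    log_q = -z + log_p
    return float(-(k * log_p + (n - k) * log_q).sum() + RIDGE * beta**2)


def fit_full(responses, mu_bounds: tuple[float, float] = (0.0, 100.0)) -> PsychometricModel:
    """Two-parameter (mu, slope) penalized maximum-likelihood fit.

    Requires responses at >= 2 distinct morph levels. Under complete
    separation the slope is capped at ``SLOPE_BOUND`` and flagged.
    """
    x, k, n = _aggregate(responses)
    if x.size < 2:
        raise ValueError("need responses at >= 2 distinct morph levels")

    def obj(theta):
        return _nll(theta[0], theta[1], x, k, n)

    best = None
    # multi-start over mu to avoid the shallow-likelihood plateau
    for mu0 in (35.0, 50.0, 65.0):
        res = minimize(
            obj,
            x0=np.array([mu0, 0.2]),
            method="L-BFGS-B",
            bounds=[mu_bounds, (-SLOPE_BOUND, SLOPE_BOUND)],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu_hat, beta_hat = float(best.x[0]), float(best.x[1])
    separation = abs(beta_hat) >= SLOPE_BOUND * (1 - 1e-9) or _is_separated(k, n)
    return PsychometricModel(
        mu=mu_hat,
        slope=beta_hat,
        loglik=-float(best.fun),
        fixed_mu=False,
        separation_flag=separation,
        converged=bool(best.success),
    )


def fit_slope_fixed_mu(responses, mu_fixed: float) -> PsychometricModel:
    """One-parameter slope fit with mu clamped (the post-training fit)."""
    if not np.isfinite(mu_fixed):
        raise ValueError("mu_fixed must be finite")
    x, k, n = _aggregate(responses)
    res = minimize_scalar(
        lambda b: _nll(mu_fixed, b, x, k, n),
        bounds=(-SLOPE_BOUND, SLOPE_BOUND),
        method="bounded",
        options={"xatol": 1e-10},
    )
    beta_hat = float(res.x)
    separation = abs(beta_hat) >= SLOPE_BOUND * (1 - 1e-6) or _is_separated(k, n)
    return PsychometricModel(
        mu=float(mu_fixed),
        slope=beta_hat,
        loglik=-float(res.fun),
        fixed_mu=True,
        separation_flag=separation,
        converged=bool(res.success),
    )


def behavioural_integration_index(
    model_s1: PsychometricModel, model_s5: PsychometricModel
) -> float:
    """Pre minus post slope; positive = integration (shallower curve)."""
    if not (model_s1.converged and model_s5.converged):
        raise ValueError("both fits must have converged")
    return model_s1.slope - model_s5.slope


def analyse_behaviour(dataset: BehaviouralDataset) -> tuple[BehaviouralIntegration, dict]:
    """Fit both axes and sessions; post-training mu fixed to pre-training.

    Returns the integration summary plus the fitted models keyed by
    (axis, session).
    """
    slope_s1, slope_s5, models = {}, {}, {}
    for axis in ("trained", "untrained"):
        m1 = fit_full(dataset.slice(axis, 1))
        m5 = fit_slope_fixed_mu(dataset.slice(axis, 5), mu_fixed=m1.mu)
        slope_s1[axis] = m1.slope
        slope_s5[axis] = m5.slope
        models[(axis, 1)] = m1
        models[(axis, 5)] = m5
    return BehaviouralIntegration(slope_s1=slope_s1, slope_s5=slope_s5), models
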