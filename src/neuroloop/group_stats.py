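"""Group-level nonparametric inference.

Effects are summarized across participants by bootstrap resampling: the
participant values are resampled with replacement (same n) many times, the
mean of each resample forms the sampling distribution, and the p-value is
the proportion of resample means whose sign opposes the observed mean. The
95% interval is the 2.5/97.5 percentile of the bootstrap distribution.
Brain-behaviour association uses the Pearson correlation, with an optional
participant-level bootstrap interval for r (an extension beyond the core
sign-based procedure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class BootstrapResult:
    observed_mean: float
    bootstrap_mean: float
    ci_lower: float
    ci_upper: float
    p_sign: float
    n_iterations: int
    seed: int


def bootstrap_mean(
    values: "np.ndarray | list[float]",
    n_iter: int = 1000,
    seed: int = 0,
    two_sided: bool = False,
) -> BootstrapResult:
    """Participant-level bootstrap of the mean with a sign-based p-value.

    ``p_sign`` is the fraction of bootstrap means with sign opposite to the
    observed mean (1.0 by convention for a zero observed mean). With
    ``two_sided=True`` the fraction is doubled and capped at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 participant values")
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(n_iter, n))
    boot_means = values[idx].mean(axis=1)
    observed = float(values.mean())
    if observed == 0:
        p_sign = 1.0
    else:
        p_sign = float(np.mean(np.sign(boot_means) == -np.sign(observed)))
        if two_sided:
            p_sign = min(1.0, 2.0 * p_sign)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return BootstrapResult(
        observed_mean=observed,
        bootstrap_mean=float(boot_means.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_sign=p_sign,
        n_iterations=n_iter,
        seed=seed,
    )


def pearson(x: "np.ndarray | list[float]", y: "np.ndarray | list[float]") -> float:
    """Product-moment correlation between two participant-level vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bootstrap_pearson(
    x: np.ndarray, y: np.ndarray, n_iter: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for r (resampling participant pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = pearson(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    rs = []
    for _ in range(n_iter):
        idx = rng.integers(0, n, size=n)
        xi, yi = x[idx], y[idx]
        if np.std(xi) == 0 or np.std(yi) == 0:
            continue
        rs.append(pearson(xi, yi))
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return r, float(lo), float(hi)
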