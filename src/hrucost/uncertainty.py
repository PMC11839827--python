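"""Confidence intervals for cohort mean costs.

Cost data are positive and right-skewed, so the primary interval is from an
intercept-only gamma GLM with log link: the maximum-likelihood fitted mean of
that model is exactly the arithmetic mean (score-equation property of the
log-link intercept model), and a Wald interval on the log scale is
exponentiated. Dispersion is the Pearson chi-square estimate on n-1 degrees
of freedom.

The gamma model has no mass at zero, but several cost components are
zero for most patients. Such vectors are routed to a seeded percentile
bootstrap of the mean instead; an opt-in epsilon-shift (add a small epsilon,
fit, subtract after back-transform) is provided for comparability with
all-gamma analyses.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["CIMethod", "MeanWithCI", "ZeroCostsError", "gamma_glm_mean_ci", "bootstrap_mean_ci", "mean_ci"]


class CIMethod(str, enum.Enum):
    GAMMA_GLM = "gamma_glm"
    BOOTSTRAP_PERCENTILE = "bootstrap_percentile"


class ZeroCostsError(ValueError):
    """Gamma GLM requested on data with zeros (unsupported without a policy)."""


@dataclass(frozen=True)
class MeanWithCI:
    mean: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: CIMethod = CIMethod.GAMMA_GLM

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not self.ci_low <= self.mean + 1e-12 or not self.mean <= self.ci_high + 1e-12:
            raise ValueError(
                f"interval [{self.ci_low}, {self.ci_high}] does not bracket mean {self.mean}"
            )


def gamma_glm_mean_ci(
    costs,
    level: float = 0.95,
    zero_policy: str = "error",
    epsilon: float = 0.01,
) -> MeanWithCI:
    """Mean and Wald CI from an intercept-only gamma GLM with log link.

    ``zero_policy``: ``"error"`` (default) raises :class:`ZeroCostsError` if
    any value is zero, directing the caller to :func:`bootstrap_mean_ci`;
    ``"epsilon_shift"`` adds ``epsilon`` to every value, fits, and subtracts
    ``epsilon`` from mean and bounds after back-transform.
    """
    y = np.asarray(costs, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need a 1-d vector of at least 2 cost values")
    if np.any(y < 0):
        raise ValueError("costs must be non-negative")
    shift = 0.0
    if np.any(y == 0):
        if zero_policy == "epsilon_shift":
            shift = epsilon
            y = y + epsilon
        else:
            raise ZeroCostsError(
                "gamma GLM cannot represent zero costs; use bootstrap_mean_ci "
                "or zero_policy='epsilon_shift'"
            )
    if np.all(y == y[0]):
        # zero dispersion: the Wald interval degenerates to the point
        c = float(y[0]) - shift
        return MeanWithCI(mean=c, ci_low=c, ci_high=c, level=level, method=CIMethod.GAMMA_GLM)
    with warnings.catch_warnings():
        # log is a non-canonical link for Gamma; statsmodels flags it although
        # it is the standard choice for cost models
        warnings.simplefilter("ignore")
        model = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Gamma(sm.families.links.Log()))
        try:
            res = model.fit(scale="X2")  # Pearson chi2 / (n - 1)
        except Exception as e:  # pragma: no cover - surfaced with context
            raise RuntimeError(f"gamma GLM failed to converge: {e}") from e
    b0 = float(res.params[0])
    se = float(res.bse[0])
    z = stats.norm.ppf(0.5 + level / 2)
    mean = float(np.exp(b0)) - shift
    lo = float(np.exp(b0 - z * se)) - shift
    hi = float(np.exp(b0 + z * se)) - shift
    return MeanWithCI(mean=mean, ci_low=lo, ci_high=hi, level=level, method=CIMethod.GAMMA_GLM)


def bootstrap_mean_ci(
    costs,
    reps: int = 2000,
    seed: int | None = 0,
    level: float = 0.95,
) -> MeanWithCI:
    """Seeded percentile-bootstrap CI of the mean (handles zero-heavy data)."""
    y = np.asarray(costs, dtype=float)
    if y.size == 0:
        raise ValueError("cannot bootstrap an empty cost vector")
    if reps < 200:
        raise ValueError(f"reps must be >= 200, got {reps}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, y.size, size=(reps, y.size))
    means = y[idx].mean(axis=1)
    alpha = 1 - level
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    m = float(y.mean())
    # guard against quantile grid straddling the mean on tiny/degenerate input
    return MeanWithCI(
        mean=m,
        ci_low=min(float(lo), m),
        ci_high=max(float(hi), m),
        level=level,
        method=CIMethod.BOOTSTRAP_PERCENTILE,
    )


def mean_ci(
    costs,
    level: float = 0.95,
    method: str = "auto",
    reps: int = 2000,
    seed: int | None = 0,
) -> MeanWithCI:
    """Dispatch: gamma GLM for strictly positive vectors, bootstrap otherwise.

    ``method`` may force ``"gamma_glm"`` (epsilon-shifting zeros) or
    ``"bootstrap_percentile"``; ``"auto"`` follows the routing policy.
    """
    y = np.asarray(costs, dtype=float)
    if method == "gamma_glm":
        return gamma_glm_mean_ci(y, level=level, zero_policy="epsilon_shift")
    if method == "bootstrap_percentile":
        return bootstrap_mean_ci(y, reps=reps, seed=seed, level=level)
    if method != "auto":
        raise ValueError(f"unknown CI method {method!r}")
    if y.size >= 2 and np.all(y > 0):
        return gamma_glm_mean_ci(y, level=level)
    return bootstrap_mean_ci(y, reps=reps, seed=seed, level=level)
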