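"""Psychometric function fitting for two-interval same/different data.

The discrimination probability is a lapse-bounded logistic in the shape
difference d = delta-rho:

    P(diff) = (1 - lapse) / (1 + exp((alpha - d) / beta))

``alpha`` is the bias (inflection point), ``beta`` the slope scale and
``lapse`` a stimulus-independent error rate bounding the upper asymptote at
1 - lapse (guess rate fixed at 0).  The threshold ``theta`` is the
delta-rho discriminated at a target rate (75% by default) and is obtained
by closed-form inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "PsychometricParams",
    "DiscriminationData",
    "PsychometricModel",
    "PsychometricResults",
    "psychometric_prob",
    "fit_psychometric",
    "threshold",
    "UnreachableTargetError",
    "DegenerateFitWarning",
    "LEVELS_DEFAULT",
]

#: delta-rho comparison intervals of the perceptual task
LEVELS_DEFAULT = (0.0, 0.05, 0.075, 0.1, 0.15)


class UnreachableTargetError(ValueError):
    """Target probability at or above the 1 - lapse asymptote."""


class DegenerateFitWarning(UserWarning):
    """Non-identifiable data: the ML estimate sits on a box boundary."""


@dataclass(frozen=True)
class PsychometricParams:
    alpha_bias: float
    beta_slope: float
    lapse: float = 0.0

    def __post_init__(self):
        if self.beta_slope <= 0:
            raise ValueError("beta_slope must be > 0")
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError("lapse outside [0, 1)")


@dataclass(frozen=True)
class DiscriminationData:
    """Aggregated same/different counts per delta-rho level."""

    levels: np.ndarray
    n_trials: np.ndarray
    n_different: np.ndarray

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        nt = np.asarray(self.n_trials, dtype=int)
        nd = np.asarray(self.n_different, dtype=int)
        if not (len(lv) == len(nt) == len(nd)):
            raise ValueError("levels/n_trials/n_different length mismatch")
        if np.any(lv < 0):
            raise ValueError("levels must be non-negative")
        if np.any(nd < 0) or np.any(nd > nt):
            raise ValueError("need 0 <= n_different <= n_trials")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "n_trials", nt)
        object.__setattr__(self, "n_different", nd)


def psychometric_prob(params: PsychometricParams, delta_rho) -> np.ndarray | float:
    """P(report 'different') at shape difference delta_rho."""
    d = np.asarray(delta_rho, dtype=float)
    p = (1.0 - params.lapse) * special.expit(
        (d - params.alpha_bias) / params.beta_slope
    )
    return float(p) if np.isscalar(delta_rho) else p


def threshold(params: PsychometricParams, target: float = 0.75) -> float:
    """Delta-rho discriminated at the target rate (closed-form inversion)."""
    if target >= 1.0 - params.lapse:
        raise UnreachableTargetError(
            f"target {target} >= upper asymptote {1.0 - params.lapse}"
        )
    if target <= 0:
        raise UnreachableTargetError("target must be positive")
    return params.alpha_bias - params.beta_slope * np.log(
        (1.0 - params.lapse) / target - 1.0
    )


class PsychometricModel:
    """Binomial ML fit of the lapse-bounded logistic.

    Parameters
    ----------
    data : DiscriminationData
    lapse_max : float
        Upper box constraint on the lapse rate (default 0.06).
    """

    def __init__(self, data: DiscriminationData, lapse_max: float = 0.06):
        if np.count_nonzero(data.n_trials > 0) < 3:
            raise ValueError("need >= 3 levels with trials")
        self.data = data
        self.lapse_max = float(lapse_max)

    def loglike(self, params: PsychometricParams) -> float:
        p = psychometric_prob(params, self.data.levels)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        k, n = self.data.n_different, self.data.n_trials
        return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    def _nll(self, x: np.ndarray) -> float:
        try:
            return -self.loglike(PsychometricParams(x[0], x[1], x[2]))
        except ValueError:
            return np.inf

    def fit(self, n_starts: int = 10, seed: int = 0) -> "PsychometricResults":
        rng = np.random.default_rng(seed)
        lo = np.array([-0.5, 1e-4, 0.0])
        hi = np.array([0.5, 1.0, self.lapse_max])
        best = None
        x0s = [np.array([0.05, 0.03, 0.01])]
        for _ in range(n_starts - 1):
            x0s.append(lo + rng.random(3) * (hi - lo))
        for x0 in x0s:
            res = optimize.minimize(
                self._nll, x0, method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
            )
            if best is None or res.fun < best.fun:
                best = res
        params = PsychometricParams(*best.x)
        # lapse = 0 is the expected interior-of-interest solution for clean
        # data; degeneracy is flagged on the location/slope box only
        at_boundary = bool(
            np.any(np.isclose(best.x[:2], lo[:2], atol=1e-6))
            or np.any(np.isclose(best.x[:2], hi[:2], atol=1e-6))
        )
        # saturated model for deviance (xlogy handles the 0 log 0 limits)
        k, n = self.data.n_different, self.data.n_trials
        phat = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        sat = float(np.sum(special.xlogy(k, phat)
                           + special.xlogy(n - k, 1.0 - phat)))
        ll = -best.fun
        if at_boundary:
            warnings.warn(
                "ML estimate lies on a parameter bound; data may be "
                "non-identifiable", DegenerateFitWarning, stacklevel=2,
            )
        return PsychometricResults(
            model=self, params=params, llf=ll,
            deviance=2.0 * (sat - ll), at_boundary=at_boundary,
        )


@dataclass(frozen=True)
class PsychometricResults:
    model: PsychometricModel
    params: PsychometricParams
    llf: float
    deviance: float
    at_boundary: bool

    def predict(self, delta_rho) -> np.ndarray | float:
        return psychometric_prob(self.params, delta_rho)

    def threshold(self, target: float = 0.75) -> float:
        return threshold(self.params, target)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Psychometric function fit (lapse-bounded logistic, binomial ML)",
            "---------------------------------------------------------------",
            f"alpha (bias)        {p.alpha_bias: .5f}",
            f"beta (slope scale)  {p.beta_slope: .5f}",
            f"lapse rate          {p.lapse: .5f}",
            f"log-likelihood      {self.llf: .3f}",
            f"deviance            {self.deviance: .3f}",
            f"theta (75% level)   {self.threshold(0.75): .5f}"
            if 0.75 < 1 - p.lapse else "theta (75% level)   unreachable",
        ]
        if self.at_boundary:
            lines.append("warning: estimate at parameter bound (degenerate)")
        return "\n".join(lines)


def fit_psychometric(data: DiscriminationData, lapse_max: float = 0.06,
                     **kwargs) -> PsychometricResults:
    """Functional wrapper around ``PsychometricModel(data, lapse_max).fit()``."""
    return PsychometricModel(data, lapse_max).fit(**kwargs)
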