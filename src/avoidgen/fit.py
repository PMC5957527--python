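"""Hierarchical empirical-Bayes fitting of the avoidance-learning models.

Each subject's free parameters are estimated in an unconstrained latent
space (logistic transform for unit-interval parameters, log for positive
ones, identity for the bias) by MAP optimization under a Gaussian prior,
with a Laplace approximation supplying the posterior covariance and an
approximate log model evidence (free energy)

    F = log p(y | theta*) + log p(theta*) - 1/2 log|H| + (d/2) log 2 pi

where H is the Hessian of the negative log joint at the mode.  Group
(mixed-effects) fitting alternates subject-level MAP fits with moment
matching of the prior to the population of posterior latents, so that
within-subject priors are iteratively matched to the inferred parent
distribution.  This MAP + Laplace scheme shares the asymptotics and the
diagnostics of full variational-Laplace inversion while remaining easy to
verify; absolute free-energy values are not comparable across toolboxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .models import (
    AgentParams,
    BehaviouralSession,
    ModelSpec,
    log_likelihood,
)

__all__ = [
    "PriorSpec",
    "SubjectPosterior",
    "GroupFit",
    "AvoidanceLearningModel",
    "HierarchicalAvoidanceModel",
    "transform_params",
    "inverse_transform_params",
    "predictive_accuracy",
    "bayes_p_random",
    "FitDivergenceError",
]

_LOG2PI = np.log(2.0 * np.pi)
_EXPIT_EPS = 1e-15


class FitDivergenceError(RuntimeError):
    """Summed free energy dropped persistently across prior refinements."""


# ---------------------------------------------------------------------------
# latent-space transforms
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "kappa": "logistic",
    "eta": "logistic",
    "beta_choice": "log",
    "bias": "identity",
    "sigma_a": "log",
    "sigma_n": "log",
}


def _fwd(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return np.clip(special.expit(x), _EXPIT_EPS, 1.0 - _EXPIT_EPS)
    if kind == "log":
        # clamp so that downstream squares of tiny widths stay nonzero
        return np.exp(np.clip(x, -150, 150))
    return x


def _inv(y: np.ndarray, kind: str):
    if kind == "logistic":
        if np.any(y <= 0) or np.any(y >= 1):
            raise ValueError("logistic inverse requires values in (0, 1)")
        return special.logit(y)
    if kind == "log":
        if np.any(y <= 0):
            raise ValueError("log inverse requires positive values")
        return np.log(y)
    return y


def _dfwd(x: np.ndarray, kind: str) -> np.ndarray:
    """Derivative of the forward transform (delta-method variances)."""
    if kind == "logistic":
        p = special.expit(x)
        return p * (1.0 - p)
    if kind == "log":
        return np.exp(np.clip(x, -150, 150))
    return np.ones_like(np.asarray(x, dtype=float))


def transform_params(latent: np.ndarray, spec: ModelSpec) -> AgentParams:
    """Map an unconstrained latent vector to native-space parameters."""
    latent = np.asarray(latent, dtype=float)
    names = spec.free_parameter_names
    if latent.shape != (len(names),):
        raise ValueError(f"latent vector must have length {len(names)}")
    vals = np.array(
        [float(_fwd(latent[k], _TRANSFORMS[n])) for k, n in enumerate(names)]
    )
    return AgentParams.from_vector(vals, spec)


def inverse_transform_params(params: AgentParams, spec: ModelSpec) -> np.ndarray:
    """Native-space parameters back to the latent scale (round-trips)."""
    vec = params.to_vector(spec)
    return np.array(
        [float(_inv(vec[k], _TRANSFORMS[n]))
         for k, n in enumerate(spec.free_parameter_names)]
    )


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors on the latent parameters."""

    names: tuple[str, ...]
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.means, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        if m.shape != (len(self.names),) or v.shape != (len(self.names),):
            raise ValueError("prior moment shapes do not match names")
        if np.any(v <= 0):
            raise ValueError("prior variances must be > 0")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "variances", v)

    @classmethod
    def default(cls, spec: ModelSpec, mean: float = 0.0,
                variance: float = 3.0) -> "PriorSpec":
        d = spec.n_params
        return cls(spec.free_parameter_names,
                   np.full(d, mean), np.full(d, variance))

    def logpdf(self, latent: np.ndarray) -> float:
        z = (latent - self.means) ** 2 / self.variances
        return float(-0.5 * np.sum(z + np.log(self.variances) + _LOG2PI))

    @property
    def transforms(self) -> tuple[str, ...]:
        return tuple(_TRANSFORMS[n] for n in self.names)


@dataclass(frozen=True)
class SubjectPosterior:
    """Laplace posterior for one subject under one model."""

    spec: ModelSpec
    latent_mean: np.ndarray
    latent_cov: np.ndarray
    free_energy: float
    llf: float
    params: AgentParams
    param_variances: dict[str, float]
    hessian_regularized: bool = False
    subject_id: str = "sub-01"

    @property
    def param_means(self) -> dict[str, float]:
        vec = self.params.to_vector(self.spec)
        return dict(zip(self.spec.free_parameter_names, vec))

    def precision(self, name: str) -> float:
        """1 / posterior variance of a native-space parameter."""
        return 1.0 / self.param_variances[name]

    def summary(self) -> str:
        lines = [
            f"Subject {self.subject_id}  model={self.spec.variant.value}",
            f"  free energy F = {self.free_energy:.3f}   "
            f"log-lik = {self.llf:.3f}",
            f"  {'param':<12}{'estimate':>12}{'post. sd':>12}",
        ]
        for n, v in self.param_means.items():
            sd = np.sqrt(self.param_variances[n])
            lines.append(f"  {n:<12}{v:>12.4f}{sd:>12.4f}")
        if self.hessian_regularized:
            lines.append("  note: Hessian ridge-regularized to PD")
        return "\n".join(lines)


class AvoidanceLearningModel:
    """MAP + Laplace fit of one avoidance-learning model to one session.

    statsmodels-style: construct from data, call :meth:`fit`.
    """

    def __init__(self, session: BehaviouralSession, spec: ModelSpec,
                 prior: PriorSpec | None = None):
        if len(session) < 1:
            raise ValueError("session must contain at least one trial")
        self.session = session
        self.spec = spec
        self.prior = prior or PriorSpec.default(spec)
        # static kernel arguments, cached once per model instance
        from . import _kernels
        from .models import _VARIANT_CODE, _design_arrays

        design = session.design
        rho, is_gs, adj = _design_arrays(design)
        self._kernel = _kernels.loglik_only
        self._static = (
            session.sequence.stimulus, session.avoided.astype(np.int64),
            session.outcome.astype(np.int64), rho, is_gs, adj,
            spec.confusion_per_trial(len(session)),
        )
        self._cost = design.avoid_cost
        self._vcode = _VARIANT_CODE[spec.variant]
        self._kinds = tuple(_TRANSFORMS[n] for n in spec.free_parameter_names)

    # objective on the latent scale (hot path: no dataclass construction)
    def _neg_log_joint(self, latent: np.ndarray) -> float:
        v = [float(_fwd(latent[k], kind))
             for k, kind in enumerate(self._kinds)]
        kappa, eta, beta, bias = v[:4]
        sigma_a = v[4] if len(v) > 4 else 1.0
        sigma_n = v[5] if len(v) > 5 else sigma_a
        ll = self._kernel(*self._static, kappa, eta, beta, bias,
                          self._cost, sigma_a, sigma_n, self._vcode,
                          self.spec.alpha0)
        val = -(ll + self.prior.logpdf(latent))
        # value recursion can diverge in extreme corners of the latent
        # space (spread overshoot feeds the associability); steer the
        # optimizer away instead of propagating non-finite numbers
        return val if np.isfinite(val) else 1e10

    def loglike(self, params: AgentParams) -> float:
        return log_likelihood(params, self.spec, self.session,
                              with_trace=False)

    def _hessian(self, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
        d = len(x)
        f = self._neg_log_joint
        H = np.empty((d, d))
        f0 = f(x)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h
            H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d)
                ej = np.zeros(d)
                ei[i] = h
                ej[j] = h
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h**2)
        return H

    def fit(self, n_starts: int = 8, seed: int = 0,
            extra_starts: np.ndarray | None = None) -> SubjectPosterior:
        """Multistart MAP optimization with Laplace evidence.

        ``extra_starts`` (k x d) are tried in addition to the prior mean
        and seeded prior draws (warm starts during group iteration).
        """
        rng = np.random.default_rng(seed)
        d = self.spec.n_params
        sd = np.sqrt(self.prior.variances)
        starts = [self.prior.means.copy()]
        if extra_starts is not None:
            starts.extend(np.atleast_2d(extra_starts))
        # deterministic offsets along the generalization-width latents:
        # the joint is prone to local optima in the sigma directions
        # (narrow-width and wide-width regimes both fit moderately well)
        for k, name in enumerate(self.spec.free_parameter_names):
            if name.startswith("sigma") and len(starts) < n_starts:
                for off in (-1.5, 1.5):
                    x = self.prior.means.copy()
                    x[k] += off * max(sd[k], 0.5)
                    starts.append(x)
        while len(starts) < max(n_starts, 1):
            starts.append(self.prior.means + rng.standard_normal(d) * sd)
        best = None
        # generous box: keeps the optimizer out of the numerically flat
        # far tails (|latent| 10 spans e.g. sigma from 5e-5 to 2e4)
        box = [(-10.0, 10.0)] * d
        for x0 in starts:
            res = optimize.minimize(self._neg_log_joint,
                                    np.clip(x0, -9.5, 9.5),
                                    method="L-BFGS-B", bounds=box)
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("no optimizer run reached a finite optimum")
        x = best.x
        H = self._hessian(x)
        H = 0.5 * (H + H.T)
        regularized = False
        eig = np.linalg.eigvalsh(H)
        if eig[0] <= 1e-8:
            H = H + (1e-6 - min(eig[0], 0.0)) * np.eye(d)
            regularized = True
        sign, logdet = np.linalg.slogdet(H)
        cov = np.linalg.inv(H)
        params = transform_params(x, self.spec)
        lp = self.prior.logpdf(x)
        llf = -best.fun - lp
        F = llf + lp - 0.5 * logdet + 0.5 * d * _LOG2PI
        grad = np.array(
            [float(_dfwd(x[k], _TRANSFORMS[n]))
             for k, n in enumerate(self.spec.free_parameter_names)]
        )
        pvar = dict(zip(self.spec.free_parameter_names,
                        np.diag(cov) * grad**2))
        return SubjectPosterior(
            spec=self.spec, latent_mean=x, latent_cov=cov,
            free_energy=float(F), llf=float(llf), params=params,
            param_variances=pvar, hessian_regularized=regularized,
            subject_id=self.session.subject_id,
        )


@dataclass
class GroupFit:
    """Results of the mixed-effects (empirical-Bayes) group fit."""

    spec: ModelSpec
    posteriors: list[SubjectPosterior]
    prior: PriorSpec
    free_energy_log: list[float] = field(default_factory=list)

    @property
    def free_energy(self) -> float:
        return self.free_energy_log[-1]

    def evidences(self) -> np.ndarray:
        return np.array([p.free_energy for p in self.posteriors])

    def param_table(self) -> dict[str, np.ndarray]:
        names = self.spec.free_parameter_names
        return {
            n: np.array([p.param_means[n] for p in self.posteriors])
            for n in names
        }

    def summary(self) -> str:
        tab = self.param_table()
        lines = [
            f"Hierarchical fit  model={self.spec.variant.value}  "
            f"n={len(self.posteriors)} subjects  "
            f"iterations={len(self.free_energy_log)}",
            f"  summed free energy = {self.free_energy:.3f}",
            f"  {'param':<12}{'group mean':>12}{'group sd':>12}",
        ]
        for n, v in tab.items():
            lines.append(f"  {n:<12}{np.mean(v):>12.4f}{np.std(v, ddof=1) if len(v) > 1 else 0.0:>12.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.spec.variant.value,
                "free_energy_log": self.free_energy_log,
                "prior": {
                    "names": list(self.prior.names),
                    "means": self.prior.means.tolist(),
                    "variances": self.prior.variances.tolist(),
                },
                "subjects": [
                    {
                        "subject_id": p.subject_id,
                        "free_energy": p.free_energy,
                        "llf": p.llf,
                        "params": {k: float(v)
                                   for k, v in p.param_means.items()},
                        "param_variances": {k: float(v)
                                            for k, v in
                                            p.param_variances.items()},
                        "latent_mean": p.latent_mean.tolist(),
                    }
                    for p in self.posteriors
                ],
            },
            indent=2,
        )


class HierarchicalAvoidanceModel:
    """Mixed-effects fit of one model variant to a cohort of sessions.

    Alternates subject-level MAP fits with a moment-matching update of the
    group prior (empirical mean of posterior latents; empirical variance
    plus mean posterior variance) until the summed free energy stabilizes.
    """

    def __init__(self, sessions: list[BehaviouralSession], spec: ModelSpec,
                 init_prior: PriorSpec | None = None):
        if len(sessions) < 2:
            raise ValueError("group fit needs >= 2 subjects")
        self.sessions = sessions
        self.spec = spec
        self.init_prior = init_prior or PriorSpec.default(spec)

    def fit(self, tol: float = 0.01, max_iter: int = 32, n_starts: int = 8,
            n_starts_refine: int = 2, seed: int = 0,
            var_floor: float = 1e-4, divergence_tol: float = 1.0,
            verbose: bool = False) -> GroupFit:
        prior = self.init_prior
        used_prior = prior
        log: list[float] = []
        posteriors: list[SubjectPosterior] = []
        n_drops = 0
        for it in range(max_iter):
            used_prior = prior
            new_posts = []
            for k, sess in enumerate(self.sessions):
                extra = (posteriors[k].latent_mean[None, :]
                         if posteriors else None)
                m = AvoidanceLearningModel(sess, self.spec, prior)
                new_posts.append(
                    m.fit(
                        n_starts=n_starts if it == 0 else n_starts_refine,
                        seed=seed + 1000 * it + k,
                        extra_starts=extra,
                    )
                )
            posteriors = new_posts
            F = float(sum(p.free_energy for p in posteriors))
            if verbose:
                print(f"  iter {it + 1}: summed F = {F:.3f}")
            if log:
                delta = F - log[-1]
                # moment matching is not an ascent scheme: sub-nat jitter
                # near the fixed point is benign; only persistent large
                # drops signal genuine divergence
                n_drops = n_drops + 1 if delta < -divergence_tol else 0
                if n_drops >= 3:
                    raise FitDivergenceError(
                        f"summed free energy fell by more than "
                        f"{divergence_tol} for 3 consecutive refinements "
                        f"(last change {delta:.4f})"
                    )
                log.append(F)
                if abs(delta) < tol:
                    break
            else:
                log.append(F)
            # an infinite tolerance is satisfied by any conceivable change:
            # stop after the first round of independent fits
            if not np.isfinite(tol):
                break
            lat = np.stack([p.latent_mean for p in posteriors])
            pv = np.stack([np.diag(p.latent_cov) for p in posteriors])
            var = (lat.var(axis=0, ddof=1) if len(lat) > 1
                   else np.ones(lat.shape[1])) + pv.mean(axis=0)
            # refinement may only sharpen the weakly-informative init
            # prior: an uncapped moment update can diverge when a
            # parameter direction is unidentified for part of the cohort
            # (flat likelihood -> posterior variance echoes prior
            # variance -> runaway feedback)
            var = np.minimum(var, self.init_prior.variances)
            prior = PriorSpec(prior.names, lat.mean(axis=0),
                              np.maximum(var, var_floor))
        return GroupFit(spec=self.spec, posteriors=posteriors,
                        prior=used_prior, free_energy_log=log)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def predictive_accuracy(posterior: SubjectPosterior,
                        session: BehaviouralSession,
                        spec: ModelSpec | None = None) -> float:
    """Fraction of choices classified correctly at posterior-mean parameters.

    For binary data this equals the predictive r-squared quoted for such
    models.  A predicted P(avoid) of exactly 0.5 counts as incorrect.
    """
    spec = spec or posterior.spec
    _, trace = log_likelihood(posterior.params, spec, session)
    a = session.avoided == 1
    correct = ((trace.p_avoid > 0.5) & a) | ((trace.p_avoid < 0.5) & ~a)
    return float(np.mean(correct))


def bayes_p_random(posterior: SubjectPosterior, n_trials: int) -> float:
    """Posterior probability of the null model of random (p=0.5) choice.

    Compares the subject's free energy with the exact evidence of the
    coin-flip model, n * log(1/2), under equal model priors.
    """
    f_null = n_trials * np.log(0.5)
    diff = np.clip(posterior.free_energy - f_null, -700, 700)
    return float(1.0 / (1.0 + np.exp(diff)))
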