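"""Generative models of instrumental avoidance learning.

Three nested model variants, all modified Q-learners with a Pearce-Hall
trial-varying learning rate (associability):

``PERCEPTUAL_ONLY``
    Stimuli are independent states; generalization arises solely from a
    fixed probability of perceptually confusing a GS with its adjacent CS+
    at evaluation time (25% for stimuli titrated to 75% discriminability).
``VALUE_1WIDTH``
    Adds Gaussian spreading of value updates across the perceptual axis
    with one free width ``sigma``.
``VALUE_2WIDTH``
    Separate spread widths after aversive (``sigma_a``) and neutral
    (``sigma_n``) outcomes.

Update rules (outcome R coded 0 = safe, -1 = shock/loss; V(avoid) pinned
at 0 because avoidance deterministically prevents the outcome):

    V[s]   <- V[s] + kappa * alpha_t * (R - V[s])
    alpha  <- eta * |R - V[s]| + (1 - eta) * alpha
    G[j]   =  exp(-(rho_i - rho_j)^2 / (2 sigma^2))     (spread weights)
    V[j]   <- V[j] + kappa * alpha_t * (R - V[i]) * G[j]
    P(avoid) = 1 / (1 + exp(-beta * (0 - V_eff - cost - bias)))

On avoided trials the outcome is never delivered, so the prediction error
is zero by construction and only the associability decays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from . import _kernels
from .stimuli import Role, Stimulus, TaskDesign, TrialSequence

__all__ = [
    "Variant",
    "ConfusionSchedule",
    "ModelSpec",
    "AgentParams",
    "LearnerState",
    "BehaviouralSession",
    "LatentTrace",
    "gaussian_weights",
    "effective_nonavoid_value",
    "p_avoid",
    "step",
    "log_likelihood",
    "simulate_agent",
]


class Variant(str, Enum):
    PERCEPTUAL_ONLY = "PERCEPTUAL_ONLY"
    VALUE_1WIDTH = "VALUE_1WIDTH"
    VALUE_2WIDTH = "VALUE_2WIDTH"


_VARIANT_CODE = {
    Variant.PERCEPTUAL_ONLY: _kernels.PERCEPTUAL_ONLY,
    Variant.VALUE_1WIDTH: _kernels.VALUE_1WIDTH,
    Variant.VALUE_2WIDTH: _kernels.VALUE_2WIDTH,
}


class ConfusionSchedule(str, Enum):
    CONSTANT = "CONSTANT"
    LINEAR = "LINEAR"


@dataclass(frozen=True)
class ModelSpec:
    """Model variant plus the GS perceptual-confusion schedule."""

    variant: Variant = Variant.VALUE_2WIDTH
    confusion_schedule: ConfusionSchedule = ConfusionSchedule.CONSTANT
    p_confuse: float = 0.25
    #: end point of the LINEAR schedule (start point is ``p_confuse``)
    p_confuse_end: float | None = None
    alpha0: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "variant", Variant(self.variant))
        object.__setattr__(self, "confusion_schedule",
                           ConfusionSchedule(self.confusion_schedule))
        if not 0.0 <= self.p_confuse <= 1.0:
            raise ValueError("p_confuse outside [0, 1]")
        if self.confusion_schedule is ConfusionSchedule.LINEAR:
            if self.p_confuse_end is None:
                raise ValueError("LINEAR schedule requires p_confuse_end")
            if not 0.0 <= self.p_confuse_end <= 1.0:
                raise ValueError("p_confuse_end outside [0, 1]")

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        base = ("kappa", "eta", "beta_choice", "bias")
        if self.variant is Variant.PERCEPTUAL_ONLY:
            return base
        if self.variant is Variant.VALUE_1WIDTH:
            return base + ("sigma_a",)
        return base + ("sigma_a", "sigma_n")

    @property
    def n_params(self) -> int:
        return len(self.free_parameter_names)

    def confusion_per_trial(self, n_trials: int) -> np.ndarray:
        if self.confusion_schedule is ConfusionSchedule.CONSTANT:
            return np.full(n_trials, self.p_confuse)
        return np.linspace(self.p_confuse, self.p_confuse_end, n_trials)


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of one agent.

    kappa, eta in (0,1): learning-rate scale and associability weight;
    beta_choice > 0: softmax sensitivity; bias: decision offset, positive
    values work against avoiding; sigma_a / sigma_n > 0: Gaussian
    generalization widths (rho units) after aversive / neutral outcomes.
    """

    kappa: float
    eta: float
    beta_choice: float
    bias: float
    sigma_a: float | None = None
    sigma_n: float | None = None

    def __post_init__(self):
        if not 0.0 < self.kappa < 1.0:
            raise ValueError("kappa outside (0, 1)")
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta outside (0, 1)")
        if self.beta_choice < 0:
            raise ValueError("beta_choice must be >= 0")
        for name in ("sigma_a", "sigma_n"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        vals = []
        for name in spec.free_parameter_names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"{spec.variant.value} requires {name}")
            vals.append(v)
        return np.array(vals, dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, spec: ModelSpec) -> "AgentParams":
        d = dict(zip(spec.free_parameter_names, np.asarray(vec, dtype=float)))
        if spec.variant is Variant.VALUE_1WIDTH:
            d["sigma_n"] = d["sigma_a"]
        return cls(**d)

    def _sigmas(self, spec: ModelSpec) -> tuple[float, float]:
        sa = self.sigma_a if self.sigma_a is not None else 1.0
        if spec.variant is Variant.VALUE_1WIDTH:
            return sa, sa
        sn = self.sigma_n if self.sigma_n is not None else 1.0
        return sa, sn


@dataclass
class LearnerState:
    """Mutable learner state: not-avoid values and global associability."""

    values: np.ndarray
    associability: float
    trial_index: int = 0

    @classmethod
    def initial(cls, design: TaskDesign, alpha0: float = 1.0) -> "LearnerState":
        return cls(values=np.zeros(len(design.stimuli)), associability=alpha0)


@dataclass(frozen=True)
class BehaviouralSession:
    """One subject's choices and realized outcomes over a trial sequence."""

    sequence: TrialSequence
    avoided: np.ndarray   # (n,) 0/1
    outcome: np.ndarray   # (n,) 0 or -1; forced 0 when avoided
    subject_id: str = "sub-01"

    def __post_init__(self):
        n = len(self.sequence)
        if len(self.avoided) != n or len(self.outcome) != n:
            raise ValueError("choices/outcomes length mismatch with sequence")
        if np.any((self.avoided == 1) & (self.outcome != 0)):
            raise ValueError("avoided trials must carry a neutral outcome")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def design(self) -> TaskDesign:
        return self.sequence.design

    def to_frame(self) -> pd.DataFrame:
        df = self.sequence.to_frame(self.subject_id)
        df["avoided"] = self.avoided
        df["outcome"] = self.outcome
        return df.drop(columns="scheduled_outcome")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, design: TaskDesign,
                   seed: int = -1) -> "BehaviouralSession":
        df = df.sort_values("trial")
        stim = np.array([design.index(s) for s in df["stimulus"]])
        seq = TrialSequence(
            design=design,
            block=df["block"].to_numpy() - 1,
            stimulus=stim,
            scheduled_outcome=df["outcome"].to_numpy(),
            seed=seed,
        )
        sid = str(df["subject_id"].iloc[0]) if "subject_id" in df else "sub-01"
        return cls(
            sequence=seq,
            avoided=df["avoided"].to_numpy().astype(np.int64),
            outcome=df["outcome"].to_numpy().astype(np.int64),
            subject_id=sid,
        )


@dataclass(frozen=True)
class LatentTrace:
    """Per-trial latent quantities (regressor export for imaging models)."""

    effective_value: np.ndarray
    p_avoid: np.ndarray
    prediction_error: np.ndarray
    associability: np.ndarray
    spread_weights: np.ndarray  # (n, S)

    @property
    def p_shock(self) -> np.ndarray:
        """Predicted outcome probability: not-avoid value times -1."""
        return -self.effective_value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self.p_avoid) + 1),
                "p_shock": self.p_shock,
                "p_avoid": self.p_avoid,
                "pe": self.prediction_error,
                "alpha": self.associability,
            }
        )


# ---------------------------------------------------------------------------
# single-trial reference functions
# ---------------------------------------------------------------------------

def gaussian_weights(rho_presented: float, rho_all: np.ndarray,
                     sigma: float) -> np.ndarray:
    """Gaussian generalization weights G_j = exp(-(rho_i-rho_j)^2/(2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rho_all = np.asarray(rho_all, dtype=float)
    return np.exp(-((rho_presented - rho_all) ** 2) / (2.0 * sigma**2))


def effective_nonavoid_value(state: LearnerState, stimulus: Stimulus,
                             design: TaskDesign,
                             confusion_prob: float = 0.25) -> float:
    """Value of not avoiding, mixing in the adjacent CS+ value for a GS."""
    v_own = float(state.values[design.index(stimulus.label)])
    if stimulus.role is not Role.GS:
        return v_own
    if not stimulus.adjacent_cs_plus:
        raise ValueError(f"GS {stimulus.label!r} lacks an adjacency link")
    v_adj = float(state.values[design.index(stimulus.adjacent_cs_plus)])
    return (1.0 - confusion_prob) * v_own + confusion_prob * v_adj


def p_avoid(effective_value: float, beta_choice: float, bias: float,
            avoid_cost: float = 0.2) -> float:
    """Softmax probability of avoiding given the effective not-avoid value.

    V(avoid) is 0, so the decision variable is 0 - V_eff - cost - bias.
    """
    if beta_choice < 0:
        raise ValueError("beta_choice must be >= 0")
    z = -beta_choice * (0.0 - effective_value - avoid_cost - bias)
    return 1.0 / (1.0 + math.exp(z)) if abs(z) < 700 else (0.0 if z > 0 else 1.0)


def step(state: LearnerState, stimulus: Stimulus, avoided: bool, reward: int,
         params: AgentParams, spec: ModelSpec, design: TaskDesign) -> tuple[
             LearnerState, dict]:
    """Advance the learner by one trial; returns (new state, trace record).

    On avoided trials the prediction error is zero by construction: values
    are untouched and the associability decays by (1 - eta).
    """
    if stimulus.label not in design.labels:
        raise ValueError(f"unknown stimulus {stimulus.label!r}")
    i = design.index(stimulus.label)
    V = state.values.copy()
    alpha = state.associability
    if avoided:
        pe = 0.0
        alpha_next = (1.0 - params.eta) * alpha
        G = np.zeros(len(V))
    else:
        pe = reward - V[i]
        upd = params.kappa * alpha * pe
        if spec.variant is Variant.PERCEPTUAL_ONLY:
            G = np.zeros(len(V))
            G[i] = 1.0
        else:
            sa, sn = params._sigmas(spec)
            sigma = sa if reward == -1 else sn
            G = gaussian_weights(design.stimuli[i].rho, design.rho, sigma)
        V = V + upd * G
        alpha_next = params.eta * abs(pe) + (1.0 - params.eta) * alpha
    record = {"pe": pe, "alpha": alpha, "spread_weights": G}
    return (
        LearnerState(values=V, associability=alpha_next,
                     trial_index=state.trial_index + 1),
        record,
    )


# ---------------------------------------------------------------------------
# session-level likelihood and simulation
# ---------------------------------------------------------------------------

def _design_arrays(design: TaskDesign):
    S = len(design.stimuli)
    is_gs = np.zeros(S, dtype=np.int64)
    adj = np.full(S, -1, dtype=np.int64)
    for i, s in enumerate(design.stimuli):
        if s.role is Role.GS:
            is_gs[i] = 1
            adj[i] = design.index(s.adjacent_cs_plus)
    return design.rho, is_gs, adj


def log_likelihood(params: AgentParams, spec: ModelSpec,
                   session: BehaviouralSession,
                   design: TaskDesign | None = None,
                   with_trace: bool = True):
    """Bernoulli log-likelihood of the observed choices under the model.

    Returns ``(ll, LatentTrace)`` (or just ``ll`` if ``with_trace`` is
    False).  The trace exposes per-trial predicted P(shock) and PE for
    regressor export.
    """
    design = design or session.design
    rho, is_gs, adj = _design_arrays(design)
    pc = spec.confusion_per_trial(len(session))
    sa, sn = params._sigmas(spec)
    args = (
        session.sequence.stimulus, session.avoided.astype(np.int64),
        session.outcome.astype(np.int64), rho, is_gs, adj, pc,
        params.kappa, params.eta, params.beta_choice, params.bias,
        design.avoid_cost, sa, sn, _VARIANT_CODE[spec.variant], spec.alpha0,
    )
    if not with_trace:
        return _kernels.loglik_only(*args)
    ll, v_eff, p_av, pe, alpha_tr, G_tr = _kernels.run_learner(*args)
    trace = LatentTrace(
        effective_value=v_eff, p_avoid=p_av, prediction_error=pe,
        associability=alpha_tr, spread_weights=G_tr,
    )
    return ll, trace


def simulate_agent(params: AgentParams, spec: ModelSpec,
                   sequence: TrialSequence, seed: int,
                   subject_id: str = "sub-01") -> tuple[
                       BehaviouralSession, LatentTrace]:
    """Generate choices from the model on a given trial sequence.

    Choices are Bernoulli draws from P(avoid); the scheduled outcome is
    delivered only when the agent does not avoid.  Reproducible from seed.
    """
    rng = np.random.default_rng(seed)
    design = sequence.design
    state = LearnerState.initial(design, spec.alpha0)
    pc = spec.confusion_per_trial(len(sequence))
    n = len(sequence)
    avoided = np.zeros(n, dtype=np.int64)
    outcome = np.zeros(n, dtype=np.int64)
    v_eff = np.zeros(n)
    p_av = np.zeros(n)
    pe = np.zeros(n)
    alpha_tr = np.zeros(n)
    G_tr = np.zeros((n, len(design.stimuli)))
    for t in range(n):
        stim = design.stimuli[sequence.stimulus[t]]
        v = effective_nonavoid_value(state, stim, design, pc[t])
        p = p_avoid(v, params.beta_choice, params.bias, design.avoid_cost)
        a = rng.random() < p
        r = 0 if a else int(sequence.scheduled_outcome[t])
        avoided[t] = int(a)
        outcome[t] = r
        v_eff[t] = v
        p_av[t] = p
        alpha_tr[t] = state.associability
        state, rec = step(state, stim, a, r, params, spec, design)
        pe[t] = rec["pe"]
        G_tr[t] = rec["spread_weights"]
    session = BehaviouralSession(
        sequence=sequence, avoided=avoided, outcome=outcome,
        subject_id=subject_id,
    )
    trace = LatentTrace(
        effective_value=v_eff, p_avoid=p_av, prediction_error=pe,
        associability=alpha_tr, spread_weights=G_tr,
    )
    return session, trace
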