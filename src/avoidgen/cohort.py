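"""Synthetic cohorts with the statistical structure the analysis assumes.

Stands in for deposited human data: samples agents from a group
distribution over latent parameters, simulates their avoidance sessions
and same/different discrimination data, plants a known association between
aversive generalization width (sigma_a) and a symptom score, and generates
pattern datasets with optional representational drift.  Every component
derives deterministically from one master seed.

Default group means echo the magnitudes reported for human cohorts
(kappa 0.5, eta 0.3, beta 5, bias 0.4, sigma_a 0.75, sigma_n 0.03); they
are generator settings, not reproduced results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import _TRANSFORMS, _inv, transform_params
from .models import (
    AgentParams,
    BehaviouralSession,
    LatentTrace,
    ModelSpec,
    simulate_agent,
)
from .psychometrics import (
    LEVELS_DEFAULT,
    DiscriminationData,
    PsychometricParams,
    psychometric_prob,
)
from .stimuli import TaskDesign, amt_design, build_design, generate_sequence
from .ldc import PatternDataset

__all__ = [
    "CohortSpec",
    "SyntheticStudy",
    "sample_cohort_params",
    "generate_study",
    "generate_patterns",
    "simulate_discrimination",
    "GROUP_MEANS_DEFAULT",
]

#: native-scale group means used unless overridden
GROUP_MEANS_DEFAULT = {
    "kappa": 0.5,
    "eta": 0.3,
    "beta_choice": 5.0,
    "bias": 0.4,
    "sigma_a": 0.75,
    "sigma_n": 0.03,
}

#: latent-scale group SDs: enough spread for individual differences to be
#: recoverable without leaving the plausible parameter range
GROUP_SDS_DEFAULT = {
    "kappa": 0.5,
    "eta": 0.5,
    "beta_choice": 0.4,
    "bias": 0.15,
    "sigma_a": 0.5,
    "sigma_n": 0.5,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for one synthetic cohort."""

    n_subjects: int = 26
    model: ModelSpec = field(default_factory=ModelSpec)
    group_means: dict = field(default_factory=dict)   # native scale
    group_sds: dict = field(default_factory=dict)     # latent scale
    symptom_slope: float = 0.04
    symptom_noise_sd: float = 1.0
    preset: str = "fmri"   # {"fmri", "amt"}
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.preset not in ("fmri", "amt"):
            raise ValueError("preset must be 'fmri' or 'amt'")
        if any(sd <= 0 for sd in self.group_sds.values()):
            raise ValueError("group SDs must be > 0")

    def design(self) -> TaskDesign:
        return build_design() if self.preset == "fmri" else amt_design()

    def latent_moments(self) -> tuple[np.ndarray, np.ndarray]:
        names = self.model.free_parameter_names
        means = {**GROUP_MEANS_DEFAULT, **self.group_means}
        sds = {**GROUP_SDS_DEFAULT, **self.group_sds}
        mu = np.array([float(_inv(np.asarray(means[n]), _TRANSFORMS[n]))
                       for n in names])
        sd = np.array([sds[n] for n in names])
        return mu, sd


@dataclass(frozen=True)
class SyntheticStudy:
    spec: CohortSpec
    design: TaskDesign
    true_latents: np.ndarray          # n_subjects x d
    true_params: list[AgentParams]
    sessions: list[BehaviouralSession]
    traces: list[LatentTrace]
    discrimination: list[DiscriminationData]
    subjects: pd.DataFrame            # one row per subject

    def sessions_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.sessions],
                         ignore_index=True)


def sample_cohort_params(spec: CohortSpec) -> tuple[
        list[AgentParams], np.ndarray]:
    """Sample per-subject parameters from the group latent Gaussian."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.master_seed, 1]))
    mu, sd = spec.latent_moments()
    lat = mu + rng.standard_normal((spec.n_subjects, len(mu))) * sd
    params = [transform_params(v, spec.model) for v in lat]
    return params, lat


def simulate_discrimination(
    params: PsychometricParams,
    seed: int,
    levels=LEVELS_DEFAULT,
    n_per_level: int = 32,
) -> DiscriminationData:
    """Binomial same/different responses on the fixed delta-rho level grid."""
    rng = np.random.default_rng(seed)
    lv = np.asarray(levels, dtype=float)
    p = np.asarray([psychometric_prob(params, d) for d in lv])
    k = rng.binomial(n_per_level, p)
    return DiscriminationData(levels=lv,
                              n_trials=np.full(len(lv), n_per_level),
                              n_different=k)


def generate_study(spec: CohortSpec,
                   include_behaviour: bool = True) -> SyntheticStudy:
    """Full synthetic study: sessions, discrimination data, symptom scores.

    ``include_behaviour=False`` skips simulating the trial-level sessions
    and discrimination data (the symptom-score pipeline only needs the
    sampled parameters, scores and precisions); the subject table is
    identical either way for a given master seed.

    Symptom scores are generated on the standardized scale against
    standardized log sigma_a:

        score_i = slope * z(log sigma_a_i) + eps_i,
        eps_i ~ N(0, noise_sd / sqrt(precision_i)),

    with per-subject precisions (emulating 1/posterior-variance weights of
    unequal estimate reliability) drawn log-normally.  The
    precision-weighted regression stage is then the matching ML estimator
    of the planted slope.
    """
    design = spec.design()
    params, lat = sample_cohort_params(spec)
    names = spec.model.free_parameter_names
    ss = np.random.SeedSequence([spec.master_seed, 2])
    child = ss.generate_state(4 * spec.n_subjects + 8) % (2**31 - 1)
    sessions, traces, disc = [], [], []
    ids = [f"sub-{i + 1:03d}" for i in range(spec.n_subjects)]
    if include_behaviour:
        for i in range(spec.n_subjects):
            seq = generate_sequence(design, int(child[4 * i]))
            sess, trace = simulate_agent(params[i], spec.model, seq,
                                         seed=int(child[4 * i + 1]),
                                         subject_id=ids[i])
            sessions.append(sess)
            traces.append(trace)
            psy = PsychometricParams(
                alpha_bias=0.05, beta_slope=0.019, lapse=0.01
            )
            disc.append(
                simulate_discrimination(psy, seed=int(child[4 * i + 2])))
    # planted symptom association
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.master_seed, 3]))
    if "sigma_a" in names:
        log_sa = np.array([np.log(p.sigma_a) for p in params])
    else:
        log_sa = np.zeros(spec.n_subjects)
    sd = log_sa.std(ddof=0)
    z = (log_sa - log_sa.mean()) / sd if sd > 0 else np.zeros_like(log_sa)
    precision = np.exp(rng.standard_normal(spec.n_subjects) * 0.5)
    noise = rng.standard_normal(spec.n_subjects) * (
        spec.symptom_noise_sd / np.sqrt(precision))
    score = spec.symptom_slope * z + noise
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            **{f"true_{n}": [getattr(p, n) for p in params] for n in names},
            "z_log_sigma_a": z,
            "symptom_score": score,
            "precision": precision,
            "age_z": rng.standard_normal(spec.n_subjects),
            "gender": rng.integers(0, 2, spec.n_subjects),
        }
    )
    return SyntheticStudy(
        spec=spec, design=design, true_latents=lat, true_params=params,
        sessions=sessions, traces=traces, discrimination=disc,
        subjects=subjects,
    )


def generate_patterns(
    condition_means: dict[str, np.ndarray],
    n_runs: int = 5,
    noise_sd: float = 1.0,
    seed: int = 0,
    late_condition_means: dict[str, np.ndarray] | None = None,
    n_early_runs: int = 2,
    n_residual_samples: int = 0,
) -> PatternDataset:
    """Gaussian patterns around per-condition means, optionally drifting.

    ``late_condition_means`` replaces the means for runs after the first
    ``n_early_runs``, planting a known representational-distance change.
    ``n_residual_samples > 0`` attaches iid residual rows (for the noise
    normalization step).
    """
    rng = np.random.default_rng(seed)
    conds = tuple(condition_means)
    P = len(next(iter(condition_means.values())))
    E = np.empty((n_runs, len(conds), P))
    for k in range(n_runs):
        means = condition_means
        if late_condition_means is not None and k >= n_early_runs:
            means = {**condition_means, **late_condition_means}
        for c, name in enumerate(conds):
            E[k, c] = np.asarray(means[name], dtype=float) + \
                rng.standard_normal(P) * noise_sd
    residuals = None
    if n_residual_samples > 0:
        residuals = rng.standard_normal(
            (n_runs, n_residual_samples, P)) * noise_sd
    return PatternDataset(
        estimates=E,
        condition_labels=conds,
        run_labels=tuple(f"run{k + 1}" for k in range(n_runs)),
        residuals=residuals,
    )
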