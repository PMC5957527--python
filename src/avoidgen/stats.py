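"""Behavioural summaries and individual-difference statistics.

Covers: per-role avoidance proportions with within-participant z-scoring
(relative GS avoidance), the peak-shift asymmetry index, sequential
quality-control filters for crowdsourced cohorts, the Nyholt
effective-number-of-tests correction, and precision-weighted (WLS)
regression for relating parameter estimates to covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import BehaviouralSession
from .stimuli import Role, TaskDesign

__all__ = [
    "AvoidanceSummary",
    "NyholtResult",
    "WlsFit",
    "avoidance_summary",
    "peak_shift_index",
    "qc_filter",
    "nyholt_meff",
    "precision_weighted_regression",
    "MissingRoleError",
]


class MissingRoleError(ValueError):
    """A stimulus role has zero trials in the session."""


@dataclass(frozen=True)
class AvoidanceSummary:
    """Avoidance proportions per role / stimulus, with relative z-values."""

    by_role: dict[Role, float]
    by_stimulus: dict[str, float]
    relative_z: dict[Role, float]
    subject_id: str = "sub-01"

    @property
    def relative_gs_avoidance(self) -> float:
        """GS avoidance standardized against the subject's own CS-/CS+ rates."""
        return self.relative_z[Role.GS]


def avoidance_summary(session: BehaviouralSession,
                      design: TaskDesign | None = None) -> AvoidanceSummary:
    """Proportion of avoided trials per role and stimulus.

    The three role proportions are z-scored within the participant to give
    *relative* avoidance, removing individual differences in overall
    tendency to avoid.  If all three proportions are equal the z-values are
    defined as zeros.
    """
    design = design or session.design
    stim_roles = np.array(
        [design.stimuli[i].role.value for i in session.sequence.stimulus]
    )
    by_role: dict[Role, float] = {}
    for role in (Role.CS_MINUS, Role.GS, Role.CS_PLUS):
        mask = stim_roles == role.value
        if not np.any(mask):
            raise MissingRoleError(f"no {role.value} trials in session")
        by_role[role] = float(np.mean(session.avoided[mask]))
    by_stim: dict[str, float] = {}
    for i, s in enumerate(design.stimuli):
        mask = session.sequence.stimulus == i
        by_stim[s.label] = (
            float(np.mean(session.avoided[mask])) if np.any(mask) else np.nan
        )
    vals = np.array([by_role[r] for r in (Role.CS_MINUS, Role.GS,
                                          Role.CS_PLUS)])
    sd = np.std(vals, ddof=1)
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(3)
    rel = dict(zip((Role.CS_MINUS, Role.GS, Role.CS_PLUS), map(float, z)))
    return AvoidanceSummary(by_role=by_role, by_stimulus=by_stim,
                            relative_z=rel, subject_id=session.subject_id)


def peak_shift_index(summary: AvoidanceSummary,
                     design: TaskDesign) -> float:
    """Asymmetry of GS avoidance around each CS+ relative to the CS-.

    For each CS+ with both flanking GS, computes avoidance(GS on the side
    *away* from the CS-) minus avoidance(GS on the side *toward* the CS-),
    then averages over CS+.  Positive values are the peak-shift signature:
    responding displaced away from the safety signal.
    """
    cs_minus = design.by_role(Role.CS_MINUS)[0]
    diffs = []
    for csp in design.by_role(Role.CS_PLUS):
        flank = [s for s in design.by_role(Role.GS)
                 if s.adjacent_cs_plus == csp.label]
        if len(flank) != 2:
            raise ValueError(f"CS+ {csp.label!r} lacks two flanking GS")
        d_near = min(flank, key=lambda s: abs(s.rho - cs_minus.rho))
        d_far = max(flank, key=lambda s: abs(s.rho - cs_minus.rho))
        a_near = summary.by_stimulus[d_near.label]
        a_far = summary.by_stimulus[d_far.label]
        if np.isnan(a_near) or np.isnan(a_far):
            raise ValueError("missing GS avoidance data for peak shift")
        diffs.append(a_far - a_near)
    return float(np.mean(diffs))


def qc_filter(
    sessions: list[BehaviouralSession],
    cs_plus_avoid_min: float = 0.5,
    catch_failed: dict[str, bool] | None = None,
) -> tuple[list[BehaviouralSession], pd.DataFrame]:
    """Sequential data-quality exclusions for crowdsourced cohorts.

    Rule 1: exclude subjects avoiding on less than ``cs_plus_avoid_min`` of
    all CS+ trials (strict 'less than': exactly 50% is kept).  Rule 2:
    among survivors, exclude subjects who failed the questionnaire catch
    item.  Returns kept sessions and a table of exclusions with reasons.
    """
    catch_failed = catch_failed or {}
    kept: list[BehaviouralSession] = []
    rows = []
    for sess in sessions:
        design = sess.design
        roles = np.array(
            [design.stimuli[i].role.value for i in sess.sequence.stimulus]
        )
        csp = roles == Role.CS_PLUS.value
        prop = float(np.mean(sess.avoided[csp]))
        if prop < cs_plus_avoid_min:
            rows.append((sess.subject_id, "low CS+ avoidance", prop))
            continue
        if catch_failed.get(sess.subject_id, False):
            rows.append((sess.subject_id, "catch item failed", prop))
            continue
        kept.append(sess)
    excluded = pd.DataFrame(
        rows, columns=["subject_id", "reason", "cs_plus_avoidance"]
    )
    return kept, excluded


@dataclass(frozen=True)
class NyholtResult:
    eigenvalues: np.ndarray
    m_eff: float
    corrected_alpha: float


def nyholt_meff(correlation_matrix: np.ndarray,
                alpha: float = 0.05) -> NyholtResult:
    """Effective number of independent variables from a correlation matrix.

    m_eff = 1 + (M - 1) * (1 - Var(lambda) / M), with Var the sample
    (M - 1 denominator) variance of the eigenvalues; the corrected
    significance level is alpha / m_eff.  Equals M for independent
    variables and 1 when all are perfectly correlated.
    """
    R = np.asarray(correlation_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh(R)
    if lam[0] < -1e-8:
        raise ValueError("correlation matrix is not PSD within tolerance")
    M = R.shape[0]
    var = float(np.var(lam, ddof=1))
    m_eff = 1.0 + (M - 1.0) * (1.0 - var / M)
    return NyholtResult(eigenvalues=lam[::-1], m_eff=float(m_eff),
                        corrected_alpha=float(alpha / m_eff))


@dataclass(frozen=True)
class WlsFit:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    weights: np.ndarray
    names: list[str]
    results: object  # underlying statsmodels results

    def summary(self) -> str:
        return str(self.results.summary())


def precision_weighted_regression(
    outcome: np.ndarray,
    predictors: np.ndarray | pd.DataFrame,
    precisions: np.ndarray,
    add_constant: bool = True,
) -> WlsFit:
    """Weighted least squares with precision (1/posterior variance) weights.

    The ML estimate under heteroscedastic Gaussian noise whose per-row
    variance is proportional to 1/precision — the standard way to regress
    posterior parameter estimates of unequal reliability on covariates.
    """
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(precisions, dtype=float)
    if np.any(w <= 0):
        raise ValueError("precisions must be > 0")
    if isinstance(predictors, pd.DataFrame):
        X = predictors.astype(float)
    else:
        X = pd.DataFrame(np.atleast_2d(np.asarray(predictors, dtype=float)))
        if X.shape[0] != len(y):
            X = X.T
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    if len(X) != len(y) or len(w) != len(y):
        raise ValueError("outcome, predictors and precisions must align")
    if add_constant:
        X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design: predictors are rank deficient")
    res = sm.WLS(y, X, weights=w).fit()
    return WlsFit(
        params=res.params.to_numpy(),
        bse=res.bse.to_numpy(),
        tvalues=res.tvalues.to_numpy(),
        pvalues=res.pvalues.to_numpy(),
        weights=w,
        names=list(X.columns),
        results=res,
    )
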