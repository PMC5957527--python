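"""Compiled inner loops for the avoidance-learning likelihood.

The per-trial recursion is inherently sequential, so the hot path is a
numba-compiled loop; the pure-Python single-trial functions in
:mod:`avoidgen.models` define the same dynamics readably.
"""

import numpy as np
from numba import njit

# variant codes
PERCEPTUAL_ONLY = 0
VALUE_1WIDTH = 1
VALUE_2WIDTH = 2

_P_FLOOR = 1e-12


@njit(cache=True)
def run_learner(
    stim,            # (n,) int64 stimulus index per trial
    avoided,         # (n,) int64 0/1
    outcome,         # (n,) int64 0 or -1 (0 forced when avoided)
    rho,             # (S,) float64
    is_gs,           # (S,) int64 0/1
    adj,             # (S,) int64 index of adjacent CS+, -1 for non-GS
    p_confuse,       # (n,) float64 per-trial confusion probability
    kappa, eta, beta, bias, cost, sigma_a, sigma_n,
    variant,         # int
    alpha0,          # float
):
    """Run the learner through a session, returning log-likelihood + traces.

    Returns (ll, v_eff, p_avoid, pe, alpha_tr, G_tr) where alpha_tr[t] is
    the associability in force on trial t and G_tr[t] the spread weights
    applied on that trial (one-hot when no value generalization applies).
    """
    S = rho.shape[0]
    n = stim.shape[0]
    V = np.zeros(S)
    # Gaussian spread weight matrices, rebuilt per parameter vector
    GA = np.eye(S)
    GN = np.eye(S)
    if variant != PERCEPTUAL_ONLY:
        sn = sigma_a if variant == VALUE_1WIDTH else sigma_n
        for i in range(S):
            for j in range(S):
                d2 = (rho[i] - rho[j]) ** 2
                GA[i, j] = np.exp(-d2 / (2.0 * sigma_a * sigma_a))
                GN[i, j] = np.exp(-d2 / (2.0 * sn * sn))

    v_eff = np.empty(n)
    p_av = np.empty(n)
    pe_tr = np.empty(n)
    alpha_tr = np.empty(n)
    G_tr = np.zeros((n, S))

    alpha = alpha0
    ll = 0.0
    for t in range(n):
        i = stim[t]
        v = V[i]
        if is_gs[i] == 1:
            v = (1.0 - p_confuse[t]) * v + p_confuse[t] * V[adj[i]]
        # V(avoid) pinned at 0; decision weighs value of not avoiding
        # against the flat avoidance cost and the bias term
        p = 1.0 / (1.0 + np.exp(-beta * (0.0 - v - cost - bias)))
        if p < _P_FLOOR:
            p = _P_FLOOR
        elif p > 1.0 - _P_FLOOR:
            p = 1.0 - _P_FLOOR
        v_eff[t] = v
        p_av[t] = p
        alpha_tr[t] = alpha
        if avoided[t] == 1:
            ll += np.log(p)
            pe_tr[t] = 0.0
            G_tr[t, i] = 0.0
            alpha = (1.0 - eta) * alpha
        else:
            ll += np.log(1.0 - p)
            pe = outcome[t] - V[i]
            pe_tr[t] = pe
            upd = kappa * alpha * pe
            if variant == PERCEPTUAL_ONLY:
                V[i] += upd
                G_tr[t, i] = 1.0
            else:
                G = GA if outcome[t] == -1 else GN
                for j in range(S):
                    V[j] += upd * G[i, j]
                    G_tr[t, j] = G[i, j]
            alpha = eta * np.abs(pe) + (1.0 - eta) * alpha
    return ll, v_eff, p_av, pe_tr, alpha_tr, G_tr


@njit(cache=True)
def loglik_only(
    stim, avoided, outcome, rho, is_gs, adj, p_confuse,
    kappa, eta, beta, bias, cost, sigma_a, sigma_n, variant, alpha0,
):
    """Log-likelihood without trace allocation (optimizer hot path)."""
    S = rho.shape[0]
    n = stim.shape[0]
    V = np.zeros(S)
    GA = np.eye(S)
    GN = np.eye(S)
    if variant != PERCEPTUAL_ONLY:
        sn = sigma_a if variant == VALUE_1WIDTH else sigma_n
        for i in range(S):
            for j in range(S):
                d2 = (rho[i] - rho[j]) ** 2
                GA[i, j] = np.exp(-d2 / (2.0 * sigma_a * sigma_a))
                GN[i, j] = np.exp(-d2 / (2.0 * sn * sn))
    alpha = alpha0
    ll = 0.0
    for t in range(n):
        i = stim[t]
        v = V[i]
        if is_gs[i] == 1:
            v = (1.0 - p_confuse[t]) * v + p_confuse[t] * V[adj[i]]
        p = 1.0 / (1.0 + np.exp(-beta * (0.0 - v - cost - bias)))
        if p < _P_FLOOR:
            p = _P_FLOOR
        elif p > 1.0 - _P_FLOOR:
            p = 1.0 - _P_FLOOR
        if avoided[t] == 1:
            ll += np.log(p)
            alpha = (1.0 - eta) * alpha
        else:
            ll += np.log(1.0 - p)
            pe = outcome[t] - V[i]
            upd = kappa * alpha * pe
            if variant == PERCEPTUAL_ONLY:
                V[i] += upd
            else:
                G = GA if outcome[t] == -1 else GN
                for j in range(S):
                    V[j] += upd * G[i, j]
            alpha = eta * np.abs(pe) + (1.0 - eta) * alpha
    return ll
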