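"""Learning-rule dynamics, choice rule, likelihood and simulation.

The likelihood is checked against a naive trial-by-trial oracle written
independently here (dictionaries and scalar arithmetic only).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from avoidgen import (
    AgentParams,
    LearnerState,
    ModelSpec,
    Role,
    Variant,
    gaussian_weights,
    generate_sequence,
    log_likelihood,
    p_avoid,
    simulate_agent,
    step,
)
from avoidgen.models import BehaviouralSession, effective_nonavoid_value

from conftest import random_agent_params


# ---------------------------------------------------------------------------
# independent oracle: naive trial loop, no shared code with the package
# ---------------------------------------------------------------------------

def oracle_loglik(params, spec, session):
    design = session.design
    labels = [s.label for s in design.stimuli]
    rho = {s.label: s.rho for s in design.stimuli}
    adj = {s.label: s.adjacent_cs_plus for s in design.stimuli
           if s.role is Role.GS}
    V = {lab: 0.0 for lab in labels}
    alpha = spec.alpha0
    n = len(session)
    if spec.confusion_schedule.value == "CONSTANT":
        pc = [spec.p_confuse] * n
    else:
        pc = list(np.linspace(spec.p_confuse, spec.p_confuse_end, n))
    ll = 0.0
    for t in range(n):
        lab = labels[session.sequence.stimulus[t]]
        v = V[lab]
        if lab in adj:
            v = (1 - pc[t]) * v + pc[t] * V[adj[lab]]
        p = 1.0 / (1.0 + math.exp(-params.beta_choice *
                                  (0.0 - v - design.avoid_cost -
                                   params.bias)))
        p = min(max(p, 1e-12), 1 - 1e-12)
        avoided = session.avoided[t] == 1
        ll += math.log(p) if avoided else math.log(1.0 - p)
        if avoided:
            alpha = (1 - params.eta) * alpha
        else:
            r = float(session.outcome[t])
            pe = r - V[lab]
            if spec.variant is Variant.PERCEPTUAL_ONLY:
                V[lab] = V[lab] + params.kappa * alpha * pe
            else:
                if spec.variant is Variant.VALUE_1WIDTH:
                    sigma = params.sigma_a
                else:
                    sigma = params.sigma_a if r == -1 else params.sigma_n
                for other in labels:
                    g = math.exp(-((rho[lab] - rho[other]) ** 2) /
                                 (2 * sigma**2))
                    V[other] = V[other] + params.kappa * alpha * pe * g
            alpha = params.eta * abs(pe) + (1 - params.eta) * alpha
    return ll


def _random_session(design, rng, n_trials=60):
    seq = generate_sequence(design, seed=int(rng.integers(2**31 - 1)))
    idx = slice(0, n_trials)
    from avoidgen import TrialSequence

    short = TrialSequence(design=design, block=seq.block[idx],
                          stimulus=seq.stimulus[idx],
                          scheduled_outcome=seq.scheduled_outcome[idx],
                          seed=seq.seed)
    avoided = rng.integers(0, 2, n_trials)
    outcome = np.where(avoided == 1, 0, short.scheduled_outcome)
    return BehaviouralSession(sequence=short,
                              avoided=avoided.astype(np.int64),
                              outcome=outcome.astype(np.int64))


class TestGaussianWeights:
    def test_zero_distance_is_one(self):
        w = gaussian_weights(0.25, np.array([0.25]), sigma=0.3)
        assert w[0] == 1.0

    def test_wide_sigma_example(self):
        w = gaussian_weights(0.25, np.array([0.40]), sigma=0.752)
        assert w[0] == pytest.approx(0.98029, abs=1e-4)

    def test_narrow_sigma_vanishes(self):
        w = gaussian_weights(0.25, np.array([0.40]), sigma=0.028)
        assert w[0] < 1e-6

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_weights(0.25, np.array([0.4]), sigma=0.0)

    @given(st_.floats(0.01, 0.99), st_.floats(0.01, 0.99),
           st_.floats(0.01, 3.0))
    @settings(deadline=None, max_examples=50)
    def test_weights_in_unit_interval(self, a, b, sigma):
        # mathematically (0, 1]; exact 0 is reachable through float
        # underflow at extreme distance/width ratios
        w = gaussian_weights(a, np.array([b]), sigma)
        assert 0.0 <= w[0] <= 1.0


class TestChoiceRule:
    def test_flat_softmax(self):
        assert p_avoid(-0.37, beta_choice=0.0, bias=1.3) == 0.5

    def test_zero_value_example(self):
        # decision variable -(0 - 0 - 0.2 - 0.415) * 5 = 3.075
        p = p_avoid(0.0, beta_choice=5.0, bias=0.415, avoid_cost=0.2)
        assert p == pytest.approx(1 / (1 + math.exp(3.075)), abs=1e-9)
        assert p == pytest.approx(0.0442, abs=5e-4)

    def test_threat_value_example(self):
        p = p_avoid(-0.8, beta_choice=5.0, bias=0.415, avoid_cost=0.2)
        assert p == pytest.approx(1 / (1 + math.exp(-0.925)), abs=1e-9)
        assert p == pytest.approx(0.716, abs=5e-4)


class TestEffectiveValue:
    def test_gs_mixing(self, design):
        st = LearnerState.initial(design)
        gs = design.by_role(Role.GS)[0]
        st.values[design.index(gs.label)] = -0.1
        st.values[design.index(gs.adjacent_cs_plus)] = -0.8
        v = effective_nonavoid_value(st, gs, design, confusion_prob=0.25)
        assert v == pytest.approx(-0.275)

    def test_cs_identity(self, design):
        st = LearnerState.initial(design)
        csp = design.by_role(Role.CS_PLUS)[0]
        st.values[design.index(csp.label)] = -0.6
        assert effective_nonavoid_value(st, csp, design) == -0.6

    def test_zeros(self, design):
        st = LearnerState.initial(design)
        gs = design.by_role(Role.GS)[0]
        assert effective_nonavoid_value(st, gs, design) == 0.0


class TestStep:
    def test_avoided_trial_decays_associability(self, design,
                                                two_width_spec):
        params = AgentParams(0.5, 0.3, 5.0, 0.4, sigma_a=0.75,
                             sigma_n=0.03)
        st = LearnerState.initial(design, alpha0=0.6)
        csp = design.by_role(Role.CS_PLUS)[0]
        st2, rec = step(st, csp, avoided=True, reward=0, params=params,
                        spec=two_width_spec, design=design)
        assert rec["pe"] == 0.0
        assert np.array_equal(st2.values, st.values)
        assert st2.associability == pytest.approx(0.42)

    def test_unavoided_shock_update(self, design):
        spec = ModelSpec(variant=Variant.PERCEPTUAL_ONLY)
        params = AgentParams(0.999999, 0.3, 5.0, 0.4)
        st = LearnerState.initial(design, alpha0=0.5)
        csp = design.by_role(Role.CS_PLUS)[0]
        i = design.index(csp.label)
        st.values[i] = -0.5
        st2, rec = step(st, csp, avoided=False, reward=-1, params=params,
                        spec=spec, design=design)
        assert rec["pe"] == pytest.approx(-0.5)
        assert st2.values[i] == pytest.approx(-0.75, abs=1e-5)
        # eta |PE| + (1 - eta) alpha = 0.3*0.5 + 0.7*0.5
        assert st2.associability == pytest.approx(0.5, abs=1e-9)

    def test_narrow_neutral_spread_negligible(self, design):
        spec = ModelSpec(variant=Variant.VALUE_2WIDTH)
        params = AgentParams(0.5, 0.3, 5.0, 0.4, sigma_a=0.75,
                             sigma_n=0.028)
        st = LearnerState.initial(design, alpha0=1.0)
        csp = design.by_role(Role.CS_PLUS)[0]
        st.values[design.index(csp.label)] = -0.4
        st2, rec = step(st, csp, avoided=False, reward=0, params=params,
                        spec=spec, design=design)
        upd = params.kappa * 1.0 * rec["pe"]
        for j, s in enumerate(design.stimuli):
            if abs(s.rho - csp.rho) >= 0.15:
                moved = abs(st2.values[j] - st.values[j])
                assert moved < 1e-6 * abs(upd)


class TestLogLikelihood:
    @pytest.mark.parametrize("variant", list(Variant))
    def test_matches_naive_oracle(self, design, variant):
        """Fast likelihood equals the naive loop on 200 random fixtures."""
        rng = np.random.default_rng(99)
        n_cases = 200 // len(list(Variant)) + 1
        spec = ModelSpec(variant=variant)
        for _ in range(n_cases):
            params = random_agent_params(rng, spec)
            sess = _random_session(design, rng)
            ll, _ = log_likelihood(params, spec, sess)
            assert ll == pytest.approx(oracle_loglik(params, spec, sess),
                                       abs=1e-10)

    def test_linear_confusion_schedule_against_oracle(self, design):
        rng = np.random.default_rng(5)
        spec = ModelSpec(variant=Variant.VALUE_2WIDTH,
                         confusion_schedule="LINEAR", p_confuse=0.25,
                         p_confuse_end=0.10)
        for _ in range(10):
            params = random_agent_params(rng, spec)
            sess = _random_session(design, rng)
            ll, _ = log_likelihood(params, spec, sess)
            assert ll == pytest.approx(oracle_loglik(params, spec, sess),
                                       abs=1e-10)

    def test_all_avoid_closed_form(self, design, two_width_spec):
        params = AgentParams(0.5, 0.3, 5.0, 0.4, sigma_a=0.75,
                             sigma_n=0.03)
        seq = generate_sequence(design, seed=2)
        n = len(seq)
        sess = BehaviouralSession(
            sequence=seq, avoided=np.ones(n, dtype=np.int64),
            outcome=np.zeros(n, dtype=np.int64))
        ll, _ = log_likelihood(params, two_width_spec, sess)
        p_star = p_avoid(0.0, 5.0, 0.4, design.avoid_cost)
        assert ll == pytest.approx(n * math.log(p_star), abs=1e-9)

    def test_zero_sensitivity(self, design, two_width_spec,
                              session_fixture):
        params = AgentParams(0.5, 0.3, 0.0, 0.4, sigma_a=0.75,
                             sigma_n=0.03)
        ll, _ = log_likelihood(params, two_width_spec, session_fixture)
        assert ll == pytest.approx(len(session_fixture) * math.log(0.5))

    def test_equal_widths_reduce_to_one_width(self, design,
                                              session_fixture):
        p2 = AgentParams(0.4, 0.25, 4.0, 0.3, sigma_a=0.5, sigma_n=0.5)
        p1 = AgentParams(0.4, 0.25, 4.0, 0.3, sigma_a=0.5)
        ll2, _ = log_likelihood(p2, ModelSpec(variant=Variant.VALUE_2WIDTH),
                                session_fixture)
        ll1, _ = log_likelihood(p1, ModelSpec(variant=Variant.VALUE_1WIDTH),
                                session_fixture)
        assert ll2 == ll1

    def test_trace_invariants(self, two_width_spec, session_fixture,
                              typical_params):
        _, tr = log_likelihood(typical_params, two_width_spec,
                               session_fixture)
        assert np.all((tr.p_avoid > 0) & (tr.p_avoid < 1))
        assert np.all(tr.prediction_error[session_fixture.avoided == 1]
                      == 0.0)
        assert np.all(tr.associability >= 0)
        assert np.array_equal(tr.p_shock, -tr.effective_value)


class TestDynamicsInvariants:
    def test_perceptual_only_values_bounded(self, design):
        rng = np.random.default_rng(3)
        spec = ModelSpec(variant=Variant.PERCEPTUAL_ONLY)
        for k in range(10):
            params = random_agent_params(rng, spec)
            seq = generate_sequence(design, seed=k)
            sess, tr = simulate_agent(params, spec, seq, seed=k + 100)
            assert np.all(tr.effective_value <= 0.0)
            assert np.all(tr.effective_value >= -1.0)

    def test_associability_bounded(self, design, two_width_spec):
        rng = np.random.default_rng(4)
        for k in range(10):
            params = random_agent_params(rng, two_width_spec)
            seq = generate_sequence(design, seed=k)
            _, tr = simulate_agent(params, two_width_spec, seq, seed=k)
            # convex-combination bound: alpha stays within [0, max(a0, max |PE|)]
            bound = max(two_width_spec.alpha0,
                        np.max(np.abs(tr.prediction_error)))
            assert np.all(tr.associability >= 0)
            assert np.all(tr.associability <= bound + 1e-12)


class TestSimulateAgent:
    def test_determinism(self, typical_params, two_width_spec, sequence):
        s1, _ = simulate_agent(typical_params, two_width_spec, sequence, 11)
        s2, _ = simulate_agent(typical_params, two_width_spec, sequence, 11)
        assert np.array_equal(s1.avoided, s2.avoided)
        assert np.array_equal(s1.outcome, s2.outcome)

    def test_gs_trials_never_aversive(self, typical_params, two_width_spec,
                                      design, sequence):
        sess, _ = simulate_agent(typical_params, two_width_spec, sequence, 8)
        roles = [design.stimuli[i].role for i in sess.sequence.stimulus]
        for role, out in zip(roles, sess.outcome):
            if role is not Role.CS_PLUS:
                assert out == 0

    def test_no_learning_constant_rate(self, design, sequence):
        spec = ModelSpec(variant=Variant.PERCEPTUAL_ONLY)
        params = AgentParams(1e-9, 0.3, 5.0, 0.4)
        sess, tr = simulate_agent(params, spec, sequence, seed=1)
        p0 = tr.p_avoid[0]
        assert np.allclose(tr.p_avoid, p0, atol=1e-6)
        # avoid rate within binomial bounds of the constant probability
        n = len(sess)
        half = 3 * math.sqrt(p0 * (1 - p0) / n)
        assert abs(sess.avoided.mean() - p0) < half

    def test_avoided_outcome_forced_neutral(self, typical_params,
                                            two_width_spec, sequence):
        sess, _ = simulate_agent(typical_params, two_width_spec, sequence, 9)
        assert np.all(sess.outcome[sess.avoided == 1] == 0)

    def test_frame_round_trip(self, typical_params, two_width_spec, design,
                              sequence):
        sess, _ = simulate_agent(typical_params, two_width_spec, sequence, 4)
        df = sess.to_frame()
        back = BehaviouralSession.from_frame(df, design)
        assert np.array_equal(back.avoided, sess.avoided)
        assert np.array_equal(back.outcome, sess.outcome)
        assert np.array_equal(back.sequence.stimulus,
                              sess.sequence.stimulus)
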