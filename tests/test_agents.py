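"""Unit and property tests of the ten learning models."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ktom.agents import (
    MODEL_IDS,
    NOTOM_FAMILY,
    TOM_FAMILY,
    Agent,
    AgentSpec,
    InfluenceState,
    KtomMachine,
    PayoffTable,
    PolicyParams,
    QValues,
    Tom0Belief,
    agent_step,
    expected_value_difference,
    influence_update,
    ktom_update,
    rl_update,
    softmax_policy,
    tom0_predict,
    tom0_update,
    ws_update,
)
from ktom.core import EPS, logit, sigmoid


class TestPolicyAndPayoffs:
    def test_softmax_closed_forms(self):
        assert softmax_policy(0.0, PolicyParams(1.0, 0.0)) == pytest.approx(0.5)
        assert softmax_policy(1.0, PolicyParams(1.0, 0.0)) == pytest.approx(
            1 / (1 + np.exp(-1))
        )
        # the greedy limit
        assert softmax_policy(1.0, PolicyParams(1e-9, 0.0)) == pytest.approx(1.0)

    def test_softmax_rejects_bad_input(self):
        with pytest.raises(ValueError):
            softmax_policy(np.nan, PolicyParams(1.0, 0.0))
        with pytest.raises(ValueError):
            PolicyParams(beta=-1.0)

    @given(
        dv=st.floats(-5, 5),
        ddv=st.floats(0.01, 2),
        bias=st.floats(-2, 2),
        beta=st.floats(0.05, 5),
    )
    def test_softmax_monotone_in_dv_and_bias(self, dv, ddv, bias, beta):
        pp = PolicyParams(beta, bias)
        assert softmax_policy(dv + ddv, pp) > softmax_policy(dv, pp)
        assert softmax_policy(dv, PolicyParams(beta, bias + 0.5)) > softmax_policy(
            dv, pp
        )

    def test_seeker_table_identity(self):
        u = PayoffTable.hide_and_seek("seeker")
        assert u.u[1, 1] - u.u[0, 1] == pytest.approx(1.0)
        assert u.u[0, 0] - u.u[1, 0] == pytest.approx(1.0)
        # dV = 2 p_op - 1 for the seeker
        assert expected_value_difference(0.75, u) == pytest.approx(0.5)
        # competitive tables are anti-symmetric between players
        hider = PayoffTable.hide_and_seek("hider")
        assert np.allclose(hider.u, -u.u)

    @given(p=st.floats(0, 1), u_vals=st.lists(st.floats(-2, 2), min_size=4, max_size=4))
    def test_evd_matches_enumeration(self, p, u_vals):
        u = PayoffTable(np.array(u_vals).reshape(2, 2))
        expect = p * (u.u[1, 1] - u.u[0, 1]) + (1 - p) * (u.u[1, 0] - u.u[0, 0])
        brute = p * u.u[1, 1] + (1 - p) * u.u[1, 0] - (
            p * u.u[0, 1] + (1 - p) * u.u[0, 0]
        )
        assert expected_value_difference(p, u) == pytest.approx(expect)
        assert expect == pytest.approx(brute)

    def test_evd_domain_check(self):
        with pytest.raises(ValueError):
            expected_value_difference(1.5, PayoffTable.hide_and_seek())


class TestTom0:
    def test_hand_evaluated_update(self):
        b = tom0_update(Tom0Belief(mu=0.0, sigma2=1.0, vol=0.0), a_op=1)
        assert b.sigma2 == pytest.approx(0.8)
        assert b.mu == pytest.approx(0.4)

    def test_zero_innovation_leaves_mean(self):
        b0 = Tom0Belief(mu=0.3, sigma2=0.5, vol=0.0)
        b1 = tom0_update(b0, a_op=sigmoid(0.3))
        assert b1.mu == pytest.approx(b0.mu)

    def test_variance_non_increasing_without_volatility(self):
        b = Tom0Belief(mu=0.0, sigma2=2.0, vol=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            nb = tom0_update(b, int(rng.random() < 0.6))
            assert nb.sigma2 <= b.sigma2 + 1e-12
            b = nb

    def test_fictitious_play_limit(self, rng):
        """With zero volatility the prediction converges to the opponent's
        stationary choice frequency."""
        f = 0.7
        seq = (rng.random(1000) < f).astype(int)
        b = Tom0Belief(vol=1e-12)
        for a in seq:
            b = tom0_update(b, int(a))
        assert abs(tom0_predict(b) - seq.mean()) < 0.02


class TestValueRules:
    def test_rl_hand_arithmetic(self):
        q = rl_update(QValues((0.0, 0.0), alpha=0.5), a_self=1, reward=1.0)
        assert q.v == (0.0, 0.5)

    def test_rl_alpha_extremes(self):
        q0 = QValues((0.2, -0.1), alpha=0.0)
        assert rl_update(q0, 0, 1.0).v == q0.v
        q1 = rl_update(QValues((0.2, -0.1), alpha=1.0), 0, 0.5)
        assert q1.v[0] == pytest.approx(0.5)
        assert q1.v[1] == pytest.approx(-0.1)

    def test_ws_structure_and_idempotence(self):
        q = ws_update(QValues(), a_self=0, reward=1.0)
        assert q.v == (1.0, -1.0)
        q2 = ws_update(QValues(), a_self=1, reward=-1.0)
        assert q2.v == (1.0, -1.0)
        # repeated wins on the same option change nothing
        assert ws_update(q, 0, 1.0).v == q.v

    def test_rl_alpha1_tracks_ws_direction(self, rng):
        """RL at alpha = 1 and WS prefer the same option whenever both
        value differences are nonzero and share a sign."""
        rl = QValues((0.0, 0.0), alpha=1.0)
        ws = QValues((0.0, 0.0))
        table = PayoffTable.hide_and_seek("seeker")
        for _ in range(200):
            a_s, a_o = int(rng.random() < 0.5), int(rng.random() < 0.5)
            r = table.reward(a_s, a_o)
            rl = rl_update(rl, a_s, r)
            ws = ws_update(ws, a_s, r)
            d_rl = rl.v[1] - rl.v[0]
            d_ws = ws.v[1] - ws.v[0]
            if d_rl != 0 and d_ws != 0:
                assert np.sign(d_rl) == np.sign(d_ws)


class TestInfluence:
    def test_frozen_state_is_fixed_point(self):
        st0 = InfluenceState(p_op=0.4, eta=0.0, lam=0.0)
        assert influence_update(st0, 1, 1).p_op == pytest.approx(0.4)

    def test_pure_delta_rule(self):
        st0 = InfluenceState(p_op=0.4, eta=0.5, lam=0.0)
        assert influence_update(st0, 0, 1).p_op == pytest.approx(0.7)

    def test_adjustment_vanishes_at_clamp_boundary(self):
        st0 = InfluenceState(p_op=EPS * 1.001, eta=0.0, lam=0.5, beta_inf=1.0)
        out = influence_update(st0, 1, 0)
        bound = 0.5 * st0.p_op * (2 + abs(logit(st0.p_op)) + 1)
        assert abs(out.p_op - st0.p_op) <= bound + 1e-12
        assert bound < 0.01

    def test_state_validation(self):
        with pytest.raises(ValueError):
            InfluenceState(p_op=0.0)
        with pytest.raises(ValueError):
            InfluenceState(eta=1.5)


class TestKtom:
    def test_level_posterior_flat_when_predictions_agree(self):
        """At initialization both sub-models predict 0.5, so the first
        observation cannot move the level posterior."""
        m = KtomMachine(2)
        m.predict()
        m.observe(1, 0)
        assert np.allclose(m.level_post, [0.5, 0.5], atol=1e-12)

    def test_level_posterior_stays_simplex(self, rng):
        m = KtomMachine(2)
        for _ in range(60):
            m.predict()
            m.observe(int(rng.random() < 0.5), int(rng.random() < 0.5))
            assert np.all(m.level_post >= 0)
            assert np.sum(m.level_post) == pytest.approx(1.0, abs=1e-10)
            for S in m.state_cov:
                assert np.all(np.linalg.eigvalsh(S) > 0)

    def test_prediction_in_open_interval(self, rng):
        m = KtomMachine(1)
        for _ in range(80):
            p = m.predict()
            assert 0.0 < p < 1.0
            m.observe(int(rng.random() < 0.9), int(rng.random() < 0.1))

    def test_nesting_consistency(self, rng):
        """A 2-ToM pinned on opponent level 0 carries exactly the 1-ToM
        belief trajectory over the same history."""
        m2 = KtomMachine(2, vol=0.4, beta=0.3)
        m2.lam = np.array([1.0, 0.0])
        m1 = KtomMachine(1, vol=0.4, beta=0.3)
        for _ in range(40):
            a_s, a_o = int(rng.random() < 0.5), int(rng.random() < 0.6)
            m2.predict()
            m1.predict()
            m2.observe(a_s, a_o)
            m1.observe(a_s, a_o)
            assert np.allclose(m2.lam, [1.0, 0.0], atol=1e-12)
            assert np.allclose(m2.subs[0].m, m1.subs[0].m, atol=1e-10)
            assert np.allclose(m2.subs[0].S, m1.subs[0].S, atol=1e-10)

    def test_functional_update_leaves_input(self):
        m = KtomMachine(1)
        m2 = ktom_update(m, 1, 0)
        assert np.allclose(m.subs[0].m, 0.0)
        assert not np.allclose(m2.subs[0].m, 0.0)

    def test_parameter_tracking_within_two_sd(self):
        """A 1-ToM watching a 0-ToM opponent with known volatility and
        temperature keeps the true transformed parameters inside 2 posterior
        SD in most runs."""
        from ktom.arena import play_session

        true = np.array([np.log(0.5), np.log(1.0)])
        hits = 0
        runs = 25
        for r in range(runs):
            rec = play_session(
                AgentSpec("1ToM-comp", {"sigma": 0.5, "beta": 0.05}),
                "OTOM",
                seed=r,
                n_trials=300,
            )
            m = KtomMachine(1, vol=0.5, beta=0.05)
            for t in range(len(rec)):
                m.predict()
                m.observe(int(rec.a_self[t]), int(rec.a_op[t]))
            est = m.subs[0].m[1:]
            sd = np.sqrt(np.diagonal(m.subs[0].S)[1:])
            if np.all(np.abs(est - true) <= 2 * sd):
                hits += 1
        assert hits / runs >= 0.8


class TestAgentStep:
    def test_model_catalogue(self):
        assert len(MODEL_IDS) == 10
        assert len(TOM_FAMILY) == 6 and len(NOTOM_FAMILY) == 4
        with pytest.raises(ValueError):
            AgentSpec("3ToM")

    def test_bn_is_chance(self):
        act, state = agent_step(AgentSpec("BN"), None, None, None, None, 0.49)
        assert act == 1  # rng_draw < 0.5
        assert state.prob() == pytest.approx(0.5)

    def test_determinism(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        spec = AgentSpec("0ToM", {"sigma": 0.5, "beta": 0.3})
        s1 = s2 = None
        last1 = last2 = (None, None, None)
        for _ in range(30):
            d = rng1.random()
            a1, s1 = agent_step(spec, s1, *last1, d)
            a2, s2 = agent_step(spec, s2, *last2, rng2.random())
            assert a1 == a2
            op = int(rng1.random() < 0.5)
            rng2.random()
            last1 = last2 = (a1, op, int(a1 == op))

    def test_inconsistent_reward_rejected(self):
        spec = AgentSpec("RL", {"alpha": 0.5, "beta": 1.0})
        _, state = agent_step(spec, None, None, None, None, 0.3)
        with pytest.raises(ValueError):
            agent_step(spec, state, 1, 1, 0, 0.3)  # match but reward 0

    def test_composition_matches_direct_machine(self, rng):
        """agent_step is exactly observe -> value difference -> softmax."""
        spec = AgentSpec("0ToM", {"sigma": 0.7, "beta": 0.4, "bias": 0.1})
        state = None
        last = (None, None, None)
        b = Tom0Belief(vol=0.7)
        table = PayoffTable.hide_and_seek("seeker")
        pp = PolicyParams(0.4, 0.1)
        for _ in range(40):
            d = rng.random()
            a, state = agent_step(spec, state, *last, d)
            p_direct = softmax_policy(
                expected_value_difference(tom0_predict(b), table), pp
            )
            assert a == int(d < p_direct)
            op = int(rng.random() < 0.65)
            b = tom0_update(b, op)
            last = (a, op, int(a == op))
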