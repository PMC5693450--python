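"""Candidate learning models for repeated two-action dyadic games.

Ten models are implemented behind a uniform observe -> act interface:

* non-mentalizing family: ``BN`` (biased Nash), ``WS`` (win-stay/lose-switch),
  ``RL`` (Rescorla-Wagner reinforcement learning) and ``0ToM`` (a Bayesian
  tracker of the opponent's action tendency, an adaptive extension of
  fictitious play);
* mentalizing family: ``Inf`` (influence learning, cooperative and
  competitive variants) and recursive meta-Bayesian ``1ToM`` / ``2ToM``
  learners (cooperative and competitive variants).

All models share the same softmax decision rule: the probability of picking
option 1 is ``s(dV / beta + bias)`` where ``dV`` is the expected payoff
difference between the two options under the model's current prediction of
the opponent's next move.

Internally every state container carries numpy arrays with an arbitrary
leading batch shape, so that a single replay can evaluate many parameter
vectors at once (used heavily by model inversion); the plain scalar case is
just batch shape ``()``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import EPS, MOMENT_A, clamp_prob, gaussian_sigmoid_mean, logit, sigmoid

__all__ = [
    "MODEL_IDS",
    "TOM_FAMILY",
    "NOTOM_FAMILY",
    "PayoffTable",
    "PolicyParams",
    "Tom0Belief",
    "QValues",
    "InfluenceState",
    "AgentSpec",
    "Agent",
    "softmax_policy",
    "expected_value_difference",
    "tom0_update",
    "tom0_predict",
    "ktom_update",
    "influence_update",
    "rl_update",
    "ws_update",
    "agent_step",
    "KtomMachine",
]

#: Canonical model identifiers (4 non-ToM + 6 ToM).
MODEL_IDS = (
    "BN",
    "WS",
    "RL",
    "0ToM",
    "Inf-coop",
    "Inf-comp",
    "1ToM-coop",
    "1ToM-comp",
    "2ToM-coop",
    "2ToM-comp",
)
TOM_FAMILY = frozenset(
    {"Inf-coop", "Inf-comp", "1ToM-coop", "1ToM-comp", "2ToM-coop", "2ToM-comp"}
)
NOTOM_FAMILY = frozenset({"BN", "WS", "RL", "0ToM"})

#: Finite-difference step on hidden states for the gradient of the nested
#: opponent mapping.
FD_STEP = 1e-4

#: Action logits of modeled opponents are clamped so the implied choice
#: probability stays within [EPS, 1-EPS]; log-scale hidden states are bounded
#: before exponentiation for the same reason.
_LOGIT_MAX = float(np.log((1.0 - EPS) / EPS))
_LOG_STATE_MAX = 20.0

# ---------------------------------------------------------------------------
# payoffs and decision rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PayoffTable:
    """Utility ``u[a_self, a_op]`` of the four action pairs, owner's view.

    The hide-and-seek game uses a +/- 1/2 utility scale: the seeker earns
    +0.5 on a match and -0.5 on a mismatch, the hider the opposite.  This
    makes the competitive seeker/hider pair anti-symmetric while satisfying
    ``U(1,1) - U(0,1) = U(0,0) - U(1,0) = 1``, i.e. ``dV = 2 p_op - 1`` for
    the seeker.
    """

    u: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if self.u.shape != (2, 2):
            raise ValueError("payoff table must be 2x2")

    @staticmethod
    def hide_and_seek(role: str = "seeker") -> "PayoffTable":
        match = np.array([[0.5, -0.5], [-0.5, 0.5]])
        if role == "seeker":
            return PayoffTable(match)
        if role == "hider":
            return PayoffTable(-match)
        raise ValueError(f"unknown role {role!r}")

    @staticmethod
    def cooperative() -> "PayoffTable":
        # coordination game: both players want to match
        return PayoffTable(np.array([[0.5, -0.5], [-0.5, 0.5]]))

    def value_difference(self, p_op):
        """Expected payoff difference dV between option 1 and option 0."""
        u = self.u
        p_op = np.asarray(p_op, dtype=float)
        return p_op * (u[1, 1] - u[0, 1]) + (1.0 - p_op) * (u[1, 0] - u[0, 0])

    @property
    def dv_slope(self) -> float:
        """d(dV)/d(p_op), a constant for 2x2 tables."""
        u = self.u
        return float((u[1, 1] - u[0, 1]) - (u[1, 0] - u[0, 0]))

    def reward(self, a_self: int, a_op: int) -> float:
        return float(self.u[a_self, a_op])


@dataclass(frozen=True)
class PolicyParams:
    """Softmax policy parameters: temperature ``beta`` > 0 and a log-odds
    ``bias`` towards option 1."""

    beta: float = 1.0
    bias: float = 0.0

    def __post_init__(self):
        if not (self.beta > 0):
            raise ValueError("behavioural temperature beta must be positive")


def softmax_policy(dv, pp: PolicyParams):
    """P(a_self = 1) = s(dV / beta + bias)."""
    dv = np.asarray(dv, dtype=float)
    if not np.all(np.isfinite(dv)):
        raise ValueError("non-finite expected value difference")
    return sigmoid(dv / pp.beta + pp.bias)


def expected_value_difference(p_op, u: PayoffTable):
    """dV = p_op (U(1,1)-U(0,1)) + (1-p_op)(U(1,0)-U(0,0))."""
    p_op = np.asarray(p_op, dtype=float)
    if np.any((p_op < 0) | (p_op > 1)):
        raise ValueError("p_op must lie in [0, 1]")
    return u.value_difference(p_op)


# ---------------------------------------------------------------------------
# 0-ToM: Bayesian tracking of the opponent's action tendency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Tom0Belief:
    """Gaussian posterior over the opponent's choice log-odds.

    ``mu``/``sigma2`` are the posterior mean and variance; ``vol`` is the
    assumed volatility of the log-odds across trials.  At ``vol = 0`` the
    update reduces to fictitious play (the prediction converges to the
    opponent's empirical choice frequency).
    """

    mu: float = 0.0
    sigma2: float = 1.0
    vol: float = 0.5

    def __post_init__(self):
        if not (self.sigma2 > 0):
            raise ValueError("posterior variance must be positive")
        if self.vol < 0:
            raise ValueError("volatility must be nonnegative")


def tom0_update(b: Tom0Belief, a_op) -> Tom0Belief:
    """One Bayesian (Laplace) update after observing the opponent's action."""
    s_mu = sigmoid(b.mu)
    sigma2 = 1.0 / (1.0 / (b.sigma2 + b.vol) + s_mu * (1.0 - s_mu))
    mu = b.mu + sigma2 * (a_op - s_mu)
    return Tom0Belief(mu=float(mu), sigma2=float(sigma2), vol=b.vol)


def tom0_predict(b: Tom0Belief):
    """Predicted P(a_op = 1) = E[s(x)] under the Gaussian posterior."""
    return gaussian_sigmoid_mean(b.mu, b.sigma2)


class Tom0Machine:
    """Batched 0-ToM tracker (arrays with arbitrary leading batch shape)."""

    def __init__(self, batch_shape=(), vol=0.5):
        self.mu = np.zeros(batch_shape)
        self.var = np.ones(batch_shape)
        self.vol = np.broadcast_to(np.asarray(vol, dtype=float), batch_shape).copy()

    def set_params(self, vol):
        self.vol = np.broadcast_to(np.asarray(vol, dtype=float), self.mu.shape).copy()

    def predict(self):
        return gaussian_sigmoid_mean(self.mu, self.var)

    def observe(self, a_other):
        s_mu = sigmoid(self.mu)
        self.var = 1.0 / (1.0 / (self.var + self.vol) + s_mu * (1.0 - s_mu))
        self.mu = self.mu + self.var * (a_other - s_mu)


# ---------------------------------------------------------------------------
# k-ToM (k >= 1): recursive meta-Bayesian belief updating
# ---------------------------------------------------------------------------


def _sym(S):
    return 0.5 * (S + np.swapaxes(S, -1, -2))


def _inv3(S):
    """Adjugate inverse of batched symmetric 3x3 matrices, with PD guard."""
    a, b, c = S[..., 0, 0], S[..., 0, 1], S[..., 0, 2]
    d, e, f = S[..., 1, 1], S[..., 1, 2], S[..., 2, 2]
    A = d * f - e * e
    B = c * e - b * f
    C = b * e - c * d
    det = a * A + b * B + c * C
    if np.any(~np.isfinite(det)) or np.any(det <= 0) or np.any(a <= 0):
        raise np.linalg.LinAlgError(
            "belief covariance is not positive definite (degenerate 3x3 "
            "hidden-state covariance)"
        )
    out = np.empty_like(S)
    out[..., 0, 0] = A / det
    out[..., 0, 1] = out[..., 1, 0] = B / det
    out[..., 0, 2] = out[..., 2, 0] = C / det
    out[..., 1, 1] = (a * f - c * c) / det
    out[..., 1, 2] = out[..., 2, 1] = (b * c - a * e) / det
    out[..., 2, 2] = (a * d - b * b) / det
    return out


def _laplace_step(m, S, W, v_c, lam_k, a_op):
    """Level-weighted Laplace measurement update of a Gaussian hidden-state
    belief from one observed binary opponent action.

    The update adds a rank-1 term to the precision, so the covariance is
    refreshed by the Sherman-Morrison identity (no matrix inversion) and
    stays positive definite by construction.
    """
    s_v = sigmoid(v_c)
    sp = s_v * (1.0 - s_v)
    c = sp * lam_k
    u = np.einsum("...ij,...j->...i", S, W)
    denom = 1.0 + c * np.einsum("...i,...i->...", W, u)
    S_new = S - (c / denom)[..., None, None] * u[..., :, None] * u[..., None, :]
    if np.any(np.diagonal(S_new, axis1=-2, axis2=-1) <= 0):
        raise np.linalg.LinAlgError(
            "belief covariance degenerated during the Laplace update"
        )
    gain = u / denom[..., None]
    m_new = m + (lam_k * (a_op - s_v))[..., None] * gain
    return m_new, S_new


#: Volatility inflates only the opponent-belief component of the hidden
#: states; the opponent's parameters (log sigma, log beta) are static, so
#: their uncertainty shrinks as evidence accumulates.  Diffusing them as
#: well creates an absorbing "the opponent is pure noise" estimate
#: (beta_op -> inf zeroes the observation gradient permanently).
_B_DIFF = np.diag([1.0, 0.0, 0.0])


def _safe_exp(x):
    return np.exp(np.clip(x, -_LOG_STATE_MAX, _LOG_STATE_MAX))


class _OpponentAs0Tom:
    """Sub-model kappa = 0: the opponent is a 0-ToM tracker of my actions.

    Hidden states x = (b, log sigma_op, log beta_op): the modeled opponent's
    belief log-odds ``b`` about my next action, and its transformed
    volatility and temperature.  ``V`` (the modeled opponent's own posterior
    variance) is an auxiliary quantity propagated at the posterior mean.
    The evolution function is the opponent's own learning rule; its Jacobian
    and the observation gradient W are obtained by central finite
    differences with step FD_STEP.
    """

    dim = 3

    def __init__(self, batch_shape, opp_table: PayoffTable):
        self.m = np.zeros(batch_shape + (3,))
        self.S = np.broadcast_to(np.eye(3), batch_shape + (3, 3)).copy()
        self.V = np.ones(batch_shape)
        self.opp_table = opp_table

    def clone(self):
        new = object.__new__(_OpponentAs0Tom)
        new.m = self.m.copy()
        new.S = self.S.copy()
        new.V = self.V.copy()
        new.opp_table = self.opp_table
        return new

    def stack(self, n):
        """Replicate the state n times along a new leading axis."""
        new = object.__new__(_OpponentAs0Tom)
        new.m = np.broadcast_to(self.m, (n,) + self.m.shape).copy()
        new.S = np.broadcast_to(self.S, (n,) + self.S.shape).copy()
        new.V = np.broadcast_to(self.V, (n,) + self.V.shape).copy()
        new.opp_table = self.opp_table
        return new

    def islice(self, i):
        new = object.__new__(_OpponentAs0Tom)
        new.m = self.m[i].copy()
        new.S = self.S[i].copy()
        new.V = self.V[i].copy()
        new.opp_table = self.opp_table
        return new

    def _v(self, b, t2):
        """Opponent action logit as a function of hidden states."""
        p_me = sigmoid(b / np.sqrt(1.0 + MOMENT_A * self.V))
        dv = self.opp_table.value_difference(p_me)
        return np.clip(dv / _safe_exp(t2), -_LOGIT_MAX, _LOGIT_MAX)

    def compute(self):
        """(v_c, W, p) at the current posterior mean.

        The observation gradient W has closed forms: the chain rule through
        the moment-matched sigmoid for the belief component, and -v for the
        log-temperature component (v is proportional to 1/beta); both vanish
        where the logit is clamped.
        """
        b, t2 = self.m[..., 0], self.m[..., 2]
        scale = np.sqrt(1.0 + MOMENT_A * self.V)
        p_me = sigmoid(b / scale)
        dv = self.opp_table.value_difference(p_me)
        raw = dv / _safe_exp(t2)
        v_c = np.clip(raw, -_LOGIT_MAX, _LOGIT_MAX)
        live = (np.abs(raw) < _LOGIT_MAX).astype(float)
        slope = self.opp_table.dv_slope
        dv_db = live * slope * p_me * (1.0 - p_me) / scale / _safe_exp(t2)
        dv_dt2 = -live * v_c
        W = np.stack([dv_db, np.zeros_like(v_c), dv_dt2], axis=-1)
        q = np.einsum("...i,...ij,...j->...", W, self.S, W)
        p = clamp_prob(sigmoid(v_c / np.sqrt(1.0 + MOMENT_A * q)))
        return v_c, W, p

    def measurement(self, a_op, lam_k, cache):
        v_c, W, _ = cache
        self.m, self.S = _laplace_step(self.m, self.S, W, v_c, lam_k, a_op)

    def _f(self, b, t1, a_self):
        """One step of the modeled opponent's learning rule (Eq-3 style)."""
        sig = _safe_exp(t1)
        sb = sigmoid(b)
        V_new = 1.0 / (1.0 / (self.V + sig) + sb * (1.0 - sb))
        b_new = b + V_new * (a_self - sb)
        return b_new, V_new

    def evolve(self, a_self, vol):
        b, t1 = self.m[..., 0], self.m[..., 1]
        bs = np.stack([b, b + FD_STEP, b - FD_STEP, b, b])
        ts = np.stack([t1, t1, t1, t1 + FD_STEP, t1 - FD_STEP])
        bn, Vn = self._f(bs, ts, a_self)
        b_new, V_new = bn[0], Vn[0]
        db_db = (bn[1] - bn[2]) / (2 * FD_STEP)
        db_dt1 = (bn[3] - bn[4]) / (2 * FD_STEP)
        J = np.broadcast_to(np.eye(3), self.S.shape).copy()
        J[..., 0, 0] = db_db
        J[..., 0, 1] = db_dt1
        S = np.einsum("...ij,...jk,...lk->...il", J, self.S, J)
        self.S = _sym(S) + vol[..., None, None] * _B_DIFF
        self.m = self.m.copy()
        self.m[..., 0] = b_new
        self.V = V_new


class _OpponentAs1Tom:
    """Sub-model kappa = 1: the opponent is a 1-ToM learner.

    Hidden states x = (b, log sigma1, log beta_op) where ``b`` is the nested
    1-ToM opponent's own belief log-odds about my actions (the bottom of its
    recursion) and sigma1/beta_op are its volatility and temperature.  The
    remaining internal quantities of the nested 1-ToM machine (covariances,
    its parameter estimates of me) are propagated deterministically at the
    posterior mean; ``b`` is kept in sync with the filtered estimate.
    """

    dim = 3

    def __init__(self, batch_shape, my_table: PayoffTable, opp_table: PayoffTable):
        self.m = np.zeros(batch_shape + (3,))
        self.S = np.broadcast_to(np.eye(3), batch_shape + (3, 3)).copy()
        self.opp_table = opp_table
        # the simulated opponent: a 1-ToM machine playing the other role
        self.nested = KtomMachine(
            1, batch_shape, vol=1.0, beta=1.0, own_table=opp_table, opp_table=my_table
        )

    def clone(self):
        new = object.__new__(_OpponentAs1Tom)
        new.m = self.m.copy()
        new.S = self.S.copy()
        new.opp_table = self.opp_table
        new.nested = self.nested.clone()
        return new

    def stack(self, n):
        new = object.__new__(_OpponentAs1Tom)
        new.m = np.broadcast_to(self.m, (n,) + self.m.shape).copy()
        new.S = np.broadcast_to(self.S, (n,) + self.S.shape).copy()
        new.opp_table = self.opp_table
        new.nested = self.nested.stack(n)
        return new

    def islice(self, i):
        new = object.__new__(_OpponentAs1Tom)
        new.m = self.m[i].copy()
        new.S = self.S[i].copy()
        new.opp_table = self.opp_table
        new.nested = self.nested.islice(i)
        return new

    def compute(self):
        """(v_c, W, p) at the current posterior mean.

        The belief component of the hidden states is kept in sync with the
        nested machine's own bottom-level belief, so the nested 1-ToM's
        prediction of my action (with its internal gradient) chains directly
        into the opponent-action logit.
        """
        t2 = self.m[..., 2]
        v0_c, W0, p_me = self.nested.subs[0].compute()
        q0 = np.einsum(
            "...i,...ij,...j->...", W0, self.nested.subs[0].S, W0
        )
        dv = self.opp_table.value_difference(p_me)
        raw = dv / _safe_exp(t2)
        v_c = np.clip(raw, -_LOGIT_MAX, _LOGIT_MAX)
        live = (np.abs(raw) < _LOGIT_MAX).astype(float)
        # d p_me / d b chains through the nested moment-matched sigmoid
        dp_db = p_me * (1.0 - p_me) * W0[..., 0] / np.sqrt(1.0 + MOMENT_A * q0)
        dv_db = live * self.opp_table.dv_slope * dp_db / _safe_exp(t2)
        dv_dt2 = -live * v_c
        W = np.stack([dv_db, np.zeros_like(v_c), dv_dt2], axis=-1)
        q = np.einsum("...i,...ij,...j->...", W, self.S, W)
        p = clamp_prob(sigmoid(v_c / np.sqrt(1.0 + MOMENT_A * q)))
        return v_c, W, p

    def measurement(self, a_op, lam_k, cache):
        v_c, W, _ = cache
        self.m, self.S = _laplace_step(self.m, self.S, W, v_c, lam_k, a_op)

    def evolve(self, a_self, a_op, vol):
        # commit the filtered belief and volatility into the nested machine
        sub = self.nested.subs[0]
        sub.m[..., 0] = self.m[..., 0]
        self.nested.vol = _safe_exp(self.m[..., 1])

        # one stacked step evaluates b +/- h and the center simultaneously
        m3 = self.nested.stack(3)
        pert = np.array([FD_STEP, -FD_STEP, 0.0]).reshape(
            (3,) + (1,) * self.m[..., 0].ndim
        )
        m3.subs[0].m[..., 0] = m3.subs[0].m[..., 0] + pert
        # the nested machine is the opponent: swap action perspectives
        m3.observe(a_op, a_self)
        b3 = m3.subs[0].m[..., 0]
        self.nested = m3.islice(2)
        b_new = b3[2]
        db_db = (b3[0] - b3[1]) / (2 * FD_STEP)
        J = np.broadcast_to(np.eye(3), self.S.shape).copy()
        J[..., 0, 0] = db_db
        S = np.einsum("...ij,...jk,...lk->...il", J, self.S, J)
        self.S = _sym(S) + vol[..., None, None] * _B_DIFF
        self.m = self.m.copy()
        self.m[..., 0] = b_new


class KtomMachine:
    """Recursive belief state of a k-ToM learner (k in {1, 2}), batched.

    A k-ToM agent entertains one sub-model per possible opponent
    sophistication level kappa < k.  Each sub-model filters a Gaussian
    belief ``(m, S)`` over the opponent's hidden states: its current belief
    log-odds about my own actions plus its transformed volatility and
    temperature (``log sigma_op``, ``log beta_op``).  The evolution function
    of each filter is the modeled opponent's own learning rule; the
    observation mapping ``v^kappa`` is the modeled opponent's action logit,
    with gradient ``W^kappa`` taken by central finite differences.

    ``level_post`` (lambda) is the posterior over opponent levels, updated
    by Bayes rule from each sub-model's prediction of the observed action;
    the hidden-state updates are level-weighted (lambda appears inside both
    the mean and covariance updates).

    ``own_table`` is the payoff table this agent maximizes; ``opp_table``
    the table it attributes to its opponent (competitive hider vs
    cooperative partner); nested machines swap the two.
    """

    def __init__(
        self,
        level: int,
        batch_shape=(),
        vol=0.5,
        beta=1.0,
        own_table: PayoffTable | None = None,
        opp_table: PayoffTable | None = None,
    ):
        if not 1 <= level <= 2:
            raise ValueError("k-ToM implemented for k in {1, 2}")
        self.level = level
        self.batch_shape = tuple(batch_shape)
        self.vol = np.broadcast_to(np.asarray(vol, dtype=float), batch_shape).copy()
        self.beta = np.broadcast_to(np.asarray(beta, dtype=float), batch_shape).copy()
        self.own_table = own_table or PayoffTable.hide_and_seek("seeker")
        self.opp_table = opp_table or PayoffTable.hide_and_seek("hider")
        self.lam = np.full(batch_shape + (level,), 1.0 / level)
        self.subs = [_OpponentAs0Tom(self.batch_shape, self.opp_table)]
        if level == 2:
            self.subs.append(
                _OpponentAs1Tom(self.batch_shape, self.own_table, self.opp_table)
            )
        self._cache = None

    def clone(self):
        new = object.__new__(KtomMachine)
        new.level = self.level
        new.batch_shape = self.batch_shape
        new.vol = self.vol.copy()
        new.beta = self.beta.copy()
        new.own_table = self.own_table
        new.opp_table = self.opp_table
        new.lam = self.lam.copy()
        new.subs = [s.clone() for s in self.subs]
        new._cache = None
        return new

    def stack(self, n):
        """Replicate the whole machine n times along a new leading axis."""
        new = object.__new__(KtomMachine)
        new.level = self.level
        new.batch_shape = (n,) + self.batch_shape
        new.vol = np.broadcast_to(self.vol, (n,) + self.vol.shape).copy()
        new.beta = np.broadcast_to(self.beta, (n,) + self.beta.shape).copy()
        new.own_table = self.own_table
        new.opp_table = self.opp_table
        new.lam = np.broadcast_to(self.lam, (n,) + self.lam.shape).copy()
        new.subs = [s.stack(n) for s in self.subs]
        new._cache = None
        return new

    def islice(self, i):
        new = object.__new__(KtomMachine)
        new.level = self.level
        new.batch_shape = self.batch_shape
        new.vol = self.vol[i].copy()
        new.beta = self.beta[i].copy()
        new.own_table = self.own_table
        new.opp_table = self.opp_table
        new.lam = self.lam[i].copy()
        new.subs = [s.islice(i) for s in self.subs]
        new._cache = None
        return new

    # -- spec-facing views -------------------------------------------------
    @property
    def level_post(self):
        return self.lam

    @property
    def state_mean(self):
        return [s.m for s in self.subs]

    @property
    def state_cov(self):
        return [s.S for s in self.subs]

    def set_params(self, vol, beta):
        self.vol = np.broadcast_to(np.asarray(vol, dtype=float), self.batch_shape).copy()
        self.beta = np.broadcast_to(np.asarray(beta, dtype=float), self.batch_shape).copy()

    # -- prediction ---------------------------------------------------------
    def _compute(self):
        caches = [sub.compute() for sub in self.subs]
        p_op = sum(self.lam[..., k] * caches[k][2] for k in range(self.level))
        self._cache = (caches, p_op)
        return self._cache

    def predict(self):
        """Predicted P(opponent plays 1) on the next trial."""
        if self._cache is None:
            self._compute()
        return self._cache[1]

    def predict_fresh(self):
        """predict() without touching the per-trial cache (used for
        finite-difference evaluations of nested machines)."""
        caches = [sub.compute() for sub in self.subs]
        return sum(self.lam[..., k] * caches[k][2] for k in range(self.level))

    def act_logit(self):
        """This agent's own (bias-free) action logit dV / beta."""
        return self.own_table.value_difference(self.predict()) / self.beta

    # -- learning -----------------------------------------------------------
    def observe(self, a_self, a_op):
        """Digest one trial (own action ``a_self``, opponent ``a_op``)."""
        if self._cache is None:
            self._compute()
        caches, _ = self._cache

        # (i) Bayes update of the opponent-level posterior
        like = [a_op * c[2] + (1 - a_op) * (1.0 - c[2]) for c in caches]
        lam_new = self.lam * np.stack(like, axis=-1)
        self.lam = lam_new / np.sum(lam_new, axis=-1, keepdims=True)

        # (ii) level-weighted Laplace update of each sub-model's states,
        # (iii) deterministic propagation of the modeled opponents
        for kappa, sub in enumerate(self.subs):
            lam_k = self.lam[..., kappa]
            sub.measurement(a_op, lam_k, caches[kappa])
            if kappa == 0:
                sub.evolve(a_self, self.vol)
            else:
                sub.evolve(a_self, a_op, self.vol)
        self._cache = None


def ktom_update(b: KtomMachine, a_self, a_op) -> KtomMachine:
    """Functional one-trial update of a k-ToM belief state.

    Returns a new belief; the input is left untouched.  The payoff tables
    and temperature live inside the belief state (set at construction).
    """
    new = b.clone()
    new.observe(a_self, a_op)
    return new


# ---------------------------------------------------------------------------
# influence learning (proto-ToM)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InfluenceState:
    """State of the influence learner: tracked opponent action probability
    ``p_op`` plus its fixed parameters.

    ``eta`` weighs the prediction error, ``lam`` the influence adjustment
    (how much the learner discounts the shift its own action induces in the
    opponent's strategy), ``beta_inf`` the temperature inside the adjustment
    and ``i_comp`` flags a competitive (1) vs cooperative (0) reading of the
    interaction.
    """

    p_op: float = 0.5
    eta: float = 0.5
    lam: float = 0.5
    beta_inf: float = 1.0
    i_comp: int = 1

    def __post_init__(self):
        if not (0.0 < self.p_op < 1.0):
            raise ValueError("p_op must lie strictly inside (0, 1)")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


def _influence_step(p_op, eta, lam, beta_inf, i_comp, a_self, a_op):
    adj = p_op * (1.0 - p_op) * (
        2.0 * a_self + (2.0 * i_comp - 1.0) * beta_inf * logit(p_op) + i_comp
    )
    p_new = p_op + eta * (a_op - p_op) - lam * adj
    return clamp_prob(p_new)


def influence_update(st: InfluenceState, a_self, a_op) -> InfluenceState:
    """Delta-rule update with the heuristic influence adjustment, clamped."""
    p_new = _influence_step(
        st.p_op, st.eta, st.lam, st.beta_inf, st.i_comp, a_self, a_op
    )
    return replace(st, p_op=float(p_new))


class InfluenceMachine:
    """Batched influence learner."""

    def __init__(self, batch_shape=(), eta=0.5, lam=0.5, beta_inf=1.0, i_comp=1):
        self.p_op = np.full(batch_shape, 0.5)
        self.eta = np.broadcast_to(np.asarray(eta, float), batch_shape).copy()
        self.lam = np.broadcast_to(np.asarray(lam, float), batch_shape).copy()
        self.beta_inf = np.broadcast_to(np.asarray(beta_inf, float), batch_shape).copy()
        self.i_comp = i_comp

    def predict(self):
        return self.p_op

    def observe(self, a_self, a_op):
        self.p_op = _influence_step(
            self.p_op, self.eta, self.lam, self.beta_inf, self.i_comp, a_self, a_op
        )


# ---------------------------------------------------------------------------
# value-based heuristics: RL and win-stay/lose-switch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QValues:
    """Option values and learning rate for the RL / WS rules."""

    v: tuple = (0.0, 0.0)
    alpha: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("learning rate alpha must lie in [0, 1]")


def rl_update(q: QValues, a_self, reward) -> QValues:
    """Rescorla-Wagner: chosen option moves towards the reward."""
    v = list(q.v)
    v[a_self] = v[a_self] + q.alpha * (reward - v[a_self])
    return replace(q, v=tuple(v))


def ws_update(q: QValues, a_self, reward) -> QValues:
    """Win-stay/lose-switch: chosen value <- R, unchosen <- -R."""
    v = [0.0, 0.0]
    v[a_self] = reward
    v[1 - a_self] = -reward
    return replace(q, v=tuple(v))


class QMachine:
    """Batched option-value learner (rule 'rl' or 'ws')."""

    def __init__(self, batch_shape=(), rule="rl", alpha=0.5):
        self.v0 = np.zeros(batch_shape)
        self.v1 = np.zeros(batch_shape)
        self.alpha = np.broadcast_to(np.asarray(alpha, float), batch_shape).copy()
        self.rule = rule

    def value_difference(self):
        return self.v1 - self.v0

    def observe(self, a_self, reward):
        # arithmetic in the (possibly batched) action so that parallel
        # replays of several sessions can share one update
        if self.rule == "rl":
            self.v1 = self.v1 + a_self * self.alpha * (reward - self.v1)
            self.v0 = self.v0 + (1 - a_self) * self.alpha * (reward - self.v0)
        else:  # win-stay/lose-switch: chosen <- R, unchosen <- -R
            sign = 2 * a_self - 1
            self.v1 = np.broadcast_to(sign * reward, np.shape(self.v1)).astype(float)
            self.v0 = -self.v1


# ---------------------------------------------------------------------------
# uniform agent interface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgentSpec:
    """A model identity plus its (natural-scale) parameters and game role.

    ``params`` keys by model: BN: bias; WS: beta, bias; RL: alpha, beta,
    bias; 0ToM: sigma, beta, bias; Inf-*: eta, lam, beta, bias (optional
    beta_inf, defaulting to beta); 1ToM-*/2ToM-*: sigma, beta, bias.
    """

    model_id: str
    params: dict = field(default_factory=dict)
    role: str = "seeker"

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.role not in ("seeker", "hider"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def cooperative(self) -> bool:
        return self.model_id.endswith("-coop")


def _tables_for(spec: AgentSpec):
    """(own_table, assumed opponent table) for a given spec."""
    own = PayoffTable.hide_and_seek(spec.role)
    if spec.cooperative:
        own = PayoffTable.cooperative()
        opp = PayoffTable.cooperative()
    else:
        opp = PayoffTable.hide_and_seek("hider" if spec.role == "seeker" else "seeker")
    return own, opp


class Agent:
    """Stateful wrapper running any of the ten models trial by trial."""

    def __init__(self, spec: AgentSpec, batch_shape=()):
        self.spec = spec
        p = dict(spec.params)
        self.policy = PolicyParams(beta=float(p.get("beta", 1.0)), bias=float(p.get("bias", 0.0)))
        self.own_table, self.opp_table = _tables_for(spec)
        mid = spec.model_id
        if mid == "BN":
            self.machine = None
        elif mid in ("WS", "RL"):
            self.machine = QMachine(
                batch_shape, rule=mid.lower(), alpha=p.get("alpha", 1.0)
            )
        elif mid == "0ToM":
            self.machine = Tom0Machine(batch_shape, vol=p.get("sigma", 0.5))
        elif mid.startswith("Inf"):
            self.machine = InfluenceMachine(
                batch_shape,
                eta=p.get("eta", 0.5),
                lam=p.get("lam", 0.5),
                beta_inf=p.get("beta_inf", self.policy.beta),
                i_comp=0 if spec.cooperative else 1,
            )
        else:
            level = int(mid[0])
            self.machine = KtomMachine(
                level,
                batch_shape,
                vol=p.get("sigma", 0.5),
                beta=self.policy.beta,
                own_table=self.own_table,
                opp_table=self.opp_table,
            )

    def value_difference(self):
        mid = self.spec.model_id
        if mid == "BN":
            return 0.0
        if mid in ("WS", "RL"):
            return self.machine.value_difference()
        # prediction-based models
        return self.own_table.value_difference(self.machine.predict())

    def prob(self):
        """P(a_self = 1) on the upcoming trial."""
        return softmax_policy(self.value_difference(), self.policy)

    def observe(self, a_self: int, a_op: int):
        """Digest one completed trial."""
        mid = self.spec.model_id
        if mid == "BN":
            return
        if mid in ("WS", "RL"):
            self.machine.observe(a_self, self.own_table.reward(a_self, a_op))
        elif mid == "0ToM":
            self.machine.observe(a_op)
        elif mid.startswith("Inf"):
            self.machine.observe(a_self, a_op)
        else:
            self.machine.observe(a_self, a_op)

    def act(self, rng_draw: float) -> int:
        return int(rng_draw < np.asarray(self.prob()))


def agent_step(
    spec: AgentSpec,
    internal_state,
    last_a_self,
    last_a_op,
    last_reward,
    rng_draw: float,
):
    """Uniform observe -> act step: returns ``(action, new_state)``.

    ``internal_state`` is ``None`` on the first trial.  ``last_reward`` is
    the binary win indicator of the previous trial; it is checked for
    consistency with the action pair under the agent's game role.
    """
    if internal_state is None:
        state = Agent(spec)
    else:
        state = internal_state
    if last_a_self is not None:
        if last_reward is not None:
            won = state.own_table.reward(last_a_self, last_a_op) > 0
            if bool(last_reward) != won:
                raise ValueError(
                    "recorded reward is inconsistent with the action pair "
                    "under this agent's payoff table"
                )
        state.observe(int(last_a_self), int(last_a_op))
    action = state.act(rng_draw)
    return action, state
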