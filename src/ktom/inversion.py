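"""Variational-Laplace model inversion of trial-by-trial choice sequences.

Each candidate model defines a deterministic mapping from (transformed)
parameters to a sequence of per-trial choice probabilities; the observed
choices are Bernoulli draws from that sequence.  Fitting maximizes the
log-joint (Bernoulli log-likelihood + Gaussian prior) by a damped
Gauss-Newton scheme whose curvature comes from the standard logistic
generalized-linear-model approximation, and reports the Laplace free energy

    F = log p(a | theta*) + log p(theta*) + (d/2) log 2pi + 1/2 log det S*

as the model log-evidence.  Parameters with positivity constraints (sigma,
beta, lam) are fitted on the log scale, rates (alpha, eta) on the logit
scale, and biases on the natural scale.  Sessions of one opponent condition
are pooled (shared parameters, state reset at each session boundary).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import (
    MODEL_IDS,
    AgentSpec,
    InfluenceMachine,
    KtomMachine,
    QMachine,
    Tom0Machine,
    _tables_for,
)
from .arena import CONDITIONS, SessionRecord
from .core import bernoulli_loglik, clamp_prob, sigmoid

__all__ = [
    "MODEL_PARAMS",
    "PriorSpec",
    "FitResult",
    "FitOptions",
    "default_prior",
    "to_natural",
    "predict_choice_probs",
    "choice_log_likelihood",
    "laplace_logistic_fit",
    "fit_condition",
    "evidence_matrix",
]

#: Transformed parameterization per model: (name, transform) with transform
#: one of 'log', 'logit', 'id'.  BN's temperature is non-identifiable at
#: dV = 0 and is therefore not fitted.
MODEL_PARAMS = {
    "BN": (("bias", "id"),),
    "WS": (("beta", "log"), ("bias", "id")),
    "RL": (("alpha", "logit"), ("beta", "log"), ("bias", "id")),
    "0ToM": (("sigma", "log"), ("beta", "log"), ("bias", "id")),
    "Inf-coop": (("eta", "logit"), ("lam", "log"), ("beta", "log"), ("bias", "id")),
    "Inf-comp": (("eta", "logit"), ("lam", "log"), ("beta", "log"), ("bias", "id")),
    "1ToM-coop": (("sigma", "log"), ("beta", "log"), ("bias", "id")),
    "1ToM-comp": (("sigma", "log"), ("beta", "log"), ("bias", "id")),
    "2ToM-coop": (("sigma", "log"), ("beta", "log"), ("bias", "id")),
    "2ToM-comp": (("sigma", "log"), ("beta", "log"), ("bias", "id")),
}

#: Prior variance by transform kind.
_PRIOR_VAR = {"log": 3.0, "logit": 3.0, "id": 10.0}


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian prior over the transformed parameters."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        object.__setattr__(
            self, "variance", np.atleast_1d(np.asarray(self.variance, float))
        )
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean/variance dimension mismatch")
        if np.any(self.variance <= 0):
            raise ValueError("prior variances must be positive")

    @property
    def dim(self) -> int:
        return self.mean.size

    def logpdf(self, theta):
        theta = np.asarray(theta, float)
        z = (theta - self.mean) ** 2 / self.variance
        return -0.5 * np.sum(z + np.log(2 * np.pi * self.variance), axis=-1)


def default_prior(model_id: str) -> PriorSpec:
    """Weakly informative prior: N(0, 3) on log/logit scales, N(0, 10) on
    biases."""
    kinds = [k for _, k in MODEL_PARAMS[model_id]]
    return PriorSpec(
        mean=np.zeros(len(kinds)), variance=np.array([_PRIOR_VAR[k] for k in kinds])
    )


def to_natural(model_id: str, theta) -> dict:
    """Map a transformed parameter vector to named natural-scale values."""
    theta = np.asarray(theta, float)
    out = {}
    for i, (name, kind) in enumerate(MODEL_PARAMS[model_id]):
        val = theta[..., i]
        if kind == "log":
            val = np.exp(np.clip(val, -30, 30))
        elif kind == "logit":
            val = sigmoid(val)
        out[name] = val
    return out


@dataclass
class FitResult:
    """Gaussian posterior summary of one condition-level fit."""

    post_mean: np.ndarray
    post_cov: np.ndarray
    free_energy: float
    n_trials: int
    converged: bool
    f_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def post_sd(self):
        return np.sqrt(np.diag(self.post_cov))


@dataclass(frozen=True)
class FitOptions:
    """Numerical controls of the Gauss-Newton scheme."""

    tol: float = 1e-3
    max_iter: int = 64
    n_starts: int = 4
    fd_step: float = 1e-3
    init_seed: int = 20170
    init_scale: float = 0.8


# ---------------------------------------------------------------------------
# batched forward predictions
# ---------------------------------------------------------------------------


def _replay(model_id: str, nat: dict, batch: tuple, sessions) -> np.ndarray:
    """Choice-probability sequences (batch + (T_total,)) for pooled sessions.

    Sessions of equal length are replayed in parallel along a trailing
    batch axis (they share parameters but not state), so the trial loop
    runs once per session length rather than once per session.
    """
    own_table, _ = _tables_for(AgentSpec(model_id, {}, role="seeker"))
    out = [None] * len(sessions)
    groups: dict = {}
    for i, s in enumerate(sessions):
        groups.setdefault(len(s), []).append(i)
    for T, idxs in groups.items():
        k = len(idxs)
        bshape = batch + (k,)

        def expand(x):
            return np.broadcast_to(np.asarray(x, float)[..., None], bshape)

        beta = expand(nat.get("beta", 1.0))
        bias = expand(nat.get("bias", 0.0))
        if model_id == "BN":
            probs = np.broadcast_to(
                np.asarray(sigmoid(bias))[..., None], bshape + (T,)
            ).copy()
        else:
            if model_id in ("WS", "RL"):
                mach = QMachine(
                    bshape, rule=model_id.lower(), alpha=expand(nat.get("alpha", 1.0))
                )
            elif model_id == "0ToM":
                mach = Tom0Machine(bshape, vol=expand(nat["sigma"]))
            elif model_id.startswith("Inf"):
                mach = InfluenceMachine(
                    bshape,
                    eta=expand(nat["eta"]),
                    lam=expand(nat["lam"]),
                    beta_inf=beta,
                    i_comp=0 if model_id.endswith("coop") else 1,
                )
            else:
                spec = AgentSpec(model_id, {}, role="seeker")
                own, opp = _tables_for(spec)
                mach = KtomMachine(
                    int(model_id[0]),
                    bshape,
                    vol=expand(nat["sigma"]),
                    beta=beta,
                    own_table=own,
                    opp_table=opp,
                )
            A_s = np.stack([sessions[i].a_self for i in idxs])  # (k, T)
            A_o = np.stack([sessions[i].a_op for i in idxs])
            R = own_table.u[A_s, A_o]
            probs = np.empty(bshape + (T,))
            for t in range(T):
                if model_id in ("WS", "RL"):
                    logits = mach.value_difference() / beta + bias
                elif model_id.startswith(("1ToM", "2ToM")):
                    logits = mach.act_logit() + bias
                else:
                    dv = own_table.value_difference(mach.predict())
                    logits = dv / beta + bias
                probs[..., t] = sigmoid(logits)
                a_s, a_o = A_s[:, t], A_o[:, t]
                if model_id in ("WS", "RL"):
                    mach.observe(a_s, R[:, t])
                elif model_id == "0ToM":
                    mach.observe(a_o)
                else:
                    mach.observe(a_s, a_o)
        for j, i in enumerate(idxs):
            out[i] = probs[..., j, :]
    return np.concatenate(out, axis=-1)


def predict_choice_probs(model_id: str, theta, sessions) -> np.ndarray:
    """Per-trial P(a_self = 1) under a model, batched over parameter rows.

    ``theta`` has shape (..., d) on the transformed scale; the return value
    has shape (..., T_total) with sessions concatenated in order (internal
    state resets at every session boundary).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    theta = np.asarray(theta, float)
    nat = to_natural(model_id, theta)
    return _replay(model_id, nat, theta.shape[:-1], sessions)


def choice_log_likelihood(model_id: str, params, sessions) -> float:
    """Summed Bernoulli log-likelihood of the observed choices."""
    conds = {s.condition for s in sessions}
    if len(conds) > 1:
        raise ValueError("sessions must share one opponent condition")
    probs = predict_choice_probs(model_id, np.atleast_1d(params), sessions)
    if not np.all(np.isfinite(probs)):
        bad = int(np.argmax(~np.isfinite(np.ravel(probs))))
        raise FloatingPointError(f"non-finite choice probability at trial {bad}")
    a = np.concatenate([s.a_self for s in sessions])
    return float(np.sum(bernoulli_loglik(probs, a)))


# ---------------------------------------------------------------------------
# damped Gauss-Newton Laplace fitter
# ---------------------------------------------------------------------------


def laplace_logistic_fit(
    predict_fn,
    a: np.ndarray,
    prior: PriorSpec,
    opts: FitOptions = FitOptions(),
    inits: np.ndarray | None = None,
) -> FitResult:
    """Gaussian posterior for a Bernoulli observation model.

    ``predict_fn(theta)`` maps a batch (P, d) of transformed parameter
    vectors to choice probabilities (P, T).  The posterior mode is found by
    damped Gauss-Newton on the log-joint, run from several fixed starting
    points in parallel; a step is accepted only if the Laplace free energy
    does not decrease, which makes each start's free-energy trace monotone
    by construction.  The best start by final free energy is returned.
    """
    a = np.asarray(a, float)
    d = prior.dim
    h = opts.fd_step
    if inits is None:
        rng = np.random.default_rng(opts.init_seed)
        pert = rng.standard_normal((max(opts.n_starts - 1, 0), d))
        inits = np.vstack(
            [prior.mean, prior.mean + opts.init_scale * np.sqrt(prior.variance) * pert]
        )[: opts.n_starts]
    inits = np.atleast_2d(inits)
    n_start = inits.shape[0]
    offsets = np.zeros((2 * d + 1, d))
    for i in range(d):
        offsets[1 + 2 * i, i] = h
        offsets[2 + 2 * i, i] = -h
    prior_prec = np.diag(1.0 / prior.variance)

    def eval_batch(thetas):
        """(loglik, gradient, GN Hessian of the negative log-joint)."""
        pts = thetas[:, None, :] + offsets[None, :, :]  # (S, 2d+1, d)
        probs = clamp_prob(
            predict_fn(pts.reshape(-1, d)).reshape(n_start, 2 * d + 1, -1)
        )
        eta = np.log(probs) - np.log1p(-probs)
        ll = np.sum(bernoulli_loglik(probs[:, 0, :], a), axis=-1)
        g = (eta[:, 1::2, :] - eta[:, 2::2, :]) / (2 * h)  # (S, d, T)
        p0 = probs[:, 0, :]
        grad = np.einsum("st,sdt->sd", a - p0, g) - (
            (thetas - prior.mean) / prior.variance
        )
        wgt = p0 * (1.0 - p0)
        H = np.einsum("st,sit,sjt->sij", wgt, g, g) + prior_prec
        return ll, grad, H

    def free_energy(ll, theta, H):
        sign, logdet = np.linalg.slogdet(H)
        out = ll + prior.logpdf(theta) + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet
        return np.where(sign > 0, out, -np.inf)

    theta = inits.copy()
    ll, grad, H = eval_batch(theta)
    F = free_energy(ll, theta, H)
    damping = np.full(n_start, 1.0)
    traces = [[f] for f in F]
    converged = np.zeros(n_start, bool)
    for _ in range(opts.max_iter):
        if np.all(converged):
            break
        Hd = H + damping[:, None, None] * np.eye(d)
        step = np.linalg.solve(Hd, grad[..., None])[..., 0]
        prop = np.where(converged[:, None], theta, theta + step)
        ll_p, grad_p, H_p = eval_batch(prop)
        F_p = free_energy(ll_p, prop, H_p)
        for s in range(n_start):
            if converged[s]:
                continue
            if F_p[s] >= F[s] - 1e-12:
                if abs(F_p[s] - F[s]) < opts.tol:
                    converged[s] = True
                theta[s], ll[s] = prop[s], ll_p[s]
                grad[s], H[s] = grad_p[s], H_p[s]
                traces[s].append(F_p[s])
                F[s] = F_p[s]
                damping[s] = max(damping[s] / 4.0, 1e-6)
            else:
                damping[s] *= 8.0
                if damping[s] > 1e8:
                    converged[s] = True
    best = int(np.argmax(F))
    cov = np.linalg.inv(H[best])
    cov = 0.5 * (cov + cov.T)
    return FitResult(
        post_mean=theta[best],
        post_cov=cov,
        free_energy=float(F[best]),
        n_trials=int(a.size),
        converged=bool(converged[best] and np.isfinite(F[best])),
        f_trace=np.asarray(traces[best]),
    )


def fit_condition(
    model_id: str,
    sessions,
    prior: PriorSpec | None = None,
    opts: FitOptions = FitOptions(),
) -> FitResult:
    """Fit one model to all (included) sessions of one opponent condition."""
    sessions = [s for s in sessions if s.included]
    if not sessions:
        raise ValueError("no included sessions to fit")
    if len({s.condition for s in sessions}) > 1:
        raise ValueError("sessions must share one opponent condition")
    prior = prior or default_prior(model_id)
    if prior.dim != len(MODEL_PARAMS[model_id]):
        raise ValueError("prior dimension does not match the model")
    a = np.concatenate([s.a_self for s in sessions])

    def predict(thetas):
        return predict_choice_probs(model_id, thetas, sessions)

    return laplace_logistic_fit(predict, a, prior, opts)


def evidence_matrix(
    individuals: dict,
    models=MODEL_IDS,
    priors: dict | None = None,
    opts: FitOptions = FitOptions(),
    return_fits: bool = False,
):
    """Per-individual, per-model log-evidence (free energy summed over the
    three opponent conditions; parameters shared within a condition, free
    across conditions).

    ``individuals`` maps individual_id -> list of SessionRecord.  An
    individual missing an opponent condition is flagged in
    ``result.attrs['excluded']`` and dropped.  Returns a DataFrame
    (individuals x models); with ``return_fits=True`` also a nested dict
    individual -> model -> condition -> FitResult.
    """
    priors = priors or {}
    rows, excluded, fits = {}, [], {}
    for ind, sessions in individuals.items():
        by_cond = {
            c: [s for s in sessions if s.condition == c and s.included]
            for c in CONDITIONS
        }
        if any(len(v) == 0 for v in by_cond.values()):
            excluded.append(ind)
            continue
        row, ind_fits = {}, {}
        for mid in models:
            total, cond_fits = 0.0, {}
            for cond, sess in by_cond.items():
                fr = fit_condition(mid, sess, priors.get(mid, default_prior(mid)), opts)
                total += fr.free_energy
                cond_fits[cond] = fr
            row[mid] = total
            ind_fits[mid] = cond_fits
        rows[ind] = row
        fits[ind] = ind_fits
    em = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(models))
    em.attrs["excluded"] = excluded
    if return_fits:
        return em, fits
    return em
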