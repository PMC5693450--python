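"""Model-free Volterra decomposition of choice sequences.

The current choice is regressed on exponentially weighted histories of both
players' past actions through a Bayesian logistic model:

    q_t = s( w0 + sum_tau w_tau^op (2 a^op_{t-tau} - 1)
                + sum_tau w_tau^self (2 a^self_{t-tau} - 1) ),
    w_tau = A exp(-lambda tau),   tau = 1 .. max_lag.

``A^op`` measures the imitative tendency (impact of the opponent's lagged
actions), ``A^self`` the perseverative tendency (impact of one's own lagged
actions), and the decays lambda set the effective memory.  Kernels are fitted
per session by the same Laplace machinery used for model inversion; early
trials simply use the lags that exist.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import CONDITIONS, SessionRecord, play_session
from .agents import AgentSpec
from .core import sigmoid
from .inversion import FitOptions, FitResult, PriorSpec, laplace_logistic_fit

__all__ = [
    "DEFAULT_MAX_LAG",
    "VolterraKernels",
    "default_volterra_prior",
    "fit_volterra",
    "volterra_accuracy",
    "kernel_similarity",
    "volterra_table",
    "optimal_kernels",
    "OPTIMAL_RESPONDER",
]

#: Default maximum lag; an exponential kernel with lambda >= 0.3 is below 1%
#: of its magnitude beyond 15 trials.
DEFAULT_MAX_LAG = 15


@dataclass
class VolterraKernels:
    """Bias and exponential kernel parameters of one session fit."""

    omega0: float
    a_op: float
    lam_op: float
    a_self: float
    lam_self: float
    max_lag: int = DEFAULT_MAX_LAG
    fit: FitResult | None = None

    def expand(self):
        """(opponent kernel, self kernel) at lags 1..max_lag."""
        tau = np.arange(1, self.max_lag + 1)
        return (
            self.a_op * np.exp(-self.lam_op * tau),
            self.a_self * np.exp(-self.lam_self * tau),
        )

    def predict(self, session: SessionRecord) -> np.ndarray:
        """Fitted per-trial choice probabilities q_t."""
        X_op, X_self = _lag_matrices(session, self.max_lag)
        k_op, k_self = self.expand()
        return sigmoid(self.omega0 + X_op @ k_op + X_self @ k_self)


def _lag_matrices(session: SessionRecord, max_lag: int):
    """Signed lagged-action design matrices (T x max_lag), zero-padded
    where the lag reaches before the session start."""
    T = len(session)
    s_op = 2.0 * session.a_op - 1.0
    s_self = 2.0 * session.a_self - 1.0
    X_op = np.zeros((T, max_lag))
    X_self = np.zeros((T, max_lag))
    for lag in range(1, max_lag + 1):
        X_op[lag:, lag - 1] = s_op[:-lag]
        X_self[lag:, lag - 1] = s_self[:-lag]
    return X_op, X_self


def default_volterra_prior() -> PriorSpec:
    """Prior over (w0, A_op, log lam_op, A_self, log lam_self)."""
    return PriorSpec(
        mean=np.array([0.0, 0.0, np.log(0.5), 0.0, np.log(0.5)]),
        variance=np.array([10.0, 10.0, 1.0, 10.0, 1.0]),
    )


def fit_volterra(
    session: SessionRecord,
    prior: PriorSpec | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    opts: FitOptions = FitOptions(),
    targets=None,
) -> VolterraKernels:
    """Laplace fit of the exponential-kernel logistic model to one session.

    ``targets`` (optional, floats in [0, 1]) replaces the recorded binary
    choices as the regression target; passing the generating probabilities
    fits the model to noiseless data (used for calibration).
    """
    if len(session) <= max_lag + 5:
        raise ValueError("session too short for the requested maximum lag")
    prior = prior or default_volterra_prior()
    a = np.asarray(session.a_self, int) if targets is None else np.asarray(targets, float)
    if a.min() == a.max():
        warnings.warn(
            "constant choice sequence: kernel fit is bias-dominated",
            RuntimeWarning,
            stacklevel=2,
        )
    X_op, X_self = _lag_matrices(session, max_lag)
    tau = np.arange(1, max_lag + 1)

    def predict(theta):
        w0, a_op, llam_op, a_self_, llam_self = (theta[:, i] for i in range(5))
        k_op = np.exp(-np.exp(np.clip(llam_op, -10, 5))[:, None] * tau)
        k_self = np.exp(-np.exp(np.clip(llam_self, -10, 5))[:, None] * tau)
        logits = (
            w0[:, None]
            + a_op[:, None] * (X_op @ k_op.T).T
            + a_self_[:, None] * (X_self @ k_self.T).T
        )
        return sigmoid(logits)

    fr = laplace_logistic_fit(predict, a, prior, opts)
    w0, a_op, llam_op, a_self_, llam_self = fr.post_mean
    return VolterraKernels(
        omega0=float(w0),
        a_op=float(a_op),
        lam_op=float(np.exp(llam_op)),
        a_self=float(a_self_),
        lam_self=float(np.exp(llam_self)),
        max_lag=max_lag,
        fit=fr,
    )


def volterra_accuracy(kernels: VolterraKernels, session: SessionRecord) -> float:
    """Fraction of trials where the fitted q_t, thresholded at 0.5,
    reproduces the recorded choice."""
    q = kernels.predict(session)
    return float(np.mean((q > 0.5).astype(int) == session.a_self))


def kernel_similarity(k1: VolterraKernels, k2: VolterraKernels) -> float:
    """Pearson correlation of the concatenated lag-expanded kernels."""
    if k1.max_lag != k2.max_lag:
        raise ValueError("kernels must share max_lag")
    v1 = np.concatenate(k1.expand())
    v2 = np.concatenate(k2.expand())
    if np.std(v1) == 0 or np.std(v2) == 0:
        warnings.warn(
            "zero-variance kernel: similarity undefined", RuntimeWarning, stacklevel=2
        )
        return float("nan")
    return float(np.corrcoef(v1, v2)[0, 1])


def volterra_table(
    individuals: dict,
    max_lag: int = DEFAULT_MAX_LAG,
    opts: FitOptions = FitOptions(),
) -> pd.DataFrame:
    """Per-session kernel fits for a cohort, one row per included session.

    Session-level parameters are meant to be averaged within individual and
    condition for group-level analyses.
    """
    rows = []
    for ind, sessions in individuals.items():
        for s in sessions:
            if not s.included or len(s) <= max_lag + 5:
                continue
            k = fit_volterra(s, max_lag=max_lag, opts=opts)
            rows.append(
                {
                    "individual_id": ind,
                    "condition": s.condition,
                    "session_index": s.session_index,
                    "omega0": k.omega0,
                    "a_op": k.a_op,
                    "lam_op": k.lam_op,
                    "a_self": k.a_self,
                    "lam_self": k.lam_self,
                }
            )
    return pd.DataFrame(rows)


#: The optimal responder for each opponent condition (one sophistication
#: level above the opponent).
OPTIMAL_RESPONDER = {
    "RB": "0ToM",
    "OTOM": "1ToM-comp",
    "ITOM": "2ToM-comp",
}


def optimal_kernels(
    condition: str,
    n_trials: int = 400,
    n_games: int = 8,
    seed: int = 0,
    sim_params: dict | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
) -> VolterraKernels:
    """Reference kernels of the optimal learning style for a condition.

    Simulates the optimal responder (0-ToM against RB, competitive 1-ToM
    against the 0-ToM hider, competitive 2-ToM against the 1-ToM hider) over
    long games and averages per-game kernel fits.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    sim_params = sim_params or {"sigma": 0.5, "beta": 0.05}
    spec = AgentSpec(OPTIMAL_RESPONDER[condition], sim_params)
    fits = []
    for g in range(n_games):
        rec = play_session(spec, condition, seed=seed + g, n_trials=n_trials)
        fits.append(fit_volterra(rec, max_lag=max_lag))
    return VolterraKernels(
        omega0=float(np.mean([k.omega0 for k in fits])),
        a_op=float(np.mean([k.a_op for k in fits])),
        lam_op=float(np.mean([k.lam_op for k in fits])),
        a_self=float(np.mean([k.a_self for k in fits])),
        lam_self=float(np.mean([k.lam_self for k in fits])),
        max_lag=max_lag,
    )
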