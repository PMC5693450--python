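"""Shared numerical primitives.

All probabilistic machinery in this package funnels through the helpers
below so that clamping and moment-matching conventions are defined in
exactly one place.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

#: Probability clamp applied wherever a probability is inverted through the
#: logit or enters a Bernoulli likelihood.
EPS = 1e-4

#: Logistic-probit moment-matching constant: E[s(x)] under N(mu, v) is
#: approximated by s(mu / sqrt(1 + MOMENT_A * v)).  The logistic distribution
#: has variance pi^2/3, hence a = 3/pi^2.
MOMENT_A = 3.0 / np.pi**2


def sigmoid(x):
    """Numerically safe logistic function."""
    out = expit(np.asarray(x, dtype=float))
    if out.ndim == 0:
        return float(out)
    return out


def logit(p):
    """Inverse sigmoid with clamping to [EPS, 1-EPS]."""
    p = clamp_prob(p)
    return np.log(p) - np.log1p(-p)


def clamp_prob(p, eps: float = EPS):
    """Clamp probabilities away from 0 and 1."""
    return np.clip(p, eps, 1.0 - eps)


def gaussian_sigmoid_mean(mu, var):
    """E[s(x)] for x ~ N(mu, var), via logistic-probit moment matching."""
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    return sigmoid(mu / np.sqrt(1.0 + MOMENT_A * var))


def inv2(m):
    """Closed-form inverse of a batch of 2x2 matrices (shape ... x 2 x 2)."""
    a = m[..., 0, 0]
    b = m[..., 0, 1]
    c = m[..., 1, 0]
    d = m[..., 1, 1]
    det = a * d - b * c
    if np.any(det <= 0):
        raise np.linalg.LinAlgError(
            "2x2 matrix is not positive definite (det <= 0); "
            "belief covariance degenerated"
        )
    out = np.empty_like(np.broadcast_arrays(m)[0], dtype=float)
    out[..., 0, 0] = d / det
    out[..., 0, 1] = -b / det
    out[..., 1, 0] = -c / det
    out[..., 1, 1] = a / det
    return out


def bernoulli_loglik(p, a):
    """a log p + (1-a) log(1-p) with clamped p.

    For binary a this is the Bernoulli log-likelihood; fractional targets
    give the (negative) cross-entropy, used when fitting to noiseless
    probability sequences.
    """
    p = clamp_prob(np.asarray(p, dtype=float))
    a = np.asarray(a, dtype=float)
    return a * np.log(p) + (1.0 - a) * np.log1p(-p)
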