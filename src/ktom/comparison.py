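"""Bayesian model comparison at the subject, family and group level.

Within subject, log-evidences are normalized under a uniform prior over the
ten models and the posterior mass on the ToM family (influence learning and
the recursive 1-/2-ToM learners) gives ``pToM``.  At the group level, a
random-effects scheme treats the generating model as varying across
subjects: a variational Dirichlet-multinomial update yields a posterior
over model frequencies, from which expected frequencies, exceedance
probabilities (the probability that a model is the most frequent) and
protected exceedance probabilities (guarding against the equal-frequency
null) are derived.  Two groups can be compared by the posterior probability
that one group's frequency-weighted mean sophistication rank exceeds the
other's.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .agents import MODEL_IDS, NOTOM_FAMILY, TOM_FAMILY

__all__ = [
    "FamilyPartition",
    "BmsResult",
    "SOPHISTICATION_RANK",
    "ptom",
    "species_ptom",
    "rfx_bms",
    "between_group_bms",
]


@dataclass(frozen=True)
class FamilyPartition:
    """Partition of the ten models into ToM and non-ToM families."""

    tom_family: frozenset = TOM_FAMILY
    notom_family: frozenset = NOTOM_FAMILY

    def __post_init__(self):
        if self.tom_family & self.notom_family:
            raise ValueError("families overlap")
        if self.tom_family | self.notom_family != set(MODEL_IDS):
            raise ValueError("families must partition the ten models")


#: Sophistication ranks used by the between-group comparison; cooperative
#: and competitive variants are tied.
SOPHISTICATION_RANK = {
    "BN": 0,
    "WS": 1,
    "RL": 2,
    "0ToM": 3,
    "Inf-coop": 4,
    "Inf-comp": 4,
    "1ToM-coop": 5,
    "1ToM-comp": 5,
    "2ToM-coop": 6,
    "2ToM-comp": 6,
}


def ptom(
    evidences,
    fp: FamilyPartition = FamilyPartition(),
    family_prior: str = "models",
) -> float:
    """Within-subject posterior probability of a ToM-compatible style.

    ``evidences`` maps model_id -> log-evidence (or a pandas Series).  With
    the default uniform-over-models prior, equal evidences give
    pToM = 6/10; ``family_prior='families'`` instead puts half the prior
    mass on each family.
    """
    ev = pd.Series(
        dict(evidences) if not isinstance(evidences, pd.Series) else evidences
    )
    if set(ev.index) != set(MODEL_IDS):
        raise ValueError("evidences must cover exactly the ten models")
    if not np.all(np.isfinite(ev.to_numpy(dtype=float))):
        raise ValueError("log-evidences must be finite")
    logp = ev.to_numpy(dtype=float).copy()
    models = list(ev.index)
    if family_prior == "families":
        for i, mid in enumerate(models):
            fam = fp.tom_family if mid in fp.tom_family else fp.notom_family
            logp[i] += np.log(0.5 / len(fam))
    elif family_prior != "models":
        raise ValueError("family_prior must be 'models' or 'families'")
    post = np.exp(logp - logsumexp(logp))
    return float(sum(p for p, mid in zip(post, models) if mid in fp.tom_family))


def species_ptom(
    em: pd.DataFrame,
    species_of: dict,
    fp: FamilyPartition = FamilyPartition(),
    family_prior: str = "models",
) -> pd.Series:
    """Species-level pToM: individual family posteriors averaged within
    species."""
    vals = {ind: ptom(em.loc[ind], fp, family_prior) for ind in em.index}
    s = pd.Series(vals, name="ptom")
    return s.groupby(pd.Series({i: species_of[i] for i in s.index})).mean()


@dataclass
class BmsResult:
    """Random-effects model-selection posterior."""

    models: tuple
    dirichlet_alpha: np.ndarray
    exp_freq: np.ndarray
    xp: np.ndarray
    pxp: np.ndarray
    bor: float
    model_post: np.ndarray = field(default_factory=lambda: np.empty(0))

    def as_series(self, what: str = "exp_freq") -> pd.Series:
        return pd.Series(getattr(self, what), index=self.models)


def _rfx_free_energy(L, z, alpha, alpha0):
    """Variational bound of the random-effects model (used for the BOR)."""
    Elogr = digamma(alpha) - digamma(np.sum(alpha))
    F = (
        gammaln(np.sum(alpha0))
        - np.sum(gammaln(alpha0))
        - gammaln(np.sum(alpha))
        + np.sum(gammaln(alpha))
        + np.sum((alpha0 - alpha) * Elogr)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        logz = np.where(z > 0, np.log(z), 0.0)
    F += np.sum(z * (L + Elogr[None, :] - logz))
    return F


def rfx_bms(
    em: pd.DataFrame,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> BmsResult:
    """Random-effects Bayesian model selection.

    ``em`` is the evidence matrix (individuals x models, log scale).  The
    variational update alternates subject-wise model posteriors and
    Dirichlet counts until the Dirichlet parameters stabilize.  Exceedance
    probabilities are estimated from ``n_samples`` Monte-Carlo draws of the
    Dirichlet posterior; protected exceedance probabilities mix with the
    equal-frequency null via the Bayesian omnibus risk (BOR).
    """
    L = em.to_numpy(dtype=float)
    n, K = L.shape
    if n < 2:
        raise ValueError("random-effects comparison needs >= 2 subjects")
    a0 = np.full(K, float(alpha0))
    alpha = a0.copy()
    z = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        logu = L + (digamma(alpha) - digamma(np.sum(alpha)))[None, :]
        z = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = a0 + z.sum(axis=0)
        delta = np.max(np.abs(alpha_new - alpha))
        alpha = alpha_new
        if delta < tol:
            break
    else:
        raise RuntimeError("random-effects BMS did not converge")
    exp_freq = alpha / alpha.sum()

    if n_samples > 0:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=n_samples)
        xp = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_samples
    else:
        xp = np.full(K, np.nan)

    # Bayesian omnibus risk: equal-frequency null vs the random-effects model
    F0 = float(np.sum(logsumexp(L, axis=1) - np.log(K)))
    F1 = float(_rfx_free_energy(L, z, alpha, a0))
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))
    pxp = (1.0 - bor) * xp + bor / K
    return BmsResult(
        models=tuple(em.columns),
        dirichlet_alpha=alpha,
        exp_freq=exp_freq,
        xp=xp,
        pxp=pxp,
        bor=bor,
        model_post=z,
    )


def between_group_bms(
    em_a: pd.DataFrame,
    em_b: pd.DataFrame,
    score: dict | None = None,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """P(group A evolved a more sophisticated learning style than group B).

    Independent Dirichlet posteriors over model frequencies are fitted per
    group; the returned value is the Monte-Carlo posterior probability that
    group A's frequency-weighted mean sophistication rank exceeds group
    B's.  ``score`` maps model_id -> rank (default: the package's
    sophistication ordering with coop/comp variants tied).
    """
    if set(em_a.index) & set(em_b.index):
        raise ValueError("groups must be disjoint")
    if list(em_a.columns) != list(em_b.columns):
        raise ValueError("evidence matrices must share the model set")
    score = score or SOPHISTICATION_RANK
    s = np.array([score[m] for m in em_a.columns], dtype=float)
    res_a = rfx_bms(em_a, alpha0=alpha0, n_samples=0, seed=seed)
    res_b = rfx_bms(em_b, alpha0=alpha0, n_samples=0, seed=seed)
    rng = np.random.default_rng(seed)
    ra = rng.dirichlet(res_a.dirichlet_alpha, size=n_samples)
    rb = rng.dirichlet(res_b.dirichlet_alpha, size=n_samples)
    return float(np.mean(ra @ s > rb @ s))
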