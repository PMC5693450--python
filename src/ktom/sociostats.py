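"""Group-level statistics: performance adjustment, factorial effects
regression, Sobel mediation and species-feature regressions.

The analysis stack mirrors a within/between-subject mixed design: session
scores are first adjusted for non-specific session effects (session
repetition, time since the previous session), then condition-level scores
enter a factorial analysis of opponent (within subject) and species
(between subjects), with optional covariate-by-opponent interactions.
Effects are tested by nested-model F comparisons; species-feature contrasts
(endocranial volume, social group size) are tested in the between-subject
stratum on log-transformed features.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "adjust_performance",
    "effects_regression",
    "sobel_mediation",
    "species_feature_regression",
    "validate_species_features",
]

REQUIRED_FEATURES = ("species", "ecv_cm3", "group_size", "life_expectancy")


def validate_species_features(features: pd.DataFrame) -> pd.DataFrame:
    """Check the species-feature table (one row per species, positive
    values) and return it indexed by species."""
    missing = [c for c in REQUIRED_FEATURES if c not in features.columns]
    if missing:
        raise ValueError(f"species feature table lacks columns {missing}")
    if features["species"].duplicated().any():
        raise ValueError("species feature table must have one row per species")
    num = features.drop(columns=["species"]).select_dtypes("number")
    if (num <= 0).any().any():
        raise ValueError("species features must be positive")
    return features.set_index("species")


# ---------------------------------------------------------------------------
# performance adjustment
# ---------------------------------------------------------------------------


def adjust_performance(scores: pd.DataFrame) -> pd.DataFrame:
    """Regress session repetition and inter-session gap out of session
    scores, per individual.

    ``scores`` needs columns individual_id, session_index, day_gap, score.
    Returns a copy with an ``adjusted`` column: the residual of the
    per-individual ordinary least-squares fit on (session_index, day_gap)
    plus the individual's mean score.  The operation is idempotent.
    """
    need = {"individual_id", "session_index", "day_gap", "score"}
    if not need <= set(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(need)}")
    out = scores.copy()
    out["adjusted"] = np.nan
    for ind, grp in scores.groupby("individual_id"):
        if len(grp) < 3:
            raise ValueError(f"individual {ind!r} has fewer than 3 sessions")
        y = grp["score"].to_numpy(float)
        X = np.column_stack(
            [
                np.ones(len(grp)),
                grp["session_index"].to_numpy(float),
                grp["day_gap"].to_numpy(float),
            ]
        )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"rank-deficient nuisance design for {ind!r}; "
                "dropping the day_gap column",
                RuntimeWarning,
                stacklevel=2,
            )
            X = X[:, :2]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out.loc[grp.index, "adjusted"] = resid + y.mean()
    return out


# ---------------------------------------------------------------------------
# factorial effects regression
# ---------------------------------------------------------------------------


def _dummies(labels):
    labels = pd.Series(np.asarray(labels))
    levels = sorted(pd.unique(labels))
    cols = [(labels == lv).astype(float).to_numpy() for lv in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(labels), 0)), levels


def _nested_f(y, X_red, X_full):
    """F-test of the extra columns of X_full over X_red (nested OLS)."""

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), np.linalg.matrix_rank(X)

    sse_r, rank_r = sse(X_red)
    sse_f, rank_f = sse(X_full)
    df1 = rank_f - rank_r
    df2 = len(y) - rank_f
    if df1 <= 0 or df2 <= 0:
        raise ValueError("contrast is not estimable in this design")
    F = ((sse_r - sse_f) / df1) / (sse_f / df2)
    p = float(stats.f.sf(F, df1, df2))
    r2 = (sse_r - sse_f) / sse_r if sse_r > 0 else 0.0
    return {"F": float(F), "df": (df1, df2), "R2": float(r2), "p": p}


def effects_regression(
    data: pd.DataFrame,
    features: pd.DataFrame | None = None,
    covariates: tuple = (),
) -> dict:
    """Factorial analysis of adjusted performance.

    ``data`` has one row per individual x opponent condition with columns
    individual_id, species, condition, adjusted (plus any covariate
    columns, constant within individual).  Tests:

    * ``opponent`` — within-subject: subject intercepts (+ covariate x
      opponent interactions) with vs without opponent terms;
    * ``interaction`` — species x opponent over the opponent model;
    * ``species`` — between-subject stratum: individual mean scores
      regressed on species;
    * one ``<feature>`` entry per numeric feature column — between-subject
      weighted linear contrast replacing species by the log feature value.

    Returns a dict of {effect: {F, df, R2, p}}.
    """
    need = {"individual_id", "species", "condition", "adjusted"}
    if not need <= set(data.columns):
        raise ValueError(f"data needs columns {sorted(need)}")
    if data.groupby(["individual_id", "condition"]).size().max() > 1:
        raise ValueError("expect one row per individual x condition")
    if data.groupby("individual_id")["condition"].nunique().nunique() != 1:
        raise ValueError("factorial coverage is incomplete")

    y = data["adjusted"].to_numpy(float)
    D_subj, _ = _dummies(data["individual_id"])
    D_cond, _ = _dummies(data["condition"])
    base = [np.ones((len(data), 1)), D_subj]
    for cov in covariates:
        c = data[cov].to_numpy(float)[:, None]
        base.append(c * D_cond)  # covariate x opponent interaction
    X_base = np.column_stack(base)
    X_opp = np.column_stack([X_base, D_cond])

    out = {"opponent": _nested_f(y, X_base, X_opp)}
    D_spec, _ = _dummies(data["species"])
    if D_spec.shape[1] > 0:  # species x opponent only testable with >1 species
        inter = [D_spec[:, j : j + 1] * D_cond for j in range(D_spec.shape[1])]
        X_int = np.column_stack([X_opp] + inter)
        out["interaction"] = _nested_f(y, X_opp, X_int)

    # between-subject stratum on individual means
    subj = (
        data.groupby("individual_id")
        .agg(score=("adjusted", "mean"), species=("species", "first"))
        .reset_index()
    )
    ys = subj["score"].to_numpy(float)
    ones_s = np.ones((len(subj), 1))
    D_spec_s, _ = _dummies(subj["species"])
    if D_spec_s.shape[1] > 0:
        out["species"] = _nested_f(ys, ones_s, np.column_stack([ones_s, D_spec_s]))

    if features is not None:
        feat = (
            features
            if features.index.name == "species"
            else validate_species_features(features)
        )
        for col in feat.columns:
            if not np.issubdtype(feat[col].dtype, np.number):
                continue
            vals = np.log(subj["species"].map(feat[col]).to_numpy(float))
            out[col] = _nested_f(ys, ones_s, np.column_stack([ones_s, vals[:, None]]))
    return out


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def sobel_mediation(x, mediator, y) -> tuple:
    """Classical Sobel test of mediation.

    Path a: mediator ~ x; path b: y ~ x + mediator.  Returns ``(z, p)``
    with z = a b / sqrt(a^2 se_b^2 + b^2 se_a^2) and a two-sided normal
    p-value.
    """
    x = np.asarray(x, float)
    m = np.asarray(mediator, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise ValueError("mediation test needs n >= 10")
    if np.std(x) == 0 or np.std(m) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to the mediation test")

    def ols(X, yy):
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        r = yy - X @ beta
        dof = len(yy) - X.shape[1]
        s2 = (r @ r) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        return beta, np.sqrt(np.diag(cov))

    Xa = np.column_stack([np.ones_like(x), x])
    beta_a, se_av = ols(Xa, m)
    a, se_a = beta_a[1], se_av[1]
    Xb = np.column_stack([np.ones_like(x), x, m])
    beta_b, se_bv = ols(Xb, y)
    b, se_b = beta_b[2], se_bv[2]
    z = a * b / np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# species-feature regression of pToM
# ---------------------------------------------------------------------------


def species_feature_regression(
    ptom_by_species: pd.Series,
    features: pd.DataFrame,
    include: tuple = ("ecv_cm3", "group_size"),
    log_features: bool = True,
    interaction: bool = False,
) -> dict:
    """Relate species-level pToM to sociobiological features.

    Reports pairwise Pearson correlations of pToM with each included
    (log-transformed) feature, and a concurrent multiple regression of pToM
    on all included features (plus an optional pairwise interaction term).
    One- and two-sided p-values are reported; phylogenetic structure is not
    modelled (with 7 species a phylogenetic correction would be advisable
    on real data).
    """
    feat = (
        features
        if features.index.name == "species"
        else validate_species_features(features)
    )
    species = list(ptom_by_species.index)
    if len(species) < 4:
        raise ValueError("need at least 4 species")
    y = ptom_by_species.to_numpy(float)
    out = {"pairwise": {}, "n_species": len(species)}
    if np.std(y) == 0:
        warnings.warn(
            "pToM has zero variance across species; correlations undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        out["degenerate"] = True
        return out

    cols = {}
    for col in include:
        v = feat.loc[species, col].to_numpy(float)
        cols[col] = np.log(v) if log_features else v
        r, p_two = stats.pearsonr(cols[col], y)
        p_one = p_two / 2 if r > 0 else 1 - p_two / 2
        out["pairwise"][col] = {
            "r": float(r),
            "p_two_sided": float(p_two),
            "p_one_sided": float(p_one),
        }

    X = np.column_stack([np.ones(len(y))] + [cols[c] for c in include])
    names = ["intercept"] + list(include)
    if interaction and len(include) >= 2:
        X = np.column_stack([X, cols[include[0]] * cols[include[1]]])
        names.append(f"{include[0]}x{include[1]}")
    cond = np.linalg.cond(X)
    if cond > 1e6:
        warnings.warn(
            f"ill-conditioned feature design (condition number {cond:.2g})",
            RuntimeWarning,
            stacklevel=2,
        )
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough species for the requested regression")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (len(y) - 1) / dof
    out["regression"] = {
        "coef": dict(zip(names, map(float, beta))),
        "se": dict(zip(names, map(float, se))),
        "t": dict(zip(names, map(float, tvals))),
        "p_two_sided": {
            n: float(2 * stats.t.sf(abs(t), dof)) for n, t in zip(names, tvals)
        },
        "p_one_sided": {n: float(stats.t.sf(t, dof)) for n, t in zip(names, tvals)},
        "df_resid": dof,
        "r2": float(r2),
        "adj_r2": float(adj_r2),
    }
    return out
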