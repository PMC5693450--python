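"""Group-level statistics tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ktom.sociostats import (
    adjust_performance,
    effects_regression,
    sobel_mediation,
    species_feature_regression,
    validate_species_features,
)
from ktom.synthetic_data import load_species_features


def _scores(rng, n_ind=8, n_sess=12, trend=0.0, noise=0.05):
    rows = []
    for i in range(n_ind):
        for s in range(n_sess):
            rows.append(
                {
                    "individual_id": f"i{i}",
                    "session_index": s,
                    "day_gap": float(rng.choice([1, 2, 3])),
                    "score": 0.5 + trend * s + noise * rng.standard_normal(),
                    "condition": ["RB", "OTOM", "ITOM"][s % 3],
                    "species": f"sp{i % 4}",
                }
            )
    return pd.DataFrame(rows)


class TestAdjustPerformance:
    def test_planted_trend_removed(self, rng):
        df = adjust_performance(_scores(rng, n_ind=30, trend=0.02))
        r = np.corrcoef(df["adjusted"], df["session_index"])[0, 1]
        assert abs(r) < 0.05

    def test_null_adjustment_small(self, rng):
        df = adjust_performance(_scores(rng, trend=0.0))
        delta = np.abs(df["adjusted"] - df["score"])
        se = df["score"].std() / np.sqrt(len(df) / df["individual_id"].nunique())
        assert delta.mean() < 2 * se

    def test_constant_scores_unchanged(self):
        df = pd.DataFrame(
            {
                "individual_id": "a",
                "session_index": range(6),
                "day_gap": [1, 2, 1, 2, 1, 2],
                "score": 0.6,
            }
        )
        out = adjust_performance(df)
        assert np.allclose(out["adjusted"], 0.6)

    def test_idempotent(self, rng):
        df = adjust_performance(_scores(rng, trend=0.01))
        again = adjust_performance(df.assign(score=df["adjusted"]))
        assert np.allclose(again["adjusted"], df["adjusted"], atol=1e-10)

    def test_too_few_sessions(self):
        df = pd.DataFrame(
            {
                "individual_id": "a",
                "session_index": [0, 1],
                "day_gap": [1, 1],
                "score": [0.5, 0.6],
            }
        )
        with pytest.raises(ValueError):
            adjust_performance(df)


def _condition_table(rng, n_ind=12, species_effect=0.0, opp_effect=0.0):
    rows = []
    for i in range(n_ind):
        sp = i % 4
        for c_idx, cond in enumerate(("RB", "OTOM", "ITOM")):
            rows.append(
                {
                    "individual_id": f"i{i}",
                    "species": f"sp{sp}",
                    "condition": cond,
                    "adjusted": 0.5
                    + species_effect * sp
                    + opp_effect * c_idx
                    + 0.05 * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


class TestEffectsRegression:
    def test_textbook_f_statistic(self):
        """One-way ANOVA special case matches a direct F computation."""
        df = pd.DataFrame(
            {
                "individual_id": [f"i{i}" for i in range(6) for _ in range(3)],
                "species": "sp0",
                "condition": ["RB", "OTOM", "ITOM"] * 6,
                "adjusted": [
                    0.61, 0.50, 0.48, 0.66, 0.52, 0.47, 0.58, 0.55, 0.50,
                    0.63, 0.49, 0.52, 0.60, 0.51, 0.46, 0.64, 0.53, 0.49,
                ],
            }
        )
        res = effects_regression(df)["opponent"]
        wide = df.pivot(index="individual_id", columns="condition", values="adjusted")
        # within-subject one-way ANOVA by hand (nested SSR over subject means)
        grand = wide.to_numpy().mean()
        sub_mean = wide.mean(axis=1).to_numpy()
        cond_mean = wide.mean(axis=0).to_numpy()
        ss_cond = 6 * np.sum((cond_mean - grand) ** 2)
        resid = (
            wide.to_numpy()
            - sub_mean[:, None]
            - cond_mean[None, :]
            + grand
        )
        ss_err = np.sum(resid**2)
        F_hand = (ss_cond / 2) / (ss_err / 10)
        assert res["F"] == pytest.approx(F_hand, rel=1e-9)
        assert res["df"] == (2, 10)
        assert res["p"] == pytest.approx(stats.f.sf(F_hand, 2, 10), rel=1e-9)

    def test_planted_opponent_effect_detected(self, rng):
        df = _condition_table(rng, n_ind=35, opp_effect=0.05)
        res = effects_regression(df)
        assert res["opponent"]["p"] < 0.001
        assert res["interaction"]["p"] > 0.001  # no planted interaction

    def test_species_effect_detected(self, rng):
        df = _condition_table(rng, n_ind=24, species_effect=0.05)
        assert effects_regression(df)["species"]["p"] < 0.001

    def test_feature_contrast_reported(self, rng):
        feats = validate_species_features(
            pd.DataFrame(
                {
                    "species": [f"sp{i}" for i in range(4)],
                    "ecv_cm3": [50.0, 100.0, 200.0, 400.0],
                    "group_size": [10.0, 20.0, 15.0, 30.0],
                    "life_expectancy": [20.0, 25.0, 30.0, 40.0],
                }
            )
        )
        df = _condition_table(rng, n_ind=24, species_effect=0.05)
        res = effects_regression(df, features=feats)
        assert res["ecv_cm3"]["p"] < 0.01  # species effect ordered by index
        assert res["ecv_cm3"]["df"][0] == 1

    def test_incomplete_design_rejected(self, rng):
        df = _condition_table(rng).iloc[:-1]
        with pytest.raises(ValueError):
            effects_regression(df)


class TestSobel:
    def test_formula_arithmetic(self):
        # z = a b / sqrt(a^2 se_b^2 + b^2 se_a^2) with fixed toy numbers
        z = 0.5 * 0.4 / np.sqrt(0.25 * 0.01 + 0.16 * 0.01)
        assert z == pytest.approx(3.123, abs=0.001)

    def test_perfect_mediation_chain(self, rng):
        x = rng.standard_normal(500)
        m = x + 0.1 * rng.standard_normal(500)
        y = m + 0.1 * rng.standard_normal(500)
        z, p = sobel_mediation(x, m, y)
        assert p < 1e-4
        assert z > 0

    def test_guards(self, rng):
        with pytest.raises(ValueError):
            sobel_mediation([1] * 12, rng.standard_normal(12), rng.standard_normal(12))
        with pytest.raises(ValueError):
            sobel_mediation([1, 2], [1, 2], [1, 2])


class TestSpeciesFeatureRegression:
    def test_pearson_matches_direct_formula(self):
        feats = validate_species_features(load_species_features())
        sp = list(feats.index)
        ptom = pd.Series(np.linspace(0.2, 0.8, len(sp)), index=sp)
        rep = species_feature_regression(ptom, feats)
        x = np.log(feats.loc[sp, "ecv_cm3"].to_numpy(float))
        y = ptom.to_numpy()
        r_direct = np.corrcoef(x, y)[0, 1]
        assert rep["pairwise"]["ecv_cm3"]["r"] == pytest.approx(r_direct)
        assert 0 <= rep["regression"]["p_two_sided"]["ecv_cm3"] <= 1

    def test_constant_ptom_flagged(self):
        feats = load_species_features()
        ptom = pd.Series(0.5, index=feats["species"])
        with pytest.warns(RuntimeWarning):
            rep = species_feature_regression(ptom, feats)
        assert rep.get("degenerate")

    def test_needs_four_species(self):
        feats = load_species_features()
        with pytest.raises(ValueError):
            species_feature_regression(
                pd.Series([0.1, 0.2, 0.3], index=feats["species"][:3]), feats
            )
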