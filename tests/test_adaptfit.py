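"""Fitness differentials, origin × pair ANOVA, and stepwise predictor selection."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from adaptdiff.core import DifferentialRecord, PairExperiment, ValidationError
from adaptdiff.adaptfit import (
    differentials,
    origin_anova,
    stepwise_predict,
)
from adaptdiff.synthdata import PairSpec, SimulationConfig, gen_pair_experiment


def make_pair(biomass_local, biomass_foreign, pair_id="p1", survived=None) -> PairExperiment:
    """Minimal balanced pair: len(biomass_*) families x 1 block."""
    n = len(biomass_local)
    rows = []
    for fam in range(1, n + 1):
        for origin, bio in (("local", biomass_local[fam - 1]),
                            ("foreign", biomass_foreign[fam - 1])):
            alive = True if survived is None else survived[origin][fam - 1]
            rows.append({
                "family_pair": fam, "block": 1, "row": fam, "column": 1,
                "origin": origin, "seed_weight": 1.0, "germinated": True,
                "survived": alive, "biomass": bio if alive else np.nan,
                "inflorescences": 3,
            })
    return PairExperiment(
        pair_id=pair_id, local_pop="L", foreign_pop="F", distance_km=10.0,
        local_N=1000, foreign_N=500, pots=pd.DataFrame(rows),
    )


class TestDifferentials:
    def test_equal_means_zero(self):
        pair = make_pair([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert differentials(pair, "biomass").delta_pct == pytest.approx(0.0)

    def test_constructed_17_3_percent_advantage(self):
        # local mean 1.173 g vs foreign 1.0 g -> +17.3%
        pair = make_pair([1.173] * 4, [1.0] * 4)
        rec = differentials(pair, "biomass")
        assert rec.delta_pct == pytest.approx(17.3, abs=1e-9)
        assert not rec.absolute

    def test_origin_swap_algebra(self):
        # swapping labels: new delta = -100 * (mL - mF) / mL (denominator
        # convention changes the magnitude, not just the sign)
        local, foreign = [2.0, 2.4], [1.5, 1.7]
        pair = make_pair(local, foreign)
        rec = differentials(pair, "biomass")
        swapped = make_pair(foreign, local)
        rec_sw = differentials(swapped, "biomass")
        m_l, m_f = np.mean(local), np.mean(foreign)
        assert rec_sw.delta_pct == pytest.approx(-100.0 * (m_l - m_f) / m_l)
        assert np.sign(rec_sw.delta_pct) == -np.sign(rec.delta_pct)

    def test_scale_invariance(self):
        pair = make_pair([1.0, 1.2, 1.4], [0.9, 1.1, 1.0])
        d1 = differentials(pair, "biomass").delta_pct
        scaled = make_pair([7.0, 8.4, 9.8], [6.3, 7.7, 7.0])
        assert differentials(scaled, "biomass").delta_pct == pytest.approx(d1)

    def test_survival_uses_pooled_proportions(self):
        surv = {"local": [True, True, False, True], "foreign": [True, False, False, True]}
        pair = make_pair([1.0] * 4, [1.0] * 4, survived=surv)
        rec = differentials(pair, "survival")
        assert rec.delta_pct == pytest.approx(100.0 * (0.75 - 0.5) / 0.5)

    def test_zero_foreign_mean_flagged_absolute(self):
        surv = {"local": [True, True], "foreign": [False, False]}
        pair = make_pair([1.0, 1.0], [1.0, 1.0], survived=surv)
        rec = differentials(pair, "survival")
        assert rec.absolute
        assert rec.delta_pct == pytest.approx(1.0)

    def test_no_survivor_for_adult_trait_rejected(self):
        surv = {"local": [False, False], "foreign": [True, True]}
        pair = make_pair([1.0, 1.0], [1.0, 1.0], survived=surv)
        with pytest.raises(ValidationError, match="local"):
            differentials(pair, "biomass")


def brute_force_two_way_anova(fam: pd.DataFrame):
    """Textbook balanced two-way ANOVA sums of squares, explicit loops."""
    grand = fam["response"].mean()
    cells = fam.groupby(["origin", "pair"])["response"].mean()
    o_means = fam.groupby("origin")["response"].mean()
    p_means = fam.groupby("pair")["response"].mean()
    n_per_cell = fam.groupby(["origin", "pair"]).size().iloc[0]
    n_o, n_p = fam["origin"].nunique(), fam["pair"].nunique()
    ss_o = n_per_cell * n_p * sum((m - grand) ** 2 for m in o_means)
    ss_p = n_per_cell * n_o * sum((m - grand) ** 2 for m in p_means)
    ss_cells = n_per_cell * sum((m - grand) ** 2 for m in cells)
    ss_int = ss_cells - ss_o - ss_p
    ss_res = sum(
        (row["response"] - cells[(row["origin"], row["pair"])]) ** 2
        for _, row in fam.iterrows()
    )
    df_o, df_p = n_o - 1, n_p - 1
    df_int = df_o * df_p
    df_res = len(fam) - n_o * n_p
    ms_res = ss_res / df_res
    return {
        "origin": (ss_o / df_o) / ms_res,
        "pair": (ss_p / df_p) / ms_res,
        "origin_x_pair": (ss_int / df_int) / ms_res,
    }


class TestOriginAnova:
    def test_single_pair_reduces_to_t_squared(self):
        local = [1.0, 1.4, 1.2, 1.6, 1.1]
        foreign = [0.9, 1.0, 1.3, 0.8, 1.05]
        pair = make_pair(local, foreign)
        res = origin_anova([pair], "biomass")
        t, _ = __import__("scipy.stats", fromlist=["ttest_ind"]).ttest_ind(
            local, foreign, equal_var=True
        )
        assert res.terms["origin"]["F"] == pytest.approx(float(t) ** 2, rel=1e-10)

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(20)
        pairs = [
            make_pair(rng.normal(1.2, 0.2, 6), rng.normal(1.0, 0.2, 6), pair_id=f"p{k}")
            for k in range(3)
        ]
        res = origin_anova(pairs, "biomass")
        from adaptdiff.adaptfit import _family_means

        fam = _family_means(pairs, "biomass")
        oracle = brute_force_two_way_anova(fam)
        for term, f_oracle in oracle.items():
            assert res.terms[term]["F"] == pytest.approx(f_oracle, rel=1e-8)

    def test_null_origin_type_one_error_calibrated(self):
        # no origin effect anywhere: rejection rate at alpha within binomial CI
        alpha = 0.034
        n_rep = 120
        hits = 0
        for s in range(n_rep):
            cfg = SimulationConfig(
                pairs=PairSpec(n_pairs=12, survival_p=0.98), seed=5000 + s
            )
            pairs, _ = gen_pair_experiment(cfg)
            res = origin_anova(pairs, "biomass", alpha=alpha)
            hits += res.terms["origin"]["p"] < alpha
        rate = hits / n_rep
        ci = 1.96 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= ci + 1e-9

    def test_planted_interaction_detected(self):
        # origin effect of ~1 within-family SD in 3 of 12 pairs: the
        # origin x pair interaction should be detected most of the time
        effects = {f"pair{k:02d}": {"biomass": math.exp(0.3) - 1.0} for k in (1, 5, 9)}
        n_rep, hits = 60, 0
        for s in range(n_rep):
            cfg = SimulationConfig(
                pairs=PairSpec(n_pairs=12, survival_p=0.98, adaptation_effects=effects),
                seed=7000 + s,
            )
            pairs, _ = gen_pair_experiment(cfg)
            res = origin_anova(pairs, "biomass", alpha=0.034)
            hits += res.terms["origin_x_pair"]["p"] < 0.034
        assert hits / n_rep > 0.8

    def test_empty_cell_names_pair_and_origin(self):
        surv = {"local": [True, True], "foreign": [False, True]}
        good = make_pair([1.0, 1.1], [1.2, 1.3], pair_id="ok")
        bad = make_pair([1.0, 1.1], [1.2, 1.3], pair_id="bad", survived=surv)
        bad.pots.loc[(bad.pots["origin"] == "foreign"), "germinated"] = [False, True]
        with pytest.raises(ValidationError, match="bad.*foreign|foreign.*bad"):
            origin_anova([good, bad], "survival")

    def test_seed_weight_covariate_residualizes(self):
        rng = np.random.default_rng(30)
        pairs = [
            make_pair(rng.normal(1.2, 0.1, 8), rng.normal(1.0, 0.1, 8), pair_id=f"p{k}")
            for k in range(2)
        ]
        plain = origin_anova(pairs, "biomass")
        adj = origin_anova(pairs, "biomass", seed_weight_covariate=True)
        # constant seed weight: residualization must not change F values
        assert adj.terms["origin"]["F"] == pytest.approx(plain.terms["origin"]["F"], rel=1e-9)


def records_from(X: dict[str, np.ndarray], y: np.ndarray, trait="biomass"):
    n = len(y)
    out = []
    for i in range(n):
        out.append(
            DifferentialRecord(
                pair_id=f"p{i}", trait=trait, delta_pct=float(y[i]),
                predictors={k: float(v[i]) for k, v in X.items()},
            )
        )
    return out


def predictor_frame(rng, n):
    return {
        "log_local_N": rng.uniform(2, 5, n),
        "log_foreign_N": rng.uniform(2, 5, n),
        "log_dist_km": rng.uniform(-0.15, 2.78, n),
        "env_dist": rng.uniform(0, 6, n),
        "qst": rng.uniform(0, 0.5, n),
        "fst": rng.uniform(0, 0.12, n),
    }


class TestStepwisePredict:
    def test_exact_predictor_selected_alone(self):
        rng = np.random.default_rng(40)
        X = predictor_frame(rng, 12)
        y = X["qst"].copy()
        res = stepwise_predict(records_from(X, y))
        assert res.selected_predictors == ["qst"]
        assert res.r2 == pytest.approx(1.0)

    def test_two_signal_recovery(self):
        # z = -20.03 + 4.17 x + 68.2 y with small noise: selection must find
        # exactly {log local size, qst} and cover the truth within fit SEs
        rng = np.random.default_rng(41)
        X = predictor_frame(rng, 12)
        y = -20.03 + 4.17 * X["log_local_N"] + 68.2 * X["qst"] + rng.normal(0, 1.0, 12)
        res = stepwise_predict(records_from(X, y))
        assert sorted(res.selected_predictors) == ["log_local_N", "qst"]
        for name, truth in (("log_local_N", 4.17), ("qst", 68.2), ("intercept", -20.03)):
            assert abs(res.coefficients[name] - truth) <= 3 * res.stderrs[name]

    def test_null_overselection_behaviour(self):
        # pure noise: AIC forward selection is known to overselect; the
        # model-level F test is then selection-biased, so its null rejection
        # rate at alpha lies between the nominal alpha (selection can only
        # inflate) and the union bound over the 21 candidate models
        rng = np.random.default_rng(42)
        n_rep, selected_any, rejected = 200, 0, 0
        for _ in range(n_rep):
            X = predictor_frame(rng, 12)
            y = rng.normal(0, 10, 12)
            res = stepwise_predict(records_from(X, y))
            if res.selected_predictors:
                selected_any += 1
                rejected += res.p_model < res.alpha_used
        assert selected_any / n_rep > 0.3  # AIC overselects under the null
        alpha = 0.025
        n_candidate_models = 6 + 15  # single terms + unordered two-term models
        assert alpha <= rejected / n_rep <= n_candidate_models * alpha

    def test_no_stopping_reduces_to_full_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(43)
        X = predictor_frame(rng, 15)
        y = rng.normal(0, 5, 15)
        res = stepwise_predict(
            records_from(X, y), max_terms=6, stop_on_aic=False
        )
        assert sorted(res.selected_predictors) == sorted(X)
        design = np.column_stack(
            [np.ones(15)] + [X[p] for p in res.selected_predictors]
        )
        full = sm.OLS(y, design).fit()
        assert res.coefficients["intercept"] == pytest.approx(full.params[0])
        assert res.r2 == pytest.approx(full.rsquared)

    def test_collinear_second_term_refused(self):
        rng = np.random.default_rng(44)
        X = predictor_frame(rng, 12)
        X["fst"] = X["qst"] * 2.0  # exact collinearity
        y = 3.0 * X["qst"] + rng.normal(0, 0.01, 12)
        with pytest.warns(UserWarning, match="condition number"):
            res = stepwise_predict(records_from(X, y), predictors=("qst", "fst"))
        # only one of the two aliased predictors enters; the second is refused
        assert len(res.selected_predictors) == 1
        assert res.selected_predictors[0] in ("qst", "fst")

    def test_too_few_records_rejected(self):
        rng = np.random.default_rng(45)
        X = predictor_frame(rng, 5)
        with pytest.raises(ValidationError, match=">= 6"):
            stepwise_predict(records_from(X, rng.normal(size=5)))
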