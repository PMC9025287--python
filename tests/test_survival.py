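import numpy as np
import pandas as pd
import pytest

from habitatpipe import survival as sv

from oracles import c_index_oracle


def _cox_data(rng, n=120, p=3, beta=None, h0=0.01, censor=80.0):
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    x = rng.standard_normal((n, p))
    lp = x @ beta
    t = -np.log(rng.uniform(size=n)) / (h0 * np.exp(lp))
    event = (t <= censor).astype(int)
    time = np.minimum(t, censor)
    cols = [f"f{j}" for j in range(p)]
    return pd.DataFrame(x, columns=cols), time, event


class TestCoxLasso:
    def test_huge_penalty_shrinks_everything(self, rng):
        x, t, e = _cox_data(rng, beta=[1.0, -1.0, 0.5])
        model = sv.fit_cox_lasso(x, t, e, lambdas=np.array([1e6]), n_folds=3)
        assert model.feature_names == []
        assert np.allclose(sv.compute_risk_score(model, x), model.h0)

    def test_zero_penalty_matches_newton_oracle(self, rng):
        from lifelines import CoxPHFitter

        x, t, e = _cox_data(rng, n=60, p=2, beta=[0.8, -0.5])
        beta = sv._fit_at_lambda(x.to_numpy(), t, e, lam=0.0, tol=1e-12, max_outer=500)
        df = x.copy()
        df["time"] = t
        df["event"] = e
        oracle = CoxPHFitter().fit(
            df, "time", "event", fit_options={"precision": 1e-11}
        )
        assert np.allclose(beta, oracle.params_.to_numpy(), atol=1e-6)

    def test_fit_improves_on_null_loglik(self, rng):
        x, t, e = _cox_data(rng, beta=[1.2, 0.0, 0.0])
        beta = sv._fit_at_lambda(x.to_numpy(), t, e, lam=0.01)
        ll_fit = sv.cox_partial_loglik(x.to_numpy() @ beta, t, e)
        ll_null = sv.cox_partial_loglik(np.zeros(len(t)), t, e)
        assert ll_fit > ll_null

    def test_path_sparsity_non_increasing_in_penalty(self, rng):
        x, t, e = _cox_data(rng, n=150, p=6, beta=[1, -1, 0.5, 0, 0, 0])
        lams = np.geomspace(1.0, 1e-4, 12)
        counts = []
        beta = np.zeros(6)
        for lam in lams:
            beta = sv._fit_at_lambda(x.to_numpy(), t, e, lam, beta0=beta)
            counts.append(int((np.abs(beta) > 1e-10).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_planted_signal_selected_with_correct_signs(self, rng):
        hits = 0
        for s in range(3):
            local = np.random.default_rng(100 + s)
            x, t, e = _cox_data(
                local, n=250, p=10, beta=[1.0, -0.8] + [0.0] * 8, censor=60.0
            )
            model = sv.fit_cox_lasso(x, t, e, seed=s)
            coef = dict(zip(model.feature_names, model.coefficients))
            if coef.get("f0", 0) > 0 and coef.get("f1", 0) < 0:
                hits += 1
        assert hits >= 2

    def test_no_events_rejected(self, rng):
        x, t, _ = _cox_data(rng)
        with pytest.raises(ValueError):
            sv.fit_cox_lasso(x, t, np.zeros(len(t), dtype=int))

    def test_model_json_round_trip(self, rng, tmp_path):
        x, t, e = _cox_data(rng, beta=[1.0, 0, 0])
        model = sv.fit_cox_lasso(x, t, e, n_folds=4)
        model.to_json(tmp_path / "m.json")
        back = sv.CoxLassoModel.from_json(tmp_path / "m.json")
        assert back.feature_names == model.feature_names
        assert np.allclose(back.coefficients, model.coefficients)
        assert back.cutoff == model.cutoff


class TestRiskScore:
    @pytest.fixture()
    def model(self):
        return sv.CoxLassoModel(
            feature_names=["a", "b"],
            coefficients=np.array([0.5, -0.25]),
            lambda_=0.1,
            h0=0.02,
            cutoff=0.02,
        )

    def test_zero_features_score_baseline(self, model):
        df = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert sv.compute_risk_score(model, df)[0] == pytest.approx(0.02)

    def test_monotone_in_linear_predictor(self, model, rng):
        df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        scores = sv.compute_risk_score(model, df)
        lp = 0.5 * df["a"] - 0.25 * df["b"]
        assert np.array_equal(np.argsort(scores), np.argsort(lp.to_numpy()))

    def test_baseline_scale_does_not_move_groups(self, model, rng):
        df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        s1 = sv.compute_risk_score(model, df)
        g1 = sv.stratify(s1, float(np.median(s1)))
        model.h0 *= 2
        s2 = sv.compute_risk_score(model, df)
        g2 = sv.stratify(s2, float(np.median(s2)))
        assert np.allclose(s2, 2 * s1)
        assert np.array_equal(g1, g2)

    def test_missing_feature_rejected(self, model):
        with pytest.raises(KeyError):
            sv.compute_risk_score(model, pd.DataFrame({"a": [1.0]}))


class TestStratify:
    @pytest.mark.parametrize(
        "score,expect_high", [(1.258, True), (0.790, False), (1.067, True)]
    )
    def test_median_cutoff_classification(self, score, expect_high):
        assert sv.stratify(np.array([score]), 1.067)[0] == expect_high


class TestGroupHazardRatio:
    def test_null_groups_near_unit_ratio(self, rng):
        _, t, e = _cox_data(rng, n=300, censor=60.0)
        high = np.arange(300) % 2 == 0
        hr, (lo, hi), p = sv.group_hazard_ratio(high, t, e)
        assert lo < 1.0 < hi
        assert p > 0.05

    def test_planted_group_effect_recovered(self):
        rng = np.random.default_rng(7)
        n = 400
        high = rng.uniform(size=n) < 0.5
        lp = 1.2 * high
        t = -np.log(rng.uniform(size=n)) / (0.02 * np.exp(lp))
        censor = 50.0
        e = (t <= censor).astype(int)
        t = np.minimum(t, censor)
        hr, (lo, hi), _ = sv.group_hazard_ratio(high, t, e)
        log_se = (np.log(hi) - np.log(lo)) / (2 * 1.96)
        assert abs(np.log(hr) - 1.2) < 3 * log_se

    def test_label_swap_inverts_ratio(self, rng):
        _, t, e = _cox_data(rng, n=200, censor=70.0)
        high = np.arange(200) < 100
        hr, _, p1 = sv.group_hazard_ratio(high, t, e)
        inv, _, p2 = sv.group_hazard_ratio(~high, t, e)
        assert inv == pytest.approx(1.0 / hr, rel=1e-6)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_empty_group_rejected(self, rng):
        _, t, e = _cox_data(rng, n=50)
        with pytest.raises(ValueError):
            sv.group_hazard_ratio(np.ones(50, dtype=bool), t, e)


class TestCIndex:
    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.ones(5, dtype=int)
        scores = -t  # earliest failure has highest risk
        c, _ = sv.harrell_c_index(scores, t, e)
        assert c == 1.0

    def test_random_scores_near_half(self, rng):
        n = 400
        t = rng.exponential(50, size=n)
        e = np.ones(n, dtype=int)
        c, se = sv.harrell_c_index(rng.standard_normal(n), t, e)
        assert abs(c - 0.5) < 0.05
        assert se > 0

    def test_five_patient_worked_instance_matches_oracle(self):
        scores = np.array([0.9, 0.1, 0.5, 0.5, 0.3])
        t = np.array([2.0, 9.0, 4.0, 7.0, 5.0])
        e = np.array([1, 0, 1, 1, 0])
        c, _ = sv.harrell_c_index(scores, t, e)
        assert c == pytest.approx(c_index_oracle(scores, t, e))

    def test_censored_data_matches_oracle_and_sksurv(self, rng):
        from sksurv.metrics import concordance_index_censored

        n = 40
        t = rng.exponential(30, size=n)
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        s = rng.standard_normal(n)
        c, _ = sv.harrell_c_index(s, t, e)
        assert c == pytest.approx(c_index_oracle(s, t, e))
        ref = concordance_index_censored(e.astype(bool), t, s)[0]
        assert c == pytest.approx(ref, abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        n = 100
        t = rng.exponential(30, size=n)
        e = rng.integers(0, 2, size=n)
        e[:5] = 1
        s = rng.standard_normal(n)
        c1, _ = sv.harrell_c_index(s, t, e)
        c2, _ = sv.harrell_c_index(np.exp(3 * s), t, e)
        assert c1 == c2

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            sv.harrell_c_index(np.array([1.0, 2.0]), np.array([5.0, 5.0]),
                               np.array([0, 0]))


class TestCompareModels:
    def test_identical_models_p_one(self, rng):
        _, t, e = _cox_data(rng, n=80)
        s = rng.standard_normal(80)
        assert sv.compare_models(s, s.copy(), t, e, n_boot=50, seed=0) == 1.0

    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(3)
        n = 200
        t = rng.exponential(30, size=n)
        e = np.ones(n, dtype=int)
        good = -t + rng.normal(0, 1e-6, n)
        bad = t.copy()
        p = sv.compare_models(good, bad, t, e, n_boot=100, seed=1)
        assert p < 0.001

    def test_symmetric_in_model_order(self, rng):
        n = 150
        t = rng.exponential(30, size=n)
        e = np.ones(n, dtype=int)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        p1 = sv.compare_models(a, b, t, e, n_boot=80, seed=5)
        p2 = sv.compare_models(b, a, t, e, n_boot=80, seed=5)
        assert p1 == pytest.approx(p2)

    def test_too_few_replicates_rejected(self, rng):
        _, t, e = _cox_data(rng, n=50)
        with pytest.raises(ValueError):
            sv.compare_models(t, t + 1, t, e, n_boot=5)


class TestFiveRiskModels:
    @pytest.fixture(scope="class")
    def cohorts(self):
        """Synthetic feature tables where only habitat heterogeneity drives risk."""
        rng = np.random.default_rng(21)

        def make(n):
            hab = pd.DataFrame(
                rng.standard_normal((n, 6)),
                columns=[f"hab{j}" for j in range(6)],
            )
            lp = 1.2 * hab["hab0"] - 0.9 * hab["hab1"]
            t = -np.log(rng.uniform(size=n)) / (0.01 * np.exp(lp))
            censor = 80.0
            return {
                "habitat_features": hab,
                "dce_features": pd.DataFrame(
                    rng.standard_normal((n, 5)),
                    columns=[f"dce{j}" for j in range(5)],
                ),
                "perfusion_features": pd.DataFrame(
                    rng.standard_normal((n, 5)),
                    columns=[f"per{j}" for j in range(5)],
                ),
                "clinical": pd.DataFrame(
                    rng.integers(0, 2, size=(n, 4)).astype(float),
                    columns=[f"clin{j}" for j in range(4)],
                ),
                "time": np.minimum(t, censor),
                "event": (t <= censor).astype(int),
            }

        return make(180), make(90)

    @pytest.fixture(scope="class")
    def report(self, cohorts):
        dev, val = cohorts
        return sv.build_all_risk_models(dev, val, seed=0, n_boot=50)

    def test_report_covers_five_models_two_cohorts(self, report):
        table, _ = report
        assert len(table) == 10
        assert set(table["model"]) == set(sv.MODEL_NAMES)
        assert set(table["cohort"]) == {"development", "validation"}

    def test_validation_reuses_development_cutoffs(self, report):
        table, models = report
        for name, model in models.items():
            cuts = table.loc[table["model"] == name, "cutoff"].to_numpy()
            assert np.all(cuts == model.cutoff)

    def test_habitat_models_beat_uninformative_panels(self, report):
        table, _ = report
        dev = table[table["cohort"] == "development"].set_index("model")
        assert dev.loc["HRS_only", "c_index"] > dev.loc["clinical", "c_index"]
        assert (
            dev.loc["combined_habitat", "c_index"]
            >= dev.loc["clinical", "c_index"]
        )
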