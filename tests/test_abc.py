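"""ABC machinery: z-scoring, PLS, rejection, posteriors, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from oracles import pls_nipals_oracle
from sweepabc import abc as A
from sweepabc.errors import SweepABCError


def gaussian_tables(rng, n=400, shift=3.0, n_stats=6, models=("M1", "M2", "M3")):
    """Synthetic reference tables: model k is a Gaussian cloud shifted by
    k * shift along the first two statistic axes."""
    tables = {}
    for k, m in enumerate(models):
        X = rng.normal(size=(n, n_stats))
        X[:, 0] += k * shift
        X[:, 1] -= k * shift
        t = pd.DataFrame(X, columns=[f"s{j}" for j in range(n_stats)])
        t.insert(0, "t_mut", rng.uniform(40, 70, n))
        tables[m] = t
    return tables


STATS = [f"s{j}" for j in range(6)]


class TestZScore:
    def test_moments_and_observed_transform(self):
        rng = np.random.default_rng(0)
        sims = pd.DataFrame(rng.normal(5, 3, size=(300, 4)),
                            columns=list("abcd"))
        obs = sims.iloc[7]
        Z, z_obs, tf = A.zscore_table(sims, obs)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0, ddof=0), 1, atol=1e-9)
        np.testing.assert_allclose(z_obs.to_numpy(), Z.iloc[7].to_numpy())
        # observed equal to the column mean maps to 0
        _, z_mean, _ = A.zscore_table(sims, sims.mean())
        assert np.allclose(z_mean, 0, atol=1e-12)

    def test_round_trip_destandardise(self):
        rng = np.random.default_rng(1)
        sims = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        Z, _, tf = A.zscore_table(sims, sims.iloc[0])
        back = Z * tf["sds"] + tf["means"]
        np.testing.assert_allclose(back.to_numpy(), sims.to_numpy(),
                                   atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        sims = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            Z, z_obs, _ = A.zscore_table(sims, {"a": 2.0, "b": 5.0})
        assert list(Z.columns) == ["a"]

    def test_missing_observed_statistic_errors(self):
        sims = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(SweepABCError):
            A.zscore_table(sims, {"c": 1.0})


class TestPLS:
    def test_separable_classes_first_component(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (150, 2)),
                       rng.normal(12, 1, (150, 2))])
        labels = ["a"] * 150 + ["b"] * 150
        table = pd.DataFrame(X, columns=["x", "y"])
        Z, _, _ = A.zscore_table(table, table.iloc[0])
        model = A.fit_pls(Z, labels, "discriminant", 2)
        scores = A.project(model, Z)[:, 0]
        ma, mb = scores[:150], scores[150:]
        pooled = np.sqrt((ma.var() + mb.var()) / 2)
        assert abs(ma.mean() - mb.mean()) > 5 * pooled

    def test_noise_response_explains_nothing(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(300, 5)))
        y = rng.normal(size=300)  # independent of X
        model = A.fit_pls(X, y, "regression", 3)
        # out-of-sample R^2 of the fitted reduction is ~0
        X2 = np.asarray(rng.normal(size=(300, 5)))
        y2 = rng.normal(size=300)
        pred = model._pls.predict(X2).ravel()
        ss_res = ((y2 - pred) ** 2).sum()
        ss_tot = ((y2 - y2.mean()) ** 2).sum()
        assert ss_res / ss_tot > 0.9

    def test_score_orthogonality_and_nipals_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 6))
        Y = X[:, :2] @ rng.normal(size=(2, 3)) + 0.1 * rng.normal(size=(80, 3))
        table = pd.DataFrame(X)
        model = A.fit_pls(table, Y, "regression", 4)
        T = model.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8
        # independent NIPALS implementation spans the same score space
        T_oracle = pls_nipals_oracle(X, Y, 4)
        for k in range(4):
            c = np.corrcoef(T[:, k], T_oracle[:, k])[0, 1]
            assert abs(abs(c) - 1) < 1e-4

    def test_excess_components_rejected(self):
        X = pd.DataFrame(np.random.default_rng(5).normal(size=(10, 3)))
        with pytest.raises(SweepABCError):
            A.fit_pls(X, ["a"] * 5 + ["b"] * 5, "discriminant", 8)


class TestRejection:
    def test_retain_all_recovers_training_proportions(self):
        rng = np.random.default_rng(6)
        sims = rng.normal(size=(100, 3))
        labels = np.array(["A"] * 50 + ["B"] * 30 + ["C"] * 20)
        rej = A.abc_reject(np.zeros(3), sims, retain_fraction=1.0)
        assert len(rej.indices) == 100
        post = A.model_posterior(labels[rej.indices],
                                 {"A": 50, "B": 30, "C": 20})
        # with counts weighted by training size, priors are recovered
        assert post.probabilities["A"] == pytest.approx(1 / 3)
        assert post.probabilities["B"] == pytest.approx(1 / 3)

    def test_exact_match_retained_at_distance_zero(self):
        rng = np.random.default_rng(7)
        sims = rng.normal(size=(200, 4))
        obs = sims[123]
        rej = A.abc_reject(obs, sims, retain_fraction=1 / 200)
        assert 123 in rej.indices
        assert rej.distances.min() == 0.0

    def test_distances_match_bruteforce(self):
        rng = np.random.default_rng(8)
        sims = rng.normal(size=(100, 5))
        obs = rng.normal(size=5)
        rej = A.abc_reject(obs, sims, retain_fraction=0.1)
        d_all = np.array([np.sqrt(((s - obs) ** 2).sum()) for s in sims])
        expected = np.sort(d_all)[: len(rej.indices)]
        np.testing.assert_allclose(np.sort(rej.distances), expected)
        assert len(rej.indices) == 10

    def test_ties_at_cutoff_all_retained(self):
        sims = np.array([[0.0], [1.0], [1.0], [1.0], [5.0]])
        rej = A.abc_reject(np.array([0.0]), sims, retain_fraction=2 / 5)
        assert len(rej.indices) == 4  # the two ties at d=1 come along


class TestModelPosterior:
    def test_proportions_and_bayes_factors(self):
        labels = ["SDN"] * 50 + ["SSV"] * 30 + ["NTR"] * 20
        post = A.model_posterior(labels, {m: 1000 for m in
                                          ("SDN", "SSV", "NTR")})
        assert post.probabilities["SDN"] == pytest.approx(0.5)
        assert post.probabilities["SSV"] == pytest.approx(0.3)
        assert post.bayes_factors[("SDN", "SSV")] == pytest.approx(5 / 3)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(["a", "b", "c"], 500)
        post = A.model_posterior(labels, {"a": 900, "b": 1000, "c": 800})
        assert sum(post.probabilities.values()) == pytest.approx(1, abs=1e-9)

    def test_unequal_training_counts_corrected(self):
        # 60 vs 30 retained, but B had half the training budget: posteriors equal
        labels = ["A"] * 60 + ["B"] * 30
        post = A.model_posterior(labels, {"A": 1000, "B": 500})
        assert post.probabilities["A"] == pytest.approx(0.5)

    def test_absent_model_floor_bound(self):
        labels = ["A"] * 100
        post = A.model_posterior(labels, {"A": 500, "B": 500})
        assert post.probabilities["B"] == 0.0
        assert "B" in post.floor_models
        # the Bayes factor uses the 1/n_retained floor
        assert post.bayes_factors[("A", "B")] == pytest.approx(100)

    def test_epanechnikov_weighting_downweights_distant(self):
        # two retained per model; model B's draws are farther away, so
        # kernel weighting shifts posterior mass toward A
        labels = ["A", "A", "B", "B"]
        d = np.array([0.1, 0.2, 0.9, 1.0])
        w = A.epanechnikov_weights(d)
        assert (np.diff(w) < 0).all()
        post_u = A.model_posterior(labels, {"A": 10, "B": 10})
        post_w = A.model_posterior(labels, {"A": 10, "B": 10}, weights=w)
        assert post_u.probabilities["A"] == pytest.approx(0.5)
        assert post_w.probabilities["A"] > 0.5
        assert sum(post_w.probabilities.values()) == pytest.approx(1)

    def test_bayes_factors_multiply(self):
        labels = ["A"] * 50 + ["B"] * 30 + ["C"] * 20
        post = A.model_posterior(labels, {m: 100 for m in "ABC"})
        bf = post.bayes_factors
        assert bf[("A", "C")] == pytest.approx(
            bf[("A", "B")] * bf[("B", "C")])


class TestParameterEstimation:
    def test_degenerate_point_mass(self):
        params = pd.DataFrame({"s": [0.3] * 80})
        est = A.estimate_parameters(params, np.zeros(80))
        assert est["s"].mode == 0.3
        assert est["s"].ci_low == est["s"].ci_high == 0.3

    def test_uniform_quantile_oracle(self):
        rng = np.random.default_rng(10)
        params = pd.DataFrame({"u": rng.uniform(0, 1, 10_000)})
        est = A.estimate_parameters(params, np.zeros(10_000))
        assert est["u"].ci_low == pytest.approx(0.025, abs=0.01)
        assert est["u"].ci_high == pytest.approx(0.975, abs=0.01)

    def test_few_rows_flagged_unstable(self):
        params = pd.DataFrame({"s": np.linspace(0, 1, 20)})
        with pytest.warns(UserWarning, match="unstable"):
            est = A.estimate_parameters(params, np.zeros(20))
        assert est["s"].unstable

    def test_local_linear_adjustment_recovers_linear_map(self):
        # parameter is an exact linear function of the scores: adjusting to
        # the observed score recovers the true value almost exactly
        rng = np.random.default_rng(11)
        scores = rng.normal(size=(200, 2))
        theta = 0.4 + scores @ np.array([0.2, -0.1])
        obs_score = np.array([0.3, 0.6])
        truth = 0.4 + obs_score @ np.array([0.2, -0.1])
        est = A.estimate_parameters(
            pd.DataFrame({"th": theta}), np.zeros(200),
            adjustment="local-linear", retained_scores=scores,
            observed_scores=obs_score)
        assert est["th"].mode == pytest.approx(truth, abs=1e-6)
        assert est["th"].ci_high - est["th"].ci_low < 1e-6

    def test_report_schema_mode_and_bracketed_ci(self):
        rng = np.random.default_rng(12)
        params = pd.DataFrame({
            "t_mut": rng.uniform(40, 70, 500),
            "s_A": rng.uniform(0, 0.015, 500),
            "s_NA": rng.uniform(0.005, 0.05, 500)})
        est = A.estimate_parameters(params, np.zeros(500))
        for k in ("t_mut", "s_A", "s_NA"):
            s = str(est[k])
            assert "(" in s and "-" in s and ")" in s
            assert est[k].ci_low <= est[k].mode <= est[k].ci_high


class TestPipelines:
    def test_infer_self_assignment_separable(self):
        rng = np.random.default_rng(13)
        tables = gaussian_tables(rng, shift=6.0)
        obs = tables["M2"].iloc[0]
        post = A.infer(tables, obs[STATS + ["t_mut"]], STATS, seed=1,
                       retain_fraction=0.02, n_components=4)
        assert post.chosen_model == "M2"
        assert post.model_posterior.probabilities["M2"] > 0.9
        assert "t_mut" in post.parameters

    def test_sentinel_rows_dropped(self):
        rng = np.random.default_rng(14)
        tables = gaussian_tables(rng, shift=6.0)
        tables["M1"].loc[0:49, "s3"] = np.nan
        obs = tables["M2"].iloc[5]
        post = A.infer(tables, obs[STATS + ["t_mut"]], STATS, seed=1)
        assert post.chosen_model == "M2"

    def test_observed_sentinel_removes_statistic(self):
        rng = np.random.default_rng(15)
        tables = gaussian_tables(rng, shift=6.0)
        obs = tables["M3"].iloc[2][STATS + ["t_mut"]].copy()
        obs["s5"] = np.nan
        with pytest.warns(UserWarning, match="s5"):
            post = A.infer(tables, obs, STATS, seed=1)
        assert post.chosen_model == "M3"

    def test_cross_validation_exchangeable_models_near_chance(self):
        """Two models drawn from the same distribution: correct-assignment
        rates sit near 50% (exchangeability)."""
        rng = np.random.default_rng(16)
        n = 600
        tables = {}
        for m in ("A", "B"):
            X = rng.normal(size=(n, 4))
            t = pd.DataFrame(X, columns=[f"s{j}" for j in range(4)])
            t.insert(0, "t_mut", rng.uniform(0, 1, n))
            tables[m] = t
        cm = A.cross_validate_power(tables, n_pseudo=100, seed=2,
                                    n_components=3)
        for m in ("A", "B"):
            se = 3 * np.sqrt(0.25 / 100)
            assert abs(cm.rates[m] - 0.5) < 3 * se + 0.05

    def test_cross_validation_disjoint_supports_perfect(self):
        rng = np.random.default_rng(17)
        tables = gaussian_tables(rng, n=300, shift=40.0, models=("A", "B"))
        cm = A.cross_validate_power(tables, n_pseudo=60, seed=3,
                                    n_components=2)
        assert cm.rates["A"] == 1.0
        assert cm.rates["B"] == 1.0
        assert set(cm.standard_errors) == {"A", "B"}

    def test_cross_validation_insufficient_rows_errors(self):
        rng = np.random.default_rng(18)
        tables = gaussian_tables(rng, n=50)
        with pytest.raises(SweepABCError):
            A.cross_validate_power(tables, n_pseudo=50, seed=0)

    def test_dominance_marginals(self):
        rng = np.random.default_rng(19)
        tables = {}
        for k, h in enumerate((0.0, 0.38, 0.5)):
            for j, m in enumerate(("SDN", "SSV")):
                X = rng.normal(size=(200, 5))
                X[:, 0] += 8 * k
                X[:, 1] += 8 * j
                t = pd.DataFrame(X, columns=[f"s{i}" for i in range(5)])
                tables[(m, h)] = t
        X = rng.normal(size=(200, 5))
        X[:, 0] -= 15
        tables["NTR"] = pd.DataFrame(X, columns=[f"s{i}" for i in range(5)])
        stat_cols = [f"s{i}" for i in range(5)]
        obs = tables[("SDN", 0.0)].iloc[0]
        res = A.dominance_model_choice(tables, obs, stat_cols, seed=4,
                                       n_components=4)
        assert sum(res.joint.values()) == pytest.approx(1, abs=1e-9)
        assert sum(res.dominance_marginal.values()) == pytest.approx(
            1, abs=1e-9)
        # drawn from the recessive table: h=0 marginal dominates
        assert res.dominance_marginal[0.0] == max(
            v for k, v in res.dominance_marginal.items() if k != "NTR")
        for h in (0.0, 0.38, 0.5):
            if res.dominance_marginal[h] > 0:
                assert sum(res.selection_marginal[h].values()) == \
                    pytest.approx(1, abs=1e-9)

    def test_dominance_missing_category_errors(self):
        with pytest.raises(SweepABCError):
            A.dominance_model_choice({"NTR": pd.DataFrame()}, {}, [],
                                     seed=0)
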