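import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mcidi import (
    McidiModel,
    McidiResults,
    ber,
    compute_mcidi,
    fit_pca_80,
    fit_stabilized_lasso,
    select_threshold,
)


def identity_covariance_matrix(n=41, p=5, seed=0):
    """n x p data whose sample covariance (ddof=1) is exactly the identity."""
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(n, p))
    g -= g.mean(axis=0)
    q, _ = np.linalg.qr(g)
    x = np.sqrt(n - 1) * q
    return pd.DataFrame(x, columns=[f"f{j}" for j in range(p)])


class TestPca:
    def test_identity_covariance_retains_four_of_five(self):
        # equal eigenvalues: cumulative ratios are 0.2,...,1.0 and the
        # inclusive 80% rule stops at exactly 4 components
        diffs = identity_covariance_matrix()
        pca = fit_pca_80(diffs, target=0.80)
        assert pca.m == 4
        np.testing.assert_allclose(pca.explained_variance_ratio, 0.2, atol=1e-10)

    def test_rank_one_data(self, rng):
        base = rng.normal(size=20)
        diffs = pd.DataFrame({"a": base, "b": 2 * base, "c": -base})
        pca = fit_pca_80(diffs, scale=False)
        assert pca.m == 1
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_bracketing_invariant(self, rng):
        for _ in range(5):
            diffs = pd.DataFrame(rng.normal(size=(30, 8)) * rng.uniform(0.5, 3, 8))
            diffs.columns = [f"f{j}" for j in range(8)]
            pca = fit_pca_80(diffs)
            cum = np.cumsum(pca.explained_variance_ratio)
            assert cum[pca.m - 1] >= 0.80 - 1e-9
            if pca.m > 1:
                assert cum[pca.m - 2] < 0.80

    def test_loadings_orthonormal(self, rng):
        diffs = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        pca = fit_pca_80(diffs)
        gram = pca.loadings @ pca.loadings.T
        np.testing.assert_allclose(gram, np.eye(pca.m), atol=1e-8)

    def test_training_scores_centered(self, rng):
        diffs = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        pca = fit_pca_80(diffs)
        scores = pca.transform(diffs)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_mean_vector_projects_to_origin(self, rng):
        diffs = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        pca = fit_pca_80(diffs)
        one = pd.DataFrame([diffs.mean(axis=0)], columns=diffs.columns)
        np.testing.assert_allclose(pca.transform(one), 0.0, atol=1e-10)

    def test_reconstruction_error_equals_discarded_mass(self, rng):
        diffs = pd.DataFrame(rng.normal(size=(40, 6)) * [3, 2, 1.5, 1, 0.5, 0.2])
        diffs.columns = [f"f{j}" for j in range(6)]
        pca = fit_pca_80(diffs, scale=False)
        xc = diffs.to_numpy() - pca.mean
        scores = pca.transform(diffs)
        residual = xc - scores @ pca.loadings
        discarded = pca.explained_variance[pca.m :].sum() * (len(diffs) - 1)
        assert (residual**2).sum() == pytest.approx(discarded, rel=1e-8)

    def test_feature_mismatch_rejected(self, rng):
        diffs = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        pca = fit_pca_80(diffs)
        with pytest.raises(ValueError):
            pca.transform(diffs.rename(columns={"a": "zzz"}))

    def test_zero_variance_rejected(self):
        diffs = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        with pytest.raises(ValueError):
            fit_pca_80(diffs)


class TestStabilizedLasso:
    def test_null_labels_give_prevalence_intercept(self, rng):
        scores = rng.normal(size=(150, 3))
        y = np.array(["MCI"] * 45 + ["healthy"] * 105)
        alpha0, alphas, _ = fit_stabilized_lasso(
            scores, y, n_repeats=5, seed=1, n_penalties=20
        )
        assert np.abs(alphas).max() < 0.1
        assert alpha0 == pytest.approx(np.log(45 / 105), abs=0.15)

    def test_predictive_component_dominates(self, rng):
        n = 100
        y01 = np.r_[np.ones(30), np.zeros(70)]
        scores = rng.normal(size=(n, 3))
        scores[:, 1] = 2.5 * (y01 - y01.mean()) + rng.normal(0, 0.4, n)
        y = np.where(y01 == 1, "MCI", "healthy")
        _, alphas, _ = fit_stabilized_lasso(scores, y, n_repeats=3, seed=2, n_penalties=20)
        assert abs(alphas[1]) > 3 * max(abs(alphas[0]), abs(alphas[2]), 1e-6)
        assert alphas[1] > 0  # MCI coded 1

    def test_seeded_determinism(self, rng):
        scores = rng.normal(size=(60, 2))
        y = np.array(["MCI"] * 20 + ["healthy"] * 40)
        out1 = fit_stabilized_lasso(scores, y, n_repeats=1, seed=9, n_penalties=20)
        out2 = fit_stabilized_lasso(scores, y, n_repeats=1, seed=9, n_penalties=20)
        assert out1[0] == out2[0]
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_averaging_stabilizes_coefficients(self, rng):
        # across-repeat spread of 5-repeat averages is below that of single
        # repeats (the stated purpose of the averaging)
        n = 80
        y01 = np.r_[np.ones(25), np.zeros(55)]
        scores = rng.normal(size=(n, 4))
        scores[:, 0] += 0.8 * y01
        y = np.where(y01 == 1, "MCI", "healthy")
        _, _, per_repeat = fit_stabilized_lasso(
            scores, y, n_repeats=20, seed=3, n_penalties=20
        )
        j = 1 + np.argmax(per_repeat[:, 1:].std(axis=0))  # most variable coef
        singles_sd = per_repeat[:, j].std(ddof=1)
        avg5 = per_repeat[:, j].reshape(4, 5).mean(axis=1)
        assert avg5.std(ddof=1) < singles_sd

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_stabilized_lasso(rng.normal(size=(10, 2)), np.array(["MCI"] * 10))


class TestMcidiFunction:
    def test_zero_predictor_gives_half(self):
        out = compute_mcidi(0.0, np.zeros(3), np.ones((1, 3)))
        assert out[0] == pytest.approx(0.5)

    def test_intercept_only_closed_form(self):
        out = compute_mcidi(np.log(3.0), np.array([]), np.zeros((1, 0)))
        assert out[0] == pytest.approx(0.75)

    def test_limits_and_monotonicity(self):
        alphas = np.array([1.0, -2.0])
        grid = np.linspace(-30, 30, 201)
        vals = compute_mcidi(0.0, alphas, np.c_[grid, np.zeros_like(grid)]).ravel()
        assert np.all(np.diff(vals) >= 0)  # increasing in a +-signed component
        assert vals[-1] == pytest.approx(1.0, abs=1e-9)
        vals2 = compute_mcidi(0.0, alphas, np.c_[np.zeros_like(grid), grid]).ravel()
        assert np.all(np.diff(vals2) <= 0)  # decreasing in a --signed component
        assert np.all((vals > 0) & (vals < 1))


class TestBer:
    @pytest.mark.parametrize(
        "fpr,fnr,mode,expected",
        [
            (0.0, 0.0, "arithmetic", 0.0),
            (0.0, 0.0, "harmonic", 0.0),
            (0.2, 0.4, "arithmetic", 0.30),
            (0.2, 0.4, "harmonic", 2 * 0.2 * 0.4 / 0.6),
            (1.0, 1.0, "arithmetic", 1.0),
        ],
    )
    def test_values(self, fpr, fnr, mode, expected):
        assert ber(fpr, fnr, mode) == pytest.approx(expected)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ber(1.2, 0.0)


class TestSelectThreshold:
    def test_separable_case(self):
        values = [0.1, 0.2, 0.8, 0.9]
        labels = ["healthy", "healthy", "MCI", "MCI"]
        tau = select_threshold(values, labels)
        assert tau == pytest.approx(0.5)

    def test_inverted_scores_boundary(self):
        # scores perfectly anti-ranked: predicting everyone MCI (tau = 0)
        # yields BER 0.5, as good as anything else, and 0 is the smallest
        # candidate achieving it
        values = [0.9, 0.8, 0.2, 0.1]
        labels = ["healthy", "healthy", "MCI", "MCI"]
        tau = select_threshold(values, labels)
        y = np.array(labels) == "MCI"
        v = np.asarray(values)
        pred = v >= tau
        fpr = (pred & ~y).sum() / 2
        fnr = (~pred & y).sum() / 2
        assert ber(fpr, fnr) == pytest.approx(0.5)
        assert tau == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.9], ["MCI", "MCI"])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_dense_grid_oracle(self, data):
        n = data.draw(st.integers(4, 30))
        values = np.round(
            np.array(data.draw(st.lists(st.floats(0.01, 0.99), min_size=n, max_size=n))), 4
        )
        raw_labels = data.draw(
            st.lists(st.sampled_from(["MCI", "healthy"]), min_size=n, max_size=n)
        )
        if len(set(raw_labels)) < 2:
            raw_labels[0], raw_labels[1] = "MCI", "healthy"
        labels = np.array(raw_labels)
        tau = select_threshold(values, labels)
        y = labels == "MCI"

        def ber_at(t):
            pred = values >= t
            return (
                (pred & ~y).sum() / (~y).sum() + ((~pred) & y).sum() / y.sum()
            ) / 2.0

        grid = np.linspace(0, 1, 1001)
        best_grid = min(ber_at(t) for t in grid)
        assert ber_at(tau) <= best_grid + 1e-12


@pytest.fixture(scope="module")
def fitted(small_cohort, fast_config):
    utt, labels, _ = small_cohort
    model = McidiModel.from_tables(utt, labels, config=fast_config)
    return model, model.fit(seed=4)


class TestModelResults:

    def test_params_shape_and_index_bounds(self, fitted):
        model, res = fitted
        assert res.params.index[0] == "alpha_0"
        assert len(res.params) == res.pca.m + 1
        values = res.predict().to_numpy()
        assert ((values > 0) & (values < 1)).all()
        assert 0.0 <= res.threshold <= 1.0

    def test_summary_mentions_key_quantities(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "threshold" in text
        assert "alpha_0" in text
        assert f"{res.pca.m}" in text

    def test_save_load_round_trip(self, fitted, tmp_path):
        model, res = fitted
        path = tmp_path / "model.json"
        res.save(path)
        loaded = McidiResults.load(path)
        np.testing.assert_allclose(
            loaded.predict(model.diffs).to_numpy(), res.predict().to_numpy(), atol=1e-12
        )
        assert loaded.threshold == res.threshold
        assert loaded.config == res.config

    def test_evaluate_reports_all_metrics(self, fitted):
        _, res = fitted
        report = res.evaluate()
        for key in ("sensitivity", "specificity", "ppv", "npv", "f_measure", "accuracy"):
            assert getattr(report, key) is not None
        assert 0.0 <= report.auc <= 1.0

    def test_no_surviving_features_rejected(self, small_cohort, fast_config):
        utt, labels, _ = small_cohort
        # an impossible correlation threshold empties the screen
        cfg = fast_config.replace(corr_threshold=0.999)
        with pytest.raises(ValueError, match="survived"):
            McidiModel.from_tables(utt, labels, config=cfg)
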