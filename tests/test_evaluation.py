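import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mcidi import (
    ConfusionMatrix,
    PipelineConfig,
    SyntheticConfig,
    confusion,
    draw_cohort,
    group_t_test,
    kfold_cv,
    metrics,
    mmse_correlation,
    roc_auc,
)
from mcidi.evaluation import round_half_up


class TestConfusion:
    def test_perfect_scores_interior_threshold(self):
        cm = confusion([0.9, 0.8, 0.1], ["MCI", "MCI", "healthy"], 0.5)
        assert (cm.fn, cm.fp) == (0, 0)
        assert (cm.tp, cm.tn) == (2, 1)

    def test_all_below_threshold(self):
        cm = confusion([0.1, 0.2], ["MCI", "healthy"], 0.9)
        assert (cm.tp, cm.fp) == (0, 0)

    def test_decision_rule_inclusive_at_threshold(self):
        cm = confusion([0.36], ["MCI"], 0.36)
        assert cm.tp == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_per_subject_tally(self, data):
        n = data.draw(st.integers(1, 40))
        values = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        labels = data.draw(
            st.lists(st.sampled_from(["MCI", "healthy"]), min_size=n, max_size=n)
        )
        tau = data.draw(st.floats(0, 1))
        cm = confusion(values, labels, tau)
        tally = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        for v, l in zip(values, labels):
            pred = "MCI" if v >= tau else "healthy"
            key = {"MCIMCI": "tp", "MCIhealthy": "fn", "healthyMCI": "fp",
                   "healthyhealthy": "tn"}[l + pred]
            tally[key] += 1
        assert cm.to_dict() == tally


class TestMetrics:
    def test_all_correct_gives_ones(self):
        rep = metrics(ConfusionMatrix(tp=1, fn=0, fp=0, tn=1))
        assert all(
            getattr(rep, k) == 1.0
            for k in ("sensitivity", "specificity", "ppv", "npv", "f_measure", "accuracy")
        )

    def test_zero_denominators_are_undefined_not_zero(self):
        rep = metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))
        assert rep.sensitivity is None
        assert rep.ppv == 0.0
        rep2 = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=0))
        assert rep2.accuracy is None

    def test_f_is_harmonic_mean_of_ppv_and_sensitivity(self, rng):
        for _ in range(10):
            tp, fn, fp, tn = rng.integers(1, 50, size=4)
            rep = metrics(ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
            expected = 2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity)
            assert rep.f_measure == pytest.approx(expected, abs=1e-12)

    def test_half_up_rounding(self):
        assert round_half_up(0.625) == 0.63
        assert round_half_up(0.875) == 0.88
        assert round_half_up(0.874999) == 0.87


class TestRocAuc:
    def test_perfect_ranking(self):
        (_, _), auc = roc_auc([0.9, 0.8, 0.2, 0.1], ["MCI", "MCI", "healthy", "healthy"])
        assert auc == 1.0

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=50)
        labels = np.array(["MCI"] * 20 + ["healthy"] * 30)
        _, auc1 = roc_auc(v, labels)
        _, auc2 = roc_auc(np.exp(3 * v) + 7, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_matches_pairwise_brute_force(self, rng):
        v = rng.integers(0, 6, size=16).astype(float)  # ties included
        labels = np.array(["MCI"] * 6 + ["healthy"] * 10)
        _, auc = roc_auc(v, labels)
        pos, neg = v[:6], v[6:]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / 60, abs=1e-12)

    def test_shuffled_labels_near_half(self, rng):
        v = rng.normal(size=4000)
        labels = np.where(rng.random(4000) < 0.3, "MCI", "healthy")
        _, auc = roc_auc(v, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], ["MCI", "MCI"])


class TestGroupTests:
    def test_welch_matches_hand_formula(self):
        a = np.array([0.8, 0.7, 0.9, 0.6, 0.75])  # MCI index values
        b = np.array([0.2, 0.3, 0.25, 0.1])  # healthy
        t, df, p = group_t_test(
            np.r_[a, b], ["MCI"] * 5 + ["healthy"] * 4
        )
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 3)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-10)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-12)

    def test_identical_distributions_near_zero_t(self, rng):
        v = np.tile(rng.normal(size=50), 2)
        labels = ["MCI"] * 50 + ["healthy"] * 50
        t, _, p = group_t_test(v, labels)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            group_t_test([1.0, 1.0, 2.0, 2.0], ["MCI", "MCI", "healthy", "healthy"])

    def test_affine_decreasing_mmse_gives_minus_one(self):
        mmse = np.array([30, 28, 26, 25, 24, 29])
        values = 1.0 - 0.03 * mmse
        r, _ = mmse_correlation(values, mmse)
        assert r == pytest.approx(-1.0, abs=1e-12)


class _ConstantHealthy:
    """Stub pipeline predicting 'healthy' for everyone."""

    threshold = 0.5

    def predict(self, diffs):
        return pd.Series(np.zeros(len(diffs)), index=diffs.index)


def _constant_fit_fn(train_utt, train_labels, config, seed):
    return _ConstantHealthy()


@pytest.fixture(scope="module")
def cohort():
    # strong MMSE link so every training fold keeps some features
    return draw_cohort(
        SyntheticConfig(
            n_subjects=45, n_features=12, frac_state_only=0.25,
            frac_state_mmse=0.5, prop_mci=0.33, mmse_link_slope=0.3, seed=41,
        )
    )


class TestKfoldCv:

    def test_leave_one_out_structure(self, cohort):
        utt, labels, _ = cohort
        n = len(labels)
        report = kfold_cv(utt, labels, k=n, fit_fn=_constant_fit_fn)
        assert report.k == n
        assert sum(report.fold_sizes) == n  # every subject held out exactly once
        assert all(s == 1 for s in report.fold_sizes)

    def test_constant_predictor_metrics(self, cohort):
        utt, labels, _ = cohort
        report = kfold_cv(utt, labels, k=4, fit_fn=_constant_fit_fn)
        assert report.pooled.sensitivity == 0.0
        assert report.pooled.specificity == 1.0

    def test_full_pipeline_cv_runs_and_pools(self, cohort, fast_config):
        utt, labels, _ = cohort
        report = kfold_cv(utt, labels, k=3, config=fast_config, seed=1)
        assert report.pooled.cm.total == len(labels)
        means = report.fold_means()
        assert set(means) == {"sensitivity", "specificity", "accuracy"}

    def test_invalid_k_rejected(self, cohort):
        utt, labels, _ = cohort
        with pytest.raises(ValueError):
            kfold_cv(utt, labels, k=1, fit_fn=_constant_fit_fn)
        with pytest.raises(ValueError):
            kfold_cv(utt, labels, k=len(labels) + 1, fit_fn=_constant_fit_fn)
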