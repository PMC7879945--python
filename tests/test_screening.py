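"""Inverted-role screen: LRT oracle checks, adjustment, CV ranking."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from invsel.exceptions import DegenerateDesignError, InvalidConfigError
from invsel.screening import (
    InvertedRoleSelector,
    adjust_pvalues,
    cv_inverted,
    filter_significant,
    lrt_pvalue,
    lrt_pvalues,
    select_top_v1,
)
from invsel.simulate import SimulationConfig, simulate_dataset


def statsmodels_lrt(feature, classification):
    """Independent Gaussian-likelihood LRT via statsmodels OLS fits."""
    full = sm.OLS(feature, sm.add_constant(np.asarray(classification, float))).fit()
    null = sm.OLS(feature, np.ones((len(feature), 1))).fit()
    stat = 2.0 * (full.llf - null.llf)
    return stats.chi2.sf(stat, df=1)


class TestLRT:
    def test_matches_statsmodels_on_fixture(self):
        feature = np.array([1.2, 0.8, 2.1, 1.9, 3.3, 2.7, 4.1, 3.8, 5.2, 4.6])
        classification = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4], dtype=float)
        assert lrt_pvalue(feature, classification) == pytest.approx(
            statsmodels_lrt(feature, classification), abs=1e-8
        )

    def test_noiseless_relation_degenerates_to_zero(self):
        y = np.array([0.0, 1, 0, 1, 1, 0, 1, 0])
        assert lrt_pvalue(y.copy(), y) == 0.0

    def test_constant_feature_gets_p_one(self):
        y = np.array([0.0, 1, 0, 1, 1, 0])
        assert lrt_pvalue(np.full(6, 3.0), y) == 1.0

    def test_constant_classification_rejected(self):
        with pytest.raises(DegenerateDesignError):
            lrt_pvalue(np.arange(6.0), np.ones(6))

    def test_null_pvalues_uniform(self):
        """Under independence the per-feature p-values are U(0,1) (KS, 1%)."""
        rng = np.random.default_rng(0)
        y = np.repeat([0.0, 1.0], 25)
        X = rng.normal(size=(50, 2000))
        p = lrt_pvalues(X, y)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_covariate_is_partialled_out(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0.0, 1.0], 30)
        cov = rng.normal(size=60)
        # feature driven by the covariate only: no classification signal
        feature = 2.0 * cov + rng.normal(scale=0.1, size=60)
        p_without = lrt_pvalue(feature, y)
        p_with = lrt_pvalue(feature, y, covariates=cov)
        assert p_with > 0.05 or p_with > p_without  # covariate absorbs the fit
        # feature driven by classification stays detected despite covariate
        feature2 = y * 3.0 + cov + rng.normal(scale=0.5, size=60)
        assert lrt_pvalue(feature2, y, covariates=cov) < 1e-6


class TestFactorEncoding:
    def test_binary_labels_factor_equals_numeric(self, rng):
        y = np.repeat([0.0, 1.0], 15)
        feature = y + rng.normal(size=30)
        assert lrt_pvalue(feature, y, encoding="factor") == pytest.approx(
            lrt_pvalue(feature, y, encoding="numeric"), abs=1e-12
        )

    def test_factor_detects_nonmonotone_pattern(self, rng):
        # group means (0, 2, 0): invisible to a linear trend, obvious to a
        # factor encoding with 2 degrees of freedom
        y = np.tile([0.0, 1.0, 2.0], 20)
        feature = np.where(y == 1.0, 2.0, 0.0) + rng.normal(scale=0.5, size=60)
        assert lrt_pvalue(feature, y, encoding="factor") < 1e-6
        assert lrt_pvalue(feature, y, encoding="numeric") > 0.05


class TestAdjust:
    def test_bonferroni_closed_form(self):
        assert adjust_pvalues([0.01, 0.02], "bonferroni").tolist() == [0.02, 0.04]

    def test_bh_step_up(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "BH")
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_none_is_identity(self):
        p = np.array([0.4, 0.01, 1.0])
        assert np.array_equal(adjust_pvalues(p, "none"), p)

    def test_holm_and_cap(self):
        out = adjust_pvalues([0.04, 0.5, 0.9], "holm")
        assert out[0] == pytest.approx(0.12)
        assert out.max() <= 1.0

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=40)
        for method in ("BH", "bonferroni", "holm"):
            assert (adjust_pvalues(p, method) >= p - 1e-15).all()

    def test_unknown_method(self):
        with pytest.raises(InvalidConfigError):
            adjust_pvalues([0.1], "fdr_qvalue")


class TestFilterSignificant:
    def test_strict_inequality_at_alpha(self):
        assert filter_significant([0.04, 0.05, 0.06], 0.05).tolist() == [0]

    def test_corners(self):
        assert filter_significant(np.ones(5)).size == 0
        assert filter_significant(np.zeros(5)).tolist() == [0, 1, 2, 3, 4]

    def test_lower_alpha_shrinks_selection(self, rng):
        p = rng.uniform(size=60)
        sizes = [filter_significant(p, a).size for a in (0.2, 0.1, 0.05, 0.01)]
        assert sizes == sorted(sizes, reverse=True)


class TestInvertedCV:
    def test_noiseless_relation_zero_error(self):
        y = np.tile([0.0, 1.0, 2.0], 4)
        feature = 2.0 * y
        assert cv_inverted(feature, y, k_folds=3, seed=0) == pytest.approx(0.0, abs=1e-20)

    def test_loo_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        y = np.array([0.0, 1, 0, 1, 1, 0])
        feature = y + rng.normal(size=6)
        got = cv_inverted(feature, y, k_folds=6, seed=0)
        sq = []
        for i in range(6):
            mask = np.arange(6) != i
            D = np.column_stack([np.ones(5), y[mask]])
            beta = np.linalg.lstsq(D, feature[mask], rcond=None)[0]
            sq.append((feature[i] - beta[0] - beta[1] * y[i]) ** 2)
        assert got == pytest.approx(np.mean(sq), abs=1e-10)

    def test_signal_ranks_below_noise(self):
        # both features share the same MARGINAL sd; the signal feature spends
        # part of it on the group difference, so its inverted-role residual
        # (hence CV error) is smaller
        wins = 0
        reps = 100
        d = 1.6  # strong group separation; between-group variance d^2/4
        resid_sd = np.sqrt(1.0 - d * d / 4.0)
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            y = np.repeat([0.0, 1.0], 20)
            signal = d * y + rng.normal(scale=resid_sd, size=40)
            noise = rng.normal(scale=1.0, size=40)
            e_sig = cv_inverted(signal, y, k_folds=3, seed=seed)
            e_noise = cv_inverted(noise, y, k_folds=3, seed=seed)
            wins += e_sig < e_noise
        assert wins >= 0.95 * reps

    def test_invalid_folds(self):
        with pytest.raises(InvalidConfigError):
            cv_inverted(np.arange(6.0), np.repeat([0.0, 1], 3), k_folds=1)


class TestSelectTopV1:
    def test_order_by_error(self):
        assert select_top_v1([0.5, 0.1, 0.3], 50).tolist() == [1, 2, 0]

    def test_cap_at_sample_count(self):
        errs = np.arange(80.0)[::-1]
        assert select_top_v1(errs, 50).size == 50

    def test_ties_keep_original_order(self):
        assert select_top_v1([0.2, 0.2, 0.2], 10).tolist() == [0, 1, 2]

    def test_maps_through_feature_indices(self):
        out = select_top_v1([0.9, 0.1], 10, feature_idx=np.array([4, 7]))
        assert out.tolist() == [7, 4]

    def test_empty_input_empty_output(self):
        assert select_top_v1(np.array([]), 10).size == 0


class TestSelectorCalibrationAndRecovery:
    def test_bonferroni_familywise_error_near_alpha(self):
        """Global null: P(any Bonferroni discovery) is close to alpha."""
        rng = np.random.default_rng(3)
        y = np.repeat([0.0, 1.0], 25)
        hits = 0
        reps = 1000
        for _ in range(reps):
            p = lrt_pvalues(rng.normal(size=(50, 100)), y)
            hits += filter_significant(adjust_pvalues(p, "bonferroni")).size > 0
        assert 0.02 <= hits / reps <= 0.10

    def test_recovers_informative_features_at_strong_effect(self):
        recalls, precisions = [], []
        for seed in range(10):
            cfg = SimulationConfig(
                n_samples=50, n_features=100, mean_diff=3.0, sd=1.0,
                prob1=0.0, prob2=1.0, seed=seed,
            )
            ds = simulate_dataset(cfg)
            sel = InvertedRoleSelector(random_state=seed)
            sel.fit(ds.features, ds.observed_labels.astype(float))
            truth = set(ds.informative_idx.tolist())
            got = set(sel.selected_idx_.tolist())
            recalls.append(len(truth & got) / len(truth))
            precisions.append(len(truth & got) / max(len(got), 1))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.9

    def test_selector_sklearn_contract(self):
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline

        from invsel.stepwise import StepwiseGLM

        cfg = SimulationConfig(mean_diff=3.0, sd=1.0, prob1=0.1, prob2=0.9, seed=2)
        ds = simulate_dataset(cfg)
        sel = InvertedRoleSelector(alpha=0.05, adjust="BH", random_state=0)
        assert clone(sel).get_params()["alpha"] == 0.05
        pipe = Pipeline([("select", sel), ("model", StepwiseGLM(random_state=0))])
        pipe.fit(ds.features, ds.observed_labels.astype(float))
        scores = pipe.named_steps["model"].predict_scores(
            pipe.named_steps["select"].transform(ds.features)
        )
        assert scores.shape == (50,)

    def test_empty_selection_transforms_to_zero_columns(self, rng):
        X = rng.normal(size=(30, 20))
        y = np.repeat([0.0, 1.0], 15)
        sel = InvertedRoleSelector(alpha=0.05, adjust="bonferroni", random_state=0)
        sel.fit(X, rng.permutation(y))
        if sel.n_selected_ == 0:  # overwhelmingly likely under the null
            assert sel.transform(X).shape == (30, 0)
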