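"""ROC/AUC, DeLong intervals, cutoffs, M-values, and logistic regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from epicascade.classify import (PerfectSeparationError, logistic_fit,
                                 m_value, optimal_cutoff, roc_auc,
                                 run_classification_suite)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([3, 2.6, 2, 0], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_all_pairs_oracle(self):
        assert roc_auc([3, 1, 2, 0], [1, 1, 0, 0]).auc == 0.75

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0)

    def test_ties_get_half_credit(self):
        assert roc_auc([1, 1], [1, 0]).auc == 0.5

    def test_matches_trapezoidal_integral(self):
        """Rank AUC equals sklearn's trapezoidal ROC integral."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(10):
            scores = rng.normal(size=80) + np.repeat([0.0, 0.7], 40)
            tie_mask = rng.random(80) < 0.3
            scores[tie_mask] = np.round(scores[tie_mask], 0)  # inject ties
            labels = np.repeat([0, 1], 40)
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_delong_interval_brackets_auc(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(1, 1, 60), rng.normal(0, 1, 60)]
        labels = np.r_[np.ones(60, int), np.zeros(60, int)]
        res = roc_auc(scores, labels)
        assert res.ci95[0] <= res.auc <= res.ci95[1]
        assert 0.0 <= res.ci95[0] and res.ci95[1] <= 1.0

    def test_delong_variance_close_to_bootstrap(self):
        """DeLong SE agrees with a bootstrap SE within 20% at n=60/60."""
        rng = np.random.default_rng(3)
        pos = rng.normal(0.8, 1, 60)
        neg = rng.normal(0.0, 1, 60)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(60, int), np.zeros(60, int)]
        res = roc_auc(scores, labels)
        delong_se = (res.ci95[1] - res.auc) / 1.96
        boot = []
        for _ in range(2000):
            p = rng.choice(pos, 60)
            n = rng.choice(neg, 60)
            boot.append(roc_auc(np.r_[p, n], labels).auc)
        boot_se = np.std(boot)
        assert delong_se == pytest.approx(boot_se, rel=0.2)


class TestOptimalCutoff:
    def test_separable_midpoint(self):
        cutoff, sens, spec = optimal_cutoff([3, 2.6, 2, 0], [1, 1, 0, 0])
        assert (cutoff, sens, spec) == (2.3, 1.0, 1.0)

    def test_anti_informative_direction_flip(self):
        # low scores mark tumors; direction must flip to keep sens high
        cutoff, sens, spec = optimal_cutoff([0, 0.4, 2, 3], [1, 1, 0, 0])
        assert sens == 1.0 and spec == 1.0
        assert cutoff == pytest.approx(1.2)

    def test_tie_breaks_toward_higher_specificity(self):
        """pos {1,3} / neg {2,4}: cutoffs 1.5 and 3.5 tie on J; the one with
        the higher specificity must be returned (direction auto-resolves to
        low-score-positive here since AUC = 0.25)."""
        cutoff, sens, spec = optimal_cutoff([1, 3, 2, 4], [1, 1, 0, 0])
        pos, neg = np.array([1, 3]), np.array([2, 4])
        best_j = sens + spec - 1.0
        for c in [1.5, 2.5, 3.5]:
            j = (pos <= c).mean() + (neg > c).mean() - 1.0
            if j == pytest.approx(best_j):
                assert spec >= (neg > c).mean()
            else:
                assert j < best_j

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff([1, 1, 1], [1, 0, 1])


class TestMValue:
    def test_half_is_zero(self):
        assert m_value(0.5) == pytest.approx(0.0)

    def test_point_eight_is_two(self):
        assert m_value(0.8) == pytest.approx(2.0)

    def test_zero_clipped(self):
        eps = 1e-6
        assert m_value(0.0) == pytest.approx(np.log2(eps / (1 - eps)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m_value(1.2)


class TestLogisticFit:
    def test_matches_brute_force_likelihood(self):
        """IRLS coefficients maximize the written log-likelihood (Nelder-Mead
        oracle) to 1e-6 on a 6-point fixture."""
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([0, 0, 1, 0, 1, 1])
        fit = logistic_fit(pd.DataFrame({"x": x}), y)

        def nll(params):
            eta = params[0] + params[1] * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(fit.coefficients.to_numpy(), res.x,
                                   atol=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = rng.normal(size=(80, 2))
        eta = 0.5 + x @ np.array([1.0, -0.7])
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_fit(pd.DataFrame(x, columns=["a", "b"]), y)
        sm_fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), sm_fit.params,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors.to_numpy(),
                                   sm_fit.bse, atol=1e-5)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(int)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert np.all(np.diff(fit.llf_trajectory) >= -1e-8)

    def test_univariate_matches_multivariate_on_orthogonal_design(self):
        """With orthogonalized, balanced predictors the joint fit reproduces
        each single-predictor coefficient."""
        rng = np.random.default_rng(6)
        n = 4000
        a = rng.choice([-1.0, 1.0], n)
        b = rng.choice([-1.0, 1.0], n)
        eta = 0.4 * a + 0.8 * b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        joint = logistic_fit(pd.DataFrame({"a": a, "b": b}), y)
        uni_a = logistic_fit(pd.DataFrame({"a": a}), y)
        # same estimand for +/-1 orthogonal designs, up to sampling noise
        assert joint.coefficients["a"] == pytest.approx(
            uni_a.coefficients["a"], abs=0.15
        )

    def test_perfect_separation_raised(self):
        x = np.array([0.0, 1, 2, 10, 11, 12])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(PerfectSeparationError):
            logistic_fit(pd.DataFrame({"x": x}), y)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(pd.DataFrame({"x": [1.0, 1, 1, 1]}), [0, 1, 0, 1])

    def test_null_wald_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=40)
            y = np.repeat([0, 1], 20)
            fit = logistic_fit(pd.DataFrame({"x": x}), y)
            pvals.append(fit.wald_p["x"])
        frac = np.mean(np.array(pvals) < 0.05)
        assert frac <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / 200)


class TestSuite:
    def test_empty_panel_empty_tables(self, cohort):
        cexpr, manifest, betas, clinical = cohort
        out = run_classification_suite([], cexpr, betas, [], clinical)
        assert len(out["genes"]) == 0
        assert len(out["probes"]) == 0

    def test_drivers_informative_in_planted_cohort(self, ko_experiment, cohort):
        truth = ko_experiment[3]
        cexpr, manifest, betas, clinical = cohort
        drivers = sorted(truth.driver_gene_ids)[:5]
        probes = manifest.loc[
            manifest.gene_id.isin(drivers), "probe_id"
        ].tolist()[:5]
        out = run_classification_suite(drivers, cexpr, betas, probes, clinical)
        # drivers are down in tumors: AUC clearly below 0.5
        assert (out["genes"]["auc"] < 0.5).all()
        # hypermethylated probes: AUC clearly above 0.5
        assert (out["probes"]["auc"] > 0.5).all()
        assert ((out["genes"]["sensitivity"] > 0.5)
                & (out["genes"]["specificity"] > 0.5)).all()

    def test_deterministic(self, ko_experiment, cohort):
        truth = ko_experiment[3]
        cexpr, manifest, betas, clinical = cohort
        drivers = sorted(truth.driver_gene_ids)[:3]
        a = run_classification_suite(drivers, cexpr, betas, [], clinical)
        b = run_classification_suite(drivers, cexpr, betas, [], clinical)
        pd.testing.assert_frame_equal(a["genes"], b["genes"])

    def test_all_missing_probe_skipped(self, cohort):
        cexpr, manifest, betas, clinical = cohort
        betas = betas.copy()
        betas.iloc[0] = np.nan
        probe = betas.index[0]
        out = run_classification_suite([], cexpr, betas, [probe], clinical)
        assert probe in set(out["skipped_probes"]["probe_id"])
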