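"""Metrics, permutation inference, power/CI closed forms, workflow behavior."""

import itertools
import math

import numpy as np
import pytest

from amygconn.cohort import CohortSpec, simulate_clinical_cohort
from amygconn.connectivity import fisher_z, zscore_across_subjects
from amygconn.evaluate import (
    check_normality,
    correlation_power,
    evaluate_predictions,
    model_based_r2,
    permutation_test,
    prediction_r2,
    r2_confidence_interval,
    run_replication,
)
from amygconn.model import FixedModelSpec


def oracle_prediction_r2(obs, full, compact):
    """From-definition recomputation: 1 - MSE(full)/MSE(compact)."""
    mse_f = sum((o - f) ** 2 for o, f in zip(obs, full)) / len(obs)
    mse_c = sum((o - c) ** 2 for o, c in zip(obs, compact)) / len(obs)
    return 1.0 - mse_f / mse_c


def oracle_model_based(obs, full, compact):
    def corr(a, b):
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        da = math.sqrt(sum((x - ma) ** 2 for x in a))
        db = math.sqrt(sum((y - mb) ** 2 for y in b))
        return num / (da * db)

    return corr(obs, full) ** 2 - corr(obs, compact) ** 2


class TestPredictionR2:
    def test_no_improvement_is_zero(self, rng):
        obs = rng.normal(0, 1, 10)
        pred = rng.normal(0, 1, 10)
        assert prediction_r2(obs, pred, pred).prediction_r2 == pytest.approx(0.0)

    def test_hand_example(self):
        m = prediction_r2([1, 2, 3], [1.5, 2, 2.5], [2, 2, 2])
        assert m.prediction_r2 == pytest.approx(0.75)
        assert m.nmse == pytest.approx(0.25)

    def test_perfect_full_model_reaches_one(self, rng):
        obs = rng.normal(0, 1, 10)
        assert prediction_r2(obs, obs, obs + 1).prediction_r2 == pytest.approx(1.0)

    def test_perfect_compact_model_is_an_error(self, rng):
        obs = rng.normal(0, 1, 10)
        with pytest.raises(ValueError):
            prediction_r2(obs, obs + 1, obs)

    def test_invariant_under_joint_subject_relabeling(self, rng):
        obs, full, compact = rng.normal(0, 1, (3, 20))
        perm = rng.permutation(20)
        assert prediction_r2(obs, full, compact).prediction_r2 == pytest.approx(
            prediction_r2(obs[perm], full[perm], compact[perm]).prediction_r2
        )


class TestModelBasedR2:
    def test_affine_map_of_observed_is_perfect(self, rng):
        obs = rng.normal(0, 1, 15)
        m = model_based_r2(obs, 3 * obs + 2, rng.normal(0, 1, 15))
        assert m.r2_full == pytest.approx(1.0)

    def test_hand_example(self):
        m = model_based_r2([0, 1, 2], [0, 2, 4], [0, 1, 1])
        assert m.r2_full == pytest.approx(1.0)
        assert m.r2_compact == pytest.approx(0.75)
        assert m.delta_model_r2 == pytest.approx(0.25)

    def test_translation_invariance(self, rng):
        obs, full, compact = rng.normal(0, 1, (3, 20))
        a = model_based_r2(obs, full, compact)
        b = model_based_r2(obs, full + 100.0, compact)
        assert a.r2_full == pytest.approx(b.r2_full)

    def test_constant_vector_is_an_error(self, rng):
        obs = rng.normal(0, 1, 10)
        with pytest.raises(ValueError):
            model_based_r2(obs, np.ones(10), obs)


def test_metrics_match_independent_oracles_on_random_instances(rng):
    """Both metrics agree with from-definition recomputations to 1e-12."""
    for _ in range(1000):
        n = int(rng.integers(5, 30))
        obs = rng.normal(0, 5, n)
        full = obs + rng.normal(0, 2, n)
        compact = obs + rng.normal(0, 3, n)
        m = evaluate_predictions(obs, full, compact)
        assert m.prediction_r2 == pytest.approx(
            oracle_prediction_r2(obs, full, compact), abs=1e-12
        )
        assert m.delta_model_r2 == pytest.approx(
            oracle_model_based(obs, full, compact), abs=1e-12
        )


class TestPermutation:
    SPEC = FixedModelSpec(centered=True)

    def _cohort_vectors(self, seed, n=42, r2_conn=0.0):
        cohort = simulate_clinical_cohort(
            CohortSpec(n_subjects=n, r2_conn_incremental=r2_conn, seed=seed)
        )
        b = np.array([r.baseline_lsas for r in cohort])
        d = np.array([r.delta_lsas for r in cohort])
        c = zscore_across_subjects(fisher_z(np.array([r.true_composite_conn for r in cohort])))
        return b - b.mean(), c, d - d.mean()

    def test_perfectly_predictive_term_reaches_the_smallest_p(self, rng):
        bc = rng.normal(0, 10, 10)
        bc -= bc.mean()
        conn = zscore_across_subjects(rng.normal(0, 1, 10))
        spec = self.SPEC
        obs = spec.beta_baseline * bc + spec.beta_conn * conn  # full model exact
        res = permutation_test(bc, conn, obs, spec, "prediction_r2", n_perms=999, seed=0)
        assert res.observed_stat == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_determinism_given_seed(self, rng):
        bc, cz, oc = self._cohort_vectors(seed=5)
        a = permutation_test(bc, cz, oc, self.SPEC, n_perms=199, seed=42)
        b = permutation_test(bc, cz, oc, self.SPEC, n_perms=199, seed=42)
        np.testing.assert_array_equal(a.null_stats, b.null_stats)
        assert a.p_value == b.p_value

    @pytest.mark.parametrize("metric", ["prediction_r2", "delta_model_r2"])
    def test_sampled_p_matches_exhaustive_oracle_at_small_n(self, metric):
        """Brute-force enumeration over all 6! orderings vs the sampled null."""
        gen = np.random.default_rng(17)
        bc = gen.normal(0, 10, 6)
        bc -= bc.mean()
        conn = zscore_across_subjects(gen.normal(0, 1, 6))
        oc = self.SPEC.beta_baseline * bc + 5.0 * conn + gen.normal(0, 8, 6)
        oc -= oc.mean()

        def stat(c):
            full = self.SPEC.beta_baseline * bc + self.SPEC.beta_conn * np.asarray(c)
            compact = self.SPEC.beta_baseline * bc
            if metric == "prediction_r2":
                return oracle_prediction_r2(oc, full, compact)
            return oracle_model_based(oc, full, compact)

        observed = stat(conn)
        null = [stat(p) for p in itertools.permutations(conn)]
        p_exact = sum(s >= observed for s in null) / len(null)

        res = permutation_test(bc, conn, oc, self.SPEC, metric, n_perms=4999, seed=3)
        assert res.observed_stat == pytest.approx(observed, abs=1e-12)
        se = math.sqrt(p_exact * (1 - p_exact) / res.n_perms)
        assert abs(res.p_value - p_exact) <= 3 * se + 1e-3

    def test_null_cohorts_reject_at_about_the_nominal_rate(self):
        rejections = 0
        for i in range(200):
            bc, cz, oc = self._cohort_vectors(seed=1000 + i)
            res = permutation_test(bc, cz, oc, self.SPEC, n_perms=499, seed=i)
            rejections += res.observed_stat > res.crit95
        assert 0.02 <= rejections / 200 <= 0.09

    def test_p_value_bounds_and_crit95(self):
        bc, cz, oc = self._cohort_vectors(seed=8)
        res = permutation_test(bc, cz, oc, self.SPEC, n_perms=99, seed=0)
        assert 1.0 / 100.0 <= res.p_value <= 1.0
        assert res.null_stats.shape == (99,)
        assert res.crit95 >= np.percentile(res.null_stats, 90)

    def test_too_few_subjects_or_perms_rejected(self, rng):
        v = rng.normal(0, 1, 4)
        with pytest.raises(ValueError):
            permutation_test(v, v, v, self.SPEC, n_perms=999)
        v = rng.normal(0, 1, 10)
        with pytest.raises(ValueError):
            permutation_test(v, v, v, self.SPEC, n_perms=50)


class TestNormality:
    def test_calibrated_under_gaussian_samples(self):
        gen = np.random.default_rng(2)
        hits = sum(check_normality(gen.normal(0, 1, 10_000))[1] > 0.05 for _ in range(100))
        assert hits >= 90

    def test_bimodal_sample_is_rejected(self, rng):
        x = np.concatenate([rng.normal(-5, 1, 250), rng.normal(5, 1, 250)])
        assert check_normality(x)[1] < 0.001

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 500)
        s1, _ = check_normality(x)
        s2, _ = check_normality(7.0 * x + 100.0)
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            check_normality(np.arange(7.0))


class TestPowerAndCI:
    def test_size_under_the_null(self):
        assert correlation_power(0.0, 40, 0.05) == pytest.approx(0.05)
        assert correlation_power(0.0, 200, 0.10) == pytest.approx(0.10)

    def test_medium_effect_closed_form(self):
        assert correlation_power(0.3, 40, 0.05) == pytest.approx(0.4693, abs=1e-4)

    def test_limit_at_strong_correlation(self):
        assert correlation_power(0.99, 40) > 0.999

    def test_invalid_queries_rejected(self):
        with pytest.raises(ValueError):
            correlation_power(1.0, 40)
        with pytest.raises(ValueError):
            correlation_power(0.3, 3)

    def test_ci_reproduces_fisher_z_endpoints(self):
        lo, hi = r2_confidence_interval(0.46, 38, 0.95)
        assert lo == pytest.approx(2.7, abs=0.05)
        assert hi == pytest.approx(46.2, abs=0.05)

    def test_degenerate_level_collapses_to_point_estimate(self):
        lo, hi = r2_confidence_interval(0.5, 38, 0.0)
        assert lo == pytest.approx(25.0)
        assert hi == pytest.approx(25.0)

    def test_interval_straddling_zero_is_clamped(self):
        lo, _ = r2_confidence_interval(0.1, 38, 0.95)
        assert lo == 0.0


class TestRunReplication:
    def test_deterministic_report(self):
        cohort = simulate_clinical_cohort(CohortSpec(seed=21))
        a = run_replication(cohort, n_perms=199, seed=7).summary()
        b = run_replication(cohort, n_perms=199, seed=7).summary()
        assert a == b

    def test_large_planted_effect_is_usually_detected(self):
        hits = 0
        for i in range(100):
            cohort = simulate_clinical_cohort(
                CohortSpec(n_subjects=38, r2_conn_incremental=0.21, seed=60_000 + i)
            )
            rep = run_replication(cohort, n_perms=499, seed=i)
            hits += rep.perm_prediction.p_value < 0.05
        assert hits > 50

    def test_null_effect_pvalues_are_roughly_uniform(self):
        pvals = []
        for i in range(100):
            cohort = simulate_clinical_cohort(
                CohortSpec(r2_conn_incremental=0.0, seed=70_000 + i)
            )
            pvals.append(run_replication(cohort, n_perms=499, seed=i).perm_prediction.p_value)
        pvals = np.array(pvals)
        # mean of a uniform is 0.5; gross departures indicate miscalibration
        assert 0.4 <= pvals.mean() <= 0.6
        assert (pvals < 0.05).mean() <= 0.12

    def test_subset_restriction_and_ineligibles(self):
        cohort = simulate_clinical_cohort(CohortSpec(n_subjects=60, dropout_rate=0.2, seed=13))
        rep = run_replication(cohort, subset="immediate_only", n_perms=199, seed=0)
        assert rep.n_total == 60
        assert rep.n_eligible < 60
        assert rep.n_analyzed < rep.n_eligible
        full = run_replication(cohort, subset="all", n_perms=199, seed=0)
        assert full.n_analyzed == full.n_eligible

    def test_report_carries_normality_and_glm(self):
        cohort = simulate_clinical_cohort(CohortSpec(seed=2))
        rep = run_replication(cohort, n_perms=199, seed=0)
        assert set(rep.normality) == {"baseline_lsas", "amyg_conn", "delta_lsas"}
        assert rep.glm.names == ["intercept", "baseline_lsas", "amyg_conn"]
        assert rep.glm.dof == rep.n_analyzed - 3
        summary = rep.summary()
        assert summary["coefficients"]["beta_conn"] == pytest.approx(8.6290)
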