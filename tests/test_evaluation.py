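import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcpmap import (
    AttributeSpec,
    CohortConfig,
    CVConfig,
    assign_folds,
    bootstrap_ci,
    derive_seed,
    fdr_adjust,
    generate_cohort,
    icv_response_association,
    pairwise_similarity,
    permutation_test,
    run_cv_binary,
    run_cv_continuous,
)


class TestAssignFolds:
    def test_disjoint_cover_equal_sizes(self):
        fa = assign_folds(10, 5, seed=0)
        sizes = np.bincount(fa.fold_of)
        assert list(sizes) == [2] * 5
        assert set(np.concatenate([fa.test_indices(f) for f in range(5)])) == set(range(10))

    def test_same_seed_identical(self):
        a, b = assign_folds(33, 5, seed=9), assign_folds(33, 5, seed=9)
        assert np.array_equal(a.fold_of, b.fold_of)

    def test_stratified_minority_spread(self):
        """90:10 labels, n=100, k=5: every fold must hold 1-3 minority
        subjects under the near-even class-balance redraw."""
        labels = np.array([1] * 10 + [0] * 90)
        for seed in range(50):
            fa = assign_folds(100, 5, seed=seed, labels=labels)
            per_fold = [labels[fa.test_indices(f)].sum() for f in range(5)]
            assert all(1 <= m <= 3 for m in per_fold)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="folds"):
            assign_folds(3, 5, seed=0)


def test_derive_seed_stable_and_bounded():
    a = derive_seed(7, "folds")
    assert a == derive_seed(7, "folds")
    assert a != derive_seed(7, "inner")
    assert 0 <= a < 2**31


class TestBootstrapCI:
    def test_perfect_accuracy_degenerate_interval(self):
        y = np.array([0, 1, 1, 0, 1])
        lo, hi = bootstrap_ci((y, y.copy()), "accuracy", n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_exhaustive_matches_enumeration_oracle(self):
        """n=3 pairs: the 27 equally likely resamples can be enumerated."""
        obs = np.array([0, 1, 1])
        pred = np.array([0, 1, 0])
        lo, hi = bootstrap_ci((obs, pred), "accuracy", exhaustive=True)
        vals = [np.mean(obs[list(ix)] == pred[list(ix)])
                for ix in itertools.product(range(3), repeat=3)]
        assert lo == pytest.approx(np.percentile(vals, 2.5))
        assert hi == pytest.approx(np.percentile(vals, 97.5))

    def test_same_seed_same_interval(self, rng):
        obs = rng.standard_normal(30)
        pred = obs + rng.standard_normal(30)
        a = bootstrap_ci((obs, pred), "pearson_r", n_boot=500, seed=3)
        b = bootstrap_ci((obs, pred), "pearson_r", n_boot=500, seed=3)
        assert a == b and a[0] <= a[1]

    def test_undefined_resamples_redrawn(self):
        # one pair differs; resamples drawing a single repeated pair have
        # undefined correlation and must be redrawn, not crash
        obs = np.array([0.0, 1.0, 2.0])
        pred = np.array([0.0, 1.1, 1.9])
        lo, hi = bootstrap_ci((obs, pred), "pearson_r", n_boot=300, seed=1)
        assert -1 <= lo <= hi <= 1


class TestFDR:
    def test_all_rejected_when_under_line(self):
        flags = fdr_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert flags.all()

    def test_none_rejected(self):
        assert not fdr_adjust([0.9, 0.95], q=0.05).any()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_brute_force_step_up(self, ps):
        q = 0.05
        flags = fdr_adjust(ps, q)
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        passing = [i for i in range(m) if p[order[i]] <= (i + 1) * q / m]
        expected = np.zeros(m, dtype=bool)
        if passing:
            expected[order[: max(passing) + 1]] = True
        assert np.array_equal(flags, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestPairwiseSimilarity:
    def test_identical_rows_perfect_correlation(self, rng):
        row = rng.standard_normal(40)
        C, summary = pairwise_similarity(np.vstack([row, row]))
        assert C[0, 1] == pytest.approx(1.0)

    def test_orthogonal_mean_zero_rows(self):
        X = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        C, _ = pairwise_similarity(X)
        assert C[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pairwise_similarity(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))

    def test_summary_over_upper_triangle(self, small_cohort):
        C, summary = pairwise_similarity(small_cohort.fingerprints)
        n = small_cohort.fingerprints.n
        iu = np.triu_indices(n, k=1)
        assert summary["n_pairs"] == n * (n - 1) // 2
        assert summary["mean"] == pytest.approx(C[iu].mean())


class TestICVAssociation:
    def test_perfect_association(self, rng):
        icv = np.exp(0.08 * rng.standard_normal(100) + 14)
        flag, p, r = icv_response_association(icv, icv, "linear")
        assert flag and r == pytest.approx(1.0)

    def test_independent_rarely_flagged(self):
        flags = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            icv = np.exp(0.08 * r.standard_normal(500) + 14)
            y = r.standard_normal(500)
            flags += icv_response_association(icv, y, "linear")[0]
        assert flags <= 5  # nominal 5% false-positive rate

    def test_binary_family_uses_group_test(self, rng):
        y = (rng.random(200) < 0.4).astype(int)
        icv = np.exp(0.08 * rng.standard_normal(200) + 14) + y * 2e5
        flag, p, t = icv_response_association(icv, y, "logistic")
        assert flag and p < 1e-6

    def test_constant_icv_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            icv_response_association(np.ones(10), np.arange(10.0), "linear")


class TestRunCVContinuous:
    def test_planted_signal_recovered(self, small_cohort):
        y = small_cohort.attributes.column("trait").to_numpy()
        res = run_cv_continuous(small_cohort.fingerprints.values,
                                small_cohort.icv, y,
                                CVConfig(seed=1, rule="min"))
        assert not res.metric_undefined
        assert res.metric > 0.2
        assert res.train_metric > res.metric - 0.1

    def test_null_response_flags_undefined_not_raises(self, small_cohort):
        """A response unrelated to everything: conservative fits go
        intercept-only in every fold; the metric must be flagged, not
        raised."""
        y = small_cohort.attributes.column("null_trait").to_numpy()
        res = run_cv_continuous(small_cohort.fingerprints.values,
                                small_cohort.icv, y, CVConfig(seed=2),
                                compute_training=False)
        if res.metric_undefined:
            assert np.isnan(res.metric)
        else:  # if any fold kept a component, the metric must be near zero
            assert abs(res.metric) < 2.5 / np.sqrt(res.n)

    def test_icv_only_response_isolated(self):
        """A response carried purely by ICV must not be predictable from the
        fingerprint once the ICV coefficient is truncated."""
        cfg = CohortConfig(n_subjects=80, n_features=300, seed=21)
        c = generate_cohort(cfg, [AttributeSpec("yicv", icv_loading=2.0,
                                                noise_sd=0.1)])
        y = c.attributes.column("yicv").to_numpy()
        res = run_cv_continuous(c.fingerprints.values, c.icv, y,
                                CVConfig(seed=4, rule="min"),
                                compute_training=False)
        if not res.metric_undefined:
            assert abs(res.metric) < 2.5 / np.sqrt(res.n)

    def test_training_folds_only_leakage_guard(self, small_cohort):
        """Perturbing held-out rows must not change the fold's fitted map."""
        X = small_cohort.fingerprints.values.copy()
        y = small_cohort.attributes.column("trait").to_numpy()
        cfg = CVConfig(seed=5, rule="min")
        res = run_cv_continuous(X, small_cohort.icv, y, cfg, keep_maps=True,
                                compute_training=False)
        X2 = X.copy()
        test0 = res.folds.test_indices(0)
        X2[test0] += np.random.default_rng(0).standard_normal(
            (len(test0), X.shape[1]))
        res2 = run_cv_continuous(X2, small_cohort.icv, y, cfg, keep_maps=True,
                                 compute_training=False)
        assert np.array_equal(res.fold_maps[0].weights, res2.fold_maps[0].weights)


class TestRunCVBinary:
    def test_null_label_forces_exact_base_rate(self, small_cohort):
        """Labels independent of everything: intercept-only logistic fits
        predict the majority class, so both accuracies equal the
        evaluation-set base rate exactly."""
        y = small_cohort.attributes.column("group").to_numpy().astype(int)
        res = run_cv_binary(small_cohort.fingerprints.values, small_cohort.icv,
                            y, CVConfig(seed=3), compute_training=False)
        base = max(np.mean(y == 0), np.mean(y == 1))
        assert res.metric == pytest.approx(base, abs=1e-12)
        assert res.metric_icv_only == pytest.approx(base, abs=1e-12)

    def test_icv_driven_label_benefits_both_models(self):
        cfg = CohortConfig(n_subjects=160, n_features=300, seed=31)
        c = generate_cohort(cfg, [AttributeSpec(
            "g", family="binary", class_fractions=(0.5, 0.5), icv_loading=3.0)])
        y = c.attributes.column("g").to_numpy().astype(int)
        res = run_cv_binary(c.fingerprints.values, c.icv, y,
                            CVConfig(seed=6, rule="min"),
                            compute_training=False)
        assert res.metric_icv_only > 0.6
        assert abs(res.metric - res.metric_icv_only) < 0.15

    def test_fingerprint_signal_beats_icv_benchmark(self):
        cfg = CohortConfig(n_subjects=160, n_features=300, n_latent=3, seed=41,
                           latent_scales=0.4)
        c = generate_cohort(cfg, [AttributeSpec(
            "g", family="binary", class_fractions=(0.5, 0.5),
            effect_axes=(0,), effect_sizes=(4.0,))])
        y = c.attributes.column("g").to_numpy().astype(int)
        res = run_cv_binary(c.fingerprints.values, c.icv, y,
                            CVConfig(seed=7, rule="min"),
                            compute_training=False)
        assert res.metric - res.metric_icv_only > 0.1


class TestPermutationTest:
    def test_p_value_consistent_with_null_stats(self, small_cohort):
        y = small_cohort.attributes.column("trait").to_numpy()
        cfg = CVConfig(seed=8, rule="min", n_inner_folds=5, n_lambda=15,
                       lambda_min_ratio=1e-2)
        res = permutation_test(small_cohort.fingerprints.values,
                               small_cohort.icv, y, cfg, n_perm=30,
                               family="linear")
        assert res.n_undefined + len(res.null_stats) == 30
        denom = 30 - res.n_undefined
        expected = np.sum(res.null_stats >= res.observed) / denom
        assert res.p_value == pytest.approx(expected)
        assert res.p_value <= 0.2  # strong planted effect

    def test_conservative_denominator_variant(self, small_cohort):
        y = small_cohort.attributes.column("trait").to_numpy()
        cfg = CVConfig(seed=8, rule="min", n_inner_folds=5, n_lambda=15,
                       lambda_min_ratio=1e-2)
        res = permutation_test(small_cohort.fingerprints.values,
                               small_cohort.icv, y, cfg, n_perm=20,
                               family="linear", conservative=True)
        expected = np.sum(res.null_stats >= res.observed) / 20
        assert res.p_value == pytest.approx(expected)

    def test_invalid_trial_count(self, small_cohort):
        y = small_cohort.attributes.column("trait").to_numpy()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(small_cohort.fingerprints.values,
                             small_cohort.icv, y, CVConfig(seed=0), n_perm=0)
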