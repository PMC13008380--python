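"""Kernel ridge prediction: confound regression, folding, permutations, FDR."""

import numpy as np
import pytest

from couplingbench.predict import (
    CvSpec,
    build_kernel,
    fdr_bh,
    krr_fit_predict,
    make_family_folds,
    nested_cv,
    permutation_test,
    residualize_behavior,
)


class TestResidualize:
    def test_behavior_linear_in_age_gives_zero_residuals(self, rng):
        age = rng.uniform(20, 40, 100)
        y = 2.0 + 0.5 * age
        tr, te = np.arange(70), np.arange(70, 100)
        r_tr, r_te = residualize_behavior(y, age, tr, te)
        assert np.max(np.abs(r_tr)) < 1e-10
        assert np.max(np.abs(r_te)) < 1e-10

    def test_orthogonal_covariates_leave_demeaned_behavior(self, rng):
        y = rng.standard_normal(200)
        c = rng.standard_normal((200, 2))
        c -= c.mean(axis=0)
        # orthogonalize covariates against the demeaned behavior exactly
        yd = y - y.mean()
        for j in range(2):
            c[:, j] -= (c[:, j] @ yd) / (yd @ yd) * yd
        tr = np.arange(200)
        r_tr, _ = residualize_behavior(y, c, tr, np.array([], dtype=int))
        assert np.allclose(r_tr, y - y.mean(), atol=1e-10)

    def test_train_coefficients_applied_to_test(self, rng):
        n = 120
        age = np.concatenate([rng.uniform(20, 30, 80), rng.uniform(35, 45, 40)])
        y = 1.0 + 0.3 * age + rng.standard_normal(n)
        tr, te = np.arange(80), np.arange(80, n)
        x_tr = np.column_stack([np.ones(80), age[tr]])
        beta = np.linalg.lstsq(x_tr, y[tr], rcond=None)[0]
        expected_te = y[te] - (beta[0] + beta[1] * age[te])
        _, r_te = residualize_behavior(y, age, tr, te)
        assert np.max(np.abs(r_te - expected_te)) < 1e-10


class TestKernel:
    def test_shared_vector_gives_all_ones(self):
        f = np.tile([1.0, 2.0, 3.0], (4, 1))
        f = f + np.zeros((4, 1))
        k = build_kernel(f)
        assert np.allclose(k, 1.0)

    def test_negated_subject_gives_minus_one(self, rng):
        v = rng.standard_normal(10)
        k = build_kernel(np.vstack([v, -v]))
        assert k[0, 1] == pytest.approx(-1.0)

    def test_hand_built_three_subjects(self, rng):
        f = rng.standard_normal((3, 6))
        k = build_kernel(f)
        for i in range(3):
            for j in range(3):
                assert k[i, j] == pytest.approx(
                    np.corrcoef(f[i], f[j])[0, 1], abs=1e-12
                )

    def test_zero_variance_subject_rejected(self):
        f = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="subject"):
            build_kernel(f)


class TestKrr:
    def test_huge_lambda_shrinks_to_zero(self, rng):
        k = build_kernel(rng.standard_normal((20, 10)))
        y = rng.standard_normal(20)
        y -= y.mean()
        pred = krr_fit_predict(k, y, k, 1e9)
        assert np.max(np.abs(pred)) < 1e-6

    def test_small_lambda_interpolates(self, rng):
        f = rng.standard_normal((10, 30))
        k = build_kernel(f)
        y = rng.standard_normal(10)
        pred = krr_fit_predict(k, y, k, 1e-10)
        assert np.max(np.abs(pred - y)) < 1e-4

    def test_four_subject_explicit_algebra(self, rng):
        k = build_kernel(rng.standard_normal((4, 8)))
        y = rng.standard_normal(4)
        lam = 0.5
        alpha = np.linalg.inv(k + lam * np.eye(4)) @ y
        kc = k[:2]
        assert np.allclose(krr_fit_predict(k, y, kc, lam), kc @ alpha, atol=1e-10)


class TestFamilyFolds:
    def test_families_never_split(self, rng):
        fams = np.repeat([f"f{i}" for i in range(40)], [3, 2] * 20)
        for rep in range(10):
            labels = make_family_folds(fams, 5, rng)
            for f in np.unique(fams):
                assert len(set(labels[fams == f])) == 1

    def test_folds_roughly_balanced(self, rng):
        fams = np.array([f"f{i}" for i in range(100)])
        labels = make_family_folds(fams, 10, rng)
        sizes = np.bincount(labels, minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_oversized_family_warns(self, rng):
        fams = np.array(["big"] * 30 + [f"f{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="larger than"):
            make_family_folds(fams, 4, rng)


class TestNestedCv:
    def _toy(self, rng, n=80, effect=0.0):
        feats = rng.standard_normal((n, 30))
        score = feats[:, :5].sum(axis=1)
        score = (score - score.mean()) / score.std()
        y = effect * score + np.sqrt(1 - effect**2) * rng.standard_normal(n)
        cov = rng.standard_normal((n, 3))
        fam = np.array([f"f{i // 2}" for i in range(n)])
        return feats, y, cov, fam

    def test_family_invariant_across_repetitions(self, rng):
        feats, y, cov, fam = self._toy(rng)
        spec = CvSpec(outer_folds=4, inner_folds=3, repetitions=3, seed=0)
        res = nested_cv(feats, y, cov, fam, spec)
        assert res.accuracies.shape == (3, 4)
        assert np.all(np.isfinite(res.accuracies))

    def test_null_effect_accuracy_near_zero(self, rng):
        accs = []
        for seed in range(8):
            feats, y, cov, fam = self._toy(np.random.default_rng(seed))
            res = nested_cv(
                feats, y, cov, fam,
                CvSpec(outer_folds=4, inner_folds=3, repetitions=2, seed=seed),
            )
            accs.append(res.mean_accuracy)
        accs = np.array(accs)
        assert abs(accs.mean()) < 2 * accs.std() / np.sqrt(len(accs)) + 0.05

    def test_strong_effect_recovered(self, rng):
        feats, y, cov, fam = self._toy(rng, n=120, effect=0.8)
        res = nested_cv(
            feats, y, cov, fam,
            CvSpec(outer_folds=4, inner_folds=3, repetitions=2, seed=1),
        )
        assert res.mean_accuracy > 0.3

    def test_anti_leakage_bit_identity(self, rng):
        """Deleting the *other* held-out subjects changes nothing about a
        fold's test predictions: every train-fold quantity is a function
        of train rows only."""
        feats, y, cov, fam = self._toy(rng, n=60)
        kernel = build_kernel(feats)
        test = np.arange(0, 12)
        train = np.arange(12, 60)
        y_tr, y_te = residualize_behavior(y, cov, train, test)
        lam = 1.0
        pred_full = krr_fit_predict(
            kernel[np.ix_(train, train)], y_tr, kernel[np.ix_(test, train)], lam
        )
        # rebuild the world with only train + this test fold present
        keep = np.concatenate([test, train])
        feats2, y2, cov2 = feats[keep], y[keep], cov[keep]
        kernel2 = build_kernel(feats2)
        test2 = np.arange(0, 12)
        train2 = np.arange(12, 60)
        y_tr2, y_te2 = residualize_behavior(y2, cov2, train2, test2)
        pred_sub = krr_fit_predict(
            kernel2[np.ix_(train2, train2)], y_tr2,
            kernel2[np.ix_(test2, train2)], lam,
        )
        assert np.array_equal(pred_full, pred_sub)
        assert np.array_equal(y_te, y_te2)


class TestPermutation:
    def test_extreme_observation_gives_minimum_p(self, rng):
        feats = rng.standard_normal((40, 20))
        y = rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        fam = np.array([f"f{i}" for i in range(40)])
        p, null = permutation_test(
            feats, y, cov, fam, observed_mean_accuracy=10.0,
            n_perm=49, outer_folds=4, inner_folds=2, seed=3,
        )
        assert p == pytest.approx(1 / 50)

    def test_deterministic_given_seed(self, rng):
        feats = rng.standard_normal((40, 20))
        y = rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        fam = np.array([f"f{i // 2}" for i in range(40)])
        args = dict(n_perm=19, outer_folds=4, inner_folds=2, seed=11)
        p1, n1 = permutation_test(feats, y, cov, fam, 0.1, **args)
        p2, n2 = permutation_test(feats, y, cov, fam, 0.1, **args)
        assert p1 == p2
        assert np.array_equal(n1, n2)

    def test_null_distribution_centered_at_zero(self, rng):
        feats = rng.standard_normal((48, 25))
        y = rng.standard_normal(48)
        cov = rng.standard_normal((48, 2))
        fam = np.array([f"f{i}" for i in range(48)])
        _, null = permutation_test(
            feats, y, cov, fam, 0.0, n_perm=200, outer_folds=4,
            inner_folds=2, seed=5,
        )
        assert abs(null.mean()) < 2 * null.std() / np.sqrt(len(null))


class TestFdrBh:
    def test_hand_example_all_rejected(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        reject, q = fdr_bh(p, q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        reject, _ = fdr_bh(np.ones(6), q=0.05)
        assert not reject.any()

    def test_single_small_p_rejected(self):
        reject, q = fdr_bh(np.array([0.04]), q=0.05)
        assert reject[0]
        assert q[0] >= 0.04

    def test_empty_input(self):
        reject, q = fdr_bh(np.array([]))
        assert reject.size == 0 and q.size == 0

    def test_matches_step_up_rule_by_enumeration(self, rng):
        """Cross-check against a direct implementation of the step-up rule."""
        for _ in range(20):
            p = rng.uniform(size=12)
            reject, _ = fdr_bh(p, q=0.05)
            order = np.argsort(p)
            ps = p[order]
            ks = np.flatnonzero(ps <= (np.arange(1, 13) / 12) * 0.05)
            expected = np.zeros(12, dtype=bool)
            if ks.size:
                expected[order[: ks.max() + 1]] = True
            assert np.array_equal(reject, expected)
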