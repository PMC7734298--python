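"""Tests for the nearest-class-subspace classifier and its enhancement."""

import numpy as np
import pytest

from tensorfc import (
    ClassTensor,
    TruncationRanks,
    augment_class_tensor,
    classify,
    evaluate_loocv,
    fit_class_model,
    hosvd,
    project_test,
    reconstruction_error,
    singular_value_perturbation,
    unfold,
)

from _oracles import least_squares_by_normal_equations


def gaussian_class(rng, T=12, R=8, S=5, label="a"):
    return ClassTensor(rng.standard_normal((T, R, S)), label)


class TestAugment:
    def test_appends_test_as_last_slice(self, rng):
        X = gaussian_class(rng, S=3)
        test = rng.standard_normal((12, 8))
        aug = augment_class_tensor(X, test)
        assert aug.n_samples == 4
        np.testing.assert_array_equal(aug.data[:, :, 3], test)
        np.testing.assert_array_equal(aug.data[:, :, :3], X.data)

    def test_roundtrip_by_dropping_last_slice(self, rng):
        X = gaussian_class(rng)
        aug = augment_class_tensor(X, rng.standard_normal((12, 8)))
        np.testing.assert_array_equal(aug.drop_sample(aug.n_samples - 1).data, X.data)

    def test_duplicate_sample_gives_identical_gram_rows(self, rng):
        X = gaussian_class(rng)
        aug = augment_class_tensor(X, X.data[:, :, 0])
        M = unfold(aug.data, 3)
        G = M @ M.T
        np.testing.assert_allclose(G[0], G[-1], rtol=1e-12)

    def test_shape_mismatch_names_expected_dims(self, rng):
        X = gaussian_class(rng)
        with pytest.raises(ValueError, match=r"\(12, 8\)"):
            augment_class_tensor(X, rng.standard_normal((8, 12)))


class TestFitAndProject:
    def test_constant_class_reconstructs_its_pattern_at_rank_one(self, rng):
        M = rng.standard_normal((10, 6))
        X = ClassTensor(np.repeat(M[:, :, None], 4, axis=2), "const")
        model = fit_class_model(X, TruncationRanks(1, 1, 1))
        Z = project_test(M, model)
        r, _ = reconstruction_error(Z, model, 1)
        assert r < 1e-8

    def test_core_slices_match_hosvd_restriction(self, rng):
        X = gaussian_class(rng)
        ranks = TruncationRanks(3, 3, 2)
        model = fit_class_model(X, ranks)
        h = hosvd(X.data)
        np.testing.assert_allclose(model.core_slices, h.core[:3, :3, :], atol=1e-12)
        np.testing.assert_allclose(model.time_basis, h.factors[0][:, :3], atol=1e-12)
        np.testing.assert_allclose(model.region_basis, h.factors[1][:, :3], atol=1e-12)

    def test_projection_identity_on_subspace_member(self, rng):
        X = gaussian_class(rng)
        model = fit_class_model(X, TruncationRanks(4, 3, 2))
        M = rng.standard_normal((4, 3))
        test = model.time_basis @ M @ model.region_basis.T
        np.testing.assert_allclose(project_test(test, model), M, atol=1e-10)

    def test_projection_of_orthogonal_test_is_zero(self, rng):
        X = gaussian_class(rng)
        model = fit_class_model(X, TruncationRanks(4, 3, 2))
        # build a test orthogonal to both subspaces
        raw = rng.standard_normal((12, 8))
        Pt = model.time_basis @ model.time_basis.T
        Pr = model.region_basis @ model.region_basis.T
        test = (np.eye(12) - Pt) @ raw @ (np.eye(8) - Pr)
        assert np.max(np.abs(project_test(test, model))) < 1e-10

    def test_projection_matches_double_sum(self, rng):
        X = gaussian_class(rng)
        model = fit_class_model(X, TruncationRanks(3, 4, 2))
        test = rng.standard_normal((12, 8))
        Z = project_test(test, model)
        brute = np.zeros_like(Z)
        for a in range(3):
            for b in range(4):
                for t in range(12):
                    for r in range(8):
                        brute[a, b] += (
                            model.time_basis[t, a] * test[t, r] * model.region_basis[r, b]
                        )
        np.testing.assert_allclose(Z, brute, atol=1e-10)


class TestReconstructionError:
    def test_exact_membership_recovers_scale(self, rng):
        model = fit_class_model(gaussian_class(rng), TruncationRanks(3, 3, 3))
        Z = 2.0 * model.core_slices[:, :, 0]
        r, lam = reconstruction_error(Z, model, 1)
        assert r < 1e-10
        np.testing.assert_allclose(lam, [2.0], atol=1e-10)

    def test_orthogonal_target_keeps_full_norm(self, rng):
        model = fit_class_model(gaussian_class(rng), TruncationRanks(3, 3, 3))
        D = np.column_stack(
            [model.core_slices[:, :, k].ravel() for k in range(3)]
        )
        raw = rng.standard_normal(9)
        resid = raw - D @ np.linalg.lstsq(D, raw, rcond=None)[0]
        Z = resid.reshape(3, 3)
        r, lam = reconstruction_error(Z, model, 3)
        assert abs(r - np.linalg.norm(Z)) < 1e-8
        assert np.max(np.abs(lam)) < 1e-8

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            k1, k2, k3 = rng.integers(2, 6, size=3)
            slices = rng.standard_normal((k1, k2, max(k3, 3)))
            Z = rng.standard_normal((k1, k2))
            model = fit_class_model(
                gaussian_class(rng, T=k1 + 2, R=k2 + 2, S=max(k3, 3)),
                TruncationRanks(k1, k2, int(k3)),
            )
            model.core_slices = slices
            r, lam = reconstruction_error(Z, model, int(k3))
            r_o, lam_o = least_squares_by_normal_equations(slices[:, :, : int(k3)], Z)
            assert abs(r - r_o) < 1e-8
            np.testing.assert_allclose(lam, lam_o, atol=1e-6)

    def test_residual_non_increasing_in_k3(self, rng):
        model = fit_class_model(gaussian_class(rng, S=6), TruncationRanks(4, 4, 6))
        Z = rng.standard_normal((4, 4))
        errors = [reconstruction_error(Z, model, k)[0] for k in range(1, 7)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_invalid_k3_rejected(self, rng):
        model = fit_class_model(gaussian_class(rng), TruncationRanks(3, 3, 3))
        with pytest.raises(ValueError, match="at least 1"):
            reconstruction_error(np.zeros((3, 3)), model, 0)
        with pytest.raises(ValueError, match="available core slices"):
            reconstruction_error(np.zeros((3, 3)), model, 99)


class TestClassify:
    def test_training_sample_assigned_to_home_class_with_zero_error(self, rng):
        A, B = gaussian_class(rng, label="a"), gaussian_class(rng, S=6, label="b")
        ranks = {"a": TruncationRanks(12, 8, 5), "b": TruncationRanks(12, 8, 6)}
        res = classify(A.data[:, :, 2], [A, B], ranks, enhance=True)
        assert res.predicted_label == "a"
        assert res.errors["a"] < 1e-8
        assert res.errors["b"] > 1e-6

    def test_identical_classes_tie_deterministically(self, rng):
        data = rng.standard_normal((10, 6, 4))
        A = ClassTensor(data, "first")
        B = ClassTensor(data.copy(), "second")
        res = classify(
            rng.standard_normal((10, 6)), [A, B], TruncationRanks(3, 3, 2)
        )
        assert res.tie
        assert res.predicted_label == "first"
        assert abs(res.errors["first"] - res.errors["second"]) < 1e-10

    def test_sign_and_convention_invariance_of_errors(self, rng):
        """r_i depends only on subspaces, not on singular-vector signs."""
        A, B = gaussian_class(rng, label="a"), gaussian_class(rng, S=6, label="b")
        test = rng.standard_normal((12, 8))
        ranks = TruncationRanks(5, 4, 3)
        res = classify(test, [A, B], ranks, enhance=False)
        # flipping the sign of whole samples of the training tensor flips
        # singular vectors but must not change the reconstruction error
        flipped = ClassTensor(A.data * -1.0, "a")
        res2 = classify(test, [flipped, B], ranks, enhance=False)
        assert abs(res.errors["a"] - res2.errors["a"]) < 1e-8

    def test_requires_two_classes_and_consistent_shapes(self, rng):
        A = gaussian_class(rng)
        with pytest.raises(ValueError, match="at least two"):
            classify(rng.standard_normal((12, 8)), [A])
        B = ClassTensor(rng.standard_normal((12, 9, 4)), "b")
        with pytest.raises(ValueError, match="shape"):
            classify(rng.standard_normal((12, 8)), [A, B])

    def test_k3_exceeding_augmented_samples_rejected(self, rng):
        A, B = gaussian_class(rng, label="a"), gaussian_class(rng, label="b")
        with pytest.raises(ValueError, match="k3=7 exceeds"):
            classify(
                rng.standard_normal((12, 8)),
                [A, B],
                TruncationRanks(3, 3, 7),
                enhance=True,
            )


class TestLOOCV:
    def test_perfectly_separable_copies_classified_exactly(self, rng):
        Ma, Mb = rng.standard_normal((10, 6)), rng.standard_normal((10, 6))
        A = ClassTensor(np.repeat(Ma[:, :, None], 3, axis=2), "a")
        B = ClassTensor(np.repeat(Mb[:, :, None], 3, axis=2), "b")
        counts, records = evaluate_loocv(
            [A, B], TruncationRanks(2, 2, 1), enhance=True, positive_class="b"
        )
        assert counts.tp == 3 and counts.tn == 3 and counts.fp == 0 and counts.fn == 0
        assert len(records) == 6

    def test_enhancement_flag_changes_fitted_models(self, small_cohort):
        """The enhanced harness re-decomposes with the held-out sample; the
        per-subject errors must differ from the plain run."""
        classes, _ = small_cohort
        sub = [c for c in classes]
        test = sub[0].data[:, :, 0]
        ranks = TruncationRanks(5, 5, 3)
        plain = classify(test, sub, ranks, enhance=False)
        enhanced = classify(test, sub, ranks, enhance=True)
        assert any(
            abs(plain.errors[k] - enhanced.errors[k]) > 1e-10 for k in plain.errors
        )

    def test_loocv_recovers_labels_on_synthetic_cohort(self, small_cohort):
        classes, _ = small_cohort
        counts, _ = evaluate_loocv(classes, enhance=True, positive_class="eMCI")
        acc = (counts.tp + counts.tn) / counts.total
        assert acc >= 0.9

    def test_minimum_class_size_enforced(self, rng):
        A = gaussian_class(rng, S=2, label="a")
        B = gaussian_class(rng, S=5, label="b")
        with pytest.raises(ValueError, match="at least 3"):
            evaluate_loocv([A, B])


class TestSingularValuePerturbation:
    def test_zero_test_leaves_spectrum_unchanged(self, rng):
        X = gaussian_class(rng)
        d = singular_value_perturbation(X, np.zeros((12, 8)))
        assert d.shape == (X.n_samples + 1,)
        assert np.max(d) < 1e-10

    def test_duplicate_sample_grows_leading_values(self, rng):
        X = gaussian_class(rng)
        d = singular_value_perturbation(X, X.data[:, :, 0])
        assert d[0] > 1e-3  # leading singular value must move

    def test_in_class_sample_perturbs_leading_half_more(self):
        """Shared-components cohorts with attenuated patient expression show
        the augmentation asymmetry the enhanced classifier relies on."""
        from tensorfc import SyntheticConfig, generate_cohort

        diffs = []
        for seed in range(5):
            classes, _ = generate_cohort(SyntheticConfig.small_shared(seed=700 + seed))
            A, B = classes
            reduced = A.drop_sample(0)
            half = (reduced.n_samples + 1) // 2
            d_in = singular_value_perturbation(reduced, A.data[:, :, 0])
            d_out = singular_value_perturbation(reduced, B.data[:, :, 0])
            diffs.append(d_in[:half].mean() - d_out[:half].mean())
        assert np.mean(diffs) > 0
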