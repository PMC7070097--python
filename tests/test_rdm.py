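"""Noise covariance, whitening, RDM construction/comparison, ceilings, MDS."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.linalg import cholesky

from oracles import lower_triangle_list, rdm_bruteforce, spearman_bruteforce
from toporsa import (
    ar1_covariance,
    compute_noise_ceiling,
    compute_rdm,
    estimate_noise_covariance,
    mds_embed,
    spearman_rdm_similarity,
    whiten_patterns,
)
from toporsa.experiments import mds_roundtrip_residual, whitening_identity_check
from toporsa.rdm import read_rdm_text, validate_rdm, write_rdm_text


class TestNoiseCovariance:
    def test_identity_recovery_at_large_t(self, rng):
        F = 6
        R = rng.standard_normal((50 * F, F))
        est = estimate_noise_covariance(R)
        assert np.linalg.norm(est - np.eye(F)) < 0.1 * F

    def test_variance_scaling_preserved(self, rng):
        R = rng.standard_normal((500, 5))
        R[:, 2] *= 10.0
        est = estimate_noise_covariance(R)
        baseline = np.mean(np.delete(np.diag(est), 2))
        assert 50 < est[2, 2] / baseline < 200

    @pytest.mark.parametrize("method", ["diag_shrink", "ledoit_wolf", "sample_ridge"])
    def test_positive_definite_when_features_exceed_timepoints(self, rng, method):
        R = rng.standard_normal((20, 100))
        est = estimate_noise_covariance(R, shrinkage=method)
        assert np.linalg.eigvalsh(est).min() > 0

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_covariance(np.ones((1, 4)))

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="shrinkage"):
            estimate_noise_covariance(rng.standard_normal((10, 3)), shrinkage="nope")


class TestWhitening:
    def test_identity_covariance_is_noop(self, rng):
        P = rng.standard_normal((6, 5))
        assert np.allclose(whiten_patterns(P, np.eye(5)), P)

    def test_diagonal_covariance_divides_by_sd(self, rng):
        P = rng.standard_normal((6, 4))
        sds = np.array([0.5, 1.0, 2.0, 4.0])
        out = whiten_patterns(P, np.diag(sds**2))
        assert np.allclose(out, P / sds)

    def test_known_covariance_whitens_to_identity(self):
        assert whitening_identity_check(n_features=8, n_samples=10_000, seed=3) < 0.1

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            whiten_patterns(rng.standard_normal((4, 5)), np.eye(3))

    def test_whiten_identity_then_rdm_equals_plain_rdm(self, rng):
        P = rng.standard_normal((5, 8))
        assert np.array_equal(compute_rdm(whiten_patterns(P, np.eye(8))), compute_rdm(P))


class TestComputeRdm:
    def test_identical_patterns_distance_zero(self):
        P = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        rdm = compute_rdm(P)
        assert rdm[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_pattern_distance_two(self):
        P = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]])
        assert compute_rdm(P)[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_instance_matches_bruteforce(self):
        P = np.array(
            [[0.2, 1.5, -0.3, 0.8], [1.1, -0.4, 0.9, 0.0], [-0.7, 0.6, 0.2, 1.3]]
        )
        assert np.allclose(compute_rdm(P), rdm_bruteforce(P), atol=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.standard_normal((6, rng.integers(3, 9)))
        assert np.allclose(compute_rdm(P), rdm_bruteforce(P), atol=1e-10)

    def test_zero_variance_pattern_names_condition(self):
        P = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match=r"condition\(s\) \[1\]"):
            compute_rdm(P)

    @given(
        arrays(
            np.float64,
            (7, 9),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rdm_invariants_hold(self, P):
        if np.any(P.std(axis=1) == 0):
            return
        rdm = compute_rdm(P)
        validate_rdm(rdm)


class TestSpearmanSimilarity:
    def test_self_similarity_is_one(self, rng):
        rdm = compute_rdm(rng.standard_normal((6, 5)))
        assert spearman_rdm_similarity(rdm, rdm) == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self, rng):
        rdm = compute_rdm(rng.standard_normal((6, 5)))
        reversed_rdm = 2.0 - rdm  # antitone in every entry
        np.fill_diagonal(reversed_rdm, 0.0)
        assert spearman_rdm_similarity(rdm, reversed_rdm) == pytest.approx(-1.0)

    def test_hand_instance_matches_rank_enumeration(self):
        a = np.array(
            [
                [0.0, 0.3, 0.7, 1.1, 0.9],
                [0.3, 0.0, 0.5, 0.3, 1.2],
                [0.7, 0.5, 0.0, 0.8, 0.4],
                [1.1, 0.3, 0.8, 0.0, 0.6],
                [0.9, 1.2, 0.4, 0.6, 0.0],
            ]
        )
        b = np.array(
            [
                [0.0, 1.0, 0.2, 0.9, 0.5],
                [1.0, 0.0, 0.6, 0.2, 0.8],
                [0.2, 0.6, 0.0, 1.3, 0.7],
                [0.9, 0.2, 1.3, 0.0, 0.3],
                [0.5, 0.8, 0.7, 0.3, 0.0],
            ]
        )
        expected = spearman_bruteforce(lower_triangle_list(a), lower_triangle_list(b))
        assert spearman_rdm_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a = compute_rdm(rng.standard_normal((6, 4)))
        b = compute_rdm(rng.standard_normal((6, 4)))
        expected = spearman_bruteforce(lower_triangle_list(a), lower_triangle_list(b))
        assert spearman_rdm_similarity(a, b) == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_monotone_invariance(self, rng):
        a = compute_rdm(rng.standard_normal((7, 5)))
        b = compute_rdm(rng.standard_normal((7, 5)))
        assert spearman_rdm_similarity(a, b) == pytest.approx(
            spearman_rdm_similarity(b, a)
        )
        # strictly increasing transform of either triangle changes nothing
        transformed = np.exp(1.7 * a)
        np.fill_diagonal(transformed, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # transform must not trigger fallbacks
            rho = np.corrcoef(  # sanity: transform is monotone
                a[np.tril_indices(7, -1)], transformed[np.tril_indices(7, -1)]
            )[0, 1]
        assert rho > 0
        assert spearman_rdm_similarity(transformed, b) == pytest.approx(
            spearman_rdm_similarity(a, b), abs=1e-12
        )

    def test_constant_triangle_returns_nan_with_warning(self):
        const = np.zeros((4, 4))
        other = compute_rdm(np.random.default_rng(0).standard_normal((4, 4)))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman_rdm_similarity(const, other))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman_rdm_similarity(np.zeros((3, 3)), np.zeros((4, 4)))


class TestNoiseCeiling:
    def test_identical_subjects_ceiling_one(self, rng):
        rdm = compute_rdm(rng.standard_normal((6, 5)))
        nc = compute_noise_ceiling([rdm, rdm, rdm])
        assert nc.lower == pytest.approx(1.0)
        assert nc.upper == pytest.approx(1.0)

    def test_lower_never_exceeds_upper(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            rdms = [compute_rdm(rng.standard_normal((6, 5))) for _ in range(4)]
            nc = compute_noise_ceiling(rdms)
            assert nc.lower <= nc.upper + 1e-12

    def test_true_model_falls_within_ceiling(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(100):
            shared = compute_rdm(rng.standard_normal((16, 8)))
            rdms = []
            for _ in range(10):
                noise = rng.normal(0, 0.1, shared.shape)
                noisy = np.clip(shared + (noise + noise.T) / 2, 0, 2)
                np.fill_diagonal(noisy, 0.0)
                rdms.append(noisy)
            nc = compute_noise_ceiling(rdms)
            group = np.mean([spearman_rdm_similarity(r, shared) for r in rdms])
            hits += nc.lower - 1e-12 <= group <= nc.upper + 1e-12
        assert hits >= 95

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_noise_ceiling([compute_rdm(rng.standard_normal((4, 4)))])


class TestMds:
    def test_planar_roundtrip(self):
        assert mds_roundtrip_residual(seed=0) < 1e-8

    def test_output_shape_156(self, rng):
        rdm = compute_rdm(rng.standard_normal((156, 30)))
        assert mds_embed(rdm, 2).shape == (156, 2)

    def test_cluster_separation(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0.0] * 6, [8.0] * 6])
        pts = np.vstack(
            [c + 0.1 * rng.standard_normal((5, 6)) for c in centers]
        )
        diff = pts[:, None] - pts[None, :]
        rdm = np.sqrt((diff**2).sum(-1))
        coords = mds_embed(rdm, 2)
        c0, c1 = coords[:5].mean(axis=0), coords[5:].mean(axis=0)
        spread = max(
            np.linalg.norm(coords[:5] - c0, axis=1).max(),
            np.linalg.norm(coords[5:] - c1, axis=1).max(),
        )
        assert np.linalg.norm(c0 - c1) > 5 * spread

    def test_excess_dims_truncated_with_warning(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        diff = pts[:, None] - pts[None, :]
        rdm = np.sqrt((diff**2).sum(-1))
        with pytest.warns(UserWarning, match="positive MDS dimensions"):
            coords = mds_embed(rdm, 4)
        assert coords.shape[1] == 2


class TestRdmIO:
    def test_text_roundtrip(self, rng, tmp_path):
        rdm = compute_rdm(rng.standard_normal((8, 6)))
        path = tmp_path / "rdm.tsv"
        write_rdm_text(rdm, path)
        back = read_rdm_text(path)
        assert np.allclose(back, rdm, atol=1e-12)

    def test_invalid_matrix_rejected_on_write(self, tmp_path):
        bad = np.array([[0.0, 1.0], [0.5, 0.0]])  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            write_rdm_text(bad, tmp_path / "bad.tsv")
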