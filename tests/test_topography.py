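"""Per-position RDM fields, correlation maps and upsampling."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from oracles import bilinear_by_hand
from toporsa import (
    ActivationStack,
    GroundTruthSpec,
    build_rdm_field,
    compute_rdm,
    correlation_map,
    correlation_maps,
    extract_position_patterns,
    generate_activation_stacks,
    generate_condition_set,
    generate_roi_dataset,
    spearman_rdm_similarity,
    upsample_map,
    vectorize_layer,
)
from toporsa.rdm import validate_rdm


@pytest.fixture
def toy_stack():
    """2 x 2 grid, depth 3, 4 conditions, enumerated values."""
    values = np.arange(4 * 2 * 2 * 3, dtype=float).reshape(4, 2, 2, 3)
    values += np.random.default_rng(0).normal(0, 0.01, values.shape)  # break ties
    return ActivationStack(values=values, layer_id="toy")


class TestVectorize:
    def test_degenerate_grid_returns_depth_vectors(self, rng):
        values = rng.standard_normal((5, 1, 1, 7))
        stack = ActivationStack(values=values)
        assert np.array_equal(vectorize_layer(stack), values[:, 0, 0, :])

    def test_flattening_order_is_row_major_y_x_d(self, toy_stack):
        row = vectorize_layer(toy_stack)[1]
        expected = []
        for y in range(2):
            for x in range(2):
                expected.extend(toy_stack.values[1, y, x, :])
        assert np.array_equal(row, np.array(expected))

    def test_rdm_invariant_to_unit_permutation(self, rng):
        values = rng.standard_normal((5, 3, 3, 4))
        stack = ActivationStack(values=values)
        flat = vectorize_layer(stack)
        perm = rng.permutation(flat.shape[1])
        assert np.allclose(compute_rdm(flat), compute_rdm(flat[:, perm]), atol=1e-12)


class TestExtractPosition:
    def test_single_cell_grid_returns_full_depth(self, rng):
        values = rng.standard_normal((4, 1, 1, 6))
        stack = ActivationStack(values=values)
        assert np.array_equal(extract_position_patterns(stack, 0, 0), values[:, 0, 0, :])

    def test_toy_slice_matches_enumeration(self, toy_stack):
        out = extract_position_patterns(toy_stack, x=1, y=0)
        assert np.array_equal(out, toy_stack.values[:, 0, 1, :])

    def test_out_of_range_reports_valid_range(self, toy_stack):
        with pytest.raises(ValueError, match=r"x in \[0, 1\]"):
            extract_position_patterns(toy_stack, x=2, y=0)

    def test_identical_tensors_give_zero_position_distance(self):
        base = np.random.default_rng(1).standard_normal((1, 2, 2, 3))
        values = np.vstack([base, base])
        field = build_rdm_field(ActivationStack(values=values))
        assert np.allclose(field.values[:, :, 0, 1], 0.0, atol=1e-12)


class TestRdmField:
    def test_collapsed_grid_equals_layer_rdm(self, rng):
        values = rng.standard_normal((6, 1, 1, 8))
        stack = ActivationStack(values=values)
        field = build_rdm_field(stack)
        layer_rdm = compute_rdm(vectorize_layer(stack))
        assert np.allclose(field.values[0, 0], layer_rdm, atol=1e-12)

    def test_mirror_symmetric_stack_gives_mirror_symmetric_field(self, rng):
        v = rng.standard_normal((5, 3, 4, 6))
        v = (v + v[:, :, ::-1, :]) / 2.0  # exactly left-right symmetric
        field = build_rdm_field(ActivationStack(values=v))
        for x in range(4):
            assert np.allclose(field.values[:, x], field.values[:, 3 - x], atol=1e-12)

    def test_every_valid_cell_satisfies_rdm_invariants(self, rng):
        stack = ActivationStack(values=rng.standard_normal((6, 3, 3, 5)))
        field = build_rdm_field(stack)
        assert field.valid.all()
        for y in range(3):
            for x in range(3):
                validate_rdm(field.values[y, x])

    def test_degenerate_cell_flagged_not_fatal(self, rng):
        values = rng.standard_normal((4, 2, 2, 3))
        values[2, 0, 0, :] = 7.0  # zero-variance depth vector at one cell
        field = build_rdm_field(ActivationStack(values=values))
        assert not field.valid[0, 0]
        assert field.valid[1, 1]
        assert np.isnan(field.values[0, 0]).all()


class TestCorrelationMap:
    def test_matching_roi_gives_constant_one(self, rng):
        values = np.tile(rng.standard_normal((5, 1, 1, 6)), (1, 2, 2, 1))
        field = build_rdm_field(ActivationStack(values=values))
        roi_rdm = field.values[0, 0]
        assert np.allclose(correlation_map(field, roi_rdm), 1.0)

    def test_uniform_gain_zero_noise_constant_map(self):
        conditions = generate_condition_set(15, seed=2)
        spec = GroundTruthSpec(spatial_gain_profile="uniform", seed=3)
        stack = generate_activation_stacks(
            conditions, spec, n_layers=1, H=3, W=3, D=10, noise_sd=0.0
        )[0]
        field = build_rdm_field(stack)
        roi_rdm = compute_rdm(
            generate_roi_dataset(conditions, spec, n_subjects=1, n_voxels=40)[0][0]
        )
        m = correlation_map(field, roi_rdm)
        assert np.allclose(m, m[0, 0], atol=1e-10)

    def test_center_gain_center_beats_corners(self):
        conditions = generate_condition_set(30, seed=4)
        spec = GroundTruthSpec(spatial_gain_profile="center", seed=5)
        stack = generate_activation_stacks(
            conditions, spec, n_layers=1, H=9, W=9, D=24
        )[0]
        roi_rdm = compute_rdm(
            generate_roi_dataset(conditions, spec, n_subjects=1, n_voxels=60)[0][0]
        )
        m = correlation_map(build_rdm_field(stack), roi_rdm)
        corners = np.mean([m[0, 0], m[0, 8], m[8, 0], m[8, 8]])
        assert m[4, 4] > corners

    def test_condition_mismatch_rejected(self, rng):
        field = build_rdm_field(ActivationStack(values=rng.standard_normal((4, 2, 2, 3))))
        with pytest.raises(ValueError, match="does not match"):
            correlation_map(field, np.zeros((5, 5)))

    def test_batch_agrees_with_scalar_path(self, rng):
        stack = ActivationStack(values=rng.standard_normal((6, 3, 3, 5)))
        field = build_rdm_field(stack)
        rois = [compute_rdm(rng.standard_normal((6, 7))) for _ in range(3)]
        batch = correlation_maps(field, rois)
        for j, roi in enumerate(rois):
            for y in range(3):
                for x in range(3):
                    expected = spearman_rdm_similarity(field.values[y, x], roi)
                    assert batch[j, y, x] == pytest.approx(expected, abs=1e-10)

    def test_collapse_equivalence_field_map_equals_layer_rsa(self, rng):
        values = rng.standard_normal((8, 1, 1, 10))
        stack = ActivationStack(values=values)
        roi_rdm = compute_rdm(rng.standard_normal((8, 6)))
        m = correlation_map(build_rdm_field(stack), roi_rdm)
        layer_rho = spearman_rdm_similarity(compute_rdm(vectorize_layer(stack)), roi_rdm)
        assert m[0, 0] == pytest.approx(layer_rho, abs=1e-12)


class TestUpsample:
    def test_constant_input_constant_output(self):
        m = np.full((3, 3), 0.4)
        out = upsample_map(m, 10, 12)
        assert out.shape == (10, 12)
        assert np.allclose(out, 0.4)

    def test_same_size_is_identity(self, rng):
        m = rng.standard_normal((4, 5))
        assert np.array_equal(upsample_map(m, 4, 5), m)

    def test_hand_computed_bilinear_grid(self):
        m = np.array([[0.0, 0.0], [1.0, 1.0]])
        out = upsample_map(m, 4, 4)
        expected = np.repeat(np.array([0.0, 1 / 3, 2 / 3, 1.0])[:, None], 4, axis=1)
        assert np.allclose(out, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bilinear_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((3, 4))
        out = upsample_map(m, 7, 9)
        assert np.allclose(out, bilinear_by_hand(m, 7, 9), atol=1e-10)

    def test_extremes_bounded_by_input(self, rng):
        m = rng.standard_normal((5, 5))
        out = upsample_map(m, 17, 17)
        assert out.min() >= m.min() - 1e-12
        assert out.max() <= m.max() + 1e-12

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError, match="downsample"):
            upsample_map(np.zeros((4, 4)), 3, 8)

    def test_nan_cells_excluded_and_propagated(self):
        m = np.array([[0.0, 1.0], [np.nan, 1.0]])
        out = upsample_map(m, 6, 6)
        finite = out[np.isfinite(out)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0
        assert np.isnan(out[5, 0])  # nearest input cell is the invalid one
        assert np.isfinite(out[0, 0])

    def test_nearest_method_preserves_blocks(self):
        m = np.array([[0.0, 1.0], [2.0, 3.0]])
        out = upsample_map(m, 4, 4, method="nearest")
        assert set(np.unique(out)) <= {0.0, 1.0, 2.0, 3.0}


class TestMonotoneDegradation:
    def test_noise_erodes_center_contrast(self):
        conditions = generate_condition_set(25, seed=9)
        levels = [0.25, 0.5, 1.0, 2.0, 4.0]
        contrasts = []
        for level in levels:
            vals = []
            for rep in range(3):
                spec = GroundTruthSpec(spatial_gain_profile="center", seed=50 + rep)
                stack = generate_activation_stacks(
                    conditions, spec, n_layers=1, H=9, W=9, D=24, noise_sd=level
                )[0]
                roi_rdm = compute_rdm(
                    generate_roi_dataset(conditions, spec, n_subjects=1, n_voxels=60)[0][0]
                )
                m = correlation_map(build_rdm_field(stack), roi_rdm)
                corners = np.mean([m[0, 0], m[0, 8], m[8, 0], m[8, 8]])
                vals.append(m[4, 4] - corners)
            contrasts.append(np.mean(vals))
        rho = spearmanr(levels, contrasts).statistic
        assert rho < -0.8
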