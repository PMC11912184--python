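import numpy as np
import pytest

from gpcnet.network import (
    OmicsTensor,
    bce_loss,
    encode_labels,
    forward,
    gene_layer_forward,
    head_forward,
    init_params,
    load_checkpoint,
    load_cohort,
    load_labels,
    make_dense_baseline,
    masked_layer_forward,
    save_checkpoint,
    total_loss,
)
from gpcnet.hierarchy import count_parameters
from gpcnet.synthetic import write_cohort

from oracles import loop_forward, plain_mlp_forward


class TestLabelEncoding:
    @pytest.mark.parametrize("text,expected", [
        ("poorly differentiated", 1),
        ("undifferentiated", 1),
        ("well-differentiated", 0),
        ("Moderately Differentiated", 0),
    ])
    def test_grade_categories(self, text, expected):
        assert encode_labels([text])[0] == expected

    def test_unknown_category_listed_in_error(self):
        with pytest.raises(ValueError, match="metaplastic"):
            encode_labels(["poorly differentiated", "metaplastic"])


class TestLayerOps:
    def test_zero_input_zero_bias_gives_zero_gene_layer(self, toy_params):
        h = toy_params.hierarchy
        toy_params.b_gene[:] = 0.0
        x = OmicsTensor(np.zeros((4, h.n_genes, 4)), [f"s{i}" for i in range(4)], h.genes)
        np.testing.assert_array_equal(gene_layer_forward(x, toy_params), 0.0)

    def test_single_gene_hand_value(self, tiny_hierarchy):
        params = init_params(tiny_hierarchy, 0)
        params.w_gene[:] = 1.0
        params.b_gene[:] = 0.0
        x = np.zeros((1, 3, 4))
        x[0, 0, 0] = 1.0   # one mutated gene
        t = OmicsTensor(x, ["s"], tiny_hierarchy.genes)
        h1 = gene_layer_forward(t, params)
        assert h1[0, 0] == pytest.approx(np.tanh(1.0), abs=1e-12)
        assert h1[0, 1] == 0.0

    def test_unavailable_channel_equals_zero_filled(self, toy_params):
        h = toy_params.hierarchy
        rng = np.random.default_rng(0)
        vals = np.zeros((5, h.n_genes, 4))
        vals[:, :, :3] = rng.integers(0, 2, size=(5, h.n_genes, 3))
        flagged = OmicsTensor(vals, [f"s{i}" for i in range(5)], h.genes,
                              channel_available=(True, True, True, False))
        explicit = OmicsTensor(vals.copy(), [f"s{i}" for i in range(5)], h.genes)
        np.testing.assert_array_equal(
            gene_layer_forward(flagged, toy_params),
            gene_layer_forward(explicit, toy_params))

    def test_identity_mask_equals_dense_layer(self):
        rng = np.random.default_rng(3)
        h_in, w, b = rng.normal(size=(6, 5)), rng.normal(size=(5, 3)), rng.normal(size=3)
        out = masked_layer_forward(h_in, np.ones((5, 3)), w, b)
        np.testing.assert_allclose(out, np.tanh(h_in @ w + b), atol=1e-15)

    def test_zero_mask_collapses_to_bias(self):
        rng = np.random.default_rng(4)
        h_in, w, b = rng.normal(size=(6, 5)), rng.normal(size=(5, 3)), rng.normal(size=3)
        out = masked_layer_forward(h_in, np.zeros((5, 3)), w, b)
        np.testing.assert_allclose(out, np.broadcast_to(np.tanh(b), (6, 3)), atol=1e-15)

    def test_masked_layer_matches_scalar_loop(self):
        rng = np.random.default_rng(5)
        h_in = rng.normal(size=(5, 4))
        mask = (rng.random((4, 3)) < 0.5).astype(float)
        w, b = rng.normal(size=(4, 3)), rng.normal(size=3)
        out = masked_layer_forward(h_in, mask, w, b)
        for s in range(5):
            for c in range(3):
                z = b[c] + sum(mask[k, c] * w[k, c] * h_in[s, k] for k in range(4))
                assert out[s, c] == pytest.approx(np.tanh(z), abs=1e-12)

    def test_head_at_zero_logit_is_half_and_monotone(self):
        w = np.array([1.0, -1.0])
        assert head_forward(np.array([[1.0, 1.0]]), w, 0.0)[0] == pytest.approx(0.5)
        grid = np.linspace(-10, 10, 41)
        probs = head_forward(grid[:, None], np.array([1.0]), 0.0)
        assert (np.diff(probs) > 0).all() and probs.min() > 0 and probs.max() < 1

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            masked_layer_forward(np.ones((2, 3)), np.ones((4, 2)), np.ones((4, 2)),
                                 np.zeros(2))


class TestForward:
    def test_zero_weights_give_half_everywhere(self, tiny_hierarchy):
        params = init_params(tiny_hierarchy, 0)
        for name in ("w_gene", "b_gene", "w_gp", "b_p", "w_pc", "b_c",
                     "head_gene_w", "head_pathway_w", "head_out_w"):
            getattr(params, name)[:] = 0.0
        params.head_gene_b = params.head_pathway_b = params.head_out_b = 0.0
        acts = forward(np.random.default_rng(0).normal(size=(3, 3, 4)), params)
        for p in (acts.p1, acts.p2, acts.p3):
            np.testing.assert_array_equal(p, 0.5)

    def test_matches_triple_loop_oracle(self, toy_params):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, toy_params.hierarchy.n_genes, 4))
        acts = forward(x, toy_params)
        ref = loop_forward(toy_params, x)
        for key in ref:
            np.testing.assert_allclose(getattr(acts, key), ref[key], atol=1e-12)

    def test_all_ones_mask_equals_plain_mlp(self, tiny_hierarchy):
        rng = np.random.default_rng(2)
        for trial in range(20):
            params = make_dense_baseline(tiny_hierarchy, seed=trial)
            x = rng.normal(size=(5, 3, 4))
            p3 = forward(x, params).p3
            oracle = plain_mlp_forward(
                x, params.w_gene, params.b_gene, params.w_gp, params.b_p,
                params.w_pc, params.b_c, params.head_out_w, params.head_out_b)
            np.testing.assert_allclose(p3, oracle, atol=1e-10)

    def test_mask_zero_weights_never_matter(self, toy_params):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(6, 3, 4))
        base = forward(x, toy_params).p3
        zero_gp = np.argwhere(toy_params.mask_gp == 0)
        zero_pc = np.argwhere(toy_params.mask_pc == 0)
        for _ in range(100):
            perturbed = toy_params.copy()
            for (i, j) in zero_gp:
                perturbed.w_gp[i, j] = rng.normal() * 100
            for (i, j) in zero_pc:
                perturbed.w_pc[i, j] = rng.normal() * 100
            np.testing.assert_array_equal(forward(x, perturbed).p3, base)

    def test_activation_ranges(self, toy_params):
        x = np.random.default_rng(10).normal(size=(20, 3, 4)) * 5
        acts = forward(x, toy_params)
        for h in (acts.h1, acts.h2, acts.h3):
            assert np.abs(h).max() <= 1.0
        for p in (acts.p1, acts.p2, acts.p3):
            assert p.min() > 0.0 and p.max() < 1.0

    def test_deterministic_given_seed(self, tiny_hierarchy):
        x = np.random.default_rng(0).normal(size=(4, 3, 4))
        a = forward(x, init_params(tiny_hierarchy, 42))
        b = forward(x, init_params(tiny_hierarchy, 42))
        np.testing.assert_array_equal(a.p3, b.p3)


class TestLosses:
    def test_perfect_prediction_is_tiny(self):
        y = np.array([0.0, 1.0, 1.0])
        assert bce_loss(y, y) <= 1e-5

    def test_uninformative_prediction_is_ln2(self):
        p = np.full(10, 0.5)
        y = np.tile([0.0, 1.0], 5)
        assert bce_loss(p, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_single_sample_closed_form(self):
        assert bce_loss(np.array([0.8]), np.array([1.0])) == pytest.approx(
            -np.log(0.8), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1.0, 0.0]))

    def test_one_hot_alpha_recovers_components(self, toy_params):
        x = np.random.default_rng(1).normal(size=(6, 3, 4))
        y = np.tile([0.0, 1.0], 3)
        acts = forward(x, toy_params)
        assert total_loss(acts, y, (0, 0, 1)) == pytest.approx(bce_loss(acts.p3, y))
        assert total_loss(acts, y, (1, 0, 0)) == pytest.approx(bce_loss(acts.p1, y))
        hand = (0.3 * bce_loss(acts.p1, y) + 1.7 * bce_loss(acts.p2, y)
                + 0.9 * bce_loss(acts.p3, y))
        assert total_loss(acts, y, (0.3, 1.7, 0.9)) == pytest.approx(hand, abs=1e-12)


class TestDenseBaseline:
    def test_dense_has_at_least_sparse_parameters(self, tiny_hierarchy):
        dense = make_dense_baseline(tiny_hierarchy, 0)
        assert (count_parameters(dense.hierarchy).sparse
                >= count_parameters(tiny_hierarchy).sparse)

    def test_seeds_change_init_not_shapes(self, tiny_hierarchy):
        a, b = make_dense_baseline(tiny_hierarchy, 0), make_dense_baseline(tiny_hierarchy, 1)
        assert a.w_gp.shape == b.w_gp.shape
        assert not np.array_equal(a.w_gp, b.w_gp)


class TestIO:
    def test_cohort_roundtrip_and_labels(self, tmp_path, small_cohort):
        h, x, y, truth, spec = small_cohort
        manifest = write_cohort(x, y, truth, tmp_path)
        channel_paths = {k: v for k, v in manifest.items()
                         if k not in ("labels", "ground_truth")}
        loaded = load_cohort(channel_paths, gene_ids=h.genes)
        np.testing.assert_array_equal(loaded.values, x.values)
        assert loaded.sample_ids == x.sample_ids
        y2 = load_labels(manifest["labels"], loaded.sample_ids)
        np.testing.assert_array_equal(y2, y)

    def test_missing_channel_zero_filled_and_flagged(self, tmp_path, small_cohort):
        h, x, y, truth, spec = small_cohort
        manifest = write_cohort(x, y, truth, tmp_path)
        loaded = load_cohort({"mutation": manifest["mutation"]}, gene_ids=h.genes)
        assert loaded.channel_available == (True, False, False, False)
        np.testing.assert_array_equal(loaded.values[:, :, 3], 0.0)

    def test_binary_channel_validation(self):
        vals = np.zeros((2, 2, 4))
        vals[0, 0, 0] = 0.5
        with pytest.raises(ValueError, match="binary"):
            OmicsTensor(vals, ["a", "b"], ["g1", "g2"])

    def test_checkpoint_roundtrip(self, tmp_path, toy_params):
        path = tmp_path / "ckpt.zip"
        save_checkpoint(toy_params, path, config={"note": "toy"})
        loaded, cfg = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.w_gp, toy_params.w_gp)
        np.testing.assert_array_equal(loaded.mask_gp, toy_params.mask_gp)
        assert cfg == {"note": "toy"}
        x = np.random.default_rng(0).normal(size=(3, 3, 4))
        np.testing.assert_array_equal(forward(x, loaded).p3, forward(x, toy_params).p3)
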