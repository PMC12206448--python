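"""Atom alignment, attention scoring, regression head, parameter accounting."""

import numpy as np
import pytest

from lnpfusion import fusion
from lnpfusion.fusion import LabelScaler, MolAttentionBlock, align, count_parameters
from lnpfusion.minigrad import Tensor


class TestAlign:
    def test_identity_gather(self):
        z2 = np.arange(12.0).reshape(4, 3)
        out = align(z2, [0, 1, 2, 3])
        assert np.array_equal(out.data, z2)

    def test_subset_gather(self):
        z2 = np.arange(12.0).reshape(4, 3)
        out = align(z2, [0, 2])
        assert np.array_equal(out.data, z2[[0, 2]])

    def test_random_gather_matches_loop_selection(self, rng):
        z2 = rng.normal(size=(30, 8))
        pos = np.sort(rng.choice(30, size=11, replace=False))
        out = align(z2, pos).data
        expected = np.stack([z2[p] for p in pos])
        assert np.array_equal(out, expected)

    def test_out_of_range_position_rejected(self):
        with pytest.raises(IndexError):
            align(np.zeros((3, 2)), [0, 5])


class TestScoreAtoms:
    def test_zero_weights_give_half_scores(self):
        blk = MolAttentionBlock(fused_width=16, r=2, reg_hidden=8)
        for p in blk.parameters():
            p.data[:] = 0.0
        scores = blk.score_atoms(Tensor(np.ones((5, 8))), Tensor(np.ones((5, 8)))).scores
        assert np.allclose(scores.data, 0.5)

    def test_scores_strictly_inside_unit_interval(self, rng):
        blk = MolAttentionBlock(fused_width=32, r=4, reg_hidden=8, seed=1)
        s = blk.score_atoms(
            Tensor(rng.normal(size=(9, 16)) * 10), Tensor(rng.normal(size=(9, 16)) * 10)
        ).scores.data
        assert np.all(s > 0) and np.all(s < 1)

    def test_degenerate_widths_match_pencil_and_paper(self):
        """fused width 2, r=2 (hidden 1): score = sigmoid(w2*relu(w1.z + b1) + b2)."""
        blk = MolAttentionBlock(fused_width=2, r=2, reg_hidden=1, seed=0)
        blk.score_w1.weight.data[:] = np.array([[1.0], [2.0]])
        blk.score_w1.bias.data[:] = 0.5
        blk.score_w2.weight.data[:] = np.array([[2.0]])
        blk.score_w2.bias.data[:] = -1.0
        z1, z2p = Tensor(np.array([[0.3]])), Tensor(np.array([[-0.2]]))
        score = float(blk.score_atoms(z1, z2p).scores.data[0, 0])
        hidden = max(1.0 * 0.3 + 2.0 * (-0.2) + 0.5, 0.0)
        expected = 1.0 / (1.0 + np.exp(-(2.0 * hidden - 1.0)))
        assert abs(score - expected) < 1e-6

    def test_indivisible_compression_ratio_rejected(self):
        with pytest.raises(ValueError):
            MolAttentionBlock(fused_width=10, r=3)

    def test_scores_permutation_invariant_per_atom(self, rng):
        blk = MolAttentionBlock(fused_width=16, r=2, reg_hidden=4, seed=2)
        z1 = Tensor(rng.normal(size=(6, 8)))
        z2p = Tensor(rng.normal(size=(6, 8)))
        s = blk.score_atoms(z1, z2p).scores.data
        perm = rng.permutation(6)
        s_perm = blk.score_atoms(Tensor(z1.data[perm]), Tensor(z2p.data[perm])).scores.data
        assert np.allclose(s_perm, s[perm])


class TestPredict:
    def test_zero_weights_predict_label_midpoint(self, rng):
        blk = MolAttentionBlock(fused_width=8, r=2, reg_hidden=4)
        for p in blk.parameters():
            p.data[:] = 0.0
        scaler = LabelScaler.fit([-9.0, 3.0])
        pred, _ = blk.predict(
            Tensor(rng.normal(size=(4, 4))), Tensor(rng.normal(size=(4, 4))), scaler
        )
        assert abs(pred - (-3.0)) < 1e-12

    def test_raw_output_bounded_by_tanh(self, rng):
        blk = MolAttentionBlock(fused_width=8, r=2, reg_hidden=4, seed=3)
        for p in blk.parameters():
            p.data[:] = rng.normal(size=p.data.shape) * 3
        raw, _ = blk.predict_raw(
            Tensor(rng.normal(size=(4, 4)) * 5), Tensor(rng.normal(size=(4, 4)) * 5)
        )
        assert -1.0 < float(raw.data[0]) < 1.0

    def test_missing_scaler_rejected(self, rng):
        blk = MolAttentionBlock(fused_width=8, r=2, reg_hidden=4)
        with pytest.raises(ValueError):
            blk.predict(Tensor(np.zeros((2, 4))), Tensor(np.zeros((2, 4))), None)

    def test_two_atom_fixture_matches_explicit_matrix_evaluation(self):
        blk = MolAttentionBlock(fused_width=2, r=2, reg_hidden=2, seed=0)
        W1s = np.array([[0.5], [-1.0]])
        b1s = np.array([0.1])
        W2s = np.array([[2.0]])
        b2s = np.array([-0.2])
        W1r = np.array([[0.3, -0.4], [1.0, 0.2]])
        b1r = np.array([0.0, 0.1])
        W2r = np.array([[0.7], [-0.5]])
        b2r = np.array([0.05])
        blk.score_w1.weight.data[:] = W1s
        blk.score_w1.bias.data[:] = b1s
        blk.score_w2.weight.data[:] = W2s
        blk.score_w2.bias.data[:] = b2s
        blk.reg_w1.weight.data[:] = W1r
        blk.reg_w1.bias.data[:] = b1r
        blk.reg_w2.weight.data[:] = W2r
        blk.reg_w2.bias.data[:] = b2r
        z1 = np.array([[0.2], [-0.6]])
        z2p = np.array([[0.4], [0.9]])
        raw, _ = blk.predict_raw(Tensor(z1), Tensor(z2p))
        # independent evaluation
        z = np.hstack([z1, z2p])
        hidden = np.maximum(z @ W1s + b1s, 0.0)
        scores = 1.0 / (1.0 + np.exp(-(hidden @ W2s + b2s)))
        pooled = (z * scores).mean(axis=0)
        expected = np.tanh(np.tanh(pooled @ W1r + b1r) @ W2r + b2r)
        assert abs(float(raw.data[0]) - float(expected[0])) < 1e-6

    def test_gradient_reaches_both_branch_inputs(self, rng):
        blk = MolAttentionBlock(fused_width=8, r=2, reg_hidden=4, seed=4)
        z1 = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        z2p = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        raw, _ = blk.predict_raw(z1, z2p)
        raw.sum().backward()
        assert z1.grad is not None and np.abs(z1.grad).sum() > 0
        assert z2p.grad is not None and np.abs(z2p.grad).sum() > 0


class TestParameterCount:
    def test_default_widths_reproduce_published_count(self):
        assert count_parameters() == 1_050_626

    def test_score_path_alone(self):
        hidden = 1024 // 2
        score_path = 1024 * hidden + hidden + hidden * 1 + 1
        assert score_path == 525_313

    @pytest.mark.parametrize(
        "fused_width,r,reg_hidden", [(1024, 2, 512), (64, 2, 32), (16, 4, 8), (2, 2, 1)]
    )
    def test_formula_matches_instantiated_block(self, fused_width, r, reg_hidden):
        blk = MolAttentionBlock(fused_width=fused_width, r=r, reg_hidden=reg_hidden)
        assert blk.n_parameters() == count_parameters(fused_width, r, reg_hidden)


class TestExplain:
    def test_row_count_and_determinism(self, rng):
        blk = MolAttentionBlock(fused_width=16, r=2, reg_hidden=4, seed=6)
        z1 = Tensor(rng.normal(size=(5, 8)))
        z2p = Tensor(rng.normal(size=(5, 8)))
        df1 = blk.explain(z1, z2p, list("CCNOC"))
        df2 = blk.explain(z1, z2p, list("CCNOC"))
        assert len(df1) == 5
        assert list(df1.columns) == ["atom_index", "element", "score"]
        assert np.array_equal(df1["score"].to_numpy(), df2["score"].to_numpy())
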