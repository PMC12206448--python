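"""Pair bias, biased attention, corruption and pretraining losses."""

import numpy as np
import pytest

from lnpfusion import chemio, encoder3d
from lnpfusion.encoder3d import (
    Encoder3D,
    GaussianPairBias,
    biased_attention,
    corrupt,
    cross_entropy,
    gaussian_pair_bias,
    pretrain_losses,
    smooth_l1,
)
from lnpfusion.minigrad import Tensor


@pytest.fixture()
def toy_geometry():
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(4, 3))
    delta = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((delta**2).sum(-1))
    bonds = np.zeros((4, 4), dtype=int)
    bonds[0, 1] = bonds[1, 0] = 1
    bonds[1, 2] = bonds[2, 1] = 2
    return dist, bonds


class TestPairBias:
    def test_gate_zero_keeps_only_distance_term(self, toy_geometry):
        dist, bonds = toy_geometry
        pb = GaussianPairBias(n_heads=2, n_kernels=4)
        pb.gate_logit.data[:] = -50.0  # sigmoid -> ~0
        with_bonds = gaussian_pair_bias(dist, bonds, pb).bias.data
        without_bonds = gaussian_pair_bias(dist, np.zeros_like(bonds), pb).bias.data
        assert np.allclose(with_bonds, without_bonds, atol=1e-12)

    def test_symmetric_inputs_give_symmetric_bias(self, toy_geometry):
        dist, bonds = toy_geometry
        pb = GaussianPairBias(n_heads=3, n_kernels=8)
        bias = gaussian_pair_bias(dist, bonds, pb).bias.data
        assert np.allclose(bias, bias.transpose(1, 0, 2))

    def test_single_gaussian_kernel_matches_closed_form(self):
        """K=1 kernel (mu=0, sigma=1, unit weight), gate 0: bias = exp(-d^2/2)."""
        pb = GaussianPairBias(n_heads=1, n_kernels=1)
        pb.width = 1.0
        pb.centers = np.array([0.0])
        pb.kernel_weights.data[:] = 1.0
        pb.gate_logit.data[:] = -50.0
        dist = np.array([[0.0, 1.7], [1.7, 0.0]])
        bias = gaussian_pair_bias(dist, np.zeros((2, 2), dtype=int), pb).bias.data
        expected = np.exp(-(dist**2) / 2.0)
        assert np.allclose(bias[:, :, 0], expected, atol=1e-6)

    def test_nan_distance_rejected(self, toy_geometry):
        dist, bonds = toy_geometry
        dist = dist.copy()
        dist[0, 1] = np.nan
        pb = GaussianPairBias(n_heads=1, n_kernels=2)
        with pytest.raises(ValueError):
            gaussian_pair_bias(dist, bonds, pb)


class TestBiasedAttention:
    def test_identical_keys_zero_bias_give_uniform_attention(self):
        rng = np.random.default_rng(0)
        n, d = 5, 4
        q = Tensor(rng.normal(size=(n, d)))
        k = Tensor(np.tile(rng.normal(size=(1, d)), (n, 1)))
        v = Tensor(rng.normal(size=(n, d)))
        out = biased_attention(q, k, v, np.zeros((n, n)))
        assert np.allclose(out.data, np.tile(v.data.mean(0), (n, 1)), atol=1e-9)

    def test_large_negative_bias_masks_attention(self):
        rng = np.random.default_rng(1)
        n, d = 4, 3
        q, k, v = (Tensor(rng.normal(size=(n, d))) for _ in range(3))
        bias = np.zeros((n, n))
        bias[0, 2] = -1e9
        out_masked = biased_attention(q, k, v, bias).data
        v2 = v.data.copy()
        v2[2] += 100.0  # row 2 must not reach output row 0
        out_masked2 = biased_attention(q, k, Tensor(v2), bias).data
        assert np.allclose(out_masked[0], out_masked2[0], atol=1e-6)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(2)
        n, d = 3, 2
        q, k, v = rng.normal(size=(3, n, d))
        bias = rng.normal(size=(n, n))
        out = biased_attention(Tensor(q), Tensor(k), Tensor(v), bias).data
        expected = np.zeros((n, d))
        for i in range(n):
            logits = np.array([q[i] @ k[j] / np.sqrt(d) + bias[i, j] for j in range(n)])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            assert abs(w.sum() - 1.0) < 1e-6
            expected[i] = sum(w[j] * v[j] for j in range(n))
        assert np.allclose(out, expected, atol=1e-6)

    def test_zero_head_width_rejected(self):
        z = Tensor(np.zeros((2, 0)))
        with pytest.raises(ValueError):
            biased_attention(z, z, z, np.zeros((2, 2)))


class TestCorrupt:
    @pytest.fixture()
    def record(self):
        return chemio.featurize_3d("CCCCCCCCCCCCCCCCCCCC", seed=0)  # n = 20

    def test_zero_rate_zero_noise_is_identity(self, record):
        plan = corrupt(record, rate=0.0, halfwidth=0.0, seed=1)
        assert len(plan.masked_atom_indices) == 0
        assert np.array_equal(plan.noisy_coords, record.coords)

    def test_full_rate_masks_all_atoms(self, record):
        plan = corrupt(record, rate=1.0, seed=1)
        assert len(plan.masked_atom_indices) == record.n_atoms

    def test_mask_count_is_rounded_rate(self, record):
        plan = corrupt(record, rate=0.15, seed=1)
        assert len(plan.masked_atom_indices) == 3  # round(0.15 * 20)

    def test_noise_bounded_by_halfwidth(self, record):
        plan = corrupt(record, rate=0.15, halfwidth=0.3, seed=2)
        assert np.abs(plan.noisy_coords - record.coords).max() <= 0.3

    def test_seeded_reproducibility_and_seed_sensitivity(self, record):
        a = corrupt(record, rate=0.3, seed=9)
        b = corrupt(record, rate=0.3, seed=9)
        c = corrupt(record, rate=0.3, seed=10)
        assert np.array_equal(a.masked_atom_indices, b.masked_atom_indices)
        assert np.array_equal(a.noisy_coords, b.noisy_coords)
        assert not np.array_equal(a.masked_atom_indices, c.masked_atom_indices) or not np.array_equal(
            a.noisy_coords, c.noisy_coords
        )

    def test_rate_out_of_range_rejected(self, record):
        with pytest.raises(ValueError):
            corrupt(record, rate=1.5)


class TestPretrainLosses:
    def test_perfect_coord_and_dist_predictions_zero_those_terms(self):
        truth = {
            "types": np.array([0, 1]),
            "coords": np.zeros((2, 3)),
            "dists": np.array([1.0, 2.0]),
        }
        logits = Tensor(np.eye(2, 30) * 50.0)
        total, comp = pretrain_losses(
            logits, Tensor(np.zeros((2, 3))), Tensor(np.array([1.0, 2.0])), truth
        )
        assert comp["coord_smooth_l1"] == 0.0
        assert comp["dist_smooth_l1"] == 0.0

    def test_uniform_type_prediction_costs_ln_30(self):
        logits = Tensor(np.zeros((4, 30)))
        ce = cross_entropy(logits, np.array([0, 5, 10, 29]))
        assert abs(float(ce.data) - np.log(30)) < 1e-9

    def test_smooth_l1_matches_piecewise_formula(self):
        residuals = np.array([-2.5, -1.0, -0.3, 0.0, 0.4, 0.99, 1.0, 3.0])
        pred = Tensor(residuals)
        val = float(smooth_l1(pred, np.zeros_like(residuals)).data)
        expected = np.mean(
            [0.5 * r**2 if abs(r) < 1 else abs(r) - 0.5 for r in residuals]
        )
        assert abs(val - expected) < 1e-6

    def test_total_is_weighted_sum_of_components(self):
        rng = np.random.default_rng(0)
        truth = {
            "types": np.array([2, 3, 4]),
            "coords": rng.normal(size=(3, 3)),
            "dists": rng.uniform(1, 5, size=6),
        }
        total, comp = pretrain_losses(
            Tensor(rng.normal(size=(3, 30))),
            Tensor(rng.normal(size=(3, 3))),
            Tensor(rng.uniform(0, 5, size=6)),
            truth,
        )
        assert abs(
            comp["total"]
            - (comp["type_ce"] + 5 * comp["coord_smooth_l1"] + 10 * comp["dist_smooth_l1"])
        ) < 1e-9

    def test_no_corrupted_atoms_warns_and_zeroes_terms(self):
        truth = {"types": np.array([], dtype=int), "coords": np.zeros((0, 3)), "dists": np.array([])}
        with pytest.warns(UserWarning):
            total, comp = pretrain_losses(None, None, None, truth)
        assert comp["total"] == 0.0


class TestEncoder3D:
    @pytest.fixture(scope="class")
    def encoder(self):
        return Encoder3D(width=32, n_layers=2, n_heads=4, n_kernels=8, seed=3)

    def test_output_shape_is_atoms_by_width(self, encoder):
        rec = chemio.featurize_3d("CCN(CC)CCO", seed=1)
        z1 = encoder(rec)
        assert z1.shape == (rec.n_atoms, 32)

    def test_permutation_equivariance(self, encoder):
        rec = chemio.featurize_3d("CCN(CC)CCO", seed=1)
        z1 = encoder(rec).data
        rng = np.random.default_rng(0)
        perm = rng.permutation(rec.n_atoms)
        permuted = chemio.Molecule3DRecord(
            atom_symbols=[rec.atom_symbols[i] for i in perm],
            coords=rec.coords[perm],
            dist=rec.dist[np.ix_(perm, perm)],
            bonds=rec.bonds[np.ix_(perm, perm)],
        )
        z1_perm = encoder(permuted).data
        assert np.allclose(z1_perm, z1[perm], atol=1e-8)

    def test_fixed_weights_are_deterministic(self, encoder):
        rec = chemio.featurize_3d("CCOC(=O)CC", seed=1)
        assert np.array_equal(encoder(rec).data, encoder(rec).data)
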