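"""Encoder coupling: QR basis, feature pipeline, masking, projections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcflow._autodiff import Tensor
from dcflow.encoder import (EPS_D, EncoderParams, IdentityFeatureMap,
                            NestedDropoutConfig, alignment_loss,
                            apply_prefix_mask, cap_norm, effective_dimension,
                            encode, encode_batch, latent_coordinates,
                            normalize_features, orthonormal_basis,
                            project_velocity, raw_features,
                            sample_prefix_length, sample_prefix_lengths,
                            update_ema_stats)
from dcflow.nn import ConditionedMLP


def identity_params(d, norm_cap=None):
    """Encoder whose full chain is the identity map (analytic harness)."""
    p = EncoderParams.create(d, d, IdentityFeatureMap(),
                             np.random.default_rng(0), norm_cap=norm_cap)
    p.L_raw.data = np.eye(d, dtype=np.float32)
    p.rho.data = np.full(d, np.log(np.expm1(1.0 - EPS_D)), dtype=np.float32)
    p.m = np.zeros(d, dtype=np.float32)
    p.sigma = np.ones(d, dtype=np.float32)
    if norm_cap is None:
        p.norm_cap = 1e9  # effectively uncapped for the analytic chain
    return p


# ------------------------------------------------------------------ basis

class TestOrthonormalBasis:
    def test_identity_is_fixed_point(self):
        assert np.allclose(orthonormal_basis(np.eye(4)), np.eye(4))

    def test_positive_scaling_absorbed_into_r(self):
        assert np.allclose(orthonormal_basis(2.0 * np.eye(4)), np.eye(4))

    def test_matches_reference_qr_and_reconstructs(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 3))
        q = orthonormal_basis(a)
        assert np.allclose(q.T @ q, np.eye(3), atol=1e-6)
        # Q R reconstructs A: R = Q^T A must be upper triangular, diag > 0
        r = q.T @ a
        assert np.allclose(q @ r, a, atol=1e-6)
        assert np.allclose(np.tril(r, -1), 0, atol=1e-8)
        assert np.all(np.diagonal(r) > 0)

    def test_column_scale_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(7, 4))
        scales = np.array([0.5, 2.0, 3.0, 0.1])
        assert np.allclose(orthonormal_basis(a), orthonormal_basis(a * scales),
                           atol=1e-8)

    def test_rank_deficient_raises(self):
        a = np.ones((5, 3))
        with pytest.raises(np.linalg.LinAlgError):
            orthonormal_basis(a)


# --------------------------------------------------------------- features

class TestFeaturePipeline:
    def test_identity_feature_map_returns_input(self):
        x = np.arange(4.0)
        assert np.allclose(raw_features(x, IdentityFeatureMap()), x)

    def test_feature_map_deterministic(self):
        psi = ConditionedMLP(5, 3, np.random.default_rng(0), width=8, depth=2)
        x = np.random.default_rng(1).normal(size=5)
        assert np.array_equal(raw_features(x, psi), raw_features(x, psi))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            raw_features(np.array([1.0, np.nan]), IdentityFeatureMap())

    @pytest.mark.parametrize("f,c,expected", [
        ((3.0, 4.0), 10.0, (3.0, 4.0)),   # under cap
        ((3.0, 4.0), 5.0, (3.0, 4.0)),    # exactly at cap
        ((6.0, 8.0), 5.0, (3.0, 4.0)),    # rescaled by 5/10
    ])
    def test_cap_norm(self, f, c, expected):
        assert np.allclose(cap_norm(np.array(f), c), expected)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_cap_norm_bound_holds(self, seed):
        f = np.random.default_rng(seed).normal(scale=3.0, size=6)
        assert np.linalg.norm(cap_norm(f, 2.5)) <= 2.5 + 1e-9

    def test_normalize_at_mean_is_zero(self):
        m = np.array([1.0, -2.0])
        s = np.array([2.0, 3.0])
        assert np.allclose(normalize_features(m, m, s), 0)
        assert np.allclose(normalize_features(m + s, m, s), 1)

    def test_normalize_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            normalize_features(np.zeros(2), np.zeros(2), np.array([1.0, 0.0]))

    def test_converged_ema_standardizes_stream(self):
        rng = np.random.default_rng(0)
        m = np.zeros(3)
        s = np.ones(3)
        stream = rng.normal(loc=1.5, scale=2.0, size=(400, 64, 3))
        for batch in stream:
            m, s = update_ema_stats(batch, m, s, 0.98)
        z = normalize_features(stream.reshape(-1, 3), m, s)
        n = z.shape[0]
        assert np.abs(z.mean(axis=0)).max() < 3.0 / np.sqrt(n) + 0.05
        assert np.abs(z.std(axis=0) - 1.0).max() < 0.05


class TestEmaUpdate:
    def test_decay_one_is_identity(self):
        m, s = np.array([1.0]), np.array([2.0])
        m2, s2 = update_ema_stats(np.random.default_rng(0).normal(size=(8, 1)),
                                  m, s, 1.0)
        assert np.allclose(m2, m) and np.allclose(s2, s)

    def test_decay_zero_takes_batch_stats(self):
        batch = np.array([[1.0], [3.0]])
        m2, s2 = update_ema_stats(batch, np.zeros(1), np.ones(1), 0.0)
        assert np.allclose(m2, 2.0)
        assert np.allclose(s2, batch.std(ddof=1))

    def test_single_row_skips_std_update(self):
        m2, s2 = update_ema_stats(np.array([[5.0]]), np.zeros(1),
                                  np.full(1, 0.7), 0.5)
        assert np.allclose(m2, 2.5)
        assert np.allclose(s2, 0.7)

    def test_repeated_batches_converge_geometrically(self):
        batch = np.random.default_rng(0).normal(size=(16, 2))
        target = batch.mean(axis=0)
        m = np.zeros(2)
        s = np.ones(2)
        decay = 0.9
        for n in range(1, 60):
            m, s = update_ema_stats(batch, m, s, decay)
            # closed form: m_n = (1 - decay^n) * batch_mean
            assert np.allclose(m, (1 - decay ** n) * target, atol=1e-6)


# ---------------------------------------------------------- nested dropout

class TestPrefixSampling:
    def test_p_one_always_one(self):
        cfg = NestedDropoutConfig(1.0, 1, 16)
        rng = np.random.default_rng(0)
        assert all(sample_prefix_length(cfg, rng) == 1 for _ in range(50))

    def test_degenerate_clamp(self):
        cfg = NestedDropoutConfig(0.5, 7, 7)
        rng = np.random.default_rng(0)
        assert all(sample_prefix_length(cfg, rng) == 7 for _ in range(50))

    def test_geometric_mean_matches_rate(self):
        cfg = NestedDropoutConfig(1.0 / 50.0, 1, 512)
        ks = sample_prefix_lengths(cfg, 1_000_000, np.random.default_rng(0))
        se = ks.std() / np.sqrt(len(ks))
        assert abs(ks.mean() - 50.0) < 3 * se

    def test_reproducible_under_seed(self):
        cfg = NestedDropoutConfig(0.1, 1, 100)
        a = sample_prefix_lengths(cfg, 100, np.random.default_rng(9))
        b = sample_prefix_lengths(cfg, 100, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestPrefixMask:
    def test_full_prefix_is_identity(self):
        f = np.array([1.0, 2.0, 3.0])
        assert np.allclose(apply_prefix_mask(f, 3), f)

    def test_prefix_one(self):
        assert np.allclose(apply_prefix_mask(np.array([5.0, 6.0, 7.0]), 1),
                           [5.0, 0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_prefix_mask(np.ones(3), 4)
        with pytest.raises(ValueError):
            apply_prefix_mask(np.ones(3), 0)

    @given(st.integers(1, 8), st.integers(1, 8))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_masks_are_nested(self, k1, k2):
        if k1 > k2:
            k1, k2 = k2, k1
        f = np.arange(1.0, 9.0)
        assert np.allclose(apply_prefix_mask(f, k1),
                           apply_prefix_mask(apply_prefix_mask(f, k2), k1))

    def test_masked_coordinates_get_zero_gradient(self):
        rng = np.random.default_rng(0)
        f = Tensor(rng.normal(size=(4, 6)).astype(np.float32),
                   requires_grad=True)
        masked = apply_prefix_mask(f, 3)
        (masked ** 2).sum().backward()
        assert np.all(f.grad[:, 3:] == 0.0)
        assert np.any(f.grad[:, :3] != 0.0)


# ----------------------------------------------------------------- encode

class TestEncode:
    def test_identity_chain_full_prefix(self):
        p = identity_params(4)
        x = np.array([0.3, -1.2, 0.7, 2.0])
        assert np.allclose(encode(x, p, 4), x, atol=1e-5)

    def test_scale_collapse_to_bias(self):
        p = identity_params(3)
        p.rho.data = np.full(3, -40.0, dtype=np.float32)  # d -> EPS_D
        p.b.data = np.array([1.0, 2.0, 3.0], dtype=np.float32)
        out = encode(np.array([5.0, -5.0, 9.0]), p, 3)
        assert np.allclose(out, p.b.data, atol=1e-2)

    def test_output_in_masked_affine_subspace(self):
        rng = np.random.default_rng(3)
        p = EncoderParams.create(8, 5,
                                 ConditionedMLP(8, 5, rng, width=16, depth=2),
                                 rng)
        L = p.basis_values()
        for k in (1, 3, 5):
            x0 = encode(rng.normal(size=8), p, k)
            resid = x0 - p.b.data
            # projection onto columns beyond k vanishes
            assert np.abs(L[:, k:].T @ resid).max(initial=0.0) < 1e-6
            proj = L[:, :k] @ (L[:, :k].T @ resid)
            assert np.allclose(proj, resid, atol=1e-6)

    def test_latent_roundtrip_recovers_masked_features(self):
        rng = np.random.default_rng(4)
        p = EncoderParams.create(10, 4, ConditionedMLP(10, 4, rng, width=16,
                                                       depth=2), rng,
                                 d_init=0.5)
        x = rng.normal(size=10)
        for k in (1, 2, 4):
            x0 = encode(x, p, k)
            mu = latent_coordinates(x0, p)
            f, _ = encode_batch(Tensor(x.astype(np.float32)[None]), p,
                                np.array([k]))
            expected = latent_coordinates(f.data[0], p)
            assert np.allclose(mu, expected, atol=1e-6)
            assert np.allclose(mu[k:], 0.0, atol=1e-5)


class TestAlignmentLoss:
    def test_identity_chain_zero(self):
        p = identity_params(3)
        batch = Tensor(np.random.default_rng(0).normal(
            size=(5, 3)).astype(np.float32))
        loss = alignment_loss(batch, p, np.full(5, 3))
        assert float(loss.data) < 1e-9

    def test_unit_offset_gives_one(self):
        p = identity_params(3)
        p.b.data = np.array([1.0, 0.0, 0.0], dtype=np.float32)
        batch = Tensor(np.random.default_rng(0).normal(
            size=(4, 3)).astype(np.float32))
        loss = alignment_loss(batch, p, np.full(4, 3))
        assert abs(float(loss.data) - 1.0) < 1e-5

    def test_mean_of_squared_norms(self):
        # prefix K=1 on an identity chain zeroes the second coordinate, so
        # the residual norms^2 are exactly {4, 16}
        p = identity_params(2)
        batch = Tensor(np.array([[1.0, 2.0], [1.0, 4.0]], dtype=np.float32))
        loss = alignment_loss(batch, p, np.full(2, 1))
        assert abs(float(loss.data) - 10.0) < 1e-4


# -------------------------------------------------------------- projections

class TestLatentProjections:
    def _params(self):
        p = identity_params(2)
        p.rho.data = np.log(np.expm1(
            np.array([4.0, 1.0]) - EPS_D)).astype(np.float32)
        return p

    def test_bias_maps_to_origin(self):
        p = self._params()
        p.b.data = np.array([3.0, -1.0], dtype=np.float32)
        assert np.allclose(latent_coordinates(p.b.data, p), 0.0)

    def test_componentwise_inverse_scaling(self):
        p = self._params()
        assert np.allclose(latent_coordinates(np.array([2.0, 3.0]), p),
                           [1.0, 3.0], atol=1e-6)

    def test_velocity_projection_matches_and_is_linear(self):
        p = self._params()
        assert np.allclose(project_velocity(np.array([2.0, 3.0]), p),
                           [1.0, 3.0], atol=1e-6)
        assert np.allclose(project_velocity(np.zeros(2), p), 0.0)
        v1, v2 = np.array([1.0, -2.0]), np.array([0.5, 4.0])
        lhs = project_velocity(3.0 * v1 + v2, p)
        rhs = 3.0 * project_velocity(v1, p) + project_velocity(v2, p)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_velocity_projection_ignores_bias(self):
        p = self._params()
        p.b.data = np.array([10.0, 10.0], dtype=np.float32)
        assert np.allclose(project_velocity(np.array([2.0, 3.0]), p),
                           [1.0, 3.0], atol=1e-6)


# ------------------------------------------------------ effective dimension

class TestEffectiveDimension:
    @pytest.mark.parametrize("d,th,expected", [
        ((1.0, 0.0, 0.0), 0.95, 1),
        (tuple([0.1] * 10), 0.95, 10),       # cumulative 9/10 < 0.95
        ((0.5, 0.3, 0.15, 0.05), 0.95, 3),   # threshold met exactly at 3
    ])
    def test_prefix_rule(self, d, th, expected):
        assert effective_dimension(np.array(d), th) == expected

    def test_invariant_to_uniform_rescaling(self):
        d = np.array([0.4, 0.3, 0.2, 0.1])
        assert (effective_dimension(d, 0.9)
                == effective_dimension(123.0 * d, 0.9))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            effective_dimension(np.zeros(3))

    def test_uses_stored_order_not_sorted(self):
        # mass concentrated late: the prefix must extend through it
        d = np.array([0.01, 0.01, 1.0])
        assert effective_dimension(d, 0.95) == 3
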