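"""Diffeomorphic machinery: scaling-and-squaring, composition, warping,
Jacobians, elasticity, the symmetric losses and velocity distillation."""
import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from vbmflow import (DeformationField, ElasticityParams, RegNetConfig,
                     RegTrainConfig, SupervisedTarget, VelocityPair, Volume,
                     build_regnet, compose, full_deformations,
                     jacobian_determinant, linear_elasticity, normalized_grid,
                     scaling_squaring, supervised_full_loss,
                     supervised_velocity_loss, syn_loss, train_registration,
                     velocity_from_deformation, warp)
from vbmflow import autodiff as ad
from vbmflow.diffeo import _syn_loss_t

SHAPE = (32, 32, 32)


def _smooth_velocity(shape=SHAPE, amplitude_vox=2.0, sigma=3.0, seed=0):
    rng = np.random.default_rng(seed)
    v = np.stack([gaussian_filter(rng.normal(0, 1, shape), sigma)
                  for _ in range(3)])
    v *= amplitude_vox / np.abs(v).max()
    vox_to_norm = np.asarray([2.0 / (n - 1) for n in shape],
                             np.float32)[:, None, None, None]
    return (v * vox_to_norm).astype(np.float32)


def _vox(shape):
    return np.asarray([(n - 1) / 2.0 for n in shape])[:, None, None, None]


class TestScalingSquaring:
    def test_zero_velocity_is_identity(self):
        phi = scaling_squaring(np.zeros((3,) + SHAPE, np.float32))
        assert np.abs(phi.disp).max() == 0.0

    def test_constant_velocity_is_translation(self):
        v = np.zeros((3,) + SHAPE, np.float32)
        v[0] = 0.05
        phi = scaling_squaring(v, tau=7)
        interior = phi.disp[:, 2:-2, 2:-2, 2:-2]
        target = np.array([0.05, 0, 0])[:, None, None, None]
        assert np.abs(interior - target).max() < 1e-4

    def test_group_inverse(self):
        v = _smooth_velocity(amplitude_vox=2.0)
        residual = compose(scaling_squaring(v), scaling_squaring(-v))
        assert np.abs(residual.disp * _vox(SHAPE)).max() < 0.5

    def test_jacobian_positive_for_moderate_field(self):
        v = _smooth_velocity(amplitude_vox=2.0, seed=4)
        assert jacobian_determinant(scaling_squaring(v)).min() > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="tau"):
            scaling_squaring(np.zeros((3,) + SHAPE), tau=0)
        bad = np.full((3,) + SHAPE, np.nan, np.float32)
        with pytest.raises(ValueError, match="finite"):
            scaling_squaring(bad)


class TestCompose:
    def test_identity_neutral(self):
        b = DeformationField(_smooth_velocity(seed=1))
        out = compose(DeformationField.identity(SHAPE), b)
        assert np.abs(out.disp - b.disp).max() < 1e-5

    def test_translations_add(self):
        a = np.zeros((3,) + SHAPE, np.float32)
        a[0] = 0.04
        b = np.zeros((3,) + SHAPE, np.float32)
        b[1] = -0.03
        out = compose(DeformationField(a), DeformationField(b))
        expected = np.array([0.04, -0.03, 0.0])[:, None, None, None]
        assert np.abs(out.disp - expected).max() < 1e-6

    def test_associative_within_tolerance(self):
        fields = [DeformationField(_smooth_velocity(seed=s, amplitude_vox=0.5))
                  for s in (2, 3, 4)]
        left = compose(compose(fields[0], fields[1]), fields[2])
        right = compose(fields[0], compose(fields[1], fields[2]))
        assert np.abs(left.disp - right.disp).max() < 1e-3

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compose(DeformationField.identity((8, 8, 8)),
                    DeformationField.identity(SHAPE))


class TestWarp:
    def test_identity_warp(self):
        rng = np.random.default_rng(0)
        img = gaussian_filter(rng.normal(0, 1, SHAPE), 2).astype(np.float32)
        out = warp(img, DeformationField.identity(SHAPE))
        assert np.abs(out - img).max() < 1e-5

    def test_blob_centroid_moves_by_translation(self):
        idx = np.indices(SHAPE) - 15.5
        blob = np.exp(-(idx ** 2).sum(axis=0) / (2 * 2.0 ** 2)).astype(np.float32)
        disp = np.zeros((3,) + SHAPE, np.float32)
        disp[0] = 4.0 * 2.0 / 31  # sample 4 voxels upstream -> blob moves -4
        out = warp(blob, DeformationField(disp))
        w = np.indices(SHAPE)[0]
        c_in = (blob * w).sum() / blob.sum()
        c_out = (out * w).sum() / out.sum()
        assert c_out - c_in == pytest.approx(-4.0, abs=0.05)

    def test_constant_image_stays_constant(self):
        img = np.full(SHAPE, 1.7, np.float32)
        phi = DeformationField(_smooth_velocity(amplitude_vox=1.0, seed=5))
        out = warp(img, phi)
        inner = (slice(4, -4),) * 3
        np.testing.assert_allclose(out[inner], 1.7, atol=1e-4)

    def test_volume_wrapper_and_mismatch(self):
        v = Volume(np.zeros(SHAPE, np.float32))
        out = warp(v, DeformationField.identity(SHAPE))
        assert isinstance(out, Volume)
        with pytest.raises(ValueError, match="mismatch"):
            warp(np.zeros((8, 8, 8)), DeformationField.identity(SHAPE))


class TestJacobianAndElasticity:
    def test_identity_jacobian_is_one(self):
        jd = jacobian_determinant(DeformationField.identity(SHAPE))
        np.testing.assert_allclose(jd, 1.0, atol=1e-5)

    def test_uniform_zoom_jacobian(self):
        eps = 0.1
        phi = DeformationField(eps * normalized_grid(SHAPE))
        jd = jacobian_determinant(phi)
        np.testing.assert_allclose(jd, (1 + eps) ** 3, rtol=1e-5)

    def test_volume_preserving_field_has_unit_mean_jacobian(self):
        # divergence-free periodic field: v = (sin(y), 0, 0) in grid phase
        x = np.linspace(0, 2 * np.pi, SHAPE[0], endpoint=False)
        disp = np.zeros((3,) + SHAPE, np.float32)
        disp[0] = 0.02 * np.sin(x)[None, :, None]
        jd = jacobian_determinant(DeformationField(disp))
        assert abs(jd[2:-2, 2:-2, 2:-2].mean() - 1.0) < 1e-2

    def test_elasticity_closed_forms(self):
        params = ElasticityParams(mu=1.3, lam=0.7)
        assert linear_elasticity(DeformationField.identity(SHAPE), params) == 0
        shift = np.zeros((3,) + SHAPE, np.float32)
        shift[0] = 0.1
        assert linear_elasticity(DeformationField(shift), params) == 0
        eps = 0.1
        zoom = DeformationField(eps * normalized_grid(SHAPE))
        expected = (3 * params.mu + 4.5 * params.lam) * eps ** 2
        assert linear_elasticity(zoom, params) == pytest.approx(expected,
                                                                rel=1e-4)

    def test_elasticity_quadratic_scaling(self):
        params = ElasticityParams(mu=1.0, lam=1.0)
        u = _smooth_velocity(amplitude_vox=1.0, seed=7)
        le1 = linear_elasticity(DeformationField(u), params)
        le2 = linear_elasticity(DeformationField(2.0 * u), params)
        assert le2 == pytest.approx(4.0 * le1, rel=1e-3)


class TestSymmetricLosses:
    def _image(self, seed=0):
        rng = np.random.default_rng(seed)
        return gaussian_filter(rng.normal(0, 1, SHAPE), 2).astype(np.float32)

    def test_zero_velocity_identical_images(self):
        img = self._image()
        zeros = np.zeros((3,) + SHAPE, np.float32)
        assert syn_loss(img, img, VelocityPair(zeros, zeros),
                        ElasticityParams()) == pytest.approx(0.0, abs=1e-10)

    def test_nonzero_velocity_positive_loss(self):
        img = self._image()
        v = _smooth_velocity(amplitude_vox=1.0, seed=2)
        assert syn_loss(img, img, VelocityPair(v, -v), ElasticityParams()) > 0

    def test_direct_optimization_decreases_loss(self):
        """50 gradient steps on the velocity pair reduce the symmetric loss."""
        moving, template = self._image(3), self._image(4)
        vf = ad.Parameter(np.zeros((3,) + SHAPE, np.float32))
        vb = ad.Parameter(np.zeros((3,) + SHAPE, np.float32))
        opt = ad.Adam([vf, vb], lr=3e-3)
        I = ad.as_tensor(moving[None])
        J = ad.as_tensor(template[None])
        params = ElasticityParams(Lambda=0.01)
        losses = []
        for _ in range(50):
            total, _ = _syn_loss_t(I, J, vf, vb, params, tau=4)
            opt.zero_grad()
            total.backward()
            opt.step()
            losses.append(total.item())
        assert losses[-1] < losses[0]
        assert np.median(np.diff(losses)) < 0  # mostly downhill

    def test_velocity_loss_algebra(self):
        v = _smooth_velocity(seed=6)
        pair = VelocityPair(v, -v)
        assert supervised_velocity_loss(pair, pair) == 0
        c = 0.02
        shifted = VelocityPair(v + c, -v)
        assert supervised_velocity_loss(shifted, pair) == pytest.approx(
            c ** 2, rel=1e-4)
        assert supervised_velocity_loss(shifted, pair) == pytest.approx(
            supervised_velocity_loss(pair, shifted), rel=1e-6)

    def test_full_loss_composition(self):
        img = self._image(8)
        v = _smooth_velocity(amplitude_vox=1.0, seed=9)
        pair = VelocityPair(v, -v)
        phi_f, _ = full_deformations(pair)
        target = SupervisedTarget(pair, jacobian_determinant(phi_f))
        params = ElasticityParams()
        total0, parts0 = supervised_full_loss(pair, target, img, img, params,
                                              beta=0.0)
        assert parts0["L_v"] == 0
        assert parts0["L_jdet"] == pytest.approx(0.0, abs=1e-8)
        total1, parts1 = supervised_full_loss(pair, target, img, img, params,
                                              beta=2e-5)
        total2, _ = supervised_full_loss(pair, target, img, img, params,
                                         beta=4e-5)
        # doubling beta doubles the SyN contribution on top of L_{v,J}
        assert (total2 - total0) == pytest.approx(2 * (total1 - total0),
                                                  rel=1e-4)


class TestVelocityDistillation:
    def test_identity_target_gives_zero_velocities(self):
        ident = DeformationField.identity((16, 16, 16))
        pair, info = velocity_from_deformation(ident, ident, iters=50)
        assert info["residual_vox2"] < 1e-6
        assert np.abs(pair.v_fwd).max() < 1e-4

    def test_self_consistency_recovery(self):
        shape = (24, 24, 24)
        v = _smooth_velocity(shape, amplitude_vox=1.5, seed=11)
        truth = VelocityPair(v, -v)
        phi_f, phi_b = full_deformations(truth)
        rec, info = velocity_from_deformation(phi_f, phi_b, iters=100,
                                              tol=1e-6)
        rf, rb = full_deformations(rec)
        vox = _vox(shape)
        assert np.abs((rf.disp - phi_f.disp) * vox).max() < 0.1
        assert np.abs((rb.disp - phi_b.disp) * vox).max() < 0.1
        # velocities themselves need not match exactly (non-uniqueness), but
        # should be close for smooth fields
        assert supervised_velocity_loss(rec, truth) < 1e-3


class TestRegistrationNetwork:
    def test_untrained_output_strictly_bounded(self):
        net = build_regnet(RegNetConfig(depth=2, base_channels=2))
        x = np.random.default_rng(0).normal(0, 1, (4, 16, 16, 16)).astype(np.float32)
        pair = net.predict(x)
        assert np.abs(pair.v_fwd).max() < 1.0
        assert np.abs(pair.v_bwd).max() < 1.0

    def test_antisymmetric_mode(self):
        net = build_regnet(RegNetConfig(depth=2, base_channels=2,
                                        antisymmetric=True))
        x = np.random.default_rng(1).normal(0, 1, (4, 16, 16, 16)).astype(np.float32)
        pair = net.predict(x)
        np.testing.assert_array_equal(pair.v_bwd, -pair.v_fwd)

    def test_overfit_reduces_velocity_loss(self, trained_regnet):
        _, history = trained_regnet
        assert history["loss"][-1] < 0.1 * history["loss"][0]

    def test_training_deterministic(self, reg_truth):
        cfg = RegTrainConfig(epochs=3, net=RegNetConfig(depth=2, base_channels=2))
        _, h1 = train_registration([(reg_truth["channels"],
                                     reg_truth["target"])], cfg, seed=1)
        _, h2 = train_registration([(reg_truth["channels"],
                                     reg_truth["target"])], cfg, seed=1)
        assert h1["loss"] == h2["loss"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_registration([], RegTrainConfig())
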