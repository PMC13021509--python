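"""Segmentation mechanics: multilevel activation, label codec, patch grid,
Gaussian-importance assembly, flip sharing and cascade training."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vbmflow import (MultilevelActivation, Volume, decode_labels,
                     encode_labels, gaussian_importance, multilevel_activation,
                     optimize_patch_positions, regular_patch_grid,
                     run_patchwise, tissue_scores)
from vbmflow.tissue_seg import (PatchGrid, SegNetConfig, SegTrainConfig,
                                TissueLabelMap, _coverage, _regular_origins,
                                train_cascade)
from vbmflow import autodiff as ad


class TestMultilevelActivation:
    def test_limits(self):
        assert multilevel_activation(-100.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert multilevel_activation(100.0, 1.0) == pytest.approx(3.0, abs=1e-9)

    def test_midpoint_at_sharp_slope(self):
        # at x=0 with large alpha only the first sigmoid is at its midpoint
        assert multilevel_activation(0.0, 50.0) == pytest.approx(0.5, abs=1e-6)

    def test_positive_alpha_required(self):
        with pytest.raises(ValueError):
            multilevel_activation(1.0, 0.0)
        with pytest.raises(ValueError):
            MultilevelActivation(-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(0.1, 20))
    def test_range_and_monotonicity(self, x, alpha):
        y = multilevel_activation(x, alpha)
        assert 0.0 < y <= 3.0  # float64 saturates at the plateau
        assert multilevel_activation(x + 0.25, alpha) >= y

    def test_layer_matches_function(self):
        layer = MultilevelActivation(alpha=2.5)
        x = np.linspace(-2, 5, 50).astype(np.float32)
        out = layer(ad.as_tensor(x)).data
        np.testing.assert_allclose(out, multilevel_activation(x, 2.5),
                                   rtol=1e-5, atol=1e-6)


class TestLabelCodec:
    @pytest.mark.parametrize("label,expected", [
        (2.0, [0, 0, 1, 0]),            # pure GM
        (1.5, [0, 0.5, 0.5, 0]),        # CSF-GM partial volume
        (0.25, [0.75, 0.25, 0, 0]),     # mostly background
        (3.0, [0, 0, 0, 1]),
    ])
    def test_decode_examples(self, label, expected):
        out = decode_labels(np.full((2, 2, 2), label, np.float32))
        np.testing.assert_allclose(out[:, 0, 0, 0], expected, atol=1e-6)

    def test_round_trip(self):
        labels = np.linspace(0, 3, 64).astype(np.float32).reshape(4, 4, 4)
        lm = encode_labels(decode_labels(labels))
        np.testing.assert_allclose(lm.data, labels, atol=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decode_labels(np.full((2, 2, 2), 3.5))
        with pytest.raises(ValueError):
            TissueLabelMap(Volume(np.full((2, 2, 2), -1.0)))


class TestPatchGrid:
    def test_production_counts(self):
        grid = regular_patch_grid((336, 384, 336), (128, 128, 128))
        assert len(grid.origins) == 27
        assert grid.n_models == 18
        for i in range(27):
            o = grid.origins[i]
            assert np.all(o >= 0)
            assert np.all(o + 128 <= np.array([336, 384, 336]))

    def test_flip_partners_are_exact_mirrors(self):
        grid = regular_patch_grid((336, 384, 336), (128, 128, 128))
        for i, (model, flipped, _) in enumerate(grid.equivalence):
            if flipped:
                o = grid.origins[i]
                partner = [j for j, (m, f, _) in enumerate(grid.equivalence)
                           if m == model and not f][0]
                po = grid.origins[partner]
                assert po[0] == 336 - 128 - o[0]
                assert tuple(po[1:]) == tuple(o[1:])

    def test_full_mask_stays_on_regular_grid(self):
        grid = optimize_patch_positions([np.ones((24, 24))],
                                        grid_shape=(24, 24), patch_shape=(8, 8))
        np.testing.assert_array_equal(grid.origins,
                                      _regular_origins((24, 24), (8, 8)))

    def test_empty_mask_converges_to_center(self):
        grid = optimize_patch_positions([np.zeros((24, 24))],
                                        grid_shape=(24, 24), patch_shape=(8, 8))
        assert np.all(grid.origins == 8)  # all patches at the centered origin

    def test_blob_coverage_and_local_maximality(self):
        mask = np.zeros((24, 24))
        mask[7:16, 9:14] = 1
        grid = optimize_patch_positions([mask], grid_shape=(24, 24),
                                        patch_shape=(8, 8))
        cov = _coverage(grid.origins, (8, 8), (24, 24))
        assert np.all(cov[mask > 0.5])
        # no lockstep group can take one more inward step on any axis
        mirror0 = 24 - 8
        for i, o in enumerate(grid.origins):
            for axis in range(2):
                d = int(np.sign((24 - 8) - 2 * o[axis]))
                if d == 0:
                    continue
                trial = grid.origins.copy()
                trial[i][axis] += d
                if axis == 0 and 2 * o[0] != mirror0:
                    j = [k for k, p in enumerate(grid.origins)
                         if p[0] == mirror0 - o[0] and p[1] == o[1]][0]
                    trial[j][0] -= d
                assert np.any((mask > 0.5) & ~_coverage(trial, (8, 8), (24, 24)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search_on_quasi_1d_instances(self, seed):
        """On a (24, 8) grid with 8-wide patches only the sagittal pair can
        move; brute-force enumeration of its inward offset is the oracle."""
        rng = np.random.default_rng(seed)
        lo, hi = sorted(rng.integers(0, 24, 2))
        hi = max(hi, lo + 1)
        mask = np.zeros((24, 8))
        mask[lo:hi] = 1

        def feasible(a):
            origins = np.array([[a, 0], [8, 0], [16 - a, 0]])
            return np.all(_coverage(origins, (8, 8), (24, 8))[mask > 0.5])

        best = 0
        for a in range(1, 9):  # stepwise: the path must stay feasible
            if feasible(a):
                best = a
            else:
                break
        grid = optimize_patch_positions([mask], grid_shape=(24, 8),
                                        patch_shape=(8, 8))
        lefts = sorted(set(o[0] for o in grid.origins))
        assert lefts == sorted({best, 8, 16 - best})

    def test_uncoverable_mask_names_voxel(self):
        mask = np.ones((24, 24))
        with pytest.raises(ValueError, match="not coverable"):
            optimize_patch_positions([mask], grid_shape=(24, 24),
                                     patch_shape=(4, 4))


class TestGaussianImportance:
    def test_maximal_at_center_decreasing_outward(self):
        w = gaussian_importance((16, 16, 16))
        assert w.max() == w[7:9, 7:9, 7:9].max()
        center_line = w[:, 8, 8]
        assert np.all(np.diff(center_line[:8]) > 0)
        assert np.all(np.diff(center_line[8:]) < 0)


class _ConstantModel:
    def __init__(self, c):
        self.c = c

    def __call__(self, x):
        return ad.Tensor(np.full((1,) + x.data.shape[1:], self.c, np.float32))


def _desk_grid():
    return regular_patch_grid((48, 48, 48), (16, 16, 16))


class TestRunPatchwise:
    def test_constant_models_give_constant_output(self, phantom_assets):
        _, vol, label, _ = phantom_assets
        grid = _desk_grid()
        bank = [_ConstantModel(1.25)] * grid.n_models
        out = run_patchwise(bank, vol, label, grid)
        np.testing.assert_allclose(out.data, 1.25, atol=1e-5)

    def test_bank_size_mismatch(self, phantom_assets):
        _, vol, label, _ = phantom_assets
        with pytest.raises(ValueError, match="model bank"):
            run_patchwise([_ConstantModel(1.0)] * 3, vol, label, _desk_grid())

    def test_overlap_weighting_on_1d_toy(self):
        """Two overlapping patches with constant outputs a and b: the blend is
        between them and closer to the nearer patch center."""
        grid = PatchGrid(origins=np.array([[0, 0, 0], [8, 0, 0]]),
                         patch_shape=(16, 16, 16), grid_shape=(24, 16, 16),
                         equivalence=[(0, False, False), (1, False, False)])
        bank = [_ConstantModel(1.0), _ConstantModel(3.0)]
        vol = Volume(np.zeros((24, 16, 16), np.float32))
        out = run_patchwise(bank, vol, vol, grid).data
        overlap = out[8:16, 8, 8]
        assert np.all(overlap > 1.0) and np.all(overlap < 3.0)
        assert overlap[0] < 2.0 < overlap[-1]  # nearer center dominates

    def test_mirror_equivariance_exact(self, trained_bank, phantom_assets):
        _, vol, _, _ = phantom_assets
        rng = np.random.default_rng(6)
        bumpy = Volume((vol.data + 0.05 * rng.random(vol.shape)).astype(np.float32),
                       vol.affine)
        pred = trained_bank.segment(bumpy)
        mirrored = Volume(np.flip(bumpy.data, axis=0).copy(), bumpy.affine)
        pred_m = trained_bank.segment(mirrored)
        np.testing.assert_allclose(np.flip(pred_m.data, axis=0), pred.data,
                                   atol=1e-5)


class TestTrainCascade:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_cascade([], SegTrainConfig())

    def test_single_phantom_overfit_reaches_high_dice(self, trained_bank,
                                                      phantom_assets):
        _, vol, label, _ = phantom_assets
        pred = trained_bank.segment(vol)
        scores = tissue_scores(pred, label)
        assert scores["dsc_foreground"] > 90.0

    def test_one_cycle_schedule_peaks_at_configured_rate(self, trained_bank):
        lrs = trained_bank.history["stage1_lr"]
        assert max(lrs) == pytest.approx(trained_bank.config.max_lr, rel=1e-6)
        peak = int(np.argmax(lrs))
        assert all(a <= b + 1e-12 for a, b in zip(lrs[:peak], lrs[1:peak + 1]))
        assert all(a >= b - 1e-12 for a, b in zip(lrs[peak:], lrs[peak + 1:]))

    def test_training_is_deterministic(self, phantom_assets):
        _, vol, label, _ = phantom_assets
        cfg = SegTrainConfig(net=SegNetConfig(depth=2, base_channels=2),
                             stage1_epochs=3, foundation_epochs=1,
                             finetune_epochs=1)
        h1 = train_cascade([(vol, label)], cfg, seed=3).history
        h2 = train_cascade([(vol, label)], cfg, seed=3).history
        assert h1["stage1_loss"] == h2["stage1_loss"]
        assert h1["foundation_loss"] == h2["foundation_loss"]
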