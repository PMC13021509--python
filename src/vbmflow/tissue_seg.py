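"""Cascaded patchwise tissue segmentation.

Tissue maps are continuous labels in [0, 3]: 0 background, 1 CSF, 2 GM, 3 WM,
with the half-integer values 1.5 and 2.5 encoding the CSF-GM and GM-WM
partial-volume mixtures.  A coarse full-view UNet (stage 1) produces an
initial map; stage 2 refines it at full resolution with a 3 x 3 x 3 grid of
patch-specific UNets whose positions are optimized to hug the tissue, whose
left/right-hemisphere members share weights through a sagittal flip, and whose
overlapping predictions are blended with Gaussian importance weights.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .config import (DESK_PATCH_SHAPE, GRID_PRESETS, IMPORTANCE_SIGMA_FRACTION,
                     MAX_LR)
from .nn import Module, UNet3d, mae_loss
from .volume import Volume

MULTILEVEL_OFFSETS = (1.5, 2.0, 2.5, 3.0)


# -- multilevel activation ------------------------------------------------

def multilevel_activation(x, alpha: float):
    """Six-sigmoid multilevel activation.

    f(x) = S(a*x) + sum_{i in {1.5, 2, 2.5, 3}} S(a*(x - i)) / 2 with the
    logistic S; it maps the real line onto (0, 3) with plateaus at the label
    values 0, 1, 1.5, 2, 2.5 and 3 (the slope ``alpha`` sets their sharpness).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=np.float64)

    def S(z):
        return 1.0 / (1.0 + np.exp(-z))

    out = S(alpha * x)
    for i in MULTILEVEL_OFFSETS:
        out = out + S(alpha * (x - i)) / 2.0
    return out


class MultilevelActivation(Module):
    """Trainable-slope multilevel head for segmentation networks."""

    def __init__(self, alpha: float = 4.0):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = Parameter(np.array([alpha], np.float32))

    def forward(self, x: Tensor) -> Tensor:
        a = self.alpha.reshape(())
        out = ad.sigmoid(x * a)
        for i in MULTILEVEL_OFFSETS:
            out = out + ad.sigmoid((x - i) * a) * 0.5
        return out


# -- label encoding -------------------------------------------------------

@dataclass
class TissueLabelMap:
    """Continuous tissue-label volume with values in [0, 3]."""

    volume: Volume

    def __post_init__(self):
        d = self.volume.data
        if d.min() < -1e-4 or d.max() > 3.0 + 1e-4:
            raise ValueError(
                f"labels must lie in [0, 3], got [{d.min()}, {d.max()}]")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def decode_labels(label_map: TissueLabelMap | np.ndarray) -> np.ndarray:
    """Continuous label -> probability channels (background, CSF, GM, WM).

    Triangular kernels: p_k(x) = max(0, 1 - |x - k|) for the class centers
    k = 1, 2, 3 and max(0, 1 - x) for background, so each voxel is a mixture
    of at most two adjacent classes.
    """
    x = label_map.data if isinstance(label_map, TissueLabelMap) else np.asarray(label_map)
    if x.min() < -1e-4 or x.max() > 3.0 + 1e-4:
        raise ValueError("labels outside [0, 3]")
    chans = [np.maximum(0.0, 1.0 - x)]
    for k in (1.0, 2.0, 3.0):
        chans.append(np.maximum(0.0, 1.0 - np.abs(x - k)))
    return np.stack(chans).astype(np.float32)


def encode_labels(prob: np.ndarray, affine=None) -> TissueLabelMap:
    """Probability channels (background, CSF, GM, WM) -> continuous label.

    Inverse of :func:`decode_labels` on voxels mixing at most two adjacent
    classes: the label is the probability-weighted mean of the class centers.
    """
    prob = np.asarray(prob, dtype=np.float32)
    if prob.min() < -1e-6:
        raise ValueError("probabilities must be non-negative")
    if np.any(prob.sum(axis=0) > 1.0 + 1e-5):
        raise ValueError("per-voxel probabilities must sum to at most 1")
    label = prob[1] + 2.0 * prob[2] + 3.0 * prob[3]
    vol = Volume(label, np.eye(4) if affine is None else affine)
    return TissueLabelMap(vol)


# -- patch grid -----------------------------------------------------------

@dataclass
class PatchGrid:
    """3^nd patch origins with sagittal-flip weight-sharing classes.

    ``equivalence[i]`` is ``(model_index, flip, symmetrize)``: right-hemisphere
    patches reuse the mirrored left-hemisphere model (``flip``); mid-column
    patches are symmetrized at inference so the assembled prediction is exactly
    mirror-equivariant.
    """

    origins: np.ndarray
    patch_shape: tuple
    grid_shape: tuple
    equivalence: list = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return 1 + max(m for m, _, _ in self.equivalence)

    def patch_slices(self, i: int):
        o = self.origins[i]
        return tuple(slice(int(o[d]), int(o[d]) + self.patch_shape[d])
                     for d in range(len(self.patch_shape)))


def _regular_origins(grid_shape, patch_shape) -> np.ndarray:
    """3-per-axis starting origins: [0, centered, flush-right]."""
    nd = len(grid_shape)
    per_axis = [(0, (grid_shape[d] - patch_shape[d]) // 2,
                 grid_shape[d] - patch_shape[d]) for d in range(nd)]
    return np.array(list(itertools.product(*per_axis)), dtype=np.int64)


def _equivalence(origins, grid_shape, patch_shape) -> list:
    """Assign model indices; sagittal axis is axis 0."""
    nd = origins.shape[1]
    key_to_model: dict = {}
    eq = []
    mirror = grid_shape[0] - patch_shape[0]
    for o in origins:
        o = tuple(int(x) for x in o)
        center = 2 * o[0] == mirror
        right = 2 * o[0] > mirror
        canon = (mirror - o[0],) + o[1:] if right else o
        if canon not in key_to_model:
            key_to_model[canon] = len(key_to_model)
        eq.append((key_to_model[canon], bool(right), bool(center)))
    return eq


def _coverage(origins, patch_shape, grid_shape) -> np.ndarray:
    cov = np.zeros(grid_shape, dtype=bool)
    for o in origins:
        sl = tuple(slice(int(o[d]), int(o[d]) + patch_shape[d])
                   for d in range(len(grid_shape)))
        cov[sl] = True
    return cov


def regular_patch_grid(grid_shape, patch_shape) -> PatchGrid:
    origins = _regular_origins(grid_shape, patch_shape)
    return PatchGrid(origins, tuple(patch_shape), tuple(grid_shape),
                     _equivalence(origins, grid_shape, patch_shape))


def optimize_patch_positions(tissue_masks, grid_shape=None,
                             patch_shape=None) -> PatchGrid:
    """Move patches voxel-by-voxel toward the image center while every tissue
    voxel of every mask stays covered by at least one patch.

    Left/right hemisphere patches move in mirrored lockstep along the sagittal
    axis (axis 0) so their weight sharing stays exact.  Works in any dimension
    (2D instances are used for brute-force verification).
    """
    masks = [m.data if isinstance(m, Volume) else np.asarray(m) for m in tissue_masks]
    if grid_shape is None:
        grid_shape = masks[0].shape if masks else GRID_PRESETS["desk_high"].shape
    grid_shape = tuple(grid_shape)
    nd = len(grid_shape)
    if patch_shape is None:
        patch_shape = DESK_PATCH_SHAPE[:nd]
    patch_shape = tuple(patch_shape)
    union = np.zeros(grid_shape, dtype=bool)
    for m in masks:
        if m.shape != grid_shape:
            raise ValueError(f"mask shape {m.shape} does not match grid {grid_shape}")
        union |= m > 0.5
    origins = _regular_origins(grid_shape, patch_shape)
    uncovered = union & ~_coverage(origins, patch_shape, grid_shape)
    if uncovered.any():
        vox = tuple(int(i) for i in np.argwhere(uncovered)[0])
        raise ValueError(f"tissue voxel {vox} not coverable by the starting grid")

    # lockstep groups: mirrored sagittal pairs plus mid-column singletons
    mirror0 = grid_shape[0] - patch_shape[0]
    groups, seen = [], set()
    for i, o in enumerate(origins):
        if i in seen:
            continue
        if 2 * o[0] != mirror0:
            j = next(k for k, p in enumerate(origins)
                     if k not in seen and k != i
                     and p[0] == mirror0 - o[0] and tuple(p[1:]) == tuple(o[1:]))
            groups.append([i, j])
            seen.update((i, j))
        else:
            groups.append([i])
            seen.add(i)

    def directions(idx, axis):
        # +1/-1 toward the image center along `axis`, 0 if centered
        c2 = grid_shape[axis] - patch_shape[axis]
        return int(np.sign(c2 - 2 * origins[idx][axis]))

    moved = True
    while moved:
        moved = False
        for axis in range(nd):
            for grp in groups:
                dirs = [directions(i, axis) for i in grp]
                if all(d == 0 for d in dirs):
                    continue
                trial = origins.copy()
                for i, d in zip(grp, dirs):
                    trial[i][axis] += d
                if not (union & ~_coverage(trial, patch_shape, grid_shape)).any():
                    origins = trial
                    moved = True
    return PatchGrid(origins, patch_shape, grid_shape,
                     _equivalence(origins, grid_shape, patch_shape))


def gaussian_importance(patch_shape,
                        sigma_fraction: float = IMPORTANCE_SIGMA_FRACTION) -> np.ndarray:
    """Separable Gaussian weight, maximal at the patch center (sigma = edge/8)."""
    w = np.ones(patch_shape, dtype=np.float64)
    for d, n in enumerate(patch_shape):
        c = (n - 1) / 2.0
        sig = max(n * sigma_fraction, 1e-6)
        g = np.exp(-((np.arange(n) - c) ** 2) / (2 * sig ** 2))
        shape = [1] * len(patch_shape)
        shape[d] = n
        w = w * g.reshape(shape)
    return (w / w.max()).astype(np.float32)


# -- patchwise inference --------------------------------------------------

def _resize(data: np.ndarray, shape, order: int = 1) -> np.ndarray:
    """Resample to ``shape`` with endpoints aligned to the voxel centers."""
    coords = np.meshgrid(*[np.linspace(0, data.shape[d] - 1, shape[d])
                           for d in range(data.ndim)], indexing="ij")
    return ndimage.map_coordinates(data.astype(np.float64), coords, order=order,
                                   mode="nearest").astype(np.float32)


def run_patchwise(model_bank, v: Volume, stage1_pred, grid: PatchGrid,
                  sigma_fraction: float = IMPORTANCE_SIGMA_FRACTION) -> TissueLabelMap:
    """Assemble the full-size stage-2 prediction.

    Each voxel is the Gaussian-importance-weighted average of all patch
    predictions covering it; right-hemisphere patches are sagittally flipped
    to reuse left-hemisphere models, and mid-column predictions are
    symmetrized so the assembly commutes exactly with a sagittal mirror.
    """
    if len(model_bank) != grid.n_models:
        raise ValueError(
            f"model bank has {len(model_bank)} models, grid needs {grid.n_models}")
    img = v.data if isinstance(v, Volume) else np.asarray(v, np.float32)
    s1 = stage1_pred.data if hasattr(stage1_pred, "data") else np.asarray(stage1_pred)
    if s1.shape != img.shape:
        s1 = _resize(s1, img.shape, order=1)
    channels = np.stack([img, s1]).astype(np.float32)
    weight = gaussian_importance(grid.patch_shape, sigma_fraction)
    acc = np.zeros(img.shape, dtype=np.float64)
    wsum = np.zeros(img.shape, dtype=np.float64)
    for i in range(len(grid.origins)):
        model_idx, flipped, symmetrize = grid.equivalence[i]
        sl = grid.patch_slices(i)
        x = channels[(slice(None),) + sl]
        model = model_bank[model_idx]

        def predict(arr):
            out = model(ad.as_tensor(arr))
            return out.data[0] if out.data.ndim == 4 else out.data

        if flipped:
            pred = np.flip(predict(np.flip(x, axis=1).copy()), axis=0)
        elif symmetrize:
            pred = 0.5 * (predict(x)
                          + np.flip(predict(np.flip(x, axis=1).copy()), axis=0))
        else:
            pred = predict(x)
        acc[sl] += weight * pred
        wsum[sl] += weight
    out = np.where(wsum > 0, acc / np.maximum(wsum, 1e-12), 0.0)
    out = np.clip(out, 0.0, 3.0).astype(np.float32)
    affine = v.affine if isinstance(v, Volume) else np.eye(4)
    return TissueLabelMap(Volume(out, affine, space_tag="template"))


# -- training -------------------------------------------------------------

@dataclass
class SegNetConfig:
    depth: int = 2
    base_channels: int = 4
    alpha_init: float = 4.0


@dataclass
class SegTrainConfig:
    net: SegNetConfig = field(default_factory=SegNetConfig)
    mid_shape: tuple = GRID_PRESETS["desk_mid"].shape
    patch_shape: tuple = DESK_PATCH_SHAPE
    stage1_epochs: int = 60
    foundation_epochs: int = 2
    finetune_epochs: int = 20
    patch_batch: int = 2
    max_lr: float = MAX_LR
    flip_probability: float = 0.5


class SegNet(Module):
    """UNet with a multilevel-activation head producing labels in (0, 3)."""

    def __init__(self, in_channels, config: SegNetConfig, seed=0):
        self.unet = UNet3d(in_channels, 1, depth=config.depth,
                           base_channels=config.base_channels,
                           activation="relu", seed=seed)
        self.act = MultilevelActivation(config.alpha_init)

    def forward(self, x):
        return self.act(self.unet(x))


@dataclass
class SegModelBank:
    stage1: SegNet
    patch_models: list
    grid: PatchGrid
    config: SegTrainConfig
    history: dict

    def segment(self, v: Volume) -> TissueLabelMap:
        """Full cascade: coarse stage-1 pass, upsample, patchwise refinement.

        The stage-1 prediction is symmetrized over the sagittal mirror so the
        whole cascade is exactly mirror-equivariant (the patch stage already
        is, via weight sharing and mid-column symmetrization).
        """
        coarse_in = _resize(v.data, self.config.mid_shape, order=1)
        s1 = self.stage1(ad.as_tensor(coarse_in[None])).data[0]
        s1_f = self.stage1(ad.as_tensor(np.flip(coarse_in, 0).copy()[None])).data[0]
        s1 = 0.5 * (s1 + np.flip(s1_f, 0))
        s1_up = _resize(s1, v.data.shape, order=1)
        return run_patchwise(self.patch_models, v, s1_up, self.grid)


def save_bank(bank: SegModelBank, path) -> None:
    """Serialize a model bank (weights + patch-grid metadata + version)."""
    import json
    from pathlib import Path

    arrays = {"grid_origins": bank.grid.origins}
    arrays.update({f"stage1.{k}": v for k, v in bank.stage1.state_dict().items()})
    for m, model in enumerate(bank.patch_models):
        arrays.update({f"patch{m}.{k}": v for k, v in model.state_dict().items()})
    meta = {
        "version": 1,
        "patch_shape": list(bank.grid.patch_shape),
        "grid_shape": list(bank.grid.grid_shape),
        "equivalence": [list(e) for e in bank.grid.equivalence],
        "n_models": bank.grid.n_models,
        "net": bank.config.net.__dict__,
        "mid_shape": list(bank.config.mid_shape),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8),
             **arrays)


def load_bank(path) -> SegModelBank:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        net_cfg = SegNetConfig(**meta["net"])
        config = SegTrainConfig(net=net_cfg, mid_shape=tuple(meta["mid_shape"]),
                                patch_shape=tuple(meta["patch_shape"]))
        grid = PatchGrid(z["grid_origins"], tuple(meta["patch_shape"]),
                         tuple(meta["grid_shape"]),
                         [(int(a), bool(b), bool(c))
                          for a, b, c in meta["equivalence"]])
        stage1 = SegNet(1, net_cfg)
        stage1.load_state_dict({k[len("stage1."):]: z[k] for k in z.files
                                if k.startswith("stage1.")})
        models = []
        for m in range(meta["n_models"]):
            net = SegNet(2, net_cfg)
            pre = f"patch{m}."
            net.load_state_dict({k[len(pre):]: z[k] for k in z.files
                                 if k.startswith(pre)})
            models.append(net)
    return SegModelBank(stage1, models, grid, config, history={})


def _one_cycle_steps(n_epochs, n_items):
    return max(1, n_epochs * n_items)


def train_cascade(dataset, config: SegTrainConfig | None = None,
                  seed: int = 0) -> SegModelBank:
    """Train the two-stage cascade on (normalized Volume, TissueLabelMap) pairs.

    Stage 1 trains a full-view UNet at the coarse resolution; stage 2 trains a
    foundation UNet across all effective patch positions and fine-tunes one
    copy per position.  All losses are MAE against the continuous labels, all
    schedules one-cycle with the configured peak learning rate.  Flip
    augmentation is applied only to mid-column patches (hemisphere patches
    already share weights through the mirror).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    config = config or SegTrainConfig()
    rng = np.random.default_rng(seed)
    history = {"stage1_loss": [], "stage1_lr": [], "foundation_loss": [],
               "finetune_loss": [], "alpha": []}

    vols = [v.data if isinstance(v, Volume) else np.asarray(v) for v, _ in dataset]
    labels = [t.data if hasattr(t, "data") else np.asarray(t) for _, t in dataset]
    high_shape = vols[0].shape

    # ---- stage 1: coarse full-view model (batch size 1)
    stage1 = SegNet(1, config.net, seed=seed)
    opt = ad.Adam(stage1.parameters())
    n_steps = _one_cycle_steps(config.stage1_epochs, len(dataset))
    step = 0
    coarse = [( _resize(v, config.mid_shape, 1), _resize(t, config.mid_shape, 1))
              for v, t in zip(vols, labels)]
    for _ in range(config.stage1_epochs):
        for cv, ct in coarse:
            pred = stage1(ad.as_tensor(cv[None]))
            loss = mae_loss(pred, ct[None])
            opt.zero_grad()
            loss.backward()
            lr = ad.one_cycle_lr(step, n_steps, config.max_lr)
            opt.step(lr=lr)
            stage1.act.alpha.data = np.maximum(stage1.act.alpha.data, 1e-2)
            history["stage1_loss"].append(float(loss.item()))
            history["stage1_lr"].append(lr)
            step += 1

    # ---- patch grid from the training tissue masks
    masks = [(t > 0.5).astype(np.float32) for t in labels]
    grid = optimize_patch_positions(masks, grid_shape=high_shape,
                                    patch_shape=config.patch_shape)

    # ---- stage-1 predictions upsampled as the second input channel
    s1_up = []
    for cv, _ in coarse:
        p = stage1(ad.as_tensor(cv[None])).data[0]
        s1_up.append(_resize(p, high_shape, 1))

    def patch_samples():
        """One sample per (training volume, effective position)."""
        out = []
        for v, t, s1 in zip(vols, labels, s1_up):
            chans = np.stack([v, s1]).astype(np.float32)
            for i in range(len(grid.origins)):
                model_idx, flipped, center = grid.equivalence[i]
                if flipped:
                    continue  # mirrored duplicates of left-hemisphere samples
                sl = grid.patch_slices(i)
                out.append((model_idx, center, chans[(slice(None),) + sl],
                            t[sl][None]))
        return out

    samples = patch_samples()

    def train_model(model, items, epochs, allow_flip):
        n_steps = _one_cycle_steps(epochs, max(1, len(items) // config.patch_batch))
        opt = ad.Adam(model.parameters())
        losses = []
        step = 0
        for _ in range(epochs):
            order = rng.permutation(len(items))
            for b0 in range(0, len(items), config.patch_batch):
                batch = [items[i] for i in order[b0:b0 + config.patch_batch]]
                loss = None
                for _, center, x, t in batch:
                    if allow_flip and center and rng.random() < config.flip_probability:
                        x = np.flip(x, axis=1).copy()
                        t = np.flip(t, axis=1).copy()
                    term = mae_loss(model(ad.as_tensor(x)), t)
                    loss = term if loss is None else loss + term
                loss = loss * (1.0 / len(batch))
                opt.zero_grad()
                loss.backward()
                lr = ad.one_cycle_lr(step, n_steps, config.max_lr)
                opt.step(lr=lr)
                model.act.alpha.data = np.maximum(model.act.alpha.data, 1e-2)
                losses.append(float(loss.item()))
                step += 1
        return losses

    # ---- foundation model across all effective positions, then fine-tuning
    foundation = SegNet(2, config.net, seed=seed + 1)
    history["foundation_loss"] = train_model(
        foundation, samples, config.foundation_epochs, allow_flip=True)
    found_state = foundation.state_dict()

    patch_models = []
    for m in range(grid.n_models):
        model = SegNet(2, config.net, seed=seed + 2 + m)
        model.load_state_dict(found_state)
        items = [s for s in samples if s[0] == m]
        losses = train_model(model, items, config.finetune_epochs,
                             allow_flip=True)
        history["finetune_loss"].append(losses)
        history["alpha"].append(float(model.act.alpha.data[0]))
        patch_models.append(model)

    return SegModelBank(stage1, patch_models, grid, config, history)
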