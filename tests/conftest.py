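"""Shared fixtures: phantoms and (expensively) trained desk-scale models."""
import numpy as np
import pytest

from vbmflow import (PhantomSpec, RegNetConfig, RegTrainConfig, SegNetConfig,
                     SegTrainConfig, SupervisedTarget, decode_labels,
                     jacobian_determinant, make_deformation_truth,
                     make_phantom, train_cascade, train_registration, warp)
from vbmflow.config import GRID_PRESETS


@pytest.fixture(scope="session")
def phantom_assets():
    """Default desk phantom: (spec, intensity volume, label map, masks)."""
    spec = PhantomSpec(seed=0)
    vol, label, masks = make_phantom(spec)
    return spec, vol, label, masks


@pytest.fixture(scope="session")
def trained_bank(phantom_assets):
    """Tiny cascade overfit on a single phantom (shared across tests)."""
    _, vol, label, _ = phantom_assets
    cfg = SegTrainConfig(net=SegNetConfig(depth=2, base_channels=6),
                         stage1_epochs=120, foundation_epochs=6,
                         finetune_epochs=25, max_lr=0.01)
    return train_cascade([(vol, label)], cfg, seed=0)


@pytest.fixture(scope="session")
def reg_truth():
    """Registration-grid template maps plus a ground-truth deformation."""
    grid = GRID_PRESETS["desk_reg"]
    spec = PhantomSpec(grid=grid, seed=5)
    _, label, masks = make_phantom(spec)
    prob = decode_labels(label)
    gm, wm = prob[2], prob[3]
    pair, (phi_f, phi_b) = make_deformation_truth(grid, amplitude_vox=1.5,
                                                  seed=3)
    channels = np.stack([warp(gm, phi_b), warp(wm, phi_b), gm, wm])
    target = SupervisedTarget(pair, jacobian_determinant(phi_f))
    return {"grid": grid, "gm": gm, "wm": wm, "pair": pair,
            "phi_f": phi_f, "phi_b": phi_b, "channels": channels,
            "target": target, "masks": masks}


@pytest.fixture(scope="session")
def trained_regnet(reg_truth):
    cfg = RegTrainConfig(epochs=300, loss="lv",
                         net=RegNetConfig(depth=2, base_channels=4))
    net, history = train_registration([(reg_truth["channels"],
                                        reg_truth["target"])], cfg, seed=0)
    return net, history
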