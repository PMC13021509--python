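"""Package-wide constants: grid presets, artifact presets and desk-scale defaults.

Two families of grids exist side by side.  The production presets mirror the
template-space conventions of classical VBM preprocessing: a 0.5 mm
high-resolution grid (339 x 411 x 339) whose analysis crop (336 x 384 x 336) is
divisible by 16, a 0.75 mm grid (224 x 256 x 224) for the coarse segmentation
stage, and a 1.5 mm grid (113 x 137 x 113) for registration and VBM.  The desk
presets shrink every grid by roughly a factor of 7 while preserving all
structural relations (3 x 3 x 3 patch tiling, stage-1/stage-2 resolution ratio
of 2/3, crop divisibility), so the full pipeline runs in minutes on one CPU.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid with an optional analysis crop.

    ``crop_origin``/``crop_shape`` delimit the sub-grid that the patchwise
    segmentation operates on; for grids used whole they equal the full grid.
    """

    shape: tuple
    spacing: tuple
    crop_origin: tuple = (0, 0, 0)
    crop_shape: tuple | None = None

    def __post_init__(self):
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if self.crop_shape is None:
            object.__setattr__(self, "crop_shape", tuple(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """Canonical voxel-to-world matrix: axis-aligned, centered at the origin."""
        a = np.eye(4)
        for i in range(3):
            a[i, i] = self.spacing[i]
            a[i, 3] = -self.spacing[i] * (self.shape[i] - 1) / 2.0
        return a


# Production template-space presets.  The analysis-crop origin within the
# 0.5 mm grid is a recorded constant (centered crop).
GRID_PRESETS = {
    "high_0p5mm": GridSpec(shape=(339, 411, 339), spacing=(0.5, 0.5, 0.5),
                           crop_origin=(1, 13, 1), crop_shape=(336, 384, 336)),
    "mid_0p75mm": GridSpec(shape=(224, 256, 224), spacing=(0.75, 0.75, 0.75)),
    "reg_1p5mm": GridSpec(shape=(113, 137, 113), spacing=(1.5, 1.5, 1.5)),
    # Desk-scale analogues (same structural ratios, minutes-scale compute).
    "desk_high": GridSpec(shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0)),
    "desk_mid": GridSpec(shape=(32, 32, 32), spacing=(4.5, 4.5, 4.5)),
    "desk_reg": GridSpec(shape=(24, 24, 24), spacing=(6.0, 6.0, 6.0)),
}

PATCH_SHAPE = (128, 128, 128)        # production patch size on the 0.5 mm crop
DESK_PATCH_SHAPE = (16, 16, 16)      # desk patch size on the 48^3 desk grid

# Gaussian importance weighting: sigma as a fraction of the patch edge length.
IMPORTANCE_SIGMA_FRACTION = 1.0 / 8.0

# Scaling-and-squaring time steps.
TAU = 7

# Supervised registration loss weight on the SyN term.
BETA_SYN = 2e-5

# Smoothing kernel applied before the GLM stage.
SMOOTH_FWHM_MM = 6.0

# One-cycle schedule peak learning rate used by every training loop.
MAX_LR = 1e-3

# Medium/strong parameter tables for the seven-artifact test protocol.  The
# numeric strengths are recorded package constants (chosen once; the protocol
# itself only fixes the set of artifacts and the two intensity tiers).
ARTIFACT_PRESETS = {
    "noise": {"medium": 0.05, "strong": 0.15},
    "bias_field": {"medium": 0.3, "strong": 0.8},
    "blur": {"medium": 0.7, "strong": 1.5},
    "ghosting": {"medium": 0.25, "strong": 0.6},
    "motion": {"medium": 0.5, "strong": 1.5},
    "gibbs": {"medium": 0.35, "strong": 0.6},
    "spike": {"medium": 0.15, "strong": 0.5},
}

AUGMENT_KINDS = (
    "bias_field", "motion", "noise", "blur", "ghosting", "spike",
    "downsample", "translate", "flip", "brightness", "contrast", "gibbs",
)

ARTIFACT_SUITE_KINDS = tuple(ARTIFACT_PRESETS)
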