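"""Synthetic head-phantom generator.

Produces everything the rest of the package consumes at desk scale:
skull-stripped head phantoms built from nested ellipsoidal compartments
(WM core, cortical GM shell, CSF envelope, ventricles, a brainstem stub) with
continuous tissue labels in [0, 3] and partial-volume ramps one voxel wide;
atrophy progressions (stepwise cortical thinning at a fixed head envelope);
smooth ground-truth velocity/deformation pairs for registration tests; and
VBM cohorts with covariates and an injected regional effect.

What the phantoms emulate is geometry and tissue contrast, not MR physics:
image artifacts come from the augmentation module.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from . import diffeo
from .config import GRID_PRESETS, GridSpec
from .tissue_seg import TissueLabelMap, decode_labels
from .volume import Volume


@dataclass
class PhantomSpec:
    grid: GridSpec = field(default_factory=lambda: GRID_PRESETS["desk_high"])
    head_radii: tuple = (52.0, 62.0, 55.0)      # outer CSF envelope (mm)
    wm_radii: tuple = (34.0, 42.0, 36.0)        # WM core (mm)
    gm_thickness: float = 8.0                   # cortical GM shell (mm)
    csf_min_thickness: float = 2.0
    ventricle_radii: tuple = (7.0, 14.0, 7.0)   # central CSF cavities (mm)
    ventricle_offset: tuple = (10.0, 0.0, 4.0)  # lateral +/- x pair (mm)
    brainstem_radii: tuple = (9.0, 9.0, 18.0)   # inferior WM stub (mm)
    # posterior cortical protrusion: breaks the rotational near-symmetry of a
    # plain ellipsoid head (as the occipital lobe does) while keeping the
    # label map mirror-symmetric about the midsagittal plane
    bulge_radii: tuple = (26.0, 30.0, 24.0)
    bulge_center_frac: tuple = (0.0, -0.72, 0.12)  # relative to head radii
    intensity_means: tuple = (0.0, 0.22, 0.55, 0.85)  # bg, CSF, GM, WM
    texture_amplitude: float = 0.03
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        gm_outer = tuple(r + self.gm_thickness for r in self.wm_radii)
        if self.gm_thickness <= 0:
            raise ValueError("gm_thickness must be positive")
        if any(g + self.csf_min_thickness > h
               for g, h in zip(gm_outer, self.head_radii)):
            raise ValueError("compartments are not nested: GM shell reaches "
                             "the head envelope")


def _world_coords(grid: GridSpec) -> np.ndarray:
    """Physical coordinates (mm, 3 x shape) centered on the grid."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(grid.shape, grid.spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def _soft_inside(coords, radii, center=(0.0, 0.0, 0.0), spacing_mm=1.0):
    """Soft ellipsoid indicator with a linear one-voxel partial-volume ramp."""
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        return np.zeros(coords.shape[1:], dtype=np.float64)
    rel = (coords - np.asarray(center, float)[:, None, None, None]) / radii[:, None, None, None]
    rho = np.sqrt((rel ** 2).sum(axis=0))
    # approximate signed distance (mm) to the surface
    dist = (rho - 1.0) * radii.min()
    return np.clip(0.5 - dist / spacing_mm, 0.0, 1.0)


def make_phantom(spec: PhantomSpec):
    """Build one phantom.

    Returns ``(Volume, TissueLabelMap, masks)`` where ``masks`` holds binary
    brain/ventricle/brainstem Volumes.  The label map is the exact ground
    truth; the intensity volume mixes class means through the decoded partial
    volumes plus smooth within-class texture.
    """
    grid = spec.grid
    coords = _world_coords(grid)
    h = float(min(grid.spacing))
    gm_outer = tuple(r + spec.gm_thickness for r in spec.wm_radii)

    env = _soft_inside(coords, spec.head_radii, spacing_mm=h)
    gm = _soft_inside(coords, gm_outer, spacing_mm=h)
    wm = _soft_inside(coords, spec.wm_radii, spacing_mm=h)

    if any(r > 0 for r in spec.bulge_radii):
        bc = tuple(f * r for f, r in zip(spec.bulge_center_frac, spec.head_radii))
        bulge_env = _soft_inside(coords, spec.bulge_radii, center=bc, spacing_mm=h)
        shrink = tuple(max(r - spec.csf_min_thickness, 1.0)
                       for r in spec.bulge_radii)
        bulge_gm = _soft_inside(coords, shrink, center=bc, spacing_mm=h)
        env = np.maximum(env, bulge_env)
        gm = np.maximum(gm, bulge_gm)

    stem = _soft_inside(coords, spec.brainstem_radii,
                        center=(0.0, 0.0, -spec.head_radii[2] * 0.55),
                        spacing_mm=h)
    stem = np.minimum(stem, env)
    gm = np.maximum(gm, stem)
    wm = np.maximum(wm, stem)

    vent = np.zeros_like(env)
    off = np.asarray(spec.ventricle_offset, float)
    for side in (+1.0, -1.0):
        c = (side * off[0], off[1], off[2])
        vent = np.maximum(vent, _soft_inside(coords, spec.ventricle_radii,
                                             center=c, spacing_mm=h))
    label = env + gm * (1.0 - vent) + wm * (1.0 - vent)
    label = np.clip(label, 0.0, 3.0).astype(np.float32)

    affine = grid.affine
    label_map = TissueLabelMap(Volume(label, affine, space_tag="template"))
    prob = decode_labels(label_map)
    means = np.asarray(spec.intensity_means, float)
    intensity = np.tensordot(means, prob, axes=(0, 0))

    rng = np.random.default_rng(spec.seed)
    if spec.texture_amplitude > 0:
        texture = gaussian_filter(rng.normal(0, 1, grid.shape), 2.0)
        texture /= max(np.abs(texture).max(), 1e-9)
        intensity = intensity + spec.texture_amplitude * texture * (label > 0.5)
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0, spec.noise_sigma, grid.shape)
    vol = Volume(np.clip(intensity, 0, None).astype(np.float32), affine,
                 space_tag="template")

    masks = {
        "brain": Volume((label > 0.5).astype(np.float32), affine, "template"),
        "ventricles": Volume((vent > 0.5).astype(np.float32), affine, "template"),
        "brainstem": Volume((stem > 0.5).astype(np.float32), affine, "template"),
    }
    return vol, label_map, masks


def atrophy_series(base: PhantomSpec, steps: int = 10,
                   max_reduction_mm: float = 1.0,
                   include_original: bool = False):
    """Global cortical-thinning progression.

    Step k reduces the GM thickness by k * max_reduction_mm / steps at a fixed
    head envelope and WM core, mirroring a graded neocortical atrophy
    protocol; with 20 base subjects, 10 steps and the originals included this
    yields 220 volumes.
    """
    if max_reduction_mm >= base.gm_thickness:
        raise ValueError("thickness reduction must stay below the GM thickness")
    out = []
    if include_original:
        out.append((0.0, make_phantom(base)))
    for k in range(1, steps + 1):
        red = k * max_reduction_mm / steps
        spec = replace(base, gm_thickness=base.gm_thickness - red)
        out.append((red, make_phantom(spec)))
    return out


def make_deformation_truth(grid: GridSpec | tuple, amplitude_vox: float = 1.5,
                           smoothness_vox: float = 3.0, seed: int = 0,
                           max_tries: int = 5):
    """Smooth random ground-truth deformation with positive Jacobian.

    The half-velocity pair is antisymmetric (v_bwd = -v_fwd); the forward and
    backward deformations are its scaling-and-squaring flows.  Regenerates
    with a new seed up to ``max_tries`` times if folding occurs.
    """
    shape = tuple(grid.shape) if isinstance(grid, GridSpec) else tuple(grid)
    vox_to_norm = np.asarray([2.0 / (n - 1) for n in shape],
                             np.float32)[:, None, None, None]
    for attempt in range(max_tries):
        rng = np.random.default_rng(seed + attempt)
        if amplitude_vox == 0:
            v = np.zeros((3,) + shape, np.float32)
        else:
            v = np.stack([gaussian_filter(rng.normal(0, 1, shape), smoothness_vox)
                          for _ in range(3)]).astype(np.float32)
            v *= amplitude_vox / max(np.abs(v).max(), 1e-9)
            v = v * vox_to_norm
        pair = diffeo.VelocityPair(v, -v)
        phi_f, phi_b = diffeo.full_deformations(pair)
        if diffeo.jacobian_determinant(phi_f).min() > 0:
            return pair, (phi_f, phi_b)
    raise RuntimeError(
        f"could not generate a fold-free deformation in {max_tries} tries "
        f"(amplitude {amplitude_vox} voxels)")


def make_cohort(n: int, effect_center=(0.0, 10.0, 10.0),
                effect_radius_mm: float = 12.0,
                effect_size: float = 0.15,
                covariate: str = "age",
                noise_sigma: float = 0.02,
                grid: GridSpec | None = None,
                seed: int = 0):
    """Synthetic VBM cohort: warped GM/WM maps with an injected effect.

    Each subject's GM map is the template GM plus ``effect_size`` per standard
    deviation of the covariate of interest inside a spherical region, plus
    spatially smooth noise.  Returns ``(CohortTable, effect_mask)``.
    """
    from .vbm_stats import CohortTable  # local import; vbm_stats is downstream

    if n < 10:
        raise ValueError("cohort needs at least 10 subjects")
    grid = grid or GRID_PRESETS["desk_reg"]
    spec = PhantomSpec(grid=grid, texture_amplitude=0.0, seed=seed)
    _, label_map, _ = make_phantom(spec)
    prob = decode_labels(label_map)
    template_gm, template_wm = prob[2], prob[3]

    coords = _world_coords(grid)
    d2 = ((coords - np.asarray(effect_center, float)[:, None, None, None]) ** 2).sum(axis=0)
    region = (d2 <= effect_radius_mm ** 2) & (template_gm > 0.05)

    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 70, n)
    sex = rng.integers(0, 2, n)
    group = rng.integers(0, 2, n)
    cov = {"age": age, "sex": sex, "group": group}[covariate]
    z = (cov - cov.mean()) / max(cov.std(), 1e-9)

    gm_maps = np.empty((n,) + tuple(grid.shape), np.float32)
    wm_maps = np.empty_like(gm_maps)
    for i in range(n):
        noise = gaussian_filter(rng.normal(0, 1, grid.shape), 1.5)
        noise *= noise_sigma / max(noise.std(), 1e-9)
        g = template_gm + effect_size * z[i] * region + noise
        w_noise = gaussian_filter(rng.normal(0, 1, grid.shape), 1.5)
        w_noise *= noise_sigma / max(w_noise.std(), 1e-9)
        gm_maps[i] = np.clip(g, 0, 1)
        wm_maps[i] = np.clip(template_wm + w_noise, 0, 1)

    import pandas as pd
    table = pd.DataFrame({"id": [f"sub-{i:03d}" for i in range(n)],
                          "age": age, "sex": sex, "group": group})
    cohort = CohortTable(table=table, maps={"gm": gm_maps, "wm": wm_maps},
                         grid=grid)
    return cohort, region
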