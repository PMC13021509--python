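"""End-to-end prediction pipeline and workflow utilities.

The prediction pipeline runs six steps in order: brain extraction (an
*interface* — the binary mask must be supplied by an external tool),
affine registration, tissue segmentation, tissue separation (probability
decoding plus GM masking), nonlinear registration and smoothing.  Every
intermediate is written as NIfTI with a JSON sidecar recording the step
order, a configuration hash and the seed, so reruns are byte-auditable.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diffeo, vbm_stats
from .affine_reg import AffineConfig, affine_register
from .config import GRID_PRESETS, SMOOTH_FWHM_MM, GridSpec
from .intensity import apply_brain_mask, minmax_log_scale
from .tissue_seg import SegModelBank, decode_labels
from .volume import Volume, resample_to_grid, write_nifti


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, artifacts: dict):
        super().__init__(f"pipeline failed at stage {stage!r}: {message}")
        self.stage = stage
        self.artifacts = artifacts


@dataclass
class PipelineModels:
    """Trained components plus template resources consumed by the pipeline."""

    seg_bank: SegModelBank
    reg_net: object                      # RegNet
    template: Volume                     # intensity template (high grid)
    template_mask: Volume
    template_gm: np.ndarray              # registration-grid template maps
    template_wm: np.ndarray
    gm_mask_resource: Volume | None = None


@dataclass
class PipelineConfig:
    high_grid: GridSpec = field(default_factory=lambda: GRID_PRESETS["desk_high"])
    reg_grid: GridSpec = field(default_factory=lambda: GRID_PRESETS["desk_reg"])
    fwhm_mm: float = SMOOTH_FWHM_MM
    modulate: bool = True
    affine: AffineConfig = field(default_factory=AffineConfig)
    tau: int = 7
    seed: int = 0

    def hash(self) -> str:
        def enc(o):
            if isinstance(o, (GridSpec, AffineConfig)):
                return {k: enc(v) for k, v in o.__dict__.items()}
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            return o
        blob = json.dumps(enc(self.__dict__), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(input_volume: Volume | None, brain_mask: Volume | None,
                 models: PipelineModels, config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Execute mask -> affine -> segment -> separate -> register -> smooth.

    Returns a dict of output Volumes (and written paths when ``out_dir`` is
    given).  Any stage failure raises :class:`PipelineError` naming the stage
    and the artifacts produced so far.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    artifacts: dict = {}
    sidecar = {"config_hash": config.hash(), "seed": config.seed, "steps": []}

    def emit(name: str, vol: Volume):
        artifacts[name] = vol
        sidecar["steps"].append({"step": name,
                                 "sha256": hashlib.sha256(
                                     np.ascontiguousarray(vol.data).tobytes()
                                 ).hexdigest()[:16]})
        if out_dir is not None:
            write_nifti(vol, out_dir / f"{name}.nii.gz")

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - reported with stage context
                raise PipelineError(name, str(e), artifacts) from e
        return deco

    if brain_mask is None:
        raise PipelineError(
            "brain_extraction",
            "no brain mask supplied; brain extraction is an external "
            "interface — provide the mask produced by your extraction tool",
            artifacts)

    @stage("brain_extraction")
    def masked():
        m = apply_brain_mask(input_volume, brain_mask)
        norm = minmax_log_scale(m, brain_mask)
        emit("masked", norm)
        return norm

    @stage("affine_registration")
    def affined():
        matrix, _ = affine_register(masked, models.template, brain_mask,
                                    models.template_mask, config.affine)
        vol = resample_to_grid(masked, config.high_grid, matrix,
                               interpolation="bspline")
        vol.data[vol.data < 0] = 0.0
        emit("affine", vol)
        artifacts["affine_matrix"] = matrix
        return vol

    @stage("tissue_segmentation")
    def label_map():
        lm = models.seg_bank.segment(affined)
        emit("label", lm.volume)
        return lm

    @stage("tissue_separation")
    def separated():
        prob = decode_labels(label_map)
        gm = Volume(prob[2], affined.affine, "template")
        wm = Volume(prob[3], affined.affine, "template")
        if models.gm_mask_resource is not None:
            gm = vbm_stats.gm_mask(gm, models.gm_mask_resource)
        emit("p1_gm", gm)
        emit("p2_wm", wm)
        return gm, wm

    @stage("nonlinear_registration")
    def registered():
        gm, wm = separated
        gm_r = resample_to_grid(gm, config.reg_grid).data
        wm_r = resample_to_grid(wm, config.reg_grid).data
        channels = np.stack([gm_r, wm_r, models.template_gm, models.template_wm])
        vpair = models.reg_net.predict(channels)
        phi_f, _ = diffeo.full_deformations(vpair, tau=config.tau)
        jdet = diffeo.jacobian_determinant(phi_f)
        aff = config.reg_grid.affine
        wgm = Volume(diffeo.warp(gm_r, phi_f), aff, "template")
        wwm = Volume(diffeo.warp(wm_r, phi_f), aff, "template")
        emit("wp1_gm", wgm)
        emit("wp2_wm", wwm)
        emit("jacobian", Volume(jdet, aff, "template"))
        return wgm, wwm, jdet

    @stage("smoothing")
    def smoothed():
        wgm, wwm, jdet = registered
        outs = []
        for name, vol in (("p1_gm", wgm), ("p2_wm", wwm)):
            if config.modulate:
                vol = vbm_stats.modulate(vol, jdet)
                name = "mw" + name
            else:
                name = "w" + name
            sm = vbm_stats.smooth_fwhm(vol, config.fwhm_mm)
            emit(f"s{int(config.fwhm_mm)}{name}", sm)
            outs.append(sm)
        return outs

    _ = smoothed
    if out_dir is not None:
        (out_dir / "provenance.json").write_text(json.dumps(sidecar, indent=2))
        artifacts["sidecar_path"] = out_dir / "provenance.json"
    artifacts["sidecar"] = sidecar
    return artifacts


def crossval_split(dataset_ids, k: int = 5, seed: int = 0) -> dict:
    """Grouped k-fold assignment: every scan of a dataset shares one fold.

    Returns ``{dataset_id: fold}`` with fold sizes balanced within one
    dataset.
    """
    unique = sorted(set(dataset_ids))
    if k > len(unique):
        raise ValueError(f"cannot split {len(unique)} datasets into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    return {unique[idx]: int(i % k) for i, idx in enumerate(order)}
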