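"""Segmentation and registration evaluation metrics.

Segmentation quality is reported as Dice (DSC), Jaccard (JSC) and a
probabilistic Dice (pDSC) that compares probability maps through their
voxel-wise minimum overlap; registration quality as the voxel-wise MSE to the
template plus the linear-elasticity energy of the deformation.  Score
distributions across scans are summarized by the median, 95th percentile,
maximum and minimum (metric distributions are typically skewed, so the median
is the central-tendency statistic of choice).
"""
from __future__ import annotations

import numpy as np

from .diffeo import DeformationField, ElasticityParams, linear_elasticity
from .tissue_seg import TissueLabelMap, decode_labels
from .volume import Volume


def _arr(x):
    return x.data if isinstance(x, Volume) else np.asarray(x)


def dice(a, b) -> float:
    """DSC = 2|a n b| / (|a| + |b|); two empty masks count as perfect (1)."""
    a, b = _arr(a) > 0.5, _arr(b) > 0.5
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def jaccard(a, b) -> float:
    a, b = _arr(a) > 0.5, _arr(b) > 0.5
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def probabilistic_dice(p, q) -> float:
    """pDSC = 2 sum min(p, q) / (sum p + sum q); equals DSC on binary inputs."""
    p, q = _arr(p), _arr(q)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.min() < -1e-6 or p.max() > 1 + 1e-6 or q.min() < -1e-6 or q.max() > 1 + 1e-6:
        raise ValueError("probability maps must lie in [0, 1]")
    denom = p.sum() + q.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.minimum(p, q).sum() / denom)


_CLASSES = ("csf", "gm", "wm")


def tissue_scores(pred: TissueLabelMap, ref: TissueLabelMap) -> dict:
    """Per-class and foreground DSC/pDSC/JSC on the 0-100 scale.

    Classes are binarized by argmax over the decoded probability channels
    (background included, ties toward the lower class index); the foreground
    score is the unweighted mean of CSF, GM and WM.
    """
    p, r = decode_labels(pred), decode_labels(ref)
    if p.shape != r.shape:
        raise ValueError("label maps must share a grid")
    hard_p, hard_r = np.argmax(p, axis=0), np.argmax(r, axis=0)
    out = {}
    for k, name in enumerate(_CLASSES, start=1):
        out[f"dsc_{name}"] = 100.0 * dice(hard_p == k, hard_r == k)
        out[f"jsc_{name}"] = 100.0 * jaccard(hard_p == k, hard_r == k)
        out[f"pdsc_{name}"] = 100.0 * probabilistic_dice(p[k], r[k])
    for m in ("dsc", "jsc", "pdsc"):
        out[f"{m}_foreground"] = float(
            np.mean([out[f"{m}_{name}"] for name in _CLASSES]))
    return out


def registration_scores(warped, template, phi: DeformationField,
                        params: ElasticityParams | None = None):
    """(MSE, LE): image dissimilarity plus deformation regularity."""
    w, t = _arr(warped), _arr(template)
    if w.shape != t.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {t.shape}")
    mse = float(np.mean((w.astype(np.float64) - t.astype(np.float64)) ** 2))
    le = linear_elasticity(phi, params or ElasticityParams())
    return mse, le


def summarize(scores) -> dict:
    """Median, 95th percentile, max and min of a score list."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("empty score list")
    return {"median": float(np.median(arr)),
            "p95": float(np.percentile(arr, 95)),
            "max": float(arr.max()),
            "min": float(arr.min())}
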