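"""Brain-mask application and intensity normalization.

Inputs are assumed skull-stripped (the mask comes from an external brain
extraction) and bias-corrected; this module only zeroes non-brain voxels and
rescales intensities.  The normalization is robust min-max scaling between the
0.5th and 99.5th percentile of the in-mask intensities, with a logarithmic
tail instead of an upper clip: scaled values s > 1 map to 1 + log10(s), so
extreme intensities (e.g. blood vessels) stay ordered instead of saturating.
"""
from __future__ import annotations

import numpy as np

from .volume import Volume


def apply_brain_mask(v: Volume, tissue_mask: Volume) -> Volume:
    """Zero every voxel outside the binary tissue mask."""
    if v.shape != tissue_mask.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {tissue_mask.shape}")
    out = v.data * (tissue_mask.data > 0)
    return v.copy(data=out.astype(np.float32))


def minmax_log_scale(v: Volume, mask: Volume,
                     lo_pct: float = 0.5, hi_pct: float = 99.5) -> Volume:
    """Percentile min-max scaling with a log10 tail above the upper anchor.

    With lo/hi the in-mask percentiles, s = (x - lo) / (hi - lo); the output is
    s clipped to 0 from below, and 1 + log10(s) for s > 1.  The map is
    continuous and monotone: both branches give 1 at the breakpoint.
    """
    if v.shape != mask.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {mask.shape}")
    inside = v.data[mask.data > 0]
    if inside.size <= 100:
        raise ValueError(f"mask selects only {inside.size} voxels (need > 100)")
    lo, hi = np.percentile(inside, [lo_pct, hi_pct])
    if hi <= lo:
        raise ValueError(f"degenerate percentiles: lo={lo} hi={hi}")
    s = (v.data.astype(np.float64) - lo) / (hi - lo)
    out = np.clip(s, 0.0, 1.0)
    tail = s > 1.0
    out[tail] = 1.0 + np.log10(s[tail])
    return v.copy(data=out.astype(np.float32))
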