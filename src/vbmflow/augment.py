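"""Training augmentations and the synthetic-artifact test protocol.

Twelve augmentation kinds are supported: bias field, motion, chi-distributed
noise, blurring, ghosting, spike artifacts, downsampling, translation,
flipping, brightness, contrast and Gibbs ringing.  The k-space kinds
(motion, ghosting, spike, Gibbs) corrupt the Fourier domain of the image, the
bias field is the exponential of inverse-transformed low-frequency Gaussian
noise, noise is chi-distributed (the Rician magnitude-image model at 2
degrees of freedom), and the spatial kinds (translation, flipping) use
nearest-neighbor resampling only.  Every stochastic kind is reproducible from
(kind, strength, seed), and strength 0 is the identity for every kind.

The seven-artifact test protocol applies noise, bias field, blur, ghosting,
motion, Gibbs ringing and spikes at a medium and a strong preset intensity to
each input: 14 corrupted volumes per original.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift, zoom as nd_zoom

from .config import ARTIFACT_PRESETS, ARTIFACT_SUITE_KINDS, AUGMENT_KINDS
from .volume import Volume

# Preset strengths for the five kinds outside the artifact protocol.
_EXTRA_PRESETS = {
    "downsample": {"medium": 0.5, "strong": 1.0},
    "translate": {"medium": 2.0, "strong": 5.0},
    "flip": {"medium": 1.0, "strong": 1.0},
    "brightness": {"medium": 0.1, "strong": 0.3},
    "contrast": {"medium": 0.1, "strong": 0.3},
}
PRESETS = {**ARTIFACT_PRESETS, **_EXTRA_PRESETS}

BIAS_CUTOFF_CYCLES = 4  # low-frequency box half-width in cycles per FOV


@dataclass(frozen=True)
class AugmentSpec:
    kind: str
    strength: float | str = "medium"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in AUGMENT_KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}")

    @property
    def numeric_strength(self) -> float:
        if isinstance(self.strength, str):
            return float(PRESETS[self.kind][self.strength])
        return float(self.strength)


def _bias_field(x, s, rng):
    shape = x.shape
    k = np.zeros(shape, dtype=np.complex128)
    c = BIAS_CUTOFF_CYCLES
    box = tuple(slice(0, min(2 * c + 1, n)) for n in shape)
    noise = rng.normal(0, 1, tuple(min(2 * c + 1, n) for n in shape))
    k[box] = noise
    k = np.roll(k, shift=[-c] * 3, axis=(0, 1, 2))  # center the low-pass box
    field = np.real(np.fft.ifftn(k))
    field /= max(field.std(), 1e-12)
    return x * np.exp(s * field)


def _chi_noise(x, s, rng, dof=2):
    sq = (x + s * rng.normal(0, 1, x.shape)) ** 2
    for _ in range(dof - 1):
        sq = sq + (s * rng.normal(0, 1, x.shape)) ** 2
    return np.sqrt(sq)


def _ghosting(x, s, rng, every=4):
    k = np.fft.fftn(x)
    axis = int(rng.integers(0, 3))
    sl = [slice(None)] * 3
    idx = np.arange(x.shape[axis])
    keep = (idx % every != 0) | (idx == 0)  # spare the DC line
    sl[axis] = ~keep
    k[tuple(sl)] *= (1.0 - s)
    return np.real(np.fft.ifftn(k))


def _spike(x, s, rng):
    k = np.fft.fftn(x)
    loc = tuple(int(rng.integers(n // 8, n // 3)) for n in x.shape)
    k[loc] += s * np.abs(k).max()
    return np.real(np.fft.ifftn(k))


def _gibbs(x, s, rng):
    k = np.fft.fftshift(np.fft.fftn(x))
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in x.shape], indexing="ij")
    rho = np.sqrt(sum(g ** 2 for g in grids))
    k[rho > (1.0 - 0.9 * s)] = 0.0
    return np.real(np.fft.ifftn(np.fft.ifftshift(k)))


def _motion(x, s, rng, n_moves=2):
    ks = [np.fft.fftn(x)]
    for _ in range(n_moves):
        delta = rng.uniform(-1, 1, 3) * s
        ks.append(np.fft.fftn(nd_shift(x, delta, order=1, mode="constant")))
    weights = np.array([0.7] + [0.3 / n_moves] * n_moves)
    k = sum(w * kk for w, kk in zip(weights, ks))
    return np.real(np.fft.ifftn(k))


def _downsample(x, s, rng):
    f = 1.0 + s
    small = nd_zoom(x, 1.0 / f, order=1)
    back = nd_zoom(small, np.array(x.shape) / np.array(small.shape), order=1)
    out = np.zeros_like(x)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(x.shape, back.shape))
    out[sl] = back[sl]
    return out


def _translate(x, s, rng):
    shifts = [int(v) for v in rng.integers(-int(round(s)), int(round(s)) + 1, 3)]
    out = np.zeros_like(x)
    src = tuple(slice(max(0, -d), x.shape[i] - max(0, d)) for i, d in enumerate(shifts))
    dst = tuple(slice(max(0, d), x.shape[i] - max(0, -d)) for i, d in enumerate(shifts))
    out[dst] = x[src]
    return out


def apply_augmentation(v: Volume, spec: AugmentSpec) -> Volume:
    """Apply one augmentation; deterministic given (kind, strength, seed)."""
    x = v.data.astype(np.float64)
    if not np.isfinite(x).all():
        raise ValueError("input volume contains non-finite values")
    s = spec.numeric_strength
    if s == 0:
        return v.copy()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, zlib.crc32(spec.kind.encode()))))
    if spec.kind == "bias_field":
        out = _bias_field(x, s, rng)
    elif spec.kind == "noise":
        out = _chi_noise(x, s, rng)
    elif spec.kind == "blur":
        out = gaussian_filter(x, s)
    elif spec.kind == "ghosting":
        out = _ghosting(x, s, rng)
    elif spec.kind == "spike":
        out = _spike(x, s, rng)
    elif spec.kind == "gibbs":
        out = _gibbs(x, s, rng)
    elif spec.kind == "motion":
        out = _motion(x, s, rng)
    elif spec.kind == "downsample":
        out = _downsample(x, s, rng)
    elif spec.kind == "translate":
        out = _translate(x, s, rng)
    elif spec.kind == "flip":
        out = np.flip(x, axis=0).copy()
    elif spec.kind == "brightness":
        out = x * (1.0 + s)
    elif spec.kind == "contrast":
        m = x.mean()
        out = (x - m) * (1.0 + s) + m
    else:  # pragma: no cover - guarded by AugmentSpec
        raise ValueError(spec.kind)
    return v.copy(data=out.astype(np.float32))


def artifact_test_suite(originals, seed: int = 0):
    """Seven artifacts x two intensities per original volume.

    Returns a list of ``(corrupted Volume, AugmentSpec)`` records (14 per
    original); medium and strong share the per-(original, kind) seed so the
    two tiers differ only in artifact strength.
    """
    originals = list(originals)
    if not originals:
        raise ValueError("no original volumes supplied")
    out = []
    for i, vol in enumerate(originals):
        for kind in ARTIFACT_SUITE_KINDS:
            sub_seed = int(np.random.SeedSequence((seed, i, zlib.crc32(kind.encode())))
                           .generate_state(1)[0] % (2 ** 31))
            for tier in ("medium", "strong"):
                spec = AugmentSpec(kind=kind, strength=tier, seed=sub_seed)
                out.append((apply_augmentation(vol, spec), spec))
    return out
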