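"""Stationary-velocity-field diffeomorphic registration machinery.

A deformation is the unit-time flow of a time-constant velocity field v,
computed by scaling and squaring: v is divided by 2^tau, converted to a small
deformation, and composed with itself tau times.  Symmetric (SyN-style)
registration represents the forward and backward maps as compositions of half
deformations generated from a pair of half velocity fields (v_fwd, v_bwd):

    phi      = SS(v_fwd) o SS(-v_bwd)      (image -> template)
    phi_inv  = SS(v_bwd) o SS(-v_fwd)      (template -> image)

All fields live on the registration grid in normalized [-1, 1] coordinates and
are stored as displacements (identity + displacement = coordinate map).  The
module exposes a plain-numpy API; internally everything runs on the autodiff
engine so the same code paths serve losses and their gradients.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import BETA_SYN, TAU
from .nn import Module, UNet3d, mse_loss
from .volume import Volume, normalized_grid


# -- data types -----------------------------------------------------------

@dataclass
class VelocityPair:
    """Half velocity fields (3, D, H, W) in normalized coordinate units."""

    v_fwd: np.ndarray
    v_bwd: np.ndarray

    def __post_init__(self):
        self.v_fwd = np.asarray(self.v_fwd, dtype=np.float32)
        self.v_bwd = np.asarray(self.v_bwd, dtype=np.float32)
        if self.v_fwd.shape != self.v_bwd.shape or self.v_fwd.shape[0] != 3:
            raise ValueError("velocity fields must share a (3, D, H, W) shape")
        if not (np.isfinite(self.v_fwd).all() and np.isfinite(self.v_bwd).all()):
            raise ValueError("velocity fields must be finite")

    @property
    def grid_shape(self):
        return self.v_fwd.shape[1:]


@dataclass
class DeformationField:
    """Dense coordinate map, stored as identity + displacement."""

    disp: np.ndarray

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=np.float32)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("displacement must have shape (3, D, H, W)")

    @property
    def grid_shape(self):
        return self.disp.shape[1:]

    @property
    def phi(self) -> np.ndarray:
        """Coordinate map in normalized coordinates."""
        return normalized_grid(self.grid_shape) + self.disp

    @classmethod
    def identity(cls, shape) -> "DeformationField":
        return cls(np.zeros((3,) + tuple(shape), dtype=np.float32))


@dataclass
class ElasticityParams:
    mu: float = 1.0
    lam: float = 1.0
    Lambda: float = 0.01

    def __post_init__(self):
        if self.mu < 0 or self.lam < 0 or self.Lambda < 0:
            raise ValueError("elasticity weights must be non-negative")


@dataclass
class SupervisedTarget:
    """Distilled reference for supervised registration training."""

    v_target: VelocityPair
    jdet_target: np.ndarray = field(default=None)


# -- tensor-level primitives ----------------------------------------------

def _id_grid(shape) -> np.ndarray:
    return normalized_grid(shape)


def _compose_disp(da: Tensor, db: Tensor) -> Tensor:
    """Displacement of a o b given displacements of a and b."""
    shape = db.data.shape[1:]
    grid_b = ad.as_tensor(_id_grid(shape)) + db
    return db + ad.grid_sample3d(da, grid_b, padding="border")


def _ss_disp(v: Tensor, tau: int) -> Tensor:
    u = v * float(2.0 ** -tau)
    for _ in range(tau):
        u = _compose_disp(u, u)
    return u


def _warp_t(img: Tensor, disp: Tensor) -> Tensor:
    grid = ad.as_tensor(_id_grid(disp.data.shape[1:])) + disp
    return ad.grid_sample3d(img, grid, padding="zeros")


def _axis_gradient(t: Tensor, axis: int, spacing: float) -> Tensor:
    """Central differences interior, one-sided at the faces, along a spatial axis."""
    nd = t.data.ndim
    n = t.data.shape[axis]

    def sl(a, b):
        s = [slice(None)] * nd
        s[axis] = slice(a, b)
        return tuple(s)

    if n < 2:
        raise ValueError("axis too short for differences")
    first = t[sl(1, 2)] - t[sl(0, 1)]
    last = t[sl(n - 1, n)] - t[sl(n - 2, n - 1)]
    mid = (t[sl(2, n)] - t[sl(0, n - 2)]) * 0.5
    return ad.concat([first, mid, last], axis=axis) * (1.0 / spacing)


def _disp_jacobian(disp: Tensor):
    """3x3 per-voxel Jacobian of the displacement wrt normalized coordinates."""
    shape = disp.data.shape[1:]
    spacings = [2.0 / (n - 1) if n > 1 else 1.0 for n in shape]
    return [[_axis_gradient(disp[i:i + 1], j + 1, spacings[j])[0]
             for j in range(3)] for i in range(3)]


def _jacdet_t(disp: Tensor) -> Tensor:
    """Jacobian determinant of the coordinate map (identity -> 1 everywhere)."""
    du = _disp_jacobian(disp)
    j = [[du[i][k] + (1.0 if i == k else 0.0) for k in range(3)] for i in range(3)]
    return (j[0][0] * (j[1][1] * j[2][2] - j[1][2] * j[2][1])
            - j[0][1] * (j[1][0] * j[2][2] - j[1][2] * j[2][0])
            + j[0][2] * (j[1][0] * j[2][1] - j[1][1] * j[2][0]))


def _elasticity_t(disp: Tensor, params: ElasticityParams) -> Tensor:
    """Mean linear-elasticity energy density mu*||eps||^2 + lam/2*tr(eps)^2."""
    du = _disp_jacobian(disp)
    frob = None
    tr = du[0][0] + du[1][1] + du[2][2]
    for i in range(3):
        for k in range(3):
            e = (du[i][k] + du[k][i]) * 0.5
            frob = e * e if frob is None else frob + e * e
    density = params.mu * frob + (params.lam / 2.0) * (tr * tr)
    return ad.tmean(density)


def _half_fields(vf: Tensor, vb: Tensor, tau: int):
    """Half deformations and the composed full forward/backward displacements."""
    half_f = _ss_disp(vf, tau)
    half_b = _ss_disp(vb, tau)
    inv_half_b = _ss_disp(-vb, tau)
    inv_half_f = _ss_disp(-vf, tau)
    full_f = _compose_disp(half_f, inv_half_b)
    full_b = _compose_disp(half_b, inv_half_f)
    return half_f, half_b, full_f, full_b


# -- public numpy API -----------------------------------------------------

def scaling_squaring(v: np.ndarray, tau: int = TAU) -> DeformationField:
    """Exponentiate a stationary velocity field into a deformation."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    v = np.asarray(v, dtype=np.float32)
    if not np.isfinite(v).all():
        raise ValueError("velocity field contains non-finite values")
    return DeformationField(_ss_disp(ad.as_tensor(v), tau).data)


def compose(a: DeformationField, b: DeformationField) -> DeformationField:
    """(a o b)(x) = a(b(x)) via trilinear sampling of a's map at b's coordinates."""
    if a.grid_shape != b.grid_shape:
        raise ValueError(f"grid mismatch: {a.grid_shape} vs {b.grid_shape}")
    return DeformationField(
        _compose_disp(ad.as_tensor(a.disp), ad.as_tensor(b.disp)).data)


def warp(img: Volume | np.ndarray, phi: DeformationField) -> Volume | np.ndarray:
    """Trilinearly resample an image at the deformed coordinates (zero fill)."""
    arr = img.data if isinstance(img, Volume) else np.asarray(img, np.float32)
    if arr.shape != phi.grid_shape:
        raise ValueError(f"grid mismatch: {arr.shape} vs {phi.grid_shape}")
    out = _warp_t(ad.as_tensor(arr[None]), ad.as_tensor(phi.disp)).data[0]
    if isinstance(img, Volume):
        return img.copy(data=out)
    return out


def jacobian_determinant(phi: DeformationField) -> np.ndarray:
    return _jacdet_t(ad.as_tensor(phi.disp)).data


def linear_elasticity(phi: DeformationField, params: ElasticityParams) -> float:
    """Linear-elasticity energy of the displacement, per unit domain volume."""
    return float(_elasticity_t(ad.as_tensor(phi.disp), params).item())


def full_deformations(vpair: VelocityPair, tau: int = TAU):
    """Forward and backward full deformations of a half-velocity pair."""
    _, _, full_f, full_b = _half_fields(
        ad.as_tensor(vpair.v_fwd), ad.as_tensor(vpair.v_bwd), tau)
    return DeformationField(full_f.data), DeformationField(full_b.data)


def syn_loss(I, J, vpair: VelocityPair, params: ElasticityParams,
             tau: int = TAU) -> float:
    I = I.data if isinstance(I, Volume) else np.asarray(I, np.float32)
    J = J.data if isinstance(J, Volume) else np.asarray(J, np.float32)
    t, _ = _syn_loss_t(ad.as_tensor(I[None]), ad.as_tensor(J[None]),
                       ad.as_tensor(vpair.v_fwd), ad.as_tensor(vpair.v_bwd),
                       params, tau)
    return float(t.item())


def _syn_loss_t(I: Tensor, J: Tensor, vf: Tensor, vb: Tensor,
                params: ElasticityParams, tau: int = TAU):
    if I.data.shape != J.data.shape or I.data.shape[1:] != vf.data.shape[1:]:
        raise ValueError("grid mismatch between images and velocity fields")
    half_f, half_b, full_f, full_b = _half_fields(vf, vb, tau)
    d1 = mse_loss(_warp_t(I, full_f), J)
    d2 = mse_loss(I, _warp_t(J, full_b))
    d3 = mse_loss(_warp_t(I, half_f), _warp_t(J, half_b))
    reg = _elasticity_t(full_f, params)
    total = d1 + d2 + d3 + params.Lambda * reg
    return total, {"forward": d1, "backward": d2, "half": d3, "elasticity": reg}


def supervised_velocity_loss(pred: VelocityPair, target: VelocityPair) -> float:
    if pred.grid_shape != target.grid_shape:
        raise ValueError("grid mismatch between predicted and target velocities")
    t = _velocity_loss_t(ad.as_tensor(pred.v_fwd), ad.as_tensor(pred.v_bwd),
                         target)
    return float(t.item())


def _velocity_loss_t(vf: Tensor, vb: Tensor, target: VelocityPair) -> Tensor:
    return mse_loss(vf, target.v_fwd) + mse_loss(vb, target.v_bwd)


def supervised_full_loss(pred: VelocityPair, target: SupervisedTarget,
                         I, J, params: ElasticityParams,
                         beta: float = BETA_SYN, tau: int = TAU):
    """L_v + Jacobian-determinant MSE + beta * SyN loss; parts returned for logs."""
    I = I.data if isinstance(I, Volume) else np.asarray(I, np.float32)
    J = J.data if isinstance(J, Volume) else np.asarray(J, np.float32)
    total, parts = _supervised_full_loss_t(
        ad.as_tensor(pred.v_fwd), ad.as_tensor(pred.v_bwd), target,
        ad.as_tensor(I[None]), ad.as_tensor(J[None]), params, beta, tau)
    return float(total.item()), {k: float(v.item()) for k, v in parts.items()}


def _supervised_full_loss_t(vf: Tensor, vb: Tensor, target: SupervisedTarget,
                            I: Tensor, J: Tensor, params: ElasticityParams,
                            beta: float = BETA_SYN, tau: int = TAU):
    lv = _velocity_loss_t(vf, vb, target.v_target)
    _, _, full_f, _ = _half_fields(vf, vb, tau)
    jd = _jacdet_t(full_f)
    lj = mse_loss(jd, np.asarray(target.jdet_target, np.float32))
    lsyn, _ = _syn_loss_t(I, J, vf, vb, params, tau)
    total = lv + lj + beta * lsyn
    return total, {"L_v": lv, "L_jdet": lj, "L_syn": lsyn}


# -- velocity distillation ------------------------------------------------

class DistillationDivergence(RuntimeError):
    pass


def velocity_from_deformation(phi_target: DeformationField,
                              phi_target_inv: DeformationField,
                              iters: int = 500, lr: float = 0.1,
                              tol: float = 1e-4, tau: int = TAU):
    """Recover the half-velocity pair that reproduces given forward/backward maps.

    Gradient descent with backtracking on the mean squared coordinate residual
    (measured in voxel units) between the reconstructed and target maps.
    Returns ``(VelocityPair, info)`` with the final residual in ``info``.
    """
    if phi_target.grid_shape != phi_target_inv.grid_shape:
        raise ValueError("target deformations must share a grid")
    shape = phi_target.grid_shape
    vox_scale = np.asarray([(n - 1) / 2.0 for n in shape],
                           np.float32)[:, None, None, None]
    tf = ad.as_tensor(phi_target.disp * vox_scale)
    tb = ad.as_tensor(phi_target_inv.disp * vox_scale)

    # Initialize at half the target displacement: for small fields the full
    # map is exp(v_fwd) o exp(v_bwd)^-1 ~ id + v_fwd + v_bwd, so half the
    # displacement is a first-order solution and descent only corrects the
    # curvature terms.
    vf = ad.Parameter(phi_target.disp * 0.5)
    vb = ad.Parameter(phi_target_inv.disp * 0.5)

    def residual():
        _, _, full_f, full_b = _half_fields(vf, vb, tau)
        rf = full_f * ad.as_tensor(vox_scale) - tf
        rb = full_b * ad.as_tensor(vox_scale) - tb
        return ad.tmean(rf * rf) + ad.tmean(rb * rb)

    loss = residual()
    history = [loss.item()]
    for _ in range(iters):
        if history[-1] < tol:
            break
        vf.grad = vb.grad = None
        loss.backward()
        gf, gb = vf.grad.copy(), vb.grad.copy()
        old_f, old_b, old = vf.data.copy(), vb.data.copy(), history[-1]
        step, first_try = lr, True
        while True:
            vf.data = old_f - step * gf
            vb.data = old_b - step * gb
            loss = residual()
            if loss.item() < old:
                history.append(loss.item())
                # grow the trusted step while full steps keep descending
                if first_try:
                    lr = min(step * 1.3, 10.0)
                else:
                    lr = step
                break
            first_try = False
            step *= 0.5
            if step < 1e-10:
                raise DistillationDivergence(
                    f"no descent direction found; residual {old:.3e} after "
                    f"{len(history) - 1} iterations")
    pair = VelocityPair(vf.data, vb.data)
    info = {"residual_vox2": history[-1], "iterations": len(history) - 1,
            "history": history}
    return pair, info


# -- registration network -------------------------------------------------

@dataclass
class RegNetConfig:
    in_channels: int = 4
    depth: int = 2
    base_channels: int = 4
    tau: int = TAU
    antisymmetric: bool = False
    seed: int = 0


class RegNet(Module):
    """UNet predicting half velocity fields, tanh-bounded to (-1, 1)."""

    def __init__(self, config: RegNetConfig):
        out_ch = 3 if config.antisymmetric else 6
        self.unet = UNet3d(config.in_channels, out_ch, depth=config.depth,
                           base_channels=config.base_channels,
                           activation="leaky_relu", seed=config.seed)
        self.antisymmetric = config.antisymmetric

    def forward(self, x: Tensor):
        out = ad.tanh(self.unet(x))
        if self.antisymmetric:
            return out, -out
        return out[0:3], out[3:6]

    def predict(self, channels: np.ndarray) -> VelocityPair:
        vf, vb = self.forward(ad.as_tensor(channels))
        return VelocityPair(vf.data, vb.data)


def build_regnet(config: RegNetConfig | None = None) -> RegNet:
    return RegNet(config or RegNetConfig())


def save_regnet(net: RegNet, path) -> None:
    import json
    from pathlib import Path

    cfg = {"antisymmetric": net.antisymmetric,
           "in_channels": net.unet.enc[0].c1.weight.data.shape[1],
           "depth": net.unet.depth,
           "base_channels": net.unet.enc[0].c1.weight.data.shape[0]}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(json.dumps(cfg).encode(), np.uint8),
             **net.state_dict())


def load_regnet(path) -> "RegNet":
    import json

    with np.load(path) as z:
        cfg = json.loads(bytes(z["__meta__"]).decode())
        net = RegNet(RegNetConfig(in_channels=cfg["in_channels"],
                                  depth=cfg["depth"],
                                  base_channels=cfg["base_channels"],
                                  antisymmetric=cfg["antisymmetric"]))
        net.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return net


@dataclass
class RegTrainConfig:
    epochs: int = 50
    max_lr: float = 1e-3
    loss: str = "lv"          # "lv", "lv_jdet" or "full"
    beta: float = BETA_SYN
    elasticity: ElasticityParams = field(default_factory=ElasticityParams)
    net: RegNetConfig = field(default_factory=RegNetConfig)


def train_registration(pairs, config: RegTrainConfig | None = None,
                       seed: int = 0):
    """Supervised training against distilled velocity (and Jacobian) targets.

    ``pairs`` is a list of ``(channels, SupervisedTarget)`` where ``channels``
    stacks moving GM/WM and template GM/WM maps.  No augmentation is applied.
    Returns ``(RegNet, history)``.
    """
    if not pairs:
        raise ValueError("empty training set")
    config = config or RegTrainConfig()
    net_cfg = RegNetConfig(**{**config.net.__dict__, "seed": seed})
    net = RegNet(net_cfg)
    opt = ad.Adam(net.parameters())
    total_steps = config.epochs * len(pairs)
    history = {"loss": [], "lr": []}
    step = 0
    for _ in range(config.epochs):
        for channels, target in pairs:
            x = ad.as_tensor(np.asarray(channels, np.float32))
            vf, vb = net(x)
            if config.loss == "lv":
                loss = _velocity_loss_t(vf, vb, target.v_target)
            elif config.loss == "lv_jdet":
                loss = _velocity_loss_t(vf, vb, target.v_target)
                _, _, full_f, _ = _half_fields(vf, vb, net_cfg.tau)
                loss = loss + mse_loss(_jacdet_t(full_f),
                                       np.asarray(target.jdet_target, np.float32))
            elif config.loss == "full":
                loss, _ = _supervised_full_loss_t(
                    vf, vb, target, x[0:2], x[2:4], config.elasticity,
                    config.beta, net_cfg.tau)
            else:
                raise ValueError(f"unknown loss {config.loss!r}")
            opt.zero_grad()
            loss.backward()
            lr = ad.one_cycle_lr(step, total_steps, config.max_lr)
            opt.step(lr=lr)
            history["loss"].append(float(loss.item()))
            history["lr"].append(lr)
            step += 1
    return net, history
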