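"""Losses, training loops, and the assembled denoise->map cascade.

The denoiser is trained with a plain MSE against noise-free images.  The
mapper is trained with the *model-consistency* (physics) loss: images are
re-synthesized from the predicted (S0, R2*) maps through the mono-exponential
decay model and compared with the noise-free references, so gradients flow
through the exponential and the maps themselves are never directly
supervised.  With the denoiser in front (frozen), the mapper sees denoised
inputs — the full cascade; without it, the mapper alone is a single-stage
baseline trained directly on noisy inputs.

Intensities are divided by ``input_scale`` before the networks; the R2*
output channel is multiplied by ``r2_output_scale`` (s^-1 per unit) so both
heads live near unit magnitude for the optimizer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..phantom import PatchSet
from ..signal_model import (
    EchoTimes,
    MultiEchoSeries,
    ParameterMaps,
    synthesize_decay,
)
from .core import Adam, DTYPE, recalibrate_batchnorm
from .networks import (
    DenoiserConfig,
    MapperConfig,
    SeparableDenoiser,
    UNetMapper,
    build_denoiser,
    build_mapper,
)

__all__ = [
    "TrainConfig",
    "CascadeModel",
    "loss_denoising",
    "loss_mapping",
    "lr_at_epoch",
    "train_denoiser",
    "train_mapper",
    "train_cascade",
    "predict_cascade",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Adam schedule and normalization constants.

    lr starts at 0.01 and is halved every ``lr_halving_period`` (a dozen)
    epochs; mini-batch size 128.  ``input_scale`` is the corpus S0 scale
    (216.6 by default, matching the simulator), ``r2_output_scale`` converts
    the mapper's R2* channel to s^-1.
    """

    lr0: float = 0.01
    lr_halving_period: int = 12
    batch_size: int = 128
    epochs: int = 40
    seed: int = 0
    input_scale: float = 216.6
    r2_output_scale: float = 1000.0
    #: clip the global gradient norm before each Adam step (None disables);
    #: guards the physics loss against rare exploding batches early on
    clip_grad_norm: float | None = 1.0

    def __post_init__(self):
        if self.lr0 <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")


def _clip_gradients(params, max_norm: float | None) -> None:
    if max_norm is None:
        return
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm:
        scale = np.float32(max_norm / total)
        for p in params:
            p.grad *= scale


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a 1-based epoch index: lr0 / 2^((epoch-1) // period)."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return cfg.lr0 * 0.5 ** ((epoch - 1) // cfg.lr_halving_period)


def loss_denoising(predicted: np.ndarray, clean: np.ndarray) -> float:
    """Mean squared error between denoised output and noise-free reference.

    The squared l2 norm normalized by element count, so the value is
    batch-size invariant.
    """
    predicted = np.asarray(predicted, dtype=float)
    clean = np.asarray(clean, dtype=float)
    if predicted.shape != clean.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((predicted - clean) ** 2))


def loss_mapping(maps_hat: ParameterMaps, clean: MultiEchoSeries, te: EchoTimes) -> float:
    """Model-consistency loss: synthesize images from the estimated maps and
    measure the (mean-normalized) squared error against the noise-free
    reference.  By construction equals
    ``loss_denoising(synthesize_decay(maps_hat, te), clean)``."""
    return loss_denoising(synthesize_decay(maps_hat, te).data, clean.data)


def _physics_loss_grad(out: np.ndarray, clean_norm: np.ndarray, te_s: np.ndarray,
                       r2_scale: float):
    """Differentiable mapping loss on network outputs.

    ``out`` is (N, 2, H, W): channel 0 the normalized S0 (positive), channel
    1 the R2* head (times ``r2_scale`` gives s^-1).  Returns (loss, dL/dout).
    """
    s0n = out[:, 0]
    r2 = out[:, 1] * np.float32(r2_scale)
    raw = -te_s[None, :, None, None] * r2[:, None]
    expo = np.clip(raw, -60.0, 20.0)
    inside = (raw > -60.0) & (raw < 20.0)  # no gradient through the clip
    decay = np.exp(expo)
    synth = s0n[:, None] * decay
    diff = synth - clean_norm
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    g = (2.0 / diff.size) * diff
    dout = np.empty_like(out)
    dout[:, 0] = (g * decay).sum(axis=1)
    dr2 = (g * synth * np.where(inside, -te_s[None, :, None, None], 0.0)).sum(axis=1)
    dout[:, 1] = dr2 * np.float32(r2_scale)
    return loss, dout


def _to_nchw(patches: np.ndarray, scale: float) -> np.ndarray:
    """(n, H, W, E) float -> normalized (n, E, H, W) float32."""
    return np.ascontiguousarray(
        patches.transpose(0, 3, 1, 2), dtype=DTYPE
    ) / np.float32(scale)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_denoiser(
    patches: PatchSet,
    cfg: TrainConfig = TrainConfig(),
    net_cfg: DenoiserConfig | None = None,
) -> tuple[SeparableDenoiser, list[float]]:
    """Train the denoising network on aligned noisy/clean patch pairs."""
    if len(patches) == 0:
        raise ValueError("empty patch corpus")
    x = _to_nchw(patches.noisy, cfg.input_scale)
    t = _to_nchw(patches.clean, cfg.input_scale)
    net_cfg = net_cfg or DenoiserConfig(n_echoes=x.shape[1], seed=cfg.seed)
    net = build_denoiser(net_cfg)
    net.set_training(True)
    opt = Adam(net.params(), lr=cfg.lr0)
    rng = np.random.default_rng(cfg.seed)
    history = []
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_at_epoch(epoch, cfg)
        losses = []
        for idx in _epoch_batches(len(x), cfg.batch_size, rng):
            pred = net.forward(x[idx])
            diff = pred - t[idx]
            losses.append(float(np.mean(diff.astype(np.float64) ** 2)))
            opt.zero_grad()
            net.backward((2.0 / diff.size) * diff)
            _clip_gradients(opt.params, cfg.clip_grad_norm)
            opt.step()
        history.append(float(np.mean(losses)))
    recalibrate_batchnorm(net, x)
    net.set_training(False)
    return net, history


def _denoise_corpus(denoiser: SeparableDenoiser, x: np.ndarray,
                    chunk: int = 64) -> np.ndarray:
    denoiser.set_training(False)
    out = np.empty_like(x)
    for start in range(0, len(x), chunk):
        out[start : start + chunk] = denoiser.forward(x[start : start + chunk])
    return out


def train_mapper(
    patches: PatchSet,
    denoiser: SeparableDenoiser | None = None,
    cfg: TrainConfig = TrainConfig(),
    net_cfg: MapperConfig | None = None,
    te: EchoTimes | None = None,
) -> tuple[UNetMapper, list[float]]:
    """Train the mapping network with the model-consistency loss.

    With ``denoiser`` supplied it is frozen (its weights are never updated)
    and the mapper is trained on its outputs — the cascade configuration.
    With ``denoiser=None`` the mapper trains directly on the noisy patches
    (single-stage baseline).  ``te`` defaults to the 12-echo clinical
    schedule and must match the patch echo count.
    """
    if len(patches) == 0:
        raise ValueError("empty patch corpus")
    from ..phantom import default_te_schedule

    te = te or default_te_schedule()
    x = _to_nchw(patches.noisy, cfg.input_scale)
    if x.shape[1] != len(te):
        raise ValueError("echo count of patches does not match TE schedule")
    if denoiser is not None:
        x = _denoise_corpus(denoiser, x)
    t = _to_nchw(patches.clean, cfg.input_scale)
    te_s = te.te_s.astype(DTYPE)
    net_cfg = net_cfg or MapperConfig(in_channels=x.shape[1], seed=cfg.seed)
    net = build_mapper(net_cfg)
    net.set_training(True)
    opt = Adam(net.params(), lr=cfg.lr0)
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_at_epoch(epoch, cfg)
        losses = []
        for idx in _epoch_batches(len(x), cfg.batch_size, rng):
            out = net.forward(x[idx])
            loss, dout = _physics_loss_grad(out, t[idx], te_s, cfg.r2_output_scale)
            losses.append(loss)
            opt.zero_grad()
            net.backward(dout)
            _clip_gradients(opt.params, cfg.clip_grad_norm)
            opt.step()
        history.append(float(np.mean(losses)))
    recalibrate_batchnorm(net, x)
    net.set_training(False)
    return net, history


@dataclass
class CascadeModel:
    """Trained denoiser (optional) + mapper with their normalization."""

    mapper: UNetMapper
    denoiser: SeparableDenoiser | None
    te: EchoTimes
    input_scale: float
    r2_output_scale: float


def train_cascade(
    patches: PatchSet,
    cfg: TrainConfig = TrainConfig(),
    denoiser_cfg: DenoiserConfig | None = None,
    mapper_cfg: MapperConfig | None = None,
    te: EchoTimes | None = None,
    with_denoiser: bool = True,
) -> tuple[CascadeModel, dict]:
    """Train the two stages in sequence and assemble the cascade."""
    from ..phantom import default_te_schedule

    te = te or default_te_schedule()
    history: dict = {}
    denoiser = None
    if with_denoiser:
        denoiser, history["denoiser"] = train_denoiser(patches, cfg, denoiser_cfg)
    mapper, history["mapper"] = train_mapper(patches, denoiser, cfg, mapper_cfg, te)
    return CascadeModel(mapper, denoiser, te, cfg.input_scale, cfg.r2_output_scale), history


def predict_cascade(model: CascadeModel, noisy: MultiEchoSeries) -> ParameterMaps:
    """Run normalization -> denoiser -> mapper -> denormalization.

    Spatial dims that are not multiples of 2^depth are reflect-padded up and
    cropped back.  Output S0 is in signal units, R2* in s^-1 (clamped >= 0).
    """
    if noisy.n_echoes != model.mapper.cfg.in_channels:
        raise ValueError(
            f"series has {noisy.n_echoes} echoes but the model was trained "
            f"with {model.mapper.cfg.in_channels}"
        )
    if not np.allclose(noisy.te.te_ms, model.te.te_ms):
        raise ValueError("echo-time schedule differs from the training schedule")
    h, w = noisy.shape[:2]
    m = 2 ** model.mapper.cfg.depth
    ph, pw = (-h) % m, (-w) % m
    x = noisy.data.transpose(2, 0, 1)[None].astype(DTYPE) / np.float32(model.input_scale)
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    if model.denoiser is not None:
        model.denoiser.set_training(False)
        x = model.denoiser.forward(x)
    model.mapper.set_training(False)
    out = model.mapper.forward(x)[0, :, :h, :w]
    s0 = out[0].astype(float) * model.input_scale
    r2 = np.clip(out[1].astype(float) * model.r2_output_scale, 0.0, None)
    return ParameterMaps(np.maximum(s0, 0.0), r2)


def save_checkpoint(model: CascadeModel, path) -> None:
    """Serialize configs, normalization constants, TE schedule and weights."""
    from .networks import get_state

    meta = {
        "mapper_cfg": asdict(model.mapper.cfg),
        "denoiser_cfg": asdict(model.denoiser.cfg) if model.denoiser else None,
        "te_ms": model.te.te_ms.tolist(),
        "input_scale": model.input_scale,
        "r2_output_scale": model.r2_output_scale,
    }
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, a in enumerate(get_state(model.mapper)):
        arrays[f"m{i}"] = a
    if model.denoiser is not None:
        for i, a in enumerate(get_state(model.denoiser)):
            arrays[f"d{i}"] = a
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> CascadeModel:
    from .networks import set_state

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        mapper = build_mapper(MapperConfig(**meta["mapper_cfg"]))
        m_keys = sorted(
            (k for k in z.files if k.startswith("m") and k != "__meta__"),
            key=lambda k: int(k[1:]),
        )
        set_state(mapper, [z[k] for k in m_keys])
        denoiser = None
        if meta["denoiser_cfg"] is not None:
            denoiser = build_denoiser(DenoiserConfig(**meta["denoiser_cfg"]))
            d_keys = sorted(
                (k for k in z.files if k.startswith("d")), key=lambda k: int(k[1:])
            )
            set_state(denoiser, [z[k] for k in d_keys])
    mapper.set_training(False)
    if denoiser is not None:
        denoiser.set_training(False)
    return CascadeModel(
        mapper,
        denoiser,
        EchoTimes(np.array(meta["te_ms"])),
        meta["input_scale"],
        meta["r2_output_scale"],
    )
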