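"""Mono-exponential decay physics and Rician noise for magnitude MRI.

The measured signal of a multi-gradient-echo (mGRE) acquisition decays as

    S(TE) = S0 * exp(-TE * R2*)

with the echo time ``TE`` in seconds and the effective transverse relaxation
rate ``R2*`` in s^-1.  Magnitude reconstruction of complex Gaussian data turns
the noise Rician: the observed value is ``sqrt((S + n1)^2 + n2^2)`` with
``n1, n2 ~ N(0, sigma_g^2)``.  This module holds the container types shared by
the whole package, the forward signal model, Rician sampling and moments, and
the background-ROI noise/SNR estimators.

Echo times are *stored* in milliseconds everywhere (the clinical convention);
decay computations convert to seconds internally so that R2* is natively in
s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "EchoTimes",
    "MultiEchoSeries",
    "ParameterMaps",
    "NoiseSpec",
    "RAYLEIGH_MEAN_FACTOR",
    "BACKGROUND_FACTOR",
    "synthesize_decay",
    "add_rician_noise",
    "rician_first_moment",
    "rician_second_moment",
    "estimate_sigma_background",
    "compute_snr",
]

#: E[magnitude] = sigma * sqrt(pi/2) for zero underlying signal (Rayleigh).
RAYLEIGH_MEAN_FACTOR = float(np.sqrt(np.pi / 2.0))

#: Inverse Rayleigh-mean factor sqrt(2/pi) = 0.7979..., conventionally rounded
#: to 0.80 when estimating sigma from a background ROI.
BACKGROUND_FACTOR = 0.80


@dataclass(frozen=True)
class EchoTimes:
    """Ordered echo-time vector in milliseconds."""

    te_ms: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if te.ndim != 1 or te.size < 2:
            raise ValueError("need a 1-D vector of at least 2 echo times")
        if not np.all(np.isfinite(te)) or np.any(te <= 0):
            raise ValueError("echo times must be finite and positive")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        te.setflags(write=False)
        object.__setattr__(self, "te_ms", te)

    @property
    def te_s(self) -> np.ndarray:
        """Echo times in seconds (for TE * R2* products)."""
        return self.te_ms * 1e-3

    def __len__(self) -> int:
        return int(self.te_ms.size)


@dataclass
class MultiEchoSeries:
    """Magnitude image stack, shape (height, width, n_echoes), values >= 0."""

    data: np.ndarray
    te: EchoTimes

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("series data must be rank-3 (H, W, n_echoes)")
        if data.shape[2] != len(self.te):
            raise ValueError(
                f"echo count mismatch: data has {data.shape[2]} echoes, "
                f"te has {len(self.te)}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("series contains non-finite values")
        if np.any(data < 0):
            raise ValueError("magnitude data must be non-negative")
        self.data = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]


@dataclass
class ParameterMaps:
    """Paired S0 (signal units) and R2* (s^-1) maps of equal spatial shape."""

    s0: np.ndarray
    r2star: np.ndarray

    def __post_init__(self) -> None:
        s0 = np.asarray(self.s0, dtype=float)
        r2 = np.asarray(self.r2star, dtype=float)
        if s0.ndim != 2 or r2.ndim != 2:
            raise ValueError("parameter maps must be rank-2")
        if s0.shape != r2.shape:
            raise ValueError(
                f"shape mismatch between s0 {s0.shape} and r2star {r2.shape}"
            )
        if not (np.all(np.isfinite(s0)) and np.all(np.isfinite(r2))):
            raise ValueError("parameter maps contain non-finite values")
        if np.any(s0 < 0) or np.any(r2 < 0):
            raise ValueError("parameter maps must be non-negative")
        self.s0 = s0
        self.r2star = r2

    @property
    def shape(self) -> tuple[int, int]:
        return self.s0.shape


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level: sigma of each Gaussian quadrature channel + seed."""

    sigma_g: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_g) or self.sigma_g < 0:
            raise ValueError("sigma_g must be finite and >= 0")


def synthesize_decay(maps: ParameterMaps, te: EchoTimes) -> MultiEchoSeries:
    """Forward mono-exponential model: voxel (x, y, i) = S0 * exp(-TE_i * R2*).

    TE is converted from ms to s so the exponent TE * R2* is dimensionless.
    """
    decay = np.exp(-te.te_s[None, None, :] * maps.r2star[:, :, None])
    return MultiEchoSeries(maps.s0[:, :, None] * decay, te)


def add_rician_noise(series: MultiEchoSeries, noise: NoiseSpec) -> MultiEchoSeries:
    """Corrupt a magnitude series with stationary Rician noise.

    Each voxel value S becomes sqrt((S + n1)^2 + n2^2) with n1, n2 independent
    N(0, sigma_g^2) draws; realizations are independent across voxels and
    echoes.  Deterministic for a given ``noise.seed``; sigma_g = 0 returns the
    input unchanged.
    """
    if noise.sigma_g == 0:
        return MultiEchoSeries(series.data.copy(), series.te)
    rng = np.random.default_rng(noise.seed)
    n = rng.normal(0.0, noise.sigma_g, size=(2,) + series.data.shape)
    noisy = np.hypot(series.data + n[0], n[1])
    return MultiEchoSeries(noisy, series.te)


def rician_first_moment(s, sigma):
    """Expected magnitude E[sqrt((s+n1)^2 + n2^2)] under Rician noise.

    Evaluates sigma * sqrt(pi/2) * L_{1/2}(-s^2 / (2 sigma^2)) where L_{1/2}
    is the Laguerre function

        L_{1/2}(-a) = exp(-a/2) [(1 + a) I0(a/2) + a I1(a/2)],  a = s^2/(2 sigma^2).

    Exponentially scaled Bessel functions (``scipy.special.ive``) keep the
    product finite at arbitrarily high SNR, so one branch covers s/sigma from
    0 (the Rayleigh limit sigma*sqrt(pi/2)) to far beyond 100, where the value
    approaches sqrt(s^2 + sigma^2).  Accepts scalars or arrays; sigma = 0
    returns s exactly.
    """
    s = np.asarray(s, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(s < 0) or np.any(sigma < 0):
        raise ValueError("s and sigma must be non-negative")
    s, sigma = np.broadcast_arrays(s, sigma)
    out = np.empty(s.shape, dtype=float)
    zero = sigma == 0
    if np.any(zero):
        out[zero] = s[zero]
    nz = ~zero
    if np.any(nz):
        a = 0.5 * (s[nz] / sigma[nz]) ** 2  # noncentrality / 2
        half = 0.5 * a
        lag = (1.0 + a) * special.ive(0, half) + a * special.ive(1, half)
        out[nz] = sigma[nz] * RAYLEIGH_MEAN_FACTOR * lag
    if out.ndim == 0:
        return float(out)
    return out


def rician_second_moment(s, sigma):
    """E[M^2] = s^2 + 2 sigma^2 (exact for Rician magnitudes)."""
    s = np.asarray(s, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(s < 0) or np.any(sigma < 0):
        raise ValueError("s and sigma must be non-negative")
    out = s**2 + 2.0 * sigma**2
    if out.ndim == 0:
        return float(out)
    return out


def estimate_sigma_background(
    series: MultiEchoSeries,
    background_mask: np.ndarray,
    factor: float = BACKGROUND_FACTOR,
) -> float:
    """Estimate sigma_g from a signal-free background ROI.

    Background magnitudes are Rayleigh distributed with mean sigma*sqrt(pi/2),
    so sigma = mean * sqrt(2/pi) = mean * 0.7979...  The conventional rounded
    factor 0.80 is the default; pass ``factor=np.sqrt(2/np.pi)`` for the exact
    inversion.  The mean is taken over the masked voxels of *all* echoes.
    """
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != series.data.shape[:2]:
        raise ValueError("mask shape must match the spatial shape of the series")
    if not mask.any():
        raise ValueError("background mask is empty")
    return factor * float(series.data[mask, :].mean())


def compute_snr(
    series: MultiEchoSeries, parenchyma_mask: np.ndarray, sigma: float
) -> float:
    """SNR = mean first-echo intensity over a parenchyma ROI / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mask = np.asarray(parenchyma_mask, dtype=bool)
    if mask.shape != series.data.shape[:2]:
        raise ValueError("mask shape must match the spatial shape of the series")
    if not mask.any():
        raise ValueError("parenchyma mask is empty")
    return float(series.data[mask, 0].mean()) / float(sigma)
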