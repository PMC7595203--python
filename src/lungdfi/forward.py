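"""Talbot-Lau phase-stepping forward model.

A three-grating Talbot-Lau interferometer produces, at every detector pixel, a
sinusoidal intensity modulation as one grating is stepped laterally over ``M``
positions (the *stepping curve*),

    I_k = a0 * (1 + V * cos(2*pi*k/M + phi)),   k = 0 .. M-1.

A sample in the beam attenuates the mean (``a0``), reduces the fringe
visibility ``V`` through small-angle scattering, and shifts the fringe phase
``phi`` through refraction.  This module simulates sample and reference
(flat-field, sample removed) stepping scans from ground-truth phantom maps,
optionally with Poisson counting noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["SystemConfig", "SteppingStack", "stepping_curve", "simulate_scan"]


@dataclass(frozen=True)
class SystemConfig:
    """Interferometer and acquisition settings.

    Grating periods/heights, tube settings and exposure are carried as scanner
    metadata; the quantities that enter the simulation are ``n_steps``,
    ``effective_pixel_um``, ``reference_visibility``, ``photons_per_pixel``,
    the reference-phase mode and the noise model.
    """

    # grating metadata: source, phase, analyser
    grating_periods_um: tuple[float, float, float] = (10.0, 3.24, 4.28)
    grating_heights_um: tuple[float, float, float] = (35.0, 4.0, 45.0)
    n_steps: int = 4
    exposure_per_step_s: float = 5.0
    tube_voltage_kvp: float = 35.0
    tube_power_w: float = 20.0
    detector_pixel_um: float = 50.0
    effective_pixel_um: float = 29.0
    reference_visibility: float = 0.30
    photons_per_pixel: float = 1.0e4
    reference_phase_mode: str = "flat"  # "flat" | "linear_carrier"
    carrier_cycles_per_fov: float = 3.0
    noise: str = "none"  # "none" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 3:
            raise ValueError(
                "n_steps must be >= 3: the stepping curve has three unknowns "
                "(mean, amplitude, phase) per pixel"
            )
        if not (0.0 < self.reference_visibility <= 1.0):
            raise ValueError("reference_visibility must lie in (0, 1]")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.effective_pixel_um > self.detector_pixel_um:
            raise ValueError("effective pixel cannot exceed detector pixel")
        if self.reference_phase_mode not in ("flat", "linear_carrier"):
            raise ValueError(f"unknown reference_phase_mode {self.reference_phase_mode!r}")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SteppingStack:
    """One phase-stepping scan: ``M`` count frames plus provenance."""

    frames: np.ndarray  # (M, H, W)
    role: str  # "sample" | "reference"
    config_hash: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (M, H, W) array")
        if self.role not in ("sample", "reference"):
            raise ValueError(f"role must be 'sample' or 'reference', got {self.role!r}")
        if np.any(self.frames < 0):
            raise ValueError("negative counts in stepping stack")

    @property
    def n_steps(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def stepping_curve(a0, V, phi, M: int) -> np.ndarray:
    """Model intensities of an M-point stepping scan.

    Parameters broadcast; scalars give the per-pixel curve
    ``a0 * (1 + V cos(2 pi k / M + phi))`` for k = 0..M-1.
    """
    a0 = np.asarray(a0, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if np.any(a0 < 0):
        raise ValueError("mean counts a0 must be non-negative")
    if np.any(V < 0) or np.any(V > 1):
        raise ValueError("visibility must lie in [0, 1]")
    if M < 3:
        raise ValueError("need at least 3 stepping positions")
    theta = 2.0 * np.pi * np.arange(M) / M
    nd = max(np.ndim(a0), np.ndim(V), np.ndim(phi))
    theta = theta.reshape((M,) + (1,) * nd)
    out = a0 * (1.0 + V * np.cos(theta + phi))
    # clamp numerical dust at V == 1 nulls
    return np.clip(out, 0.0, None)


def _reference_phase(config: SystemConfig, shape: tuple[int, int]) -> np.ndarray:
    if config.reference_phase_mode == "flat":
        return np.zeros(shape)
    # linear fringe carrier along the stepping (x) direction
    x = np.arange(shape[1])
    carrier = 2.0 * np.pi * config.carrier_cycles_per_fov * x / shape[1]
    return np.broadcast_to(carrier, shape).copy()


def simulate_scan(phantom, config: SystemConfig, *, shape=None, rng=None) -> SteppingStack:
    """Simulate one stepping scan.

    ``phantom=None`` produces the reference (flat-field) scan: unit
    transmission, zero extinction and zero phase shift on top of the
    configured reference-phase pattern.  Otherwise, per pixel,

        a0  = photons_per_pixel * transmission
        V   = reference_visibility * exp(-extinction)
        phi = reference phase + phantom phase map.

    With ``noise='poisson'`` every model intensity is replaced by a seeded
    Poisson draw (pass ``rng`` to control the stream explicitly).
    """
    if phantom is None:
        if shape is None:
            raise ValueError("shape is required for a reference scan")
        T = np.ones(shape)
        eps = np.zeros(shape)
        dphi = np.zeros(shape)
        role = "reference"
    else:
        T = np.asarray(phantom.transmission_map, dtype=np.float64)
        eps = np.asarray(phantom.extinction_map, dtype=np.float64)
        dphi = np.asarray(phantom.phase_map, dtype=np.float64)
        shape = T.shape
        role = "sample"
        if np.any(T <= 0) or np.any(T > 1):
            raise ValueError("transmission map must lie in (0, 1]")
        if np.any(eps < 0):
            raise ValueError("extinction map must be non-negative")

    a0 = config.photons_per_pixel * T
    V = config.reference_visibility * np.exp(-eps)
    phi = _reference_phase(config, shape) + dphi
    frames = stepping_curve(a0, V, phi, config.n_steps)

    if config.noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        frames = rng.poisson(frames).astype(np.float64)

    return SteppingStack(frames=frames, role=role, config_hash=config.config_hash)
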