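"""Phase-stepping retrieval: stepping stacks -> absorption / dark-field / phase.

Per pixel the M stepping samples are reduced to the curve parameters
(mean ``a0``, first-harmonic amplitude ``a1``, fringe phase ``phi``) by the
M-point discrete Fourier analysis, which for a uniform step grid is the exact
least-squares fit of ``a0 + a1 cos(theta_k + phi)``.  Sample and reference
fits combine into the three modalities:

    absorption = -ln(a0_s / a0_r)                (Beer-Lambert line integral)
    dark-field = -ln((a1_s/a0_s) / (a1_r/a0_r))  (visibility-reduction log)
    phase      = wrap(phi_s - phi_r)             in (-pi, pi]

Both log conventions are signed and unclipped; healthy aerated lung gives a
dark-field signal well above 1, airless tissue close to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import SteppingStack

__all__ = ["ModalityImages", "fit_stepping", "retrieve", "wrap_phase"]


@dataclass
class ModalityImages:
    """Co-registered contrast images from one exposure series.

    All three images come from the same stepping scan, so a pixel-by-pixel
    comparison across modalities is meaningful by construction.
    ``quality_mask`` marks pixels where the retrieval was well-posed; the
    signals are NaN elsewhere.
    """

    absorption: np.ndarray
    darkfield: np.ndarray
    phase: np.ndarray
    quality_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.absorption.shape, self.darkfield.shape, self.phase.shape, self.quality_mask.shape}
        if len(shapes) != 1:
            raise ValueError("modality images must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorption.shape


def fit_stepping(intensities: np.ndarray):
    """Fit (a0, a1, phi) to stepping samples along axis 0.

    ``a0`` is the sample mean; the complex first harmonic
    ``c = (2/M) sum_k I_k exp(-i 2 pi k / M)`` gives ``a1 = |c|`` and
    ``phi = arg(c)``.  Noiseless pure first-harmonic curves are recovered
    exactly.  Zero-amplitude curves return ``phi = 0`` by convention.

    Accepts a 1-D curve (returns scalars) or an ``(M, ...)`` stack
    (returns arrays).
    """
    I = np.asarray(intensities, dtype=np.float64)
    M = I.shape[0]
    if M < 3:
        raise ValueError("need at least 3 stepping samples")
    if not np.all(np.isfinite(I)):
        raise ValueError("non-finite intensities in stepping curve")
    theta = 2.0 * np.pi * np.arange(M) / M
    theta = theta.reshape((M,) + (1,) * (I.ndim - 1))
    a0 = I.mean(axis=0)
    c = (2.0 / M) * np.sum(I * np.exp(-1j * theta), axis=0)
    a1 = np.abs(c)
    # snap numerically-flat curves (|c| at round-off level) to the convention
    tiny = 1e-12 * np.maximum(a0, 1.0)
    flat = a1 <= tiny
    a1 = np.where(flat, 0.0, a1)
    phi = np.where(flat, 0.0, np.angle(c))
    if I.ndim == 1:
        return float(a0), float(a1), float(phi)
    return a0, a1, phi


def wrap_phase(delta):
    """Principal value of a phase difference, wrapped into (-pi, pi]."""
    delta = np.asarray(delta, dtype=np.float64)
    wrapped = np.mod(delta + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def retrieve(sample: SteppingStack, reference: SteppingStack) -> ModalityImages:
    """Compute the three contrast modalities from a sample/reference scan pair.

    Pixels where the fit is ill-posed (non-positive mean counts in either
    scan, or vanishing modulation amplitude) are excluded via
    ``quality_mask`` rather than raising.
    """
    if sample.frames.shape != reference.frames.shape:
        raise ValueError("sample and reference stacks must share shape and step count")
    if sample.config_hash != reference.config_hash:
        raise ValueError("sample and reference stacks come from different configurations")

    a0s, a1s, phis = fit_stepping(sample.frames)
    a0r, a1r, phir = fit_stepping(reference.frames)

    quality = (a0s > 0) & (a0r > 0) & (a1r > 0) & (a1s > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        absorption = -np.log(a0s / a0r)
        darkfield = -np.log((a1s / a0s) / (a1r / a0r))
    phase = wrap_phase(phis - phir)

    absorption = np.where(quality, absorption, np.nan)
    darkfield = np.where(quality, darkfield, np.nan)
    phase = np.where(quality, phase, np.nan)
    return ModalityImages(absorption=absorption, darkfield=darkfield, phase=phase, quality_mask=quality)
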