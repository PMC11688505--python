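"""Transmission and differential-phase retrieval from stepping scans.

The per-pixel stepping curve ``I(s) = a + b*cos(2*pi*s/n + phi)`` is fitted
in closed form from its first discrete Fourier coefficient — the exact
least-squares solution for a single harmonic sampled equidistantly.  The
transmission is the ratio of fitted means, ``T = a_s / a_r``, and the
differential phase is the wrapped phase difference ``phi = phi_s - phi_r``.

The patchwise variant (PPR) pools each pixel's neighborhood into one joint
fit, trading spatial resolution against fit variance.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.ndimage import uniform_filter

from .acquisition import SteppingScan

__all__ = [
    "SteppingFit",
    "SinogramPair",
    "fit_stepping_curve",
    "retrieve",
    "retrieve_patchwise",
    "wrap_phase",
]

# amplitude below this fraction of the mean -> phase undefined, masked
AMPLITUDE_FLOOR = 1e-12


@dataclass
class SteppingFit:
    """Closed-form sinusoid fit of one stepping curve."""

    mean: float
    amplitude: float
    phase: float
    phase_defined: bool = True


@dataclass
class SinogramPair:
    """Retrieved sinograms: transmission and differential phase on a shared
    angle grid, plus a validity mask (False where the fit was degenerate)."""

    transmission: np.ndarray
    dphase: np.ndarray
    angles: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transmission = np.asarray(self.transmission, dtype=np.float64)
        self.dphase = np.asarray(self.dphase, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.transmission.shape != self.dphase.shape:
            raise ValueError("transmission and dphase shapes differ")
        if self.angles.ndim != 1 or self.angles.size != self.transmission.shape[0]:
            raise ValueError("angles must be 1D matching the first axis")
        if self.angles.size > 1 and np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def n_angles(self) -> int:
        return self.angles.size


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Map phase to (-pi, pi]; ties at -pi map to +pi."""
    wrapped = np.mod(-np.asarray(phi) + np.pi, 2 * np.pi)
    return np.pi - wrapped


def _dft_fit(counts: np.ndarray, n_steps: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised first-harmonic fit along the last axis.

    Returns (mean, amplitude, phase) arrays of counts.shape[:-1].
    """
    counts = np.asarray(counts, dtype=np.float64)
    s = np.arange(n_steps)
    basis = np.exp(-2j * np.pi * s / n_steps)
    mean = counts.mean(axis=-1)
    coeff = (counts * basis).sum(axis=-1) * (2.0 / n_steps)
    amplitude = np.abs(coeff)
    phase = np.angle(coeff)  # in (-pi, pi]
    return mean, amplitude, phase


def fit_stepping_curve(counts: np.ndarray, n_steps: int | None = None) -> SteppingFit:
    """Fit ``a + b*cos(2*pi*s/n + phi)`` to one equidistant step series.

    The discrete Fourier coefficients give the exact least-squares fit; an
    amplitude below ``AMPLITUDE_FLOOR * mean`` leaves the phase undefined
    (reported as 0 with ``phase_defined=False``).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1D step series")
    if n_steps is None:
        n_steps = counts.size
    if counts.size != n_steps:
        raise ValueError(f"series length {counts.size} != n_steps {n_steps}")
    if n_steps < 4:
        raise ValueError("n_steps must be >= 4")
    if not np.all(np.isfinite(counts)) or np.any(counts < 0):
        raise ValueError("counts must be finite and non-negative")

    mean, amplitude, phase = _dft_fit(counts, n_steps)
    defined = bool(amplitude > AMPLITUDE_FLOOR * max(mean, AMPLITUDE_FLOOR))
    return SteppingFit(
        mean=float(mean),
        amplitude=float(amplitude),
        phase=float(phase) if defined else 0.0,
        phase_defined=defined,
    )


def _retrieve_arrays(
    sample: np.ndarray,
    reference: np.ndarray,
    n_steps: int,
    ref_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared core: sample [angle, step, ...pixels], reference [step, ...pixels].

    ``ref_scale`` is the reference scan's exposure factor relative to the
    sample scan; the fitted reference mean is divided by it so T = 1 for an
    empty beam.
    """
    a_s, b_s, p_s = _dft_fit(np.moveaxis(sample, 1, -1), n_steps)
    a_r, b_r, p_r = _dft_fit(np.moveaxis(reference, 0, -1), n_steps)
    a_r = a_r / ref_scale
    b_r = b_r / ref_scale

    bad_ref = a_r <= 0
    if np.any(bad_ref):
        warnings.warn(
            f"{int(bad_ref.sum())} reference pixels have zero mean; masked",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        transmission = np.where(bad_ref, np.nan, a_s / np.where(bad_ref, 1.0, a_r))
    dphase = wrap_phase(p_s - p_r)

    # degenerate amplitude -> phase carries no information
    floor_s = AMPLITUDE_FLOOR * np.maximum(a_s, AMPLITUDE_FLOOR)
    floor_r = AMPLITUDE_FLOOR * np.maximum(a_r, AMPLITUDE_FLOOR)
    undefined = (b_s <= floor_s) | (b_r <= floor_r)
    dphase = np.where(undefined, 0.0, dphase)
    mask = ~(bad_ref | undefined)
    return transmission, dphase, mask


def retrieve(scan: SteppingScan) -> SinogramPair:
    """Pixel-wise retrieval of transmission and differential phase.

    The reference stepping curve is fitted once per pixel and reused across
    all projection angles.
    """
    geometry = scan.geometry
    transmission, dphase, mask = _retrieve_arrays(
        scan.sample, scan.reference, geometry.n_steps,
        ref_scale=geometry.reference_exposure_factor,
    )
    return SinogramPair(
        transmission=transmission,
        dphase=dphase,
        angles=geometry.angles,
        mask=mask,
    )


def retrieve_patchwise(scan: SteppingScan, radius: int) -> SinogramPair:
    """Patchwise phase retrieval: each pixel's fit pools the step series of
    the (2*radius+1)^2 neighborhood at the same angle (square window,
    zero-padded at borders).  Summing the neighborhood series and fitting
    once is the exact joint least-squares solution, since all pooled pixels
    share (a, b, phi) in the model.  ``radius=0`` reproduces :func:`retrieve`.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n_cols = scan.sample.shape[-1]
    if 2 * radius + 1 > n_cols:
        raise ValueError("patch radius exceeds half the detector width")
    if radius == 0:
        return retrieve(scan)

    size = 2 * radius + 1
    # pool over spatial axes only (sum = uniform_filter * window area)
    if scan.sample.ndim == 3:  # [angle, step, col]
        pooled_sample = uniform_filter(scan.sample, size=(1, 1, size), mode="constant")
        pooled_ref = uniform_filter(scan.reference, size=(1, size), mode="constant")
    else:  # [angle, step, row, col]
        pooled_sample = uniform_filter(
            scan.sample, size=(1, 1, size, size), mode="constant"
        )
        pooled_ref = uniform_filter(scan.reference, size=(1, size, size), mode="constant")

    transmission, dphase, mask = _retrieve_arrays(
        pooled_sample, pooled_ref, scan.geometry.n_steps,
        ref_scale=scan.geometry.reference_exposure_factor,
    )
    return SinogramPair(
        transmission=transmission,
        dphase=dphase,
        angles=scan.geometry.angles,
        mask=mask,
    )
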