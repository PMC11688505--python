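"""Reference-based image quality assessment.

Four metrics, each comparing a distorted image ``x`` to a reference ``y``:

* RMSE — root-mean-square voxel error.
* PSNR — ``20*log10(||y||_inf / RMSE)`` in dB; the peak is the supremum
  norm of the *reference* (images are float; no dtype maximum is assumed).
  PSNR is reference-anchored and therefore not symmetric.
* SSIM — canonical local-statistics structural similarity (Gaussian
  window, stabilisers ``C1=(0.01*L)^2``, ``C2=(0.03*L)^2`` with ``L`` the
  data range), mean over all positions.
* EPRa / EPRr — edge-preservation accuracy and robustness from Canny edge
  maps computed with one shared parameter set: with reference edge set R
  and distorted edge set D, ``EPRa = |R∩D|/|R|`` (edges retained) and
  ``EPRr = |R∩D|/|D|`` (detected edges that are true).

Slice stacks are aggregated as mean +/- standard deviation over slices
(population convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import canny

from .recon import Tomogram

__all__ = [
    "CannyParams",
    "IQAReport",
    "rmse",
    "psnr",
    "ssim",
    "edge_preservation",
    "epr_from_edge_maps",
    "assess_stack",
]


@dataclass
class CannyParams:
    """Edge-detector parameters, applied identically to both images.

    Thresholds are fractions of the reference image's maximum gradient
    magnitude, so both images see the same absolute hysteresis levels.
    """

    gaussian_sigma: float = 1.4
    low_threshold: float = 0.1
    high_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold):
            raise ValueError("need 0 < low_threshold < high_threshold")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")


def _as_array(img) -> np.ndarray:
    if isinstance(img, Tomogram):
        img = img.data
    return np.asarray(img, dtype=np.float64)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def rmse(x, y) -> float:
    """Root-mean-square error between image and reference."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def psnr(x, y) -> float:
    """Peak signal-to-noise ratio in dB, peak = sup norm of the reference.

    Returns ``inf`` for identical images; rejects an all-zero reference.
    """
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    peak = float(np.max(np.abs(y)))
    if peak == 0.0:
        raise ValueError("all-zero reference: PSNR peak undefined")
    err = rmse(x, y)
    if err == 0.0:
        return float("inf")
    return float(20.0 * np.log10(peak / err))


def ssim(
    x,
    y,
    window_sigma: float = 1.5,
    data_range: float | None = None,
) -> float:
    """Mean structural similarity with a Gaussian sliding window.

    ``data_range`` defaults to the reference's peak-to-peak range.
    """
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    if data_range is None:
        data_range = float(np.ptp(y))
    if data_range <= 0:
        raise ValueError("data_range must be > 0")

    def smooth(a):
        return ndi.gaussian_filter(a, window_sigma, mode="reflect", truncate=3.5)

    mu_x, mu_y = smooth(x), smooth(y)
    var_x = smooth(x * x) - mu_x**2
    var_y = smooth(y * y) - mu_y**2
    cov = smooth(x * y) - mu_x * mu_y

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def edge_map(img: np.ndarray, p: CannyParams, threshold_scale: float) -> np.ndarray:
    """Canny edge map with thresholds ``p.low/high * threshold_scale``."""
    return canny(
        img,
        sigma=p.gaussian_sigma,
        low_threshold=p.low_threshold * threshold_scale,
        high_threshold=p.high_threshold * threshold_scale,
        use_quantiles=False,
    )


def _max_gradient(img: np.ndarray, sigma: float) -> float:
    sm = ndi.gaussian_filter(img, sigma, mode="nearest")
    return float(np.hypot(ndi.sobel(sm, axis=0), ndi.sobel(sm, axis=1)).max())


def epr_from_edge_maps(r: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Set arithmetic on two binary edge maps: EPRa = |R&D|/|R|,
    EPRr = |R&D|/|D|.

    An empty reference set is an error; an empty distorted set yields
    ``EPRr = 1`` by convention (no false structures), logged.
    """
    r = np.asarray(r, dtype=bool)
    d = np.asarray(d, dtype=bool)
    _check_shapes(r, d)
    n_r = int(r.sum())
    n_d = int(d.sum())
    if n_r == 0:
        raise ValueError("reference image has no detected edges; EPRa undefined")
    n_both = int((r & d).sum())
    epra = n_both / n_r
    if n_d == 0:
        warnings.warn("distorted image has no edges; EPRr = 1 by convention",
                      stacklevel=2)
        return epra, 1.0
    return epra, n_both / n_d


def edge_preservation(x, y, p: CannyParams | None = None) -> tuple[float, float]:
    """(EPRa, EPRr) from Canny edge maps with shared parameters."""
    x, y = _as_array(x), _as_array(y)
    _check_shapes(x, y)
    if p is None:
        p = CannyParams()

    scale = _max_gradient(y, p.gaussian_sigma)
    return epr_from_edge_maps(edge_map(y, p, scale), edge_map(x, p, scale))


@dataclass
class IQAReport:
    """Per-slice metrics and their mean +/- (population) std over slices."""

    per_slice: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_slice.to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        """Read a per-slice table back with value-preserving float parsing."""
        return pd.read_csv(path, float_precision="round_trip")

    @staticmethod
    def metrics() -> tuple[str, ...]:
        return ("psnr", "ssim", "epra", "eprr")


def assess_stack(
    x,
    y,
    canny_params: CannyParams | None = None,
    window_sigma: float = 1.5,
    data_range: float | None = None,
) -> IQAReport:
    """Evaluate all four metrics slice by slice and aggregate.

    2D inputs are treated as single-slice stacks (std reported as 0).
    """
    xd, yd = _as_array(x), _as_array(y)
    _check_shapes(xd, yd)
    if isinstance(x, Tomogram) and isinstance(y, Tomogram):
        if x.signal_type != y.signal_type:
            raise ValueError("signal_type mismatch between stack and reference")
    if xd.ndim == 2:
        xd, yd = xd[None], yd[None]
    if xd.shape[0] < 2:
        warnings.warn("fewer than 2 slices: std reported as 0", stacklevel=2)

    rows = []
    for i in range(xd.shape[0]):
        epra, eprr = edge_preservation(xd[i], yd[i], canny_params)
        rows.append(
            {
                "slice": i,
                "psnr": psnr(xd[i], yd[i]),
                "ssim": ssim(xd[i], yd[i], window_sigma, data_range),
                "epra": epra,
                "eprr": eprr,
            }
        )
    per_slice = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "metric": list(IQAReport.metrics()),
            "mean": [per_slice[m].mean() for m in IQAReport.metrics()],
            # population standard deviation over slices
            "std": [per_slice[m].std(ddof=0) for m in IQAReport.metrics()],
        }
    )
    return IQAReport(per_slice=per_slice, summary=summary)
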