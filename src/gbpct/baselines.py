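"""Reference denoisers: Gaussian blur and adapter seams for external tools.

The blur is the classical smoothing-filter baseline; BM3D and statistical
iterative reconstruction are third-party tools in this pipeline's
comparisons and are reached through :func:`run_external` only when their
backends are installed — the core package carries no heavy dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi

from .recon import Tomogram

__all__ = [
    "DenoiserSpec",
    "gaussian_blur",
    "estimate_background_sigma",
    "run_external",
]

_KNOWN = {"gaussian", "bm3d_external", "sir_external", "none"}


@dataclass
class DenoiserSpec:
    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _KNOWN:
            raise ValueError(f"unknown denoiser {self.name!r}; known: {sorted(_KNOWN)}")
        required = {"gaussian": {"sigma"}, "bm3d_external": {"sigma"}}.get(self.name, set())
        missing = required - self.params.keys()
        if missing:
            raise ValueError(f"{self.name} requires params {sorted(missing)}")


def _slicewise(data: np.ndarray, fn) -> np.ndarray:
    if data.ndim == 2:
        return fn(data)
    return np.stack([fn(s) for s in data])


def gaussian_blur(tomo: Tomogram, sigma: float) -> Tomogram:
    """Isotropic Gaussian filtering per axial slice (reflective borders);
    sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        data = tomo.data.copy()
    else:
        data = _slicewise(tomo.data, lambda s: ndi.gaussian_filter(s, sigma, mode="reflect"))
    return Tomogram(
        data=data,
        signal_type=tomo.signal_type,
        provenance={**tomo.provenance, "denoiser": "gaussian", "sigma": sigma},
    )


def estimate_background_sigma(tomo: Tomogram, roi: tuple[int, int, int, int]) -> float:
    """Sample standard deviation over a background ROI (row0, col0, row1, col1).

    Mirrors the manual procedure used to feed an external BM3D: pick a
    region containing only background, take its standard deviation.
    """
    r0, c0, r1, c1 = roi
    data = tomo.data if tomo.data.ndim == 2 else tomo.data[0]
    n_rows, n_cols = data.shape
    if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
        raise ValueError(f"ROI {roi} out of bounds for shape {data.shape}")
    patch = data[r0:r1, c0:c1]
    if patch.size < 16:
        raise ValueError("ROI area must be >= 16 pixels")
    return float(patch.std(ddof=1))


def run_external(tomo: Tomogram, spec: DenoiserSpec) -> Tomogram:
    """Apply a denoiser by name, slice-wise.

    ``none`` is the identity; ``gaussian`` dispatches to
    :func:`gaussian_blur`; ``bm3d_external`` requires the optional ``bm3d``
    package; ``sir_external`` has no open implementation wired in and
    always raises with guidance.
    """
    if spec.name == "none":
        return Tomogram(data=tomo.data.copy(), signal_type=tomo.signal_type,
                        provenance={**tomo.provenance, "denoiser": "none"})
    if spec.name == "gaussian":
        return gaussian_blur(tomo, spec.params["sigma"])
    if spec.name == "bm3d_external":
        try:
            import bm3d  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "denoiser 'bm3d_external' needs the optional 'bm3d' package "
                "(pip install bm3d); estimate sigma with "
                "estimate_background_sigma and pass it as params['sigma']"
            ) from exc
        sigma = spec.params["sigma"]
        data = _slicewise(tomo.data, lambda s: bm3d.bm3d(s, sigma_psd=sigma))
        prov = {**tomo.provenance, "denoiser": "bm3d",
                "backend_version": getattr(bm3d, "__version__", "unknown"),
                "sigma": sigma}
        return Tomogram(data=data, signal_type=tomo.signal_type, provenance=prov)
    raise RuntimeError(
        "denoiser 'sir_external' is an adapter seam only: statistical "
        "iterative reconstruction backends are proprietary; plug one in by "
        "wrapping it behind this interface"
    )
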