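"""Parallel-beam forward projection (discrete Radon transform).

Conventions shared with :mod:`gbpct.recon`:

* pixel-centre coordinates with the origin at the grid centre,
  ``x = col - (n-1)/2``, ``y = row - (n-1)/2``;
* projection angle ``theta`` measured from the column (x) axis, so at
  ``theta = 0`` the projection sums the image over rows;
* the detector has one sample per image column, coordinate
  ``s = x cos(theta) + y sin(theta)``.

The integral is evaluated ray-driven: samples along each ray at spacing
``step`` pixels, bilinear interpolation, zero outside the grid.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["forward_project", "projection_matrix", "dphase_forward"]


def forward_project(
    image: np.ndarray,
    angles: np.ndarray,
    step: float = 0.25,
) -> np.ndarray:
    """Line integrals of ``image`` along parallel rays.

    Parameters
    ----------
    image : square 2D array.
    angles : projection angles in radians, measured from the column axis.
    step : sampling interval along each ray, in pixels.

    Returns
    -------
    sinogram : array [n_angles, n_columns], line integral per detector bin.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square 2D, got shape {image.shape}")
    n = image.shape[0]
    c = (n - 1) / 2.0

    s_axis = np.arange(n, dtype=np.float64) - c
    half_diag = n / np.sqrt(2.0) + 1.0
    t_axis = np.arange(-half_diag, half_diag + step, step)

    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    sino = np.empty((angles.size, n), dtype=np.float64)
    for i, th in enumerate(angles):
        ux, uy = np.cos(th), np.sin(th)   # detector axis
        vx, vy = -np.sin(th), np.cos(th)  # ray direction
        x = s_axis[:, None] * ux + t_axis[None, :] * vx + c
        y = s_axis[:, None] * uy + t_axis[None, :] * vy + c
        vals = map_coordinates(image, [y.ravel(), x.ravel()], order=1,
                               mode="constant", cval=0.0)
        sino[i] = vals.reshape(n, t_axis.size).sum(axis=1) * step
    return sino


def projection_matrix(n: int, angles: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Explicit system matrix A with A @ image.ravel() == forward_project(image).

    Brute-force: projects every pixel basis image.  Intended for small grids
    (oracle tests); O(n^2) projector calls.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    a = np.empty((angles.size * n, n * n), dtype=np.float64)
    basis = np.zeros((n, n), dtype=np.float64)
    for j in range(n * n):
        basis.flat[j] = 1.0
        a[:, j] = forward_project(basis, angles, step=step).ravel()
        basis.flat[j] = 0.0
    return a


def dphase_forward(proj_delta: np.ndarray, phase_sensitivity: float) -> np.ndarray:
    """Differential phase from projected delta: C times the transverse
    central finite difference along the detector axis, zero-padded at edges.
    """
    padded = np.pad(proj_delta, [(0, 0)] * (proj_delta.ndim - 1) + [(1, 1)])
    return phase_sensitivity * (padded[..., 2:] - padded[..., :-2]) / 2.0
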