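"""Synthetic tissue phantoms for grating-based phase-contrast CT studies.

A phantom carries two co-registered maps on the same pixel grid: the linear
attenuation coefficient ``mu`` (in inverse pixel units, so line integrals are
dimensionless) and the refractive-index decrement ``delta`` (dimensionless,
scaled; proportional to electron density).  The default recipe emulates a
soft-tissue specimen in a cylindrical water bath: a marbled arrangement of
elliptical tissue regions, a plastic-rod-like insert and thin fiber
structures that probe fine-detail recovery after denoising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomVolume",
    "TissueClass",
    "PhantomSpec",
    "make_phantom",
    "make_phantom_stack",
]


@dataclass
class PhantomVolume:
    """Co-registered ground-truth maps defining one phantom slice (or stack).

    Attributes
    ----------
    mu : ndarray
        Attenuation coefficient per pixel (1/px), >= 0, zero outside the bath.
    delta : ndarray
        Refractive-index decrement (scaled), >= 0, zero outside the bath.
    pixel_size : float
        Physical length per pixel; bookkeeping only, never enters the math.
    labels : ndarray of int
        Region map: 0 background, 1 water bath, >= 2 tissue classes.
    """

    mu: np.ndarray
    delta: np.ndarray
    pixel_size: float = 1.0
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.delta = np.asarray(self.delta, dtype=np.float64)
        if self.mu.shape != self.delta.shape:
            raise ValueError(
                f"mu and delta must share a shape, got {self.mu.shape} vs {self.delta.shape}"
            )
        if np.any(self.mu < 0) or np.any(self.delta < 0):
            raise ValueError("mu and delta must be non-negative everywhere")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mu.shape


@dataclass
class TissueClass:
    """One tissue type: its contrast pair and how many blobs of it to place."""

    mu: float
    delta: float
    n_regions: int = 1
    radius_range: tuple[float, float] = (3.0, 8.0)

    def __post_init__(self) -> None:
        if self.mu < 0 or self.delta < 0:
            raise ValueError("tissue contrast values must be non-negative")
        if self.n_regions < 0:
            raise ValueError("n_regions must be >= 0")


@dataclass
class PhantomSpec:
    """Recipe for :func:`make_phantom`.

    ``bath_mu``/``bath_delta`` fill a centred disk of radius
    ``bath_radius_frac * min(shape)/2``.  Each :class:`TissueClass` places
    random ellipses inside the bath; ``fiber_width`` adds thin rotated
    bar-like structures (width in pixels, <= 3 to act as a detail probe).
    """

    bath_mu: float = 0.02
    bath_delta: float = 0.010
    bath_radius_frac: float = 0.90
    tissues: list[TissueClass] = field(default_factory=list)
    n_fibers: int = 0
    fiber_width: int = 2
    fiber_mu: float = 0.035
    fiber_delta: float = 0.018

    def __post_init__(self) -> None:
        for v in (self.bath_mu, self.bath_delta, self.fiber_mu, self.fiber_delta):
            if v < 0:
                raise ValueError("contrast values must be non-negative")
        if not (0 < self.bath_radius_frac <= 1):
            raise ValueError("bath_radius_frac must lie in (0, 1]")


def default_spec() -> PhantomSpec:
    """Soft-tissue default: water bath, two tissue classes, two thin fibers.

    Values are per-pixel attenuation coefficients at desk scale: the bath
    (water) at 0.02/px gives a maximum line integral of ~1.2 across a
    64 px disk (transmission ~0.3, in the regime of a few cm of tissue);
    delta values are scaled so the simulated differential phase stays well
    inside (-pi, pi) at the default phase sensitivity.
    """
    return PhantomSpec(
        bath_mu=0.02,
        bath_delta=0.010,
        tissues=[
            TissueClass(mu=0.026, delta=0.016, n_regions=3, radius_range=(4.0, 9.0)),
            TissueClass(mu=0.014, delta=0.006, n_regions=2, radius_range=(3.0, 6.0)),
        ],
        n_fibers=2,
        fiber_width=2,
    )


def make_phantom(
    shape: tuple[int, int],
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> PhantomVolume:
    """Build a 2D phantom slice from a recipe, deterministically for a seed.

    Parameters
    ----------
    shape : (rows, cols), each >= 32.
    spec : recipe; ``None`` selects :func:`default_spec`.
    seed : RNG seed controlling region placement.
    """
    if len(shape) != 2 or shape[0] < 32 or shape[1] < 32:
        raise ValueError(f"shape must be at least 32x32 per slice, got {shape}")
    if spec is None:
        spec = default_spec()

    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    yy, xx = np.mgrid[0:n_rows, 0:n_cols].astype(np.float64)
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    bath_r = spec.bath_radius_frac * min(n_rows, n_cols) / 2.0

    bath = (yy - cy) ** 2 + (xx - cx) ** 2 <= bath_r**2
    mu = np.where(bath, spec.bath_mu, 0.0)
    delta = np.where(bath, spec.bath_delta, 0.0)
    labels = bath.astype(np.int32)  # 0 background, 1 bath

    inner_r = 0.75 * bath_r  # keep structures off the bath rim

    next_label = 2
    for tissue in spec.tissues:
        for _ in range(tissue.n_regions):
            # rejection-free placement: centre within inner_r of bath centre
            ang = rng.uniform(0, 2 * np.pi)
            rad = inner_r * np.sqrt(rng.uniform(0, 0.7))
            ry = cy + rad * np.sin(ang)
            rx = cx + rad * np.cos(ang)
            a = rng.uniform(*tissue.radius_range)
            b = rng.uniform(*tissue.radius_range)
            tilt = rng.uniform(0, np.pi)
            ct, st = np.cos(tilt), np.sin(tilt)
            u = (xx - rx) * ct + (yy - ry) * st
            v = -(xx - rx) * st + (yy - ry) * ct
            ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            ellipse &= bath
            mu[ellipse] = tissue.mu
            delta[ellipse] = tissue.delta
            labels[ellipse] = next_label
        next_label += 1

    fiber_label = next_label
    for _ in range(spec.n_fibers):
        ang = rng.uniform(0, 2 * np.pi)
        rad = inner_r * np.sqrt(rng.uniform(0, 0.5))
        fy = cy + rad * np.sin(ang)
        fx = cx + rad * np.cos(ang)
        tilt = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 0.6) * inner_r
        ct, st = np.cos(tilt), np.sin(tilt)
        u = (xx - fx) * ct + (yy - fy) * st
        v = -(xx - fx) * st + (yy - fy) * ct
        fiber = (np.abs(v) <= spec.fiber_width / 2.0) & (np.abs(u) <= length / 2.0)
        fiber &= bath
        mu[fiber] = spec.fiber_mu
        delta[fiber] = spec.fiber_delta
        labels[fiber] = fiber_label

    return PhantomVolume(mu=mu, delta=delta, labels=labels)


def make_phantom_stack(
    n_slices: int,
    shape: tuple[int, int],
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> PhantomVolume:
    """A stack of phantom slices sharing the recipe but with independently
    placed structures (axis 0 = slice).

    Emulates scanning a specimen whose cross-section varies along the
    rotation axis; a multi-slice stack is also what the denoiser trains on.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_slices)
    slices = [make_phantom(shape, spec, seed=int(s % (2**31))) for s in seeds]
    return PhantomVolume(
        mu=np.stack([p.mu for p in slices]),
        delta=np.stack([p.delta for p in slices]),
        labels=np.stack([p.labels for p in slices]),
    )
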