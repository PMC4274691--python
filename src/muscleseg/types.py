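"""Core value types shared across the segmentation pipeline.

Images carry their physical pixel scale (µm/px) so that morphometric
measurements can be reported in micrometres.  All image payloads are
plain numpy arrays; the wrappers only validate invariants and carry
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default physical scale of the regions of interest this pipeline was
#: designed for: 1030x1300 px covering 926x1169 µm, i.e. ~0.899 µm/px.
DEFAULT_PX_SCALE_UM = 0.899


class MuscleSegError(Exception):
    """Base class for all errors raised by this package."""


class DegenerateImageError(MuscleSegError):
    """Input image carries no usable signal (e.g. all-white, constant)."""


class StainDecompositionError(MuscleSegError):
    """Non-negative matrix factorisation failed to converge.

    Attributes
    ----------
    n_iter : int
        Number of iterations performed before giving up.
    """

    def __init__(self, message: str, n_iter: int = -1):
        super().__init__(message)
        self.n_iter = n_iter


class DiffusionStabilityError(MuscleSegError):
    """A diffusion step produced non-finite values.

    Advises a smaller time step ``tau`` or internal sub-stepping.
    """


class ConfigError(MuscleSegError):
    """Invalid or unknown configuration values."""


def _as_float(a) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=np.float64))


@dataclass
class RGBImage:
    """H x W x 3 raster with intensities in [0, 1] and a physical scale."""

    pixels: np.ndarray
    px_scale_um: float = DEFAULT_PX_SCALE_UM

    def __post_init__(self):
        self.pixels = _as_float(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"RGBImage expects HxWx3, got {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < 16 or w < 16:
            raise ValueError(f"image too small: {h}x{w} (need >= 16x16)")
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite pixel values")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("RGB intensities must lie in [0, 1]")
        if self.px_scale_um <= 0:
            raise ValueError("px_scale_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GrayImage:
    """H x W scalar raster.

    ``unit_range=False`` relaxes the [0, 1] bound for images that are not
    intensities (e.g. stain density maps, which are unbounded above).
    """

    pixels: np.ndarray
    px_scale_um: float = DEFAULT_PX_SCALE_UM
    unit_range: bool = True

    def __post_init__(self):
        self.pixels = _as_float(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage expects HxW, got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite pixel values")
        if self.unit_range and (self.pixels.min() < 0.0 or self.pixels.max() > 1.0):
            raise ValueError("gray intensities must lie in [0, 1]")
        if self.px_scale_um <= 0:
            raise ValueError("px_scale_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class StainPair:
    """Result of un-mixing an H&E image into its two stain densities.

    ``basis`` holds the two unit-norm stain colour vectors in optical
    density space (rows: eosin, haematoxylin).
    """

    eosin: GrayImage
    haematoxylin: GrayImage
    basis: np.ndarray

    def __post_init__(self):
        self.basis = _as_float(self.basis)
        if self.basis.shape != (2, 3):
            raise ValueError("basis must be 2x3")
        norms = np.linalg.norm(self.basis, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("basis rows must have unit Euclidean norm")
        for g in (self.eosin, self.haematoxylin):
            if g.pixels.min() < -1e-9:
                raise ValueError("stain densities must be non-negative")


@dataclass
class BinaryMask:
    """Boolean mask with explicit semantics.

    semantics="boundary": True marks connective tissue between fibres.
    semantics="fibre":    True marks fibre interior pixels.
    """

    pixels: np.ndarray
    semantics: str

    def __post_init__(self):
        self.pixels = np.ascontiguousarray(np.asarray(self.pixels, dtype=bool))
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask expects HxW")
        if self.semantics not in ("boundary", "fibre"):
            raise ValueError(f"unknown mask semantics: {self.semantics!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Integer-labelled fibre regions: 0 = background, k >= 1 = fibre k."""

    labels: np.ndarray
    px_scale_um: float = DEFAULT_PX_SCALE_UM

    def __post_init__(self):
        self.labels = np.ascontiguousarray(np.asarray(self.labels))
        if self.labels.ndim != 2:
            raise ValueError("LabelMask expects HxW")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.px_scale_um <= 0:
            raise ValueError("px_scale_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_fibres(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def foreground(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, semantics="fibre")


@dataclass
class TensorField:
    """Per-pixel symmetric 2x2 tensor stored as three component planes.

    Component convention: j11 couples the x (column) direction, j22 the
    y (row) direction, j12 the mixed term.
    """

    j11: np.ndarray
    j12: np.ndarray
    j22: np.ndarray

    def __post_init__(self):
        self.j11 = _as_float(self.j11)
        self.j12 = _as_float(self.j12)
        self.j22 = _as_float(self.j22)
        if not (self.j11.shape == self.j12.shape == self.j22.shape):
            raise ValueError("tensor component planes must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.j11.shape


@dataclass
class EigenField:
    """Eigen-system of a symmetric 2x2 tensor field.

    mu1 >= mu2 everywhere; (v1x, v1y) is the unit eigenvector of mu1 and
    the mu2 eigenvector is its perpendicular (-v1y, v1x).
    """

    mu1: np.ndarray
    mu2: np.ndarray
    v1x: np.ndarray
    v1y: np.ndarray


@dataclass
class DiffusionParams:
    """Tunables of the coherence-enhancing diffusion filter.

    tau     : explicit time-step size (the study default is 1).
    sigma   : noise scale in px -- Gaussian regularisation of the gradient
              (default 1e-4 px, i.e. effectively no pre-smoothing).
    rho     : integration scale in px -- Gaussian smoothing of the
              structure tensor; sets the texture scale of coherence.
    c1      : regularisation in (0,1) keeping D uniformly positive definite.
    c2      : eigenvalue-contrast threshold (> 0).
    n_steps : number of explicit diffusion steps.
    """

    tau: float = 1.0
    sigma: float = 1e-4
    rho: float = 4.0
    c1: float = 1e-10
    c2: float = 1e-3
    n_steps: int = 20

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not (0.0 < self.c1 < 1.0):
            raise ValueError("c1 must lie in (0, 1)")
        if self.c2 <= 0:
            raise ValueError("c2 must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class PostprocessParams:
    """Morphological clean-up tunables.

    t_area         : minimum component area in px (components strictly
                     smaller are removed; default 750).
    closing_radius : disk radius for boundary closing, px (default 4).
    erosion_radius : disk radius for watershed marker erosion, px
                     (default 10).
    """

    t_area: int = 750
    closing_radius: int = 4
    erosion_radius: int = 10

    def __post_init__(self):
        for name in ("t_area", "closing_radius", "erosion_radius"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer")
            setattr(self, name, int(v))
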