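"""Seeded synthetic H&E-like muscle sections with exact ground truth.

Transverse skeletal muscle is emulated as a Voronoi tessellation of
jittered-grid seed points: each cell is a polygonal fibre, the band
where the two nearest seeds are nearly equidistant forms the pale
endomysial boundary, interiors get an eosin-pink base colour with
smooth shade variation, and a random subset of fibres receives dark
peripheral nuclei.  Speckle noise (myofibril texture) at three
severities and deliberate weakening of inter-fibre boundary segments
reproduce the failure modes that make real sections hard: noisy
interiors and weak boundaries.  The label mask is derived from the same
geometry that paints the image, so ground truth is exact by
construction, and everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .types import DEFAULT_PX_SCALE_UM, LabelMask, MuscleSegError, RGBImage

#: Base colours in [0,1] RGB: plausible H&E rendering (config, not data).
INTERIOR_RGB = np.array([0.93, 0.70, 0.78])
BOUNDARY_RGB = np.array([0.96, 0.93, 0.95])
NUCLEUS_RGB = np.array([0.35, 0.25, 0.55])

#: Speckle / tint severities per noise stratum (multiplicative sd, tint sd).
NOISE_LEVELS = {
    "low": (0.02, 0.01),
    "medium": (0.045, 0.02),
    "high": (0.07, 0.03),
}

#: Minimum surviving interior area for a cell to count as a fibre.
_MIN_CELL_AREA = 750


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic section.

    The default canvas is 512x512 at 0.899 µm/px for fast tests; a
    1030x1300 profile mirrors a full-size region of interest.
    """

    height: int = 512
    width: int = 512
    n_seeds: int = 60
    boundary_width: int = 5
    noise_level: str = "low"
    weak_boundary_frac: float = 0.0
    rng_seed: int = 0
    px_scale_um: float = DEFAULT_PX_SCALE_UM
    jitter: float = 0.35

    def __post_init__(self):
        if self.n_seeds < 4:
            raise ValueError("n_seeds must be >= 4")
        if self.boundary_width < 1:
            raise ValueError("boundary_width must be >= 1")
        if not (0.0 <= self.weak_boundary_frac <= 1.0):
            raise ValueError("weak_boundary_frac must lie in [0, 1]")
        if self.noise_level not in NOISE_LEVELS:
            raise ValueError(f"noise_level must be one of {sorted(NOISE_LEVELS)}")

    def to_dict(self) -> dict:
        return asdict(self)


def _jittered_grid(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """n_seeds points on a jittered grid covering the canvas."""
    h, w, n = spec.height, spec.width, spec.n_seeds
    gy = max(1, round(np.sqrt(n * h / w)))
    gx = int(np.ceil(n / gy))
    cy, cx = h / gy, w / gx
    yy, xx = np.meshgrid(np.arange(gy), np.arange(gx), indexing="ij")
    centers = np.stack([(yy.ravel() + 0.5) * cy, (xx.ravel() + 0.5) * cx], axis=1)
    jit = rng.uniform(-spec.jitter, spec.jitter, size=centers.shape)
    pts = centers + jit * np.array([cy, cx])
    if len(pts) > n:
        keep = rng.choice(len(pts), size=n, replace=False)
        pts = pts[np.sort(keep)]
    return np.clip(pts, 0, [h - 1, w - 1])


def generate_muscle_image(spec: SyntheticSpec) -> tuple[RGBImage, LabelMask]:
    """Render one synthetic section and its exact label mask.

    Fibre interiors are the Voronoi cells shrunk by the boundary band
    (a pixel is boundary when its two nearest seeds are within
    ``boundary_width`` of equidistant, i.e. it lies within about half
    the band width of the cell edge).  Noise and boundary weakening are
    applied per ``spec`` after painting; they never alter the labels.
    """
    h, w = spec.height, spec.width
    if h * w / spec.n_seeds < 2 * _MIN_CELL_AREA:
        raise MuscleSegError(
            f"{spec.n_seeds} seeds on {h}x{w} leaves cells below "
            f"{2 * _MIN_CELL_AREA} px"
        )
    rng = np.random.default_rng(spec.rng_seed)
    seeds = _jittered_grid(spec, rng)

    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float64)
    tree = cKDTree(seeds)
    dist, idx = tree.query(coords, k=2)
    d1, d2 = dist[:, 0], dist[:, 1]
    nearest = idx[:, 0]

    interior = (d2 - d1) >= spec.boundary_width
    labels = np.where(interior, nearest + 1, 0).reshape(h, w).astype(np.int32)

    # Cells whose interior fell below the minimum area become boundary.
    areas = np.bincount(labels.ravel(), minlength=spec.n_seeds + 1)
    small = np.where(areas[1:] < _MIN_CELL_AREA)[0] + 1
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels = _renumber(labels)

    img = np.empty((h, w, 3))
    img[:] = BOUNDARY_RGB
    n_fib = labels.max()
    shades = rng.normal(1.0, 0.04, size=n_fib + 1).clip(0.85, 1.15)
    for fid in range(1, n_fib + 1):
        img[labels == fid] = np.clip(INTERIOR_RGB * shades[fid], 0, 1)

    # Smooth global shade field (stain thickness variation).
    field = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 40)
    field /= max(np.abs(field).max(), 1e-12)
    img *= (1.0 + 0.02 * field)[..., None]

    _paint_nuclei(img, labels, d2 - d1, spec, rng)
    img = np.clip(img, 0.0, 1.0)

    mask = LabelMask(labels, px_scale_um=spec.px_scale_um)
    rgb = RGBImage(img, px_scale_um=spec.px_scale_um)
    if spec.weak_boundary_frac > 0:
        rgb = weaken_boundaries(rgb, mask, spec.weak_boundary_frac, rng)
    rgb = add_noise(rgb, spec.noise_level, rng)
    return rgb, mask


def _renumber(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels[labels > 0])
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[labels]


def _paint_nuclei(img, labels, edge_gap, spec, rng):
    """Dark elliptical nuclei at the periphery of a random fibre subset.

    ``edge_gap`` is (d2 - d1): small values are close to the cell edge,
    so sampling pixels with a small gap places nuclei peripherally, as
    in healthy adult fibres.
    """
    h, w = labels.shape
    gap = edge_gap.reshape(h, w)
    for fid in range(1, labels.max() + 1):
        if rng.random() > 0.7:
            continue
        sel = (labels == fid) & (gap < spec.boundary_width + 6)
        ys, xs = np.nonzero(sel)
        if ys.size == 0:
            continue
        for _ in range(rng.integers(1, 4)):
            k = rng.integers(0, ys.size)
            cy, cx = ys[k], xs[k]
            ry, rx = rng.uniform(2.0, 4.0), rng.uniform(3.0, 5.5)
            theta = rng.uniform(0, np.pi)
            y0, y1 = max(cy - 8, 0), min(cy + 9, h)
            x0, x1 = max(cx - 8, 0), min(cx + 9, w)
            yy, xx = np.meshgrid(np.arange(y0, y1) - cy,
                                 np.arange(x0, x1) - cx, indexing="ij")
            c, s = np.cos(theta), np.sin(theta)
            u = c * xx + s * yy
            v = -s * xx + c * yy
            inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
            inside &= labels[y0:y1, x0:x1] == fid
            img[y0:y1, x0:x1][inside] = NUCLEUS_RGB


def add_noise(
    img: RGBImage, level: str, rng: np.random.Generator
) -> RGBImage:
    """Add intra-fibre speckle and a global stain tint.

    The speckle is a multiplicative Gaussian field smoothed at the
    myofibril scale (~1.5 px); the tint is a constant per-channel shift.
    Severity is ordered low < medium < high; ground truth is unaffected.
    """
    if level not in NOISE_LEVELS:
        raise ValueError(f"unknown noise level {level!r}")
    speckle_sd, tint_sd = NOISE_LEVELS[level]
    h, w = img.shape
    field = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 1.5)
    field /= field.std()
    out = img.pixels * (1.0 + speckle_sd * field[..., None])
    out = out + rng.normal(0.0, tint_sd, size=3)[None, None, :]
    return RGBImage(np.clip(out, 0.0, 1.0), px_scale_um=img.px_scale_um)


def weaken_boundaries(
    img: RGBImage,
    labels: LabelMask,
    frac: float,
    rng: np.random.Generator,
) -> RGBImage:
    """Attenuate a random fraction of inter-fibre boundary segments.

    For the chosen fibre pairs the boundary pixels between them are
    blended 60-90% of the way toward the interior colour, emulating the
    weak endomysium that causes congealment failures.  Labels are never
    modified.
    """
    if not (0.0 <= frac <= 1.0):
        raise ValueError("frac must lie in [0, 1]")
    if frac == 0.0:
        return RGBImage(img.pixels.copy(), px_scale_um=img.px_scale_um)

    lab = labels.labels
    boundary = lab == 0
    n_fib = int(lab.max())
    # Distance from every pixel to each fibre's interior; a boundary
    # pixel belongs to the segment of its two nearest fibres.
    dists = np.full((n_fib + 1,) + lab.shape, np.inf)
    for fid in range(1, n_fib + 1):
        dists[fid] = ndi.distance_transform_edt(lab != fid)
    order = np.argsort(dists[1:], axis=0)[:2] + 1  # (2, H, W) nearest ids
    pair_lo = np.minimum(order[0], order[1])
    pair_hi = np.maximum(order[0], order[1])
    near_enough = np.take_along_axis(
        dists, order[1][None], axis=0
    )[0] <= 2.5 * max(3, int(round(_estimate_band(boundary))))

    pair_key = pair_lo.astype(np.int64) * (n_fib + 1) + pair_hi
    seg_keys = np.unique(pair_key[boundary & near_enough])
    if seg_keys.size == 0:
        return RGBImage(img.pixels.copy(), px_scale_um=img.px_scale_um)
    n_pick = int(round(frac * seg_keys.size))
    if frac > 0 and n_pick == 0:
        n_pick = 1
    picked = rng.choice(seg_keys, size=n_pick, replace=False)

    out = img.pixels.copy()
    for key in picked:
        sel = boundary & near_enough & (pair_key == key)
        if not sel.any():
            continue
        strength = rng.uniform(0.6, 0.9)
        out[sel] = out[sel] + strength * (INTERIOR_RGB - out[sel])
    return RGBImage(np.clip(out, 0.0, 1.0), px_scale_um=img.px_scale_um)


def _estimate_band(boundary: np.ndarray) -> float:
    """Rough half-width of the boundary band from its EDT."""
    if not boundary.any():
        return 3.0
    edt = ndi.distance_transform_edt(boundary)
    return float(np.percentile(edt[boundary], 90))
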