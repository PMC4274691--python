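"""Pre-processing: stain un-mixing, grayscale conversion, contrast enhancement.

An H&E section is a mixture of two absorbing dyes: eosin (sarcoplasm,
pink) and haematoxylin (nuclei, blue-purple).  Absorption is linear in
optical density (Beer-Lambert), so the RGB image is first mapped to OD
space and factorised there with rank-2 non-negative matrix factorisation.
The eosin density map is rendered back to an intensity image in which
fibre interiors are dark and the connective-tissue boundaries light, then
contrast-limited adaptive histogram equalisation stretches local contrast
so the downstream diffusion filter sees well-separated boundary ridges.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import exposure
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .types import (
    DegenerateImageError,
    GrayImage,
    RGBImage,
    StainDecompositionError,
    StainPair,
)

#: Additive floor keeping the log transform finite on zero pixels.
OD_EPSILON = 1.0 / 255.0

#: Reference eosin colour direction in OD space, used to decide which of
#: the two NMF factors is the eosinophilic one (cosine similarity).
REFERENCE_EOSIN_OD = np.array([0.07, 0.99, 0.11]) / np.linalg.norm(
    [0.07, 0.99, 0.11]
)

#: Direction assigned to a factor that came out numerically null (a
#: haematoxylin-like placeholder, so eosin matching is unaffected).
_PLACEHOLDER_OD = np.array([0.65, 0.70, 0.29]) / np.linalg.norm(
    [0.65, 0.70, 0.29]
)

# Luminance weights (Rec. 601).
_LUMA = np.array([0.299, 0.587, 0.114])


def optical_density(pixels: np.ndarray) -> np.ndarray:
    """Map intensities in [0, 1] to non-negative optical density.

    OD = -log((I + eps) / I0) with I0 = 1, clamped at zero so that a
    fully transmitting (white) pixel has exactly zero density.
    """
    od = -np.log(np.asarray(pixels, dtype=np.float64) + OD_EPSILON)
    return np.maximum(od, 0.0)


def decompose_stains(
    rgb: RGBImage,
    rank: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    fit_sample_px: int = 50_000,
) -> StainPair:
    """Un-mix an H&E image into eosin and haematoxylin density maps.

    The stain basis is fitted by NMF (multiplicative updates, Frobenius
    objective, deterministic NNDSVD-a initialisation) on a random pixel
    subsample, then per-pixel concentrations are solved for the full
    image against the fixed basis.  Requires no user-selected regions.

    Raises
    ------
    DegenerateImageError
        If the image has (numerically) zero optical density everywhere,
        e.g. an all-white image.
    StainDecompositionError
        If the factorisation does not converge within ``max_iter``
        iterations; carries the iteration count in ``n_iter``.
    """
    if rank != 2:
        raise ValueError("stain decomposition is defined for rank 2")
    od = optical_density(rgb.pixels)
    flat = od.reshape(-1, 3)
    if flat.max() <= 1e-8:
        raise DegenerateImageError(
            "zero optical density everywhere (all-white image?)"
        )

    rng = np.random.default_rng(seed)
    if flat.shape[0] > fit_sample_px:
        idx = rng.choice(flat.shape[0], size=fit_sample_px, replace=False)
        fit_data = flat[idx]
    else:
        fit_data = flat

    # A small L1 penalty on the concentrations breaks the non-uniqueness
    # of the factorisation (stain maps are sparse: most pixels carry
    # mostly one dye), so nearly rank-1 inputs resolve to one factor.
    nmf = NMF(
        n_components=2,
        init="nndsvda",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        alpha_W=1e-3,
        l1_ratio=1.0,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        nmf.fit(fit_data)
        concentrations = nmf.transform(flat)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise StainDecompositionError(
                f"NMF did not converge within {nmf.n_iter_} iterations",
                n_iter=int(nmf.n_iter_),
            )

    basis = nmf.components_  # (2, 3) stain OD directions
    norms = np.linalg.norm(basis, axis=1)
    # A null factor is the legitimate outcome for single-stain input:
    # give it a placeholder unit direction and zero concentration.
    null = norms <= 1e-12
    if null.all():
        raise StainDecompositionError(
            "NMF produced only null stain vectors", n_iter=int(nmf.n_iter_)
        )
    basis_unit = np.where(
        null[:, None], _PLACEHOLDER_OD, basis / np.where(null, 1.0, norms)[:, None]
    )
    concentrations = concentrations * np.where(null, 0.0, norms)[None, :]

    cos = basis_unit @ REFERENCE_EOSIN_OD
    e_idx = int(np.argmax(cos))
    h_idx = 1 - e_idx

    h_img, w_img = rgb.shape
    eosin = np.maximum(concentrations[:, e_idx].reshape(h_img, w_img), 0.0)
    haem = np.maximum(concentrations[:, h_idx].reshape(h_img, w_img), 0.0)
    return StainPair(
        eosin=GrayImage(eosin, px_scale_um=rgb.px_scale_um, unit_range=False),
        haematoxylin=GrayImage(haem, px_scale_um=rgb.px_scale_um, unit_range=False),
        basis=np.vstack([basis_unit[e_idx], basis_unit[h_idx]]),
    )


def render_eosin(stains: StainPair) -> GrayImage:
    """Render the eosin density map back to an intensity image.

    exp(-density): densely stained fibre interiors come out dark, the
    weakly eosinophilic connective boundaries light.
    """
    return GrayImage(
        np.exp(-stains.eosin.pixels),
        px_scale_um=stains.eosin.px_scale_um,
    )


def to_grayscale(img: RGBImage | GrayImage) -> GrayImage:
    """Luminance grayscale (Rec. 601 weights); gray input passes through."""
    if isinstance(img, GrayImage):
        return GrayImage(img.pixels.copy(), px_scale_um=img.px_scale_um)
    gray = np.clip(img.pixels @ _LUMA, 0.0, 1.0)
    return GrayImage(gray, px_scale_um=img.px_scale_um)


def enhance_contrast(
    gray: GrayImage,
    tile_grid: tuple[int, int] = (8, 8),
    clip_limit: float = 0.01,
    nbins: int = 256,
) -> GrayImage:
    """Contrast-limited adaptive histogram equalisation.

    A constant image is returned unchanged (there is no contrast to
    redistribute).  ``tile_grid`` is (rows, cols) of equalisation tiles.
    """
    h, w = gray.shape
    ty, tx = int(tile_grid[0]), int(tile_grid[1])
    if ty < 1 or tx < 1:
        raise ValueError("tile_grid entries must be >= 1")
    if ty > h or tx > w:
        raise ValueError(f"tile grid {tile_grid} larger than image {h}x{w}")
    px = gray.pixels
    if np.ptp(px) < 1e-12:
        return GrayImage(px.copy(), px_scale_um=gray.px_scale_um)
    out = exposure.equalize_adapthist(
        px, kernel_size=(max(h // ty, 1), max(w // tx, 1)),
        clip_limit=clip_limit, nbins=nbins,
    )
    return GrayImage(np.clip(out, 0.0, 1.0), px_scale_um=gray.px_scale_um)


def preprocess(
    rgb: RGBImage,
    nmf_seed: int = 0,
    nmf_max_iter: int = 500,
    nmf_tol: float = 1e-4,
    clahe_tiles: tuple[int, int] = (8, 8),
    clahe_clip: float = 0.01,
) -> GrayImage:
    """Full pre-processing chain: un-mix, render eosin, gray, equalise.

    Output convention: lighter pixels are fibre boundaries, darker pixels
    fibre interiors.  Deterministic for a fixed ``nmf_seed``.
    """
    stains = decompose_stains(
        rgb, seed=nmf_seed, max_iter=nmf_max_iter, tol=nmf_tol
    )
    eosin_img = render_eosin(stains)
    gray = to_grayscale(eosin_img)
    return enhance_contrast(gray, tile_grid=clahe_tiles, clip_limit=clahe_clip)
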