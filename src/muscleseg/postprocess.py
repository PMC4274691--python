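"""Morphological filtering and marker-controlled watershed.

The CED output is read as a boundary-likelihood map: Otsu's threshold
turns it into a binary boundary mask, small components (staining debris)
are dropped, a disk closing bridges broken boundary runs, and the
complement yields the fibre mask.  Touching fibres are then split by a
watershed flooded from erosion-survivor markers on the negated Euclidean
distance transform.  8-connectivity is used for all component analysis.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, erosion as _erosion
from skimage.segmentation import watershed

from .types import (
    BinaryMask,
    DegenerateImageError,
    GrayImage,
    LabelMask,
    PostprocessParams,
    RGBImage,
)

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def otsu_threshold(gray: GrayImage, nbins: int = 256) -> tuple[float, BinaryMask]:
    """Otsu's threshold over a 256-bin histogram; mask = boundary pixels.

    The threshold maximises the between-class variance
    w0(t) w1(t) (m0(t) - m1(t))^2 over all histogram split points and is
    reported as the centre of the winning bin.  Pixels *above* the
    threshold are boundary (the pre-processed/CED image is light on
    connective tissue).

    Raises
    ------
    DegenerateImageError
        If the image is constant (no variance to split).
    """
    px = gray.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi - lo < 1e-12:
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist, edges = np.histogram(px, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist.astype(np.float64) / hist.sum()
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    m_tot = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = m / w0
        m1 = (m_tot - m) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-1.0)
    t_idx = int(np.argmax(var_between))  # first maximiser on ties
    threshold = float(centers[t_idx])
    mask = BinaryMask(px > threshold, semantics="boundary")
    return threshold, mask


def remove_small_components(mask: BinaryMask, t_area: int) -> BinaryMask:
    """Drop 8-connected components with area strictly less than t_area.

    A component of exactly t_area pixels survives.
    """
    lab, n = ndi.label(mask.pixels, structure=_EIGHT)
    if n == 0:
        return BinaryMask(mask.pixels.copy(), semantics=mask.semantics)
    areas = np.bincount(lab.ravel())
    keep = areas >= t_area
    keep[0] = False
    return BinaryMask(keep[lab], semantics=mask.semantics)


def close_boundaries(mask: BinaryMask, radius: int) -> BinaryMask:
    """Morphological closing with a discrete disk (joins boundary gaps).

    Computed on a zero-padded canvas so the result is the true set
    closing (extensive, idempotent, rectangles are fixed points) rather
    than a border-convention artefact.
    """
    pad = 2 * radius + 1
    padded = np.pad(mask.pixels, pad, mode="constant", constant_values=False)
    closed = ndi.binary_closing(padded, structure=disk(radius).astype(bool))
    return BinaryMask(closed[pad:-pad, pad:-pad], semantics=mask.semantics)


def fibres_from_boundaries(mask: BinaryMask) -> BinaryMask:
    """Complement of the boundary mask: fibre pixels become True."""
    flipped = {"boundary": "fibre", "fibre": "boundary"}[mask.semantics]
    return BinaryMask(~mask.pixels, semantics=flipped)


def split_touching_fibres(
    fibres: BinaryMask,
    erosion_radius: int = 10,
    px_scale_um: float = 0.899,
) -> LabelMask:
    """Marker-controlled watershed splitting of touching fibre blobs.

    Markers are the connected components of the fibre mask eroded by a
    disk of ``erosion_radius``; any fibre component that vanishes under
    erosion instead receives a single-pixel marker at the maximum of its
    Euclidean distance transform (ties broken in row-major order), so
    thin fibres are not silently dropped.  The watershed floods the
    negated distance transform restricted to the fibre mask, hence every
    fibre pixel receives a label and each marker yields one region.
    """
    fg = fibres.pixels
    if fibres.semantics != "fibre":
        raise ValueError("split_touching_fibres expects a fibre mask")
    if not fg.any():
        return LabelMask(np.zeros(fg.shape, dtype=np.int32),
                         px_scale_um=px_scale_um)

    edt = ndi.distance_transform_edt(fg)
    eroded = _erosion(fg, footprint=disk(erosion_radius))
    markers, n_markers = ndi.label(eroded, structure=_EIGHT)

    # Fallback markers for components erased by the erosion.
    comp, n_comp = ndi.label(fg, structure=_EIGHT)
    has_marker = np.zeros(n_comp + 1, dtype=bool)
    has_marker[np.unique(comp[markers > 0])] = True
    next_id = n_markers
    for cid in range(1, n_comp + 1):
        if has_marker[cid]:
            continue
        sel = comp == cid
        flat = np.where(sel.ravel(), edt.ravel(), -1.0)
        peak = int(np.argmax(flat))  # row-major tie-break
        next_id += 1
        markers.ravel()[peak] = next_id

    labels = watershed(-edt, markers=markers, mask=fg)
    return LabelMask(_relabel_consecutive(labels), px_scale_um=px_scale_um)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to 1..K preserving ascending order."""
    vals = np.unique(labels[labels > 0])
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[labels]


def remove_border_fibres(labels: LabelMask) -> LabelMask:
    """Remove any labelled region touching the image border; renumber."""
    lab = labels.labels
    border = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]
    ]))
    border = border[border > 0]
    out = lab.copy()
    if border.size:
        out[np.isin(out, border)] = 0
    return LabelMask(_relabel_consecutive(out), px_scale_um=labels.px_scale_um)


def remove_small_fibres(labels: LabelMask, t_area: int) -> LabelMask:
    """Drop labelled regions with area strictly below t_area; renumber."""
    lab = labels.labels
    areas = np.bincount(lab.ravel())
    small = np.where(areas < t_area)[0]
    small = small[small > 0]
    out = lab.copy()
    if small.size:
        out[np.isin(out, small)] = 0
    return LabelMask(_relabel_consecutive(out), px_scale_um=labels.px_scale_um)


def segment_preprocessed(
    ced_img: GrayImage,
    params: PostprocessParams | None = None,
) -> LabelMask:
    """Morphological stages only: CED output -> labelled fibres."""
    if params is None:
        params = PostprocessParams()
    _, boundary = otsu_threshold(ced_img)
    boundary = remove_small_components(boundary, params.t_area)
    boundary = close_boundaries(boundary, params.closing_radius)
    fibres = fibres_from_boundaries(boundary)
    labels = split_touching_fibres(
        fibres, params.erosion_radius, px_scale_um=ced_img.px_scale_um
    )
    labels = remove_small_fibres(labels, params.t_area)
    labels = remove_border_fibres(labels)
    return labels


def segment(rgb: RGBImage, cfg=None) -> LabelMask:
    """Full four-stage pipeline: RGB section -> labelled myofibres.

    Stages: stain un-mixing / contrast enhancement, coherence-enhancing
    diffusion, morphological filtering, marker-controlled watershed,
    then removal of sub-threshold and border-touching regions.
    ``cfg`` is a :class:`muscleseg.config.PipelineConfig`; defaults are
    used when omitted.  Deterministic for a fixed config.
    """
    from .ced import ced
    from .config import PipelineConfig
    from .preprocess import preprocess

    if cfg is None:
        cfg = PipelineConfig()
    pre = preprocess(
        rgb,
        nmf_seed=cfg.preprocess.nmf_seed,
        nmf_max_iter=cfg.preprocess.nmf_max_iter,
        nmf_tol=cfg.preprocess.nmf_tol,
        clahe_tiles=tuple(cfg.preprocess.clahe_tiles),
        clahe_clip=cfg.preprocess.clahe_clip,
    )
    logger.info("preprocessed image: range [%.3f, %.3f]",
                pre.pixels.min(), pre.pixels.max())
    diffused = ced(pre, cfg.ced_params())
    labels = segment_preprocessed(diffused, cfg.postprocess_params())
    logger.info("segmentation produced %d fibre regions", labels.n_fibres)
    return labels
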