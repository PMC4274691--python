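"""Segmentation evaluation statistics for myofibre morphometry.

Implements region-level accuracy with an enforced one-to-one mapping
between ground-truth and predicted fibres, the over-/under-segmentation
measures fragmentation (F = p/n) and congealment (C = q/n), per-image
pixel misclassification percentages with a kernel-smoothed CDF, and the
clinical morphometrics: minor-axis fibre diameters and the variability
coefficient VC = 1000 * sd / mean (VC < 250 is the conventional normal
range for adult biopsies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import norm
from skimage.measure import regionprops

from .types import BinaryMask, LabelMask, MuscleSegError

_EIGHT = np.ones((3, 3), dtype=bool)

#: Connected components smaller than this inside a mask window are
#: treated as watershed-line slivers and ignored by F and C.
DEFAULT_SLIVER_PX = 5


@dataclass
class Matching:
    """One-to-one correspondence between ground-truth and predicted fibres."""

    pairs: list[tuple[int, int]]
    unmatched_gt: list[int]
    unmatched_pred: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)


@dataclass
class MisclassSet:
    """Per-image pixel misclassification percentages, in [0, 100]."""

    S: list[float]

    def __post_init__(self):
        if any(p < 0 or p > 100 for p in self.S):
            raise ValueError("misclassification percentages must be in [0, 100]")

    @property
    def n_images(self) -> int:
        return len(self.S)


@dataclass
class CDFEstimate:
    """Kernel-smoothed CDF of misclassification percentages."""

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float


@dataclass
class MetricsReport:
    """All evaluation statistics for one prediction/ground-truth pair."""

    accuracy: float
    fragmentation: float
    congealment: float
    misclassification_pct: float
    diameters_um: list[float]
    mean_diameter_um: float
    vc: float | None
    n_gt: int
    n_pred: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "fragmentation": self.fragmentation,
            "congealment": self.congealment,
            "misclassification_pct": self.misclassification_pct,
            "diameters_um": list(map(float, self.diameters_um)),
            "mean_diameter_um": self.mean_diameter_um,
            "vc": self.vc,
            "n_gt": self.n_gt,
            "n_pred": self.n_pred,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**d)


def _intersections(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Joint label histogram: table[g, p] = |{gt==g} ∩ {pred==p}|."""
    ng, np_ = int(gt.max()) + 1, int(pred.max()) + 1
    joint = gt.astype(np.int64) * np_ + pred.astype(np.int64)
    counts = np.bincount(joint.ravel(), minlength=ng * np_)
    return counts.reshape(ng, np_)


def match_regions(
    pred: LabelMask, gt: LabelMask, encompass_frac: float = 0.5
) -> Matching:
    """Greedy one-to-one matching of predicted to ground-truth fibres.

    A predicted region is a candidate for a ground-truth fibre when at
    least ``encompass_frac`` of its area lies inside that fibre
    (it is "encompassed within" the fibre boundary).  Candidates are
    assigned greedily in order of descending intersection area (ties by
    smaller predicted label id); every region participates in at most
    one pair.  Remaining predicted regions are false positives,
    remaining ground-truth fibres false negatives.
    """
    if pred.shape != gt.shape:
        raise MuscleSegError("prediction and ground truth shapes differ")
    table = _intersections(gt.labels, pred.labels)
    gt_ids = np.unique(gt.labels[gt.labels > 0])
    pred_ids = np.unique(pred.labels[pred.labels > 0])
    pred_areas = np.bincount(pred.labels.ravel(), minlength=table.shape[1])

    candidates = []
    for g in gt_ids:
        for p in pred_ids:
            inter = table[g, p]
            if inter > 0 and inter >= encompass_frac * pred_areas[p]:
                candidates.append((int(inter), int(g), int(p)))
    candidates.sort(key=lambda t: (-t[0], t[2]))

    used_gt: set[int] = set()
    used_pred: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, g, p in candidates:
        if g in used_gt or p in used_pred:
            continue
        pairs.append((g, p))
        used_gt.add(g)
        used_pred.add(p)
    unmatched_gt = [int(g) for g in gt_ids if g not in used_gt]
    unmatched_pred = [int(p) for p in pred_ids if p not in used_pred]
    return Matching(pairs=pairs, unmatched_gt=unmatched_gt,
                    unmatched_pred=unmatched_pred)


def fibre_accuracy(m: Matching) -> float:
    """TP / (TP + FP + FN): correctly segmented fibres over all regions."""
    denom = m.tp + m.fp + m.fn
    if denom == 0:
        raise MuscleSegError("accuracy undefined: no regions on either side")
    return m.tp / denom


def _count_components(mask: np.ndarray, sliver_px: int) -> int:
    lab, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return 0
    areas = np.bincount(lab.ravel())[1:]
    return int((areas >= sliver_px).sum())


def fragmentation(
    pred_fibre_mask: BinaryMask, gt: LabelMask, sliver_px: int = DEFAULT_SLIVER_PX
) -> float:
    """F = p/n: fraction of ground-truth fibres split into >1 component.

    For every ground-truth fibre the predicted foreground is windowed to
    that fibre and its 8-connected components counted; components under
    ``sliver_px`` pixels (watershed-line debris) are ignored.
    """
    if pred_fibre_mask.shape != gt.shape:
        raise MuscleSegError("shape mismatch")
    gt_ids = np.unique(gt.labels[gt.labels > 0])
    if gt_ids.size == 0:
        raise MuscleSegError("fragmentation undefined on empty ground truth")
    objects = ndi.find_objects(gt.labels)
    p = 0
    for g in gt_ids:
        sl = objects[g - 1]
        window = pred_fibre_mask.pixels[sl] & (gt.labels[sl] == g)
        if _count_components(window, sliver_px) > 1:
            p += 1
    return p / gt_ids.size


def congealment(
    pred: LabelMask, gt: LabelMask, sliver_px: int = DEFAULT_SLIVER_PX
) -> float:
    """C = q/n: fraction of ground-truth fibres merged by the prediction.

    For every predicted region the ground-truth foreground is windowed
    to that region; if more than one 8-connected component (each at
    least ``sliver_px`` pixels) appears, the ground-truth fibres those
    components belong to are congealed.  q counts distinct congealed
    fibres.
    """
    if pred.shape != gt.shape:
        raise MuscleSegError("shape mismatch")
    gt_ids = np.unique(gt.labels[gt.labels > 0])
    if gt_ids.size == 0:
        raise MuscleSegError("congealment undefined on empty ground truth")
    gt_fg = gt.labels > 0
    congealed: set[int] = set()
    objects = ndi.find_objects(pred.labels)
    for p_id in np.unique(pred.labels[pred.labels > 0]):
        sl = objects[p_id - 1]
        window = gt_fg[sl] & (pred.labels[sl] == p_id)
        lab, n = ndi.label(window, structure=_EIGHT)
        if n < 2:
            continue
        areas = np.bincount(lab.ravel())
        big = [i for i in range(1, n + 1) if areas[i] >= sliver_px]
        if len(big) > 1:
            gt_window = gt.labels[sl]
            for i in big:
                ids, cnts = np.unique(gt_window[lab == i], return_counts=True)
                keep = ids > 0
                if keep.any():
                    ids, cnts = ids[keep], cnts[keep]
                    congealed.add(int(ids[np.argmax(cnts)]))
    return len(congealed) / gt_ids.size


def misclassification_percentage(
    pred_mask: BinaryMask, gt_mask: BinaryMask
) -> float:
    """Percentage of pixels whose binary class disagrees (XOR / total)."""
    if pred_mask.shape != gt_mask.shape:
        raise MuscleSegError("shape mismatch")
    diff = np.logical_xor(pred_mask.pixels, gt_mask.pixels)
    return 100.0 * diff.mean()


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if min(sd, iqr / 1.34) > 0 else max(sd, iqr / 1.34)
    if spread <= 0:
        return 1.0  # all values identical: fall back to a 1-point band
    return 0.9 * spread * n ** (-1.0 / 5.0)


def cdf_estimate(
    S: MisclassSet,
    grid_points: int = 512,
    bandwidth: float | None = None,
) -> CDFEstimate:
    """Gaussian-kernel CDF of the misclassification distribution.

    The CDF is the exact integral of the Gaussian KDE:
    F(x) = mean_i Phi((x - p_i) / h), evaluated on a uniform grid over
    [0, 100].  Bandwidth defaults to Silverman's rule.  An ideal
    segmenter's CDF approaches the unit step at 0.
    """
    if S.n_images < 1:
        raise MuscleSegError("cdf_estimate requires at least one image")
    x = np.asarray(S.S, dtype=np.float64)
    h = _silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, 100.0, grid_points)
    values = norm.cdf((grid[:, None] - x[None, :]) / h).mean(axis=1)
    return CDFEstimate(grid=grid, values=values, bandwidth=h)


def fibre_diameters(labels: LabelMask) -> list[float]:
    """Minor-axis diameter of each fibre, in µm.

    The diameter is the minor-axis length of the ellipse with the same
    normalised second central moments as the region — the measure least
    affected by oblique sectioning or kinking — scaled by the physical
    pixel size.
    """
    if labels.n_fibres == 0:
        raise MuscleSegError("no fibres to measure")
    props = regionprops(labels.labels)
    return [float(p.axis_minor_length * labels.px_scale_um) for p in props]


def variability_coefficient(diameters, scale: float = 1000.0) -> float:
    """VC = scale * sd / mean with the sample (n-1) standard deviation.

    Scale-invariant in the diameters; < 250 is conventionally normal.
    """
    d = np.asarray(diameters, dtype=np.float64)
    if d.size < 2:
        raise MuscleSegError("variability coefficient needs >= 2 diameters")
    mean = d.mean()
    if mean <= 0:
        raise MuscleSegError("variability coefficient needs a positive mean")
    return float(scale * d.std(ddof=1) / mean)


def evaluate(
    pred: LabelMask,
    gt: LabelMask,
    encompass_frac: float = 0.5,
    sliver_px: int = DEFAULT_SLIVER_PX,
) -> MetricsReport:
    """Compute the full metrics report for one image pair."""
    if pred.shape != gt.shape:
        raise MuscleSegError("shape mismatch")
    m = match_regions(pred, gt, encompass_frac=encompass_frac)
    acc = fibre_accuracy(m)
    frag = fragmentation(pred.foreground(), gt, sliver_px=sliver_px)
    cong = congealment(pred, gt, sliver_px=sliver_px)
    misc = misclassification_percentage(pred.foreground(), gt.foreground())
    if pred.n_fibres > 0:
        diam = fibre_diameters(pred)
        mean_d = float(np.mean(diam))
        vc = variability_coefficient(diam) if len(diam) >= 2 else None
    else:
        diam, mean_d, vc = [], 0.0, None
    return MetricsReport(
        accuracy=acc,
        fragmentation=frag,
        congealment=cong,
        misclassification_pct=misc,
        diameters_um=diam,
        mean_diameter_um=mean_d,
        vc=vc,
        n_gt=gt.n_fibres,
        n_pred=pred.n_fibres,
    )
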