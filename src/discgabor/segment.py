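"""Per-disc segmentation: candidate region, adaptive threshold, post-processing.

Each localized disc is segmented from the *grayscale* image inside a
candidate region derived from the Gabor features: the region is bounded
vertically by the disc box, laterally by quadratic curves fitted to the
thresholded maximum direction-mean feature map, and clipped to the spinal
band.  A local threshold is then found by area-constrained bisection starting
from Otsu's value, and the resulting mask is cleaned morphologically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover
    from .gabor import FeatureStack
    from .localize import DiscDetection
    from .spine import SpinalCurves

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateRegion",
    "ThresholdState",
    "SegmentationResult",
    "otsu_threshold",
    "mean_direction_gfi",
    "build_candidate_region",
    "box_region",
    "init_threshold_state",
    "adaptive_threshold",
    "coarse_segment",
    "postprocess",
    "segment_disc",
]

#: iteration cap of the adaptive threshold search
MAX_THRESHOLD_ITERATIONS = 30


def otsu_threshold(values, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance of the value histogram.

    For integer-typed input whose range does not exceed ``nbins`` levels the
    candidate thresholds are the integer values themselves and the result is
    exact: the returned ``t`` splits the data into classes ``<= t`` and
    ``> t``.  Float input is histogrammed into ``nbins`` equal bins over its
    range and the returned threshold is the upper edge of the chosen bin.
    Ties are broken toward the lowest threshold.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    vmin = values.min()
    vmax = values.max()
    if vmin == vmax:
        raise ValueError("constant input has no threshold")

    if np.issubdtype(values.dtype, np.integer) and int(vmax) - int(vmin) < nbins:
        levels = np.arange(int(vmin), int(vmax) + 1)
        counts = np.bincount((values.astype(np.int64) - int(vmin)).astype(np.intp),
                             minlength=levels.size).astype(float)
        centers = levels.astype(float)
    else:
        counts, edges = np.histogram(values.astype(float), bins=nbins,
                                     range=(float(vmin), float(vmax)))
        counts = counts.astype(float)
        centers = edges[1:]  # upper bin edges serve as candidate thresholds

    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    moment = np.cumsum(counts * centers)
    mean_total = moment[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = moment / w0
        m1 = (mean_total - moment) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    sigma_b[-1] = -1.0  # split must leave the upper class nonempty
    best = int(np.argmax(sigma_b))
    return float(centers[best])


def mean_direction_gfi(stack: "FeatureStack", mu: int) -> np.ndarray:
    """Pixelwise mean of the responses over all scales at direction ``mu``."""
    if not (0 <= mu < stack.n_directions):
        raise ValueError(f"direction index {mu} out of range")
    return stack.responses[mu].mean(axis=0)


@dataclass
class CandidateRegion:
    """Search region for one disc's threshold segmentation."""

    mask: np.ndarray
    source_box: tuple  # (top, bottom, left, right), inclusive
    boundary_fit: dict | None
    #: foreground pixel count of the Otsu-binarized max direction-mean map
    binary_area: int
    #: area of the *initial* candidate region (box intersect spinal band),
    #: before the lateral boundary-curve refinement
    initial_area: int = 0

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _box_slices(box) -> tuple:
    top, bottom, left, right = box
    return slice(top, bottom + 1), slice(left, right + 1)


def box_region(box, curves: "SpinalCurves", shape: tuple,
               binary_area: int) -> CandidateRegion:
    """Fallback / comparison region: disc box intersected with the spinal band."""
    mask = np.zeros(shape, dtype=bool)
    rs, cs = _box_slices(box)
    mask[rs, cs] = True
    cols = np.arange(shape[1])
    for r in range(shape[0]):
        mask[r] &= (cols >= curves.left[r]) & (cols <= curves.right[r])
    area = int(mask.sum())
    return CandidateRegion(mask=mask, source_box=tuple(box), boundary_fit=None,
                           binary_area=binary_area, initial_area=area)


def build_candidate_region(detection: "DiscDetection", curves: "SpinalCurves",
                           stack: "FeatureStack") -> CandidateRegion:
    """Derive the disc's candidate region from the Gabor features.

    The direction with maximal mean response energy inside the box selects the
    direction-mean feature map; its Otsu binarization inside the box (the
    disc's superior/inferior edge ridges) provides (a) the foreground area
    used by the adaptive threshold and (b) per-column outermost foreground
    rows to which quadratic upper/lower boundary curves are fitted.  The
    pixels enclosed between the two curves, laterally bounded by the spinal
    curves and the box, form the region.  If the binary map is empty the
    region falls back to box-intersect-band with a logged warning.
    """
    box = detection.box
    shape = stack.image_shape
    rs, cs = _box_slices(box)
    top, bottom, left, right = box

    scale_means = stack.responses.mean(axis=1)  # (S, M, N)
    energies = scale_means[:, rs, cs].sum(axis=(1, 2))
    mu_star = int(np.argmax(energies))
    gmap = scale_means[mu_star]

    sub = gmap[rs, cs]
    try:
        thr = otsu_threshold(sub)
    except ValueError:
        logger.warning("disc box has constant feature map; using box region")
        return box_region(box, curves, shape, binary_area=0)
    binary = sub > thr
    # noise speckles corrupt both the area estimate and the boundary fit;
    # keep only components of comparable size to the largest one
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        good = 1 + np.flatnonzero(sizes >= 0.1 * sizes.max())
        binary = np.isin(labels, good)
    binary_area = int(binary.sum())
    if binary_area == 0:
        logger.warning("empty binary feature map in disc box; using box region")
        return box_region(box, curves, shape, binary_area=0)

    rows_rel, cols_rel = np.nonzero(binary)
    cols_with_fg = np.unique(cols_rel)
    top_pts, bot_pts = [], []
    for cc in cols_with_fg:
        rr = rows_rel[cols_rel == cc]
        top_pts.append((cc + left, rr.min() + top))
        bot_pts.append((cc + left, rr.max() + top))

    def fit(points, side):
        c = np.array([p[0] for p in points], dtype=float)
        r = np.array([p[1] for p in points], dtype=float)
        deg = 2 if len(points) >= 3 else len(points) - 1
        if deg <= 0:
            return np.poly1d([r[0]])
        poly = np.poly1d(np.polyfit(c, r, deg))
        # A least-squares fit runs through the point cloud; shift it outward
        # so it envelopes (90th percentile) the outermost foreground rows.
        resid = poly(c) - r  # positive where the fit lies below the point
        if side == "top":
            return poly - float(np.percentile(resid, 90))
        return poly + float(np.percentile(-resid, 90))

    fit_t = fit(top_pts, "top")
    fit_b = fit(bot_pts, "bottom")

    mask = np.zeros(shape, dtype=bool)
    rows = np.arange(shape[0])
    for c in range(left, right + 1):
        lo = max(float(fit_t(c)), float(top))
        hi = min(float(fit_b(c)), float(bottom))
        mask[:, c] = (rows >= np.ceil(lo)) & (rows <= np.floor(hi))
        inside_band = (c >= curves.left) & (c <= curves.right)
        mask[:, c] &= inside_band
    initial = box_region(box, curves, shape, binary_area=binary_area)
    if not mask.any():
        logger.warning("candidate region empty after boundary fit; "
                       "using box region")
        return initial
    return CandidateRegion(mask=mask, source_box=tuple(box),
                           boundary_fit={"top": fit_t, "bottom": fit_b,
                                         "mu": mu_star},
                           binary_area=binary_area,
                           initial_area=initial.initial_area)


@dataclass
class ThresholdState:
    """Bookkeeping for the area-constrained threshold iteration."""

    T: float
    T_init: float
    A1: float
    A2: float
    T1: float = field(init=False)
    T2: float = field(init=False)
    iterations: int = 0

    def __post_init__(self) -> None:
        self.T1 = min(self.A1, self.A2)
        self.T2 = max(self.A1, self.A2)


def init_threshold_state(image: np.ndarray,
                         region: CandidateRegion) -> ThresholdState:
    """Initialize the threshold state from Otsu inside the region.

    ``A1`` is the candidate-region area minus the binary feature-map area
    (clamped to 10% of the region area if nonpositive); ``A2`` is half the
    binary feature-map area.
    """
    vals = image[region.mask]
    t_init = otsu_threshold(vals)
    area = region.area
    a1 = float(area - region.binary_area)
    if a1 <= 0:
        logger.warning("nonpositive area difference A1 (%.0f); iteration "
                       "will keep the Otsu threshold", a1)
    a2 = region.binary_area / 2.0
    if a2 <= 0:
        a2 = 0.5 * area
    return ThresholdState(T=t_init, T_init=t_init, A1=a1, A2=a2)


def adaptive_threshold(image: np.ndarray, region: CandidateRegion,
                       state: ThresholdState | None = None,
                       max_iter: int = MAX_THRESHOLD_ITERATIONS) -> float:
    """Area-constrained local threshold by bisection on the grayscale range.

    Starting from the Otsu threshold, the foreground area of
    ``image >= T`` inside the region is driven into ``[T1, T2]``: the
    threshold is raised when the area exceeds ``T2`` and lowered when below
    ``T1``, with a step that halves every iteration, for at most ``max_iter``
    iterations.
    """
    if state is None:
        state = init_threshold_state(image, region)
    if state.A1 <= 0:
        # degenerate geometry (region no larger than the feature blob):
        # the area window is meaningless, keep the Otsu initialization
        return float(state.T_init)
    vals = image[region.mask]
    gmin, gmax = float(vals.min()), float(vals.max())
    T = float(state.T)
    step = (gmax - gmin) / 2.0
    # When the foreground-area function jumps over [T1, T2] (sharp contrast),
    # no threshold lands inside the window; keep the best feasible iterate:
    # the one with the smallest area still >= T1.
    best_T, best_area = T, np.inf
    for it in range(max_iter):
        area = int(np.count_nonzero(vals >= T))
        if state.T1 <= area <= state.T2:
            best_T = T
            break
        if area >= state.T1 and area < best_area:
            best_T, best_area = T, area
        if area > state.T2:
            T += step
        else:
            T -= step
        T = min(max(T, gmin), gmax)
        step /= 2.0
        state.iterations = it + 1
    state.T = best_T
    return best_T


def coarse_segment(image: np.ndarray, region: CandidateRegion,
                   t_ivd: float) -> np.ndarray:
    """Binary mask of region pixels at or above the threshold."""
    return (image >= t_ivd) & region.mask


_DISK3 = np.array([[0, 1, 0],
                   [1, 1, 1],
                   [0, 1, 0]], dtype=bool)

_NEIGHBORS8 = np.array([[1, 1, 1],
                        [1, 0, 1],
                        [1, 1, 1]], dtype=int)


def _majority_pass(mask: np.ndarray) -> np.ndarray:
    """One pass of the 8-neighborhood majority rule: a background pixel with
    at least 5 foreground neighbors becomes foreground."""
    counts = ndimage.convolve(mask.astype(int), _NEIGHBORS8, mode="constant")
    return mask | (~mask & (counts >= 5))


def postprocess(mask: np.ndarray) -> np.ndarray:
    """Morphological cleanup of a coarse disc mask.

    Fill holes, erode and dilate with a 3x3 disc element, apply one pass of
    an 8-neighborhood majority rule, then keep the largest 8-connected
    component.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        logger.warning("postprocess received an empty mask")
        return mask.copy()
    out = ndimage.binary_fill_holes(mask)
    out = ndimage.binary_erosion(out, structure=_DISK3)
    out = ndimage.binary_dilation(out, structure=_DISK3)
    out = _majority_pass(out)
    labels, n = ndimage.label(out, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        logger.warning("mask vanished during post-processing")
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labels == keep


@dataclass
class SegmentationResult:
    mask: np.ndarray
    coarse_mask: np.ndarray
    T_IVD: float
    disc_id: int
    region: CandidateRegion | None = None


def segment_disc(image: np.ndarray, detection: "DiscDetection",
                 curves: "SpinalCurves", stack: "FeatureStack",
                 disc_id: int = 0,
                 use_gfi_region: bool = True) -> SegmentationResult:
    """Segment one localized disc from the grayscale image.

    ``use_gfi_region=False`` is the feature-free ablation: the region is the
    raw disc box and the threshold is plain Otsu, since the boundary curves
    and the A1/A2 area window are both derived from the feature maps.
    """
    if use_gfi_region:
        region = build_candidate_region(detection, curves, stack)
        state = init_threshold_state(image, region)
        t_ivd = adaptive_threshold(image, region, state)
    else:
        mask = np.zeros(stack.image_shape, dtype=bool)
        rs, cs = _box_slices(detection.box)
        mask[rs, cs] = True
        region = CandidateRegion(mask=mask, source_box=tuple(detection.box),
                                 boundary_fit=None, binary_area=0,
                                 initial_area=int(mask.sum()))
        t_ivd = otsu_threshold(image[region.mask])
    coarse = coarse_segment(image, region, t_ivd)
    final = postprocess(coarse)
    return SegmentationResult(mask=final, coarse_mask=coarse, T_IVD=t_ivd,
                              disc_id=disc_id, region=region)
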