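"""Disc localization from the disc-direction feature image.

Pipeline: disc feature image -> elliptical median filter -> row profile
restricted to the spinal band -> candidate disc rows (peak picking with
spacing priors) -> candidate columns per inter-disc band -> bounding boxes
from profile minima/zeros -> per-box angle estimate -> centroid-corrected
centers.

Coordinates are (row, col), 0-based.  A detection's ``center`` is
``(row, col)``; the row is the disc's vertical position and the column its
horizontal position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .gabor import FeatureStack, directional_feature
from .segment import otsu_threshold
from .spine import DetectionFailure, SpinalCurves

logger = logging.getLogger(__name__)

__all__ = [
    "DISC_U1",
    "DISC_U2",
    "Priors",
    "DiscFeature",
    "DiscDetection",
    "compute_disc_gfi",
    "elliptical_footprint",
    "elliptical_median",
    "row_profile",
    "candidate_rows",
    "candidate_cols",
    "compute_boxes",
    "estimate_angle",
    "refine_centers",
    "localize_discs",
]

#: direction subsets for the disc feature (16-direction bank):
#: U1 near the disc long axis (near-horizontal structures), U2 near-vertical.
DISC_U1 = (7, 8, 9, 10, 11)
DISC_U2 = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class Priors:
    """Anatomical priors for the disc chain.

    Vertical offsets between adjacent discs span 20-50 mm; the pixel defaults
    (25-60 px) correspond to ~0.8 mm/px and are used when no pixel spacing is
    available.  Most disc abscissae lie on a common vertical line within
    ``x_alignment_tol``; the two most inferior discs are exempt from
    alignment snapping.  Disc tilt is limited to ``angle_range`` degrees from
    horizontal.
    """

    min_dy: float = 25.0
    max_dy: float = 60.0
    x_alignment_tol: float = 15.0
    angle_range: float = 30.0
    min_dy_mm: float = 20.0
    max_dy_mm: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.min_dy < self.max_dy):
            raise ValueError("require 0 < min_dy < max_dy")

    @classmethod
    def from_spacing(cls, pixel_spacing_mm: float | None, **kw) -> "Priors":
        """Priors with the mm window converted through the pixel spacing."""
        if pixel_spacing_mm is None or pixel_spacing_mm <= 0:
            return cls(**kw)
        base = cls()
        return cls(min_dy=base.min_dy_mm / pixel_spacing_mm,
                   max_dy=base.max_dy_mm / pixel_spacing_mm, **kw)


@dataclass
class DiscFeature:
    g_disc: np.ndarray
    g_mdisc: np.ndarray
    gh: np.ndarray
    gv_per_band: list


@dataclass
class DiscDetection:
    center: tuple  # (row, col)
    box: tuple  # (top, bottom, left, right), inclusive
    angle: float  # degrees from horizontal, clamped to +-45
    coarse_center: tuple


def compute_disc_gfi(stack: FeatureStack) -> np.ndarray:
    """Disc feature image from a 16-direction response stack."""
    if stack.n_directions != 16:
        raise ValueError(
            f"disc feature requires a 16-direction bank, got {stack.n_directions}")
    return directional_feature(stack, DISC_U1, DISC_U2)


def elliptical_footprint(long_axis: int = 44, minor_axis: int = 17) -> np.ndarray:
    """Horizontal-axis-aligned elliptical boolean footprint.

    ``long_axis`` spans columns, ``minor_axis`` rows; the grid has odd side
    lengths ``2*floor(axis/2) + 1``.
    """
    if long_axis <= 0 or minor_axis <= 0 or long_axis < minor_axis:
        raise ValueError("require long_axis >= minor_axis > 0")
    a = long_axis / 2.0
    b = minor_axis / 2.0
    half_c = int(long_axis // 2)
    half_r = int(minor_axis // 2)
    dr = np.arange(-half_r, half_r + 1)[:, None]
    dc = np.arange(-half_c, half_c + 1)[None, :]
    return (dc / a) ** 2 + (dr / b) ** 2 <= 1.0


def elliptical_median(g_disc: np.ndarray, long_axis: int = 44,
                      minor_axis: int = 17) -> np.ndarray:
    """Median filter with an elliptical template, reflective boundary."""
    fp = elliptical_footprint(long_axis, minor_axis)
    return ndimage.median_filter(np.asarray(g_disc, dtype=float),
                                 footprint=fp, mode="reflect")


def row_profile(g_mdisc: np.ndarray, curves: SpinalCurves) -> np.ndarray:
    """Per-row sum of the filtered feature between the spinal curves.

    Rows outside ``curves.valid_rows`` are zero.
    """
    M, N = g_mdisc.shape
    gh = np.zeros(M, dtype=float)
    first, last = curves.valid_rows
    for r in range(max(0, first), min(M, last + 1)):
        lo = int(curves.left[r])
        hi = int(curves.right[r])
        gh[r] = g_mdisc[r, lo:hi + 1].sum()
    return gh


def _smooth(profile: np.ndarray, width: int = 5) -> np.ndarray:
    return ndimage.uniform_filter1d(np.asarray(profile, dtype=float),
                                    size=width, mode="nearest")


def _debase(profile: np.ndarray, width: int = 51) -> np.ndarray:
    """Remove the slowly varying noise floor via a morphological opening.

    The structuring width exceeds any disc bump, so bumps survive while the
    baseline (noise energy accumulated across the spinal band) is removed;
    valleys between discs then drop back to ~0 even on noisy images.
    """
    baseline = ndimage.grey_opening(profile, size=width, mode="nearest")
    return np.clip(profile - baseline, 0.0, None)


def candidate_rows(gh: np.ndarray, priors: Priors, smooth_width: int = 5,
                   prominence_frac: float = 0.05,
                   height_frac: float = 0.05) -> np.ndarray:
    """Candidate disc rows from the smoothed row profile.

    Local maxima with prominence at least ``prominence_frac * max`` are
    found; groups of peaks closer than ``priors.min_dy`` are merged to their
    profile-weighted mean row; merged candidates whose profile value falls
    below ``height_frac`` times the strongest candidate (noise-floor peaks
    that cannot be discs) are dropped.
    """
    gh = np.asarray(gh, dtype=float)
    if gh.min() < 0:
        raise ValueError("row profile must be nonnegative")
    smoothed = _smooth(gh, smooth_width)
    if smoothed.max() <= 0:
        raise DetectionFailure("row profile is identically zero")
    peaks, _ = find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
    if peaks.size == 0:
        raise DetectionFailure("no candidate disc rows found")

    groups = []
    group = [peaks[0]]
    for pk in peaks[1:]:
        if pk - group[-1] < priors.min_dy:
            group.append(pk)
        else:
            groups.append(group)
            group = [pk]
    groups.append(group)

    # A chained group spanning at least min_dy straddles more than one disc
    # (e.g. twin edge peaks of adjacent discs); split it at its widest
    # internal gap until every group is tighter than min_dy.
    def split(g):
        if len(g) < 2 or (g[-1] - g[0]) < priors.min_dy:
            return [g]
        gaps = np.diff(g)
        cut = int(np.argmax(gaps)) + 1
        return split(g[:cut]) + split(g[cut:])

    out = []
    for group in groups:
        for g in split(group):
            arr = np.array(g, dtype=float)
            wts = smoothed[g]
            out.append(int(round(np.average(arr, weights=wts))))
    out = np.array(sorted(out), dtype=int)
    heights = smoothed[out]
    keep = heights >= height_frac * heights.max()
    if not keep.all():
        logger.info("dropping %d weak row candidates", int((~keep).sum()))
    return out[keep]


def _band_bounds(y_list: np.ndarray, M: int) -> list:
    """Per-disc row intervals delimited by midpoints of adjacent candidates.

    Each interval is additionally clipped to half the median candidate
    spacing on either side, so a single spurious neighbor cannot swallow or
    truncate a genuine disc's band.
    """
    y = np.asarray(y_list)
    bounds = []
    if y.size == 1:
        half = 30
        bounds.append((max(0, y[0] - half), min(M - 1, y[0] + half)))
        return bounds
    mids = ((y[:-1] + y[1:]) // 2).astype(int)
    ext = max(1, int(np.median(np.diff(y)) // 2))
    for i in range(y.size):
        top = (y[i] - ext) if i == 0 else max(mids[i - 1], y[i] - ext)
        bot = (y[i] + ext) if i == y.size - 1 else min(mids[i], y[i] + ext)
        bounds.append((max(0, int(top)), min(M - 1, int(bot))))
    return bounds


def candidate_cols(g_mdisc: np.ndarray, y_list: np.ndarray,
                   curves: SpinalCurves, priors: Priors) -> tuple:
    """Candidate disc columns and per-band column profiles.

    Each disc's band (midpoints of adjacent candidate rows) yields a column
    profile of the filtered feature restricted to the spinal band; its argmax
    is the coarse column.  Columns deviating from the median by more than
    ``x_alignment_tol`` are snapped to the best column within tolerance of
    the median, except for the two most inferior discs.
    """
    M, N = g_mdisc.shape
    y = np.asarray(y_list, dtype=int)
    if y.size == 0:
        raise DetectionFailure("no candidate rows supplied")
    bounds = _band_bounds(y, M)
    cols = np.arange(N)
    gv_list = []
    x_list = []
    for (top, bot) in bounds:
        gv = np.zeros(N, dtype=float)
        for r in range(top, bot + 1):
            inside = (cols >= curves.left[r]) & (cols <= curves.right[r])
            gv[inside] += g_mdisc[r, inside]
        gv_list.append(gv)
        x_list.append(int(np.argmax(gv)))
    x_arr = np.array(x_list, dtype=int)

    if x_arr.size >= 3:
        med = float(np.median(x_arr))
        tol = priors.x_alignment_tol
        for i in range(x_arr.size - 2):  # most inferior two are exempt
            if abs(x_arr[i] - med) > tol:
                lo = max(0, int(np.floor(med - tol)))
                hi = min(N - 1, int(np.ceil(med + tol)))
                x_arr[i] = lo + int(np.argmax(gv_list[i][lo:hi + 1]))
                logger.info("snapped disc %d column toward the median line", i)
    return x_arr, gv_list


def _scan_to_min_or_zero(profile: np.ndarray, start: int, step: int,
                         zero_tol: float, depth: float) -> int:
    """Index of the nearest *deep* local minimum or (near-)zero of
    ``profile`` moving from ``start`` in direction ``step``.

    A local minimum only terminates the scan when its value drops below
    ``depth``; shallow dips (e.g. between the twin edge responses of one
    disc) are walked through.
    """
    n = profile.size
    i = start + step
    while 0 < i < n - 1:
        if profile[i] <= zero_tol:
            return i
        if (profile[i] <= profile[i - 1] and profile[i] <= profile[i + 1]
                and profile[i] < depth):
            return i
        i += step
    return min(max(i, 0), n - 1)


def compute_boxes(gh: np.ndarray, gv_per_band: list, y_list: np.ndarray,
                  x_list: np.ndarray, smooth_width: int = 5,
                  valley_frac: float = 0.5) -> tuple:
    """Per-disc bounding boxes from profile minima and zeros.

    Top/bottom bounds come from scanning the (smoothed) row profile up/down
    from each candidate row to the nearest zero or deep local minimum (below
    ``valley_frac`` times the profile value at the candidate); left/right
    bounds likewise from the disc's band column profile.  Degenerate boxes
    are dropped with a warning; returns ``(boxes, kept_indices)``.
    """
    gh_s = _debase(_smooth(gh, smooth_width))
    zero_h = 1e-9 * max(gh_s.max(), 1e-300)
    boxes = []
    kept = []
    for i, (yy, xx) in enumerate(zip(y_list, x_list)):
        if gh_s[int(yy)] <= zero_h:
            logger.warning("dropping disc %d: no row-profile signal", i)
            continue
        depth_h = valley_frac * gh_s[int(yy)]
        top = _scan_to_min_or_zero(gh_s, int(yy), -1, zero_h, depth_h)
        bottom = _scan_to_min_or_zero(gh_s, int(yy), +1, zero_h, depth_h)
        gv_s = _debase(_smooth(gv_per_band[i], smooth_width))
        zero_v = 1e-9 * max(gv_s.max(), 1e-300)
        depth_v = valley_frac * gv_s[int(xx)]
        left = _scan_to_min_or_zero(gv_s, int(xx), -1, zero_v, depth_v)
        right = _scan_to_min_or_zero(gv_s, int(xx), +1, zero_v, depth_v)
        if bottom <= top or right <= left:
            logger.warning("dropping disc %d: degenerate box", i)
            continue
        boxes.append((int(top), int(bottom), int(left), int(right)))
        kept.append(i)
    return boxes, kept


def estimate_angle(stack: FeatureStack, box: tuple) -> float:
    """Disc tilt estimate from the dominant response direction in the box.

    The direction index maximizing mean response energy (summed over scales)
    maps to a structure angle ``mu * 180 / S - 90`` degrees, clamped to
    +-45.  Positive angles tilt the disc's right end inferiorly.
    """
    top, bottom, left, right = box
    sub = stack.responses[:, :, top:bottom + 1, left:right + 1]
    energy = sub.mean(axis=(1, 2, 3))
    mu_star = int(np.argmax(energy))
    angle = mu_star * 180.0 / stack.n_directions - 90.0
    return float(np.clip(angle, -45.0, 45.0))


def refine_centers(g_mdisc: np.ndarray, boxes: list,
                   coarse_centers: list) -> list:
    """Centroid correction of the coarse centers.

    The filtered feature inside each box is Otsu-binarized; the foreground
    centroid replaces the coarse center.  Falls back to the coarse center
    when the foreground is empty.
    """
    refined = []
    for box, coarse in zip(boxes, coarse_centers):
        top, bottom, left, right = box
        sub = g_mdisc[top:bottom + 1, left:right + 1]
        try:
            thr = otsu_threshold(sub)
            fg = sub > thr
        except ValueError:
            fg = np.zeros_like(sub, dtype=bool)
        if fg.any():
            rr, cc = np.nonzero(fg)
            center = (top + float(rr.mean()), left + float(cc.mean()))
        else:
            center = (float(coarse[0]), float(coarse[1]))
        refined.append(center)
    return refined


def localize_discs(stack: FeatureStack, curves: SpinalCurves,
                   priors: Priors | None = None,
                   median_long_axis: int = 44,
                   median_minor_axis: int = 17) -> tuple:
    """Full localization stage; returns ``(detections, DiscFeature)``."""
    if priors is None:
        priors = Priors()
    g_disc = compute_disc_gfi(stack)
    g_mdisc = elliptical_median(g_disc, median_long_axis, median_minor_axis)
    gh = row_profile(g_mdisc, curves)
    y_list = candidate_rows(gh, priors)
    x_list, gv_list = candidate_cols(g_mdisc, y_list, curves, priors)
    boxes, kept = compute_boxes(gh, gv_list, y_list, x_list)
    coarse = [(int(y_list[i]), int(x_list[i])) for i in kept]
    centers = refine_centers(g_mdisc, boxes, coarse)
    detections = []
    for box, coarse_c, center in zip(boxes, coarse, centers):
        # keep the center inside the box (contract); centroid cannot leave it,
        # but the coarse fallback might sit on the edge after snapping
        angle = estimate_angle(stack, box)
        detections.append(DiscDetection(center=center, box=box, angle=angle,
                                        coarse_center=coarse_c))
    feature = DiscFeature(g_disc=g_disc, g_mdisc=g_mdisc, gh=gh,
                          gv_per_band=gv_list)
    return detections, feature
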