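"""Detection of the left and right spinal edge curves.

The spine feature image is the clipped difference between near-vertical and
near-horizontal direction-subset means of the Gabor responses; its two
strongest vertical ridges are the edges of the spinal column band.  The edges
are found in three stages: (1) a banded cumulative column profile locates the
column interval occupied by the spine, (2) crossing points of the edges with
the band midline seed the search, (3) the edges are traced row-by-row with a
local ridge tracker.

Coordinates are (row, col), 0-based, row increasing superior -> inferior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gabor import FeatureStack, directional_feature
from .segment import otsu_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "SPINE_U1",
    "SPINE_U2",
    "SpineFeature",
    "SpinalCurves",
    "DetectionFailure",
    "compute_spine_gfi",
    "banded_cumulative",
    "find_centers",
    "trace_curves",
    "detect_spine",
]

#: direction subsets for the spine feature (16-direction bank):
#: U1 near-vertical structure orientations, U2 near-horizontal.
SPINE_U1 = (0, 1, 2, 3, 4, 5, 14, 15)
SPINE_U2 = (7, 8, 9, 10, 11)


class DetectionFailure(RuntimeError):
    """Raised when a detection stage cannot produce a result."""


@dataclass
class SpineFeature:
    g_spine: np.ndarray
    G_cum: np.ndarray
    p: int
    center_col: int
    left_center: tuple  # (row, col)
    right_center: tuple


@dataclass
class SpinalCurves:
    """Per-row column index of the left and right spinal edges."""

    left: np.ndarray
    right: np.ndarray
    valid_rows: tuple  # (first_row, last_row) inclusive

    def band_mask(self, shape: tuple) -> np.ndarray:
        """Binary mask of the region enclosed by the two curves."""
        mask = np.zeros(shape, dtype=bool)
        cols = np.arange(shape[1])
        for r in range(shape[0]):
            mask[r] = (cols >= self.left[r]) & (cols <= self.right[r])
        return mask


def compute_spine_gfi(stack: FeatureStack) -> np.ndarray:
    """Spine feature image from a 16-direction response stack."""
    if stack.n_directions != 16:
        raise ValueError(
            f"spine feature requires a 16-direction bank, got {stack.n_directions}")
    return directional_feature(stack, SPINE_U1, SPINE_U2)


def _band_rows(M: int, p: int) -> tuple:
    """First/last (exclusive) row of the central band of height p."""
    top = (M - p) // 2
    return top, top + p


def banded_cumulative(g_spine: np.ndarray, p: int) -> np.ndarray:
    """Cumulative column sum over the central band of ``p`` rows.

    Element ``n`` is the sum of ``g_spine`` over columns ``0..n`` and the
    ``p`` central rows; nondecreasing for nonnegative input.
    """
    M, N = g_spine.shape
    if not (1 <= p <= M):
        raise ValueError(f"band height p={p} out of range [1, {M}]")
    top, bot = _band_rows(M, p)
    col_sums = g_spine[top:bot].sum(axis=0)
    return np.cumsum(col_sums)


def find_centers(g_spine: np.ndarray, G_cum: np.ndarray, p: int | None = None,
                 plateau_frac: float = 0.25) -> tuple:
    """Locate the spine center column and the two edge/midline crossing points.

    The center column is the midpoint of the longest low-slope plateau of the
    cumulative profile (slope below ``plateau_frac`` times the mean slope).
    From the center, the band midline is scanned outward; the first column on
    each side whose band-averaged spine response exceeds an Otsu threshold is
    taken as the edge crossing point.

    Returns ``(center_col, left_center, right_center)`` with the centers as
    (row, col) tuples on the band midline.
    """
    M, N = g_spine.shape
    if p is None:
        p = max(1, M // 3)
    top, bot = _band_rows(M, p)
    mid_row = (top + bot) // 2

    slopes = np.diff(G_cum, prepend=0.0)
    mean_slope = slopes.mean()
    if mean_slope <= 0:
        raise DetectionFailure("blank spine feature: cumulative profile is flat")
    low = slopes < plateau_frac * mean_slope

    # Runs of low-slope columns.  The plateau between the two edge rises sits
    # at mid-height of the cumulative curve, which distinguishes it from the
    # flat background stretches before the first edge (~0) and after the
    # second (~total); keep only mid-height runs and take the longest.
    total = G_cum[-1]
    runs = []  # (length, start)
    run_len, run_start = 0, 0
    for n in range(N + 1):
        if n < N and low[n]:
            if run_len == 0:
                run_start = n
            run_len += 1
        elif run_len > 0:
            mid = run_start + run_len // 2
            frac = G_cum[mid] / total
            if 0.15 < frac < 0.85:
                runs.append((run_len, run_start))
            run_len = 0
    if not runs:
        raise DetectionFailure("no mid-height plateau found in cumulative profile")
    best_len, best_start = max(runs)
    center_col = best_start + best_len // 2

    band = g_spine[top:bot]
    try:
        thr = otsu_threshold(band.ravel())
    except ValueError as exc:
        raise DetectionFailure(f"cannot threshold spine band: {exc}") from exc
    # scan a narrow neighborhood of the band midline: on a curved spine the
    # edge columns drift with the row, so a whole-band average would smear
    # the edge response below the pixel-level threshold
    lo_r = max(top, mid_row - 4)
    hi_r = min(bot, mid_row + 5)
    profile = g_spine[lo_r:hi_r].mean(axis=0)

    left_col = None
    for c in range(center_col, -1, -1):
        if profile[c] > thr:
            left_col = c
            break
    right_col = None
    for c in range(center_col, N):
        if profile[c] > thr:
            right_col = c
            break
    if left_col is None or right_col is None or left_col == right_col:
        raise DetectionFailure(
            "edge crossing points not found on the band midline "
            f"(center_col={center_col})")
    return center_col, (mid_row, left_col), (mid_row, right_col)


def _trace_one(g_spine: np.ndarray, start: tuple, w: int, floor: float,
               patience: int) -> tuple:
    """Ridge-track one edge from ``start`` up and down.

    Returns (cols, first_valid, last_valid): per-row column array plus the
    inclusive row range actually tracked before the ridge was lost.
    """
    M, N = g_spine.shape
    r0, c0 = start
    cols = np.empty(M, dtype=int)
    cols[r0] = c0

    def march(rows):
        prev = c0
        lost = 0
        last_good = r0
        for r in rows:
            lo = max(0, prev - w)
            hi = min(N, prev + w + 1)
            seg = g_spine[r, lo:hi]
            c = lo + int(np.argmax(seg))
            if g_spine[r, c] > floor:
                lost = 0
                last_good = r
                prev = c
            else:
                lost += 1
                c = prev
            cols[r] = c
            if lost > patience:
                break
        return last_good

    last = march(range(r0 + 1, M))
    first = march(range(r0 - 1, -1, -1))
    # extend lost rows with the last good column
    cols[:first] = cols[first]
    cols[last + 1:] = cols[last]
    return cols, first, last


def trace_curves(g_spine: np.ndarray, left_center: tuple, right_center: tuple,
                 w: int = 3, patience: int = 10,
                 floor_frac: float = 0.02) -> SpinalCurves:
    """Trace left and right spinal edges from their midline crossing points.

    At each row the tracker picks the response maximum within ``+-w`` columns
    of the previous row's position; the track is truncated (with a logged
    warning) after more than ``patience`` consecutive rows with no response
    above ``floor_frac * max(g_spine)``.
    """
    floor = floor_frac * float(g_spine.max())
    left_cols, lf, ll = _trace_one(g_spine, left_center, w, floor, patience)
    right_cols, rf, rl = _trace_one(g_spine, right_center, w, floor, patience)
    first = max(lf, rf)
    last = min(ll, rl)
    M = g_spine.shape[0]
    if first > 0 or last < M - 1:
        logger.warning("spinal curve track truncated to rows [%d, %d] of %d",
                       first, last, M)
    # curves must not cross; clamp any overlap to a 1-px separation
    bad = left_cols >= right_cols
    if bad.any():
        mid = (left_cols[bad] + right_cols[bad]) // 2
        left_cols[bad] = mid
        right_cols[bad] = mid + 1
    return SpinalCurves(left=left_cols, right=right_cols,
                        valid_rows=(first, last))


def detect_spine(stack: FeatureStack, p: int | None = None,
                 plateau_frac: float = 0.25, w: int = 3,
                 patience: int = 10) -> tuple:
    """Full spine-edge detection; returns ``(SpineFeature, SpinalCurves)``."""
    g_spine = compute_spine_gfi(stack)
    M = g_spine.shape[0]
    if p is None:
        p = max(1, M // 3)
    G_cum = banded_cumulative(g_spine, p)
    center_col, left_center, right_center = find_centers(
        g_spine, G_cum, p=p, plateau_frac=plateau_frac)
    curves = trace_curves(g_spine, left_center, right_center, w=w,
                          patience=patience)
    feature = SpineFeature(g_spine=g_spine, G_cum=G_cum, p=p,
                           center_col=center_col, left_center=left_center,
                           right_center=right_center)
    return feature, curves
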