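"""Synthetic sagittal spine phantoms with exact ground truth.

A phantom is a near-vertical bright spinal column band (optionally curved)
containing a stack of bright elliptical discs separated by darker vertebral
bodies, over a dark background, with optional additive Gaussian noise and a
smooth multiplicative bias field.  All geometry (disc masks, centers, tilt
angles, band edges) is returned as ground truth.

Angle convention matches the detector: positive disc angles tilt the right
end of the disc inferiorly (clockwise on a displayed image).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "PhantomTruth", "generate"]


@dataclass(frozen=True)
class PhantomSpec:
    image_size: tuple = (512, 256)
    n_discs: int = 8
    disc_width: tuple = (26.0, 34.0)
    thickness_ratio: float = 0.4
    # The disc-direction subsets of a 16-direction bank cover structure tilts
    # of roughly [-11, +34] degrees; default tilts stay inside that span.
    angle_deg: tuple = (-10.0, 30.0)
    spacing_px: tuple = (46.0, 58.0)
    curvature_amp: float = 0.0
    curvature_cycles: float = 1.0
    band_width: float = 60.0
    disc_level: float = 220.0
    vertebra_level: float = 90.0
    background_level: float = 25.0
    cord_level: float = 140.0
    cord_width: float = 0.0
    # Bright subchondral endplate shells hugging each disc (T2-bright marrow
    # changes common in low-back-pain patients); they abut the disc boundary
    # and make naive grayscale thresholding over-segment.
    endplate_level: float = 175.0
    endplate_thickness: float = 2.0
    endplate_width_frac: float = 0.75
    noise_sigma: float = 0.0  # fraction of the dynamic range
    bias_amp: float = 0.0  # multiplicative inhomogeneity amplitude
    degenerate_discs: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discs < 1:
            raise ValueError("n_discs must be >= 1")
        if self.disc_width[0] < 25:
            raise ValueError("disc widths below 25 px are out of scope")
        if not (25 <= self.spacing_px[0] and self.spacing_px[1] <= 60):
            raise ValueError("disc spacing must stay within the 25-60 px prior")
        if not (self.spacing_px[0] <= self.spacing_px[1]):
            raise ValueError("invalid spacing range")
        if self.disc_width[1] > self.band_width:
            raise ValueError("discs wider than the spinal band")
        if not (0 < self.thickness_ratio <= 1):
            raise ValueError("thickness_ratio must be in (0, 1]")


@dataclass
class PhantomTruth:
    image: np.ndarray
    disc_masks: list
    centers: list  # (row, col) floats
    angles: list  # degrees
    spine_left: np.ndarray  # per-row column of the left band edge
    spine_right: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore

    @property
    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.image.shape, dtype=np.uint16)
        for k, m in enumerate(self.disc_masks, start=1):
            lab[m] = k
        return lab


def _ellipse_mask(shape, center, a, b, angle_deg) -> np.ndarray:
    """Filled rotated ellipse; a = semi-long-axis (columns at 0 deg)."""
    M, N = shape
    r0, c0 = center
    phi = math.radians(angle_deg)
    rr = np.arange(M)[:, None] - r0
    cc = np.arange(N)[None, :] - c0
    u = cc * math.cos(phi) + rr * math.sin(phi)
    v = -cc * math.sin(phi) + rr * math.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _vertical_extent(a: float, b: float, angle_deg: float) -> float:
    phi = math.radians(angle_deg)
    return math.hypot(a * math.sin(phi), b * math.cos(phi))


def _bias_field(shape, amp: float, rng) -> np.ndarray:
    """Smooth multiplicative field in [1-amp, 1+amp] from a low-res grid."""
    coarse = rng.standard_normal((4, 4))
    M, N = shape
    fieldv = ndimage.zoom(coarse, (M / 4, N / 4), order=3)[:M, :N]
    span = np.abs(fieldv).max()
    if span > 0:
        fieldv = fieldv / span
    return 1.0 + amp * fieldv


def generate(spec: PhantomSpec) -> PhantomTruth:
    """Render a phantom; deterministic for a given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    M, N = spec.image_size

    # disc geometry: width, thickness, tilt
    widths = rng.uniform(*spec.disc_width, size=spec.n_discs)
    angles = rng.uniform(*spec.angle_deg, size=spec.n_discs)
    thick = widths * spec.thickness_ratio
    levels = np.full(spec.n_discs, spec.disc_level)
    for i in spec.degenerate_discs:
        levels[i] *= 0.6
        thick[i] *= 0.7

    half_a = widths / 2.0
    half_b = thick / 2.0
    exts = np.array([_vertical_extent(a, b, ang)
                     for a, b, ang in zip(half_a, half_b, angles)])

    # vertical spacings: draw inside the range but never closer than the
    # discs' vertical extents allow (keeps masks disjoint)
    spacings = []
    for i in range(spec.n_discs - 1):
        lo = max(spec.spacing_px[0], exts[i] + exts[i + 1] + 3.0)
        hi = max(spec.spacing_px[1], lo)
        spacings.append(rng.uniform(lo, hi))
    spacings = np.array(spacings)

    total = spacings.sum() + exts[0] + exts[-1]
    margin = 40.0
    if total + 2 * margin > M:
        raise ValueError(
            f"disc stack of height {total:.0f}px (+margins) does not fit in "
            f"{M} rows")
    top = (M - total) / 2.0 + exts[0]
    rows = top + np.concatenate([[0.0], np.cumsum(spacings)])

    # spinal band centerline, optionally curved
    c0 = N / 2.0
    r_idx = np.arange(M)
    centerline = c0 + spec.curvature_amp * np.sin(
        2.0 * math.pi * spec.curvature_cycles * r_idx / M)
    half_band = spec.band_width / 2.0
    spine_left = np.round(centerline - half_band).astype(int)
    spine_right = np.round(centerline + half_band).astype(int)

    cols = np.interp(rows, r_idx, centerline)

    image = np.full((M, N), spec.background_level, dtype=float)
    col_grid = np.arange(N)[None, :]
    band = (col_grid >= spine_left[:, None]) & (col_grid <= spine_right[:, None])
    image[band] = spec.vertebra_level
    if spec.cord_width > 0:
        cord = ((col_grid > spine_right[:, None]) &
                (col_grid <= (spine_right[:, None] + spec.cord_width)))
        image[cord] = spec.cord_level

    disc_masks = []
    centers = []
    for i in range(spec.n_discs):
        mask = _ellipse_mask((M, N), (rows[i], cols[i]), half_a[i], half_b[i],
                             angles[i])
        mask &= band
        if spec.endplate_thickness > 0 and spec.endplate_level > 0:
            shell = _ellipse_mask(
                (M, N), (rows[i], cols[i]),
                half_a[i] * spec.endplate_width_frac,
                half_b[i] + spec.endplate_thickness, angles[i])
            image[shell & band & ~mask] = spec.endplate_level
        image[mask] = levels[i]
        disc_masks.append(mask)
        centers.append((float(rows[i]), float(cols[i])))

    if spec.bias_amp > 0:
        image *= _bias_field((M, N), spec.bias_amp, rng)
    if spec.noise_sigma > 0:
        dyn = spec.disc_level - spec.background_level
        image = image + rng.normal(0.0, spec.noise_sigma * dyn, size=(M, N))

    return PhantomTruth(image=image, disc_masks=disc_masks, centers=centers,
                        angles=angles.tolist(), spine_left=spine_left,
                        spine_right=spine_right, spec=spec)
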