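"""2-D Gabor filter bank construction and feature-image computation.

The bank is a grid of complex Gabor kernels over ``S`` directions and ``K``
scales.  Each kernel is an anisotropic Gaussian window modulated by a complex
sinusoid::

    psi(x, y) = 1 / (2*pi*sigma_x*sigma_y)
                * exp(-0.5 * ((x'/sigma_x)**2 + (y'/sigma_y)**2) + i*omega*x')

    x' =  x*cos(theta) + y*sin(theta)
    y' = -x*sin(theta) + y*cos(theta)

Coordinate and direction convention
-----------------------------------
Kernel coordinates are ``x`` = column offset, ``y`` = row offset, both
centered at the window midpoint, with rows increasing downward (image
convention).  ``theta`` is the orientation of the sinusoidal variation axis
``x'``: a kernel with ``theta ~ 0`` oscillates along the column axis and
therefore responds maximally to *vertical* elongated structures (e.g., the
near-vertical edges of the spinal column), while ``theta ~ pi/2`` responds to
*horizontal* elongated structures (e.g., disc long axes).  Directions are
sampled as ``theta_mu = mu * pi / S`` for ``mu = 0 .. S-1`` and center
frequencies follow a geometric ladder ``omega_v = omega_max / f**v`` for
``v = 0 .. K-1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

__all__ = [
    "GaborBankParams",
    "GaborKernel",
    "FeatureStack",
    "make_kernel",
    "build_bank",
    "apply_bank",
    "directional_feature",
]

#: bandwidth constant k = sqrt(2 ln 2)
K_CONST = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class GaborBankParams:
    """Parameter set for the full filter bank.

    Defaults give a 16-direction, 5-scale bank with upper angular frequency
    ``pi/2``, frequency spacing ``2**(1/4)`` and 31x31 kernels.  The Gaussian
    envelope widths are tied to the center frequency:
    ``sigma_x = sigma_x_factor * k / omega_v`` and
    ``sigma_y = sigma_y_factor * k / omega_v`` with ``k = sqrt(2 ln 2)``,
    so the envelope is twice as wide along ``y'`` as along ``x'``.
    """

    S: int = 16
    K: int = 5
    omega_max: float = math.pi / 2.0
    f: float = 2.0 ** 0.25
    window: int = 31
    k_const: float = K_CONST
    sigma_x_factor: float = 3.0
    sigma_y_factor: float = 6.0
    #: 'magnitude' (default) or 'real' -- which part of the complex response
    #: forms the feature images.
    response: str = "magnitude"

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError(f"S must be >= 2, got {self.S}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.omega_max <= 0 or self.f <= 1:
            raise ValueError("omega_max must be > 0 and f > 1")
        if self.response not in ("magnitude", "real"):
            raise ValueError(f"response must be 'magnitude' or 'real', got {self.response!r}")

    def theta(self, mu: int) -> float:
        """Direction angle ``mu * pi / S`` in radians."""
        return mu * math.pi / self.S

    def omega(self, v: int) -> float:
        """Center angular frequency ``omega_max / f**v`` in radians/pixel."""
        return self.omega_max / self.f ** v

    def sigma_x(self, v: int) -> float:
        return self.sigma_x_factor * self.k_const / self.omega(v)

    def sigma_y(self, v: int) -> float:
        return self.sigma_y_factor * self.k_const / self.omega(v)


@dataclass(frozen=True)
class GaborKernel:
    """One complex Gabor kernel (real/imaginary parts on a square grid)."""

    real_part: np.ndarray
    imag_part: np.ndarray
    theta: float
    omega: float

    @property
    def complex(self) -> np.ndarray:
        return self.real_part + 1j * self.imag_part


@dataclass
class FeatureStack:
    """Bank responses: array of shape ``(S, K, M, N)``, nonnegative when the
    bank was applied with magnitude responses."""

    responses: np.ndarray
    params: GaborBankParams = field(default=None)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple:
        return self.responses.shape

    @property
    def n_directions(self) -> int:
        return self.responses.shape[0]

    @property
    def n_scales(self) -> int:
        return self.responses.shape[1]

    @property
    def image_shape(self) -> tuple:
        return self.responses.shape[2:]


def make_kernel(theta: float, omega: float, sigma_x: float, sigma_y: float,
                window: int) -> GaborKernel:
    """Build one complex Gabor kernel on a ``window x window`` grid.

    Grid element ``[j, i]`` holds the kernel value at row offset
    ``y = j - window//2`` and column offset ``x = i - window//2``.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if sigma_x <= 0 or sigma_y <= 0 or omega <= 0:
        raise ValueError("sigma_x, sigma_y and omega must be positive")

    half = window // 2
    off = np.arange(-half, half + 1, dtype=float)
    y, x = np.meshgrid(off, off, indexing="ij")  # y: row offset, x: col offset
    xp = x * math.cos(theta) + y * math.sin(theta)
    yp = -x * math.sin(theta) + y * math.cos(theta)
    amp = 1.0 / (2.0 * math.pi * sigma_x * sigma_y)
    env = amp * np.exp(-0.5 * ((xp / sigma_x) ** 2 + (yp / sigma_y) ** 2))
    return GaborKernel(
        real_part=env * np.cos(omega * xp),
        imag_part=env * np.sin(omega * xp),
        theta=theta,
        omega=omega,
    )


def build_bank(params: GaborBankParams | None = None) -> list[list[GaborKernel]]:
    """Build the full bank as a nested list indexed ``bank[mu][v]``."""
    if params is None:
        params = GaborBankParams()
    bank = []
    for mu in range(params.S):
        row = []
        for v in range(params.K):
            row.append(
                make_kernel(
                    theta=params.theta(mu),
                    omega=params.omega(v),
                    sigma_x=params.sigma_x(v),
                    sigma_y=params.sigma_y(v),
                    window=params.window,
                )
            )
        bank.append(row)
    return bank


def apply_bank(image: np.ndarray,
               bank: list[list[GaborKernel]],
               params: GaborBankParams | None = None) -> FeatureStack:
    """Filter ``image`` with every kernel of the bank.

    Returns a :class:`FeatureStack` whose entry ``(mu, v)`` is the modulus
    (or real part, per ``params.response``) of the same-size 2-D convolution
    of the image with kernel ``(mu, v)``, using reflective boundary padding.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if params is None:
        params = GaborBankParams(S=len(bank), K=len(bank[0]),
                                 window=bank[0][0].real_part.shape[0])

    window = bank[0][0].real_part.shape[0]
    if min(image.shape) < window:
        raise ValueError(
            f"image {image.shape} smaller than kernel window {window}")

    S, K = len(bank), len(bank[0])
    M, N = image.shape
    kernels = np.empty((S * K, window, window), dtype=complex)
    for mu in range(S):
        for v in range(K):
            kernels[mu * K + v] = bank[mu][v].complex
    ph = pw = window // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="symmetric")

    # One image FFT, reused against every kernel (chunked to bound memory).
    Mp, Np = padded.shape
    P = sfft.next_fast_len(Mp + window - 1)
    Q = sfft.next_fast_len(Np + window - 1)
    img_f = sfft.fft2(padded, s=(P, Q))
    out = np.empty((S * K, M, N), dtype=float)
    r0, c0 = window - 1, window - 1  # start of the 'valid' block
    for lo in range(0, S * K, 16):
        hi = min(lo + 16, S * K)
        ker_f = sfft.fft2(kernels[lo:hi], s=(P, Q), axes=(1, 2))
        conv = sfft.ifft2(img_f[None] * ker_f, axes=(1, 2))
        block = conv[:, r0:r0 + M, c0:c0 + N]
        if params.response == "magnitude":
            out[lo:hi] = np.abs(block)
        else:
            out[lo:hi] = block.real
    return FeatureStack(responses=out.reshape(S, K, M, N), params=params)


def directional_feature(stack: FeatureStack,
                        U1,
                        U2) -> np.ndarray:
    """Clipped difference of direction-subset response means.

    Computes ``clip0( mean_{v, mu in U1} R[mu, v] - mean_{v, mu in U2}
    R[mu, v] )`` over all scales ``v``, setting negative values to zero.
    """
    U1 = list(U1)
    U2 = list(U2)
    if not U1 or not U2:
        raise ValueError("U1 and U2 must be nonempty")
    S = stack.n_directions
    for mu in (*U1, *U2):
        if not (0 <= mu < S):
            raise ValueError(f"direction index {mu} out of range [0, {S})")
    m1 = stack.responses[U1].mean(axis=(0, 1))
    m2 = stack.responses[U2].mean(axis=(0, 1))
    return np.clip(m1 - m2, 0.0, None)
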