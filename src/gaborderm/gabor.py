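"""Directional Gabor-wavelet filter bank and image subband decomposition.

A Gabor wavelet is a complex sinusoid modulated by a Gaussian envelope,

    g(x, y) = exp(-((x-x0)^2 + (y-y0)^2) / alpha^2)
              * exp(-i * 2*pi * (u0*(x-x0) + v0*(y-y0)) / beta^2)

with radial centre frequency ``omega0 = sqrt(u0^2 + v0^2)`` in cycles/pixel
and orientation ``theta = atan2(v0, u0)``.  Each filter is a bandpass probe
selective for one (scale, orientation) pair; convolving an image with a
small bank of them splits it into directional texture subbands.

The default bank uses two scales (0.176, 0.25 cycles/pixel) and two
orientations (0 deg, 90 deg), producing four subbands tagged GW1..GW4 in
scale-major, orientation-minor order:

    GW1 = (0.176, 0 deg), GW2 = (0.176, 90 deg),
    GW3 = (0.25, 0 deg),  GW4 = (0.25, 90 deg).

Kernels are DC-corrected (complex mean subtracted) so constant regions
produce zero response; filtering is true 2-D convolution with reflect
padding on the luma channel of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "GaborFilter",
    "GaborBank",
    "SubbandSet",
    "make_gabor_filter",
    "default_bank",
    "decompose",
    "render_subband",
    "to_luma",
    "SUBBAND_TAGS",
]

#: Default scales (cycles/pixel) and orientations (degrees) of the bank.
DEFAULT_SCALES = (0.176, 0.25)
DEFAULT_ORIENTATIONS = (0.0, 90.0)
SUBBAND_TAGS = ("GW1", "GW2", "GW3", "GW4")

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GaborFilter:
    """One complex directional Gabor kernel.

    Attributes
    ----------
    omega0 : float
        Radial centre frequency, cycles/pixel.
    theta : float
        Orientation, degrees.
    u0, v0 : float
        Cartesian frequency components, cycles/pixel
        (``u0 = omega0*cos(theta)``, ``v0 = omega0*sin(theta)``).
    x0, y0 : float
        Spatial centre of the envelope, pixels.
    alpha : float
        Gaussian envelope width, pixels.
    beta : float
        Phase-term scale, dimensionless.
    kernel : ndarray
        Complex square grid of odd side length, DC-corrected.
    """

    omega0: float
    theta: float
    u0: float
    v0: float
    alpha: float
    beta: float
    x0: float = 0.0
    y0: float = 0.0
    kernel: np.ndarray = field(default=None, repr=False, compare=False)
    #: complex mean subtracted from the raw kernel during DC correction
    dc_offset: complex = 0.0

    @property
    def support_radius(self) -> int:
        return self.kernel.shape[0] // 2


@dataclass(frozen=True)
class GaborBank:
    """An ordered collection of Gabor filters (scales x orientations)."""

    filters: tuple
    scales: tuple
    orientations: tuple

    def __post_init__(self):
        if len(self.filters) != len(self.scales) * len(self.orientations):
            raise ValueError(
                "bank must hold exactly scales x orientations filters"
            )

    def __len__(self) -> int:
        return len(self.filters)

    def __iter__(self):
        return iter(self.filters)

    def tags(self):
        """Subband tags GW1..GWn in scale-major, orientation-minor order."""
        return tuple(f"GW{i + 1}" for i in range(len(self.filters)))


@dataclass
class SubbandSet:
    """Original image plus its complex subband responses and renderings.

    ``responses`` maps tag -> complex HxW grid; ``provenance`` maps
    tag -> (scale, orientation); ``rendered`` maps tag -> HxWx3 uint8.
    """

    original: np.ndarray
    responses: dict
    provenance: dict
    rendered: dict


def to_luma(image: np.ndarray) -> np.ndarray:
    """Convert an image array to a float64 luma (grayscale) plane.

    Accepts HxW or HxWx3 arrays, integer or float; RGB is collapsed with
    ITU-R BT.601 weights.  Float inputs are used as-is (no rescaling) so
    the operation is linear in the input.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"expected HxW or HxWx3 image, got shape {arr.shape}")
    return arr


def make_gabor_filter(
    omega0: float,
    theta: float,
    alpha: float,
    beta: float = 1.0,
    support_radius: int | None = None,
    x0: float = 0.0,
    y0: float = 0.0,
) -> GaborFilter:
    """Sample a DC-corrected complex Gabor kernel on the integer grid.

    Parameters
    ----------
    omega0 : float
        Radial centre frequency in cycles/pixel (> 0).
    theta : float
        Orientation in degrees.
    alpha : float
        Gaussian envelope width in pixels (> 0).
    beta : float
        Dimensionless phase-term scale (default 1).
    support_radius : int, optional
        Half-width of the kernel; defaults to ``ceil(3 * alpha)`` so the
        envelope is truncated at three standard widths.

    Returns
    -------
    GaborFilter
        The kernel has odd side ``2 * support_radius + 1`` and complex sum
        below 1e-10 in magnitude after DC correction.
    """
    if omega0 <= 0:
        raise ValueError(f"omega0 must be positive, got {omega0}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if support_radius is None:
        support_radius = int(np.ceil(3 * alpha))
    support_radius = int(support_radius)
    if support_radius < 1:
        raise ValueError(f"support_radius must be >= 1, got {support_radius}")

    th = np.deg2rad(theta)
    u0 = omega0 * np.cos(th)
    v0 = omega0 * np.sin(th)

    r = support_radius
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    dx, dy = x - x0, y - y0
    envelope = np.exp(-(dx**2 + dy**2) / alpha**2)
    phase = 2.0 * np.pi * (u0 * dx + v0 * dy) / beta**2
    kernel = envelope * np.exp(-1j * phase)
    dc = kernel.mean()
    kernel = kernel - dc  # DC correction

    return GaborFilter(
        omega0=float(omega0),
        theta=float(theta),
        u0=float(u0),
        v0=float(v0),
        alpha=float(alpha),
        beta=float(beta),
        x0=float(x0),
        y0=float(y0),
        kernel=kernel,
        dc_offset=complex(dc),
    )


def default_bank(
    scales=DEFAULT_SCALES,
    orientations=DEFAULT_ORIENTATIONS,
    alpha_mode: str = "wavelength",
    alpha: float | None = None,
    beta: float = 1.0,
) -> GaborBank:
    """Build the directional filter bank (default: 2 scales x 2 orientations).

    With ``alpha_mode='wavelength'`` each filter's envelope width is one
    wavelength, ``alpha = 1 / omega0`` (constant relative bandwidth); with
    ``alpha_mode='fixed'`` the given ``alpha`` is used for every filter.
    """
    scales = tuple(float(s) for s in scales)
    orientations = tuple(float(o) for o in orientations)
    filters = []
    for s in scales:  # scale-major, orientation-minor ordering
        for o in orientations:
            if alpha_mode == "wavelength":
                a = 1.0 / s
            elif alpha_mode == "fixed":
                if alpha is None:
                    raise ValueError("alpha required with alpha_mode='fixed'")
                a = alpha
            else:
                raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
            filters.append(make_gabor_filter(s, o, alpha=a, beta=beta))
    return GaborBank(
        filters=tuple(filters), scales=scales, orientations=orientations
    )


def _convolve_spatial(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # ndimage.convolve flips the kernel: true convolution, reflect padding
    real = ndimage.convolve(image, kernel.real, mode="reflect")
    imag = ndimage.convolve(image, kernel.imag, mode="reflect")
    return real + 1j * imag


def _convolve_fft(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # reflect-pad by the kernel radius, FFT-convolve, crop: identical
    # boundary handling to the spatial reference path
    r = kernel.shape[0] // 2
    padded = np.pad(image, r, mode="symmetric")  # scipy 'reflect' boundary
    full = signal.fftconvolve(padded, kernel, mode="same")
    return full[r:-r, r:-r]


def _convolve_complex(
    image: np.ndarray, kernel: np.ndarray, method: str = "auto"
) -> np.ndarray:
    if method == "auto":
        method = "fft" if kernel.size >= 15**2 else "spatial"
    if method == "spatial":
        return _convolve_spatial(image, kernel)
    if method == "fft":
        return _convolve_fft(image, kernel)
    raise ValueError(f"unknown convolution method {method!r}")


def decompose(
    image: np.ndarray, bank: GaborBank | None = None, method: str = "auto"
) -> SubbandSet:
    """Filter an image with every bank filter, keeping complex responses.

    The image is reduced to its luma plane; each response is a same-size
    true 2-D convolution with reflect padding.  Rendered 3-channel uint8
    subband images (magnitude, min-max scaled) are produced for feeding
    RGB-input CNN branches.  ``method`` selects the spatial reference
    convolution, its FFT-based equivalent, or an automatic choice by
    kernel size.
    """
    if bank is None:
        bank = default_bank()
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot decompose an empty image")
    if len(bank) < 1:
        raise ValueError("bank has no filters")
    gray = to_luma(image)

    responses, provenance, rendered = {}, {}, {}
    for tag, filt in zip(bank.tags(), bank.filters):
        resp = _convolve_complex(gray, filt.kernel, method=method)
        responses[tag] = resp
        provenance[tag] = (filt.omega0, filt.theta)
        rendered[tag] = render_subband(resp)
    return SubbandSet(
        original=image, responses=responses,
        provenance=provenance, rendered=rendered,
    )


def render_subband(response: np.ndarray) -> np.ndarray:
    """Render a complex response as an 8-bit 3-channel magnitude image.

    Magnitude is min-max scaled to [0, 255] and replicated across three
    channels; a zero-range (constant-magnitude) response maps to the
    all-zero image.
    """
    mag = np.abs(np.asarray(response))
    lo, hi = mag.min(), mag.max()
    if hi - lo <= 0:
        scaled = np.zeros_like(mag)
    else:
        scaled = (mag - lo) / (hi - lo) * 255.0
    out = np.rint(scaled).astype(np.uint8)
    return np.repeat(out[..., None], 3, axis=2)
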