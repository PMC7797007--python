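"""Deterministic blur (TTF), downsampling, and NPS-correlated noise operators.

The imaging chain mirrors how a reconstructed CT image degrades an idealized
object: the hyper-resolution phantom is convolved with the system point-spread
function derived from a task transfer function (TTF), then with one stochastic
motion PSF instance, block-averaged down to the clinical pixel grid, and
finally contaminated with correlated noise synthesized from a noise-power
spectrum (NPS) and scaled to the case noise magnitude sigma.

TTF and NPS are supplied as parametric radial curves (the shapes are
configurable and tabulated curves can be loaded from two-column CSV), keeping
the engine self-contained while matching the roles the measured scanner curves
play.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .motion import MotionKernel
from .phantom import GridSpec, PhantomImage

__all__ = [
    "TTFCurve",
    "NPSCurve",
    "ImageInstance",
    "parametric_ttf",
    "parametric_nps",
    "ttf_to_psf",
    "apply_blur",
    "downsample",
    "generate_correlated_noise",
    "compose_instance",
]


@dataclass
class TTFCurve:
    """Radially symmetric task transfer function (task-based MTF).

    ``mtf(0) = 1`` and ``mtf(f50) = 0.5`` by construction.  Values beyond the
    tabulated axis evaluate to zero.
    """

    frequencies: np.ndarray  # mm^-1
    mtf: np.ndarray
    f50: float  # mm^-1

    def __call__(self, f: np.ndarray | float) -> np.ndarray:
        return np.interp(np.abs(f), self.frequencies, self.mtf, right=0.0)


@dataclass
class NPSCurve:
    """Radial noise-power spectrum shape with unit 2D integral, plus magnitude.

    ``sigma`` is the target noise magnitude (HU) of synthesized fields; the
    density describes only the correlation texture.
    """

    frequencies: np.ndarray  # mm^-1
    density: np.ndarray  # normalised: integral of density * 2*pi*f df == 1
    sigma: float  # HU

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.density = np.clip(np.asarray(self.density, dtype=float), 0.0, None)
        area = np.trapezoid(self.density * 2.0 * np.pi * self.frequencies,
                            self.frequencies)
        if area > 0:
            self.density = self.density / area

    def __call__(self, f: np.ndarray | float) -> np.ndarray:
        return np.interp(np.abs(f), self.frequencies, self.density, right=0.0)


@dataclass
class BlurKernel:
    """Radially symmetric system blur kernel (sums to one)."""

    values: np.ndarray
    pixel_size: float  # mm


@dataclass
class ImageInstance:
    """One stochastic clinical-resolution image realisation with provenance."""

    values: np.ndarray  # HU, clinical grid
    pixel_size: float  # mm
    provenance: dict = field(default_factory=dict)


def parametric_ttf(
    f50: float, shape: str = "gaussian", fmax: float | None = None, n: int = 601
) -> TTFCurve:
    """Parametric TTF family pinned to ``mtf(f50) = 0.5``.

    ``gaussian``: ``exp(-ln 2 (f/f50)^2)``; ``sigmoid``: ``1/(1 + (f/f50)^4)``,
    a heavier-tailed roll-off resembling iterative-reconstruction TTFs.  With
    the default axis, ``f50`` falls exactly on a tabulation point.
    """
    if f50 <= 0:
        raise ValueError("f50 must be positive")
    if fmax is None:
        fmax = 6.0 * f50
    f = np.linspace(0.0, fmax, n)
    if shape == "gaussian":
        mtf = np.exp(-math.log(2.0) * (f / f50) ** 2)
    elif shape == "sigmoid":
        mtf = 1.0 / (1.0 + (f / f50) ** 4)
    else:
        raise ValueError(f"unknown TTF shape {shape!r}")
    return TTFCurve(frequencies=f, mtf=mtf, f50=f50)


def parametric_nps(
    peak_frequency: float,
    sigma: float,
    shape: str = "bandpass",
    fmax: float = 3.0,
    n: int = 512,
) -> NPSCurve:
    """Parametric radial NPS: ramp-like ``bandpass`` (peak at the given
    frequency, the typical filtered-backprojection texture) or ``flat`` (white).
    """
    f = np.linspace(0.0, fmax, n)
    if shape == "bandpass":
        if peak_frequency <= 0:
            raise ValueError("peak_frequency must be positive")
        density = f * np.exp(-(f**2) / (2.0 * peak_frequency**2))
    elif shape == "flat":
        density = np.ones_like(f)
    else:
        raise ValueError(f"unknown NPS shape {shape!r}")
    return NPSCurve(frequencies=f, density=density, sigma=sigma)


def ttf_to_psf(ttf: TTFCurve, grid: GridSpec, size: int | None = None) -> BlurKernel:
    """System PSF whose discrete radial MTF reproduces the TTF curve.

    The radial curve is sampled on the kernel's 2D frequency grid and inverse
    Fourier transformed; the DC sample pins the kernel sum to one.
    """
    h = grid.hyper_pixel_size
    nyquist = 0.5 / h
    if ttf.f50 >= nyquist:
        raise ValueError("TTF support exceeds the hyper-grid Nyquist frequency")
    if size is None:
        # halfwidth ~4 sigma of the matching Gaussian PSF
        halfwidth_mm = 0.8 / ttf.f50
        size = 2 * int(math.ceil(halfwidth_mm / h)) + 1
        size = min(size, grid.n_hyper if grid.n_hyper % 2 == 1 else grid.n_hyper - 1)
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    fx = np.fft.fftfreq(size, d=h)
    fr = np.hypot(fx[:, None], fx[None, :])
    amp = ttf(fr)
    psf = np.fft.fftshift(np.real(np.fft.ifft2(amp)))
    psf /= psf.sum()
    return BlurKernel(values=psf, pixel_size=h)


def _embed_kernel(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad a centred odd kernel into ``shape`` with its centre at (0, 0)."""
    ky, kx = kernel.shape
    if ky > shape[0] or kx > shape[1]:
        raise ValueError("kernel larger than image")
    big = np.zeros(shape)
    big[:ky, :kx] = kernel
    return np.roll(big, (-(ky // 2), -(kx // 2)), axis=(0, 1))


def apply_blur(
    image: np.ndarray,
    kernel: BlurKernel | MotionKernel,
    pixel_size: float,
) -> np.ndarray:
    """Linear shift-invariant convolution of an image with a unit-sum kernel.

    Implemented as a circular convolution via the FFT (the uniform background
    makes wrap-around benign for centred vessels); the kernel sum of one
    preserves the image mean.
    """
    if not math.isclose(kernel.pixel_size, pixel_size, rel_tol=1e-9):
        raise ValueError(
            f"pixel size mismatch: image {pixel_size} mm vs kernel "
            f"{kernel.pixel_size} mm"
        )
    kpad = _embed_kernel(kernel.values, image.shape)
    out = np.fft.irfft2(np.fft.rfft2(image) * np.fft.rfft2(kpad), s=image.shape)
    return out


def downsample(image: np.ndarray, hyper_factor: int) -> np.ndarray:
    """Block-average (area integration) down to the clinical grid."""
    if hyper_factor == 1:
        return image.copy()
    ny, nx = image.shape
    if ny % hyper_factor or nx % hyper_factor:
        raise ValueError(
            f"image shape {image.shape} not divisible by hyper_factor {hyper_factor}"
        )
    return image.reshape(
        ny // hyper_factor, hyper_factor, nx // hyper_factor, hyper_factor
    ).mean(axis=(1, 3))


def generate_correlated_noise(
    nps: NPSCurve,
    shape: tuple[int, int],
    rng: np.random.Generator,
    pixel_size: float,
) -> np.ndarray:
    """Zero-mean correlated noise field with sample SD equal to ``nps.sigma``.

    A white Gaussian field is filtered with the square root of the NPS density
    in frequency space; each field is then recentred and rescaled so its sample
    standard deviation matches sigma exactly, honouring per-case noise
    magnitude matching.
    """
    if min(shape) < 16:
        raise ValueError("noise field must be at least 16x16")
    white = rng.standard_normal(shape)
    if nps.sigma == 0:
        return np.zeros(shape)
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.rfftfreq(shape[1], d=pixel_size)
    fr = np.hypot(fy[:, None], fx[None, :])
    filt = np.sqrt(nps(fr))
    field_ = np.fft.irfft2(np.fft.rfft2(white) * filt, s=shape)
    field_ -= field_.mean()
    sd = field_.std()
    if sd == 0:
        return np.zeros(shape)
    return field_ * (nps.sigma / sd)


def compose_instance(
    phantom: PhantomImage,
    ttf: TTFCurve | None,
    motion_kernel: MotionKernel | None,
    nps: NPSCurve | None,
    rng: np.random.Generator | None = None,
    system_kernel: BlurKernel | None = None,
    provenance: dict | None = None,
) -> ImageInstance:
    """Compose one stochastic image instance from the full chain.

    System blur, then motion blur, then downsampling to clinical resolution,
    then additive correlated noise.  Passing ``system_kernel`` skips the
    (deterministic) TTF-to-PSF conversion when composing many instances.
    """
    grid = phantom.grid
    if grid is None:
        raise ValueError("phantom must carry its GridSpec")
    values = phantom.values
    if system_kernel is None and ttf is not None:
        system_kernel = ttf_to_psf(ttf, grid)
    if system_kernel is not None:
        values = apply_blur(values, system_kernel, phantom.pixel_size)
    if motion_kernel is not None:
        values = apply_blur(values, motion_kernel, phantom.pixel_size)
    values = downsample(values, grid.hyper_factor)
    if nps is not None and nps.sigma > 0:
        if rng is None:
            raise ValueError("rng required when adding noise")
        values = values + generate_correlated_noise(
            nps, values.shape, rng, grid.clinical_pixel_size
        )
    return ImageInstance(
        values=values,
        pixel_size=grid.clinical_pixel_size,
        provenance=provenance or {},
    )
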