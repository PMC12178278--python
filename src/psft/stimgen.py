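"""2D FFT bandpass filtering of grayscale stimulus images.

Letters and noise carriers are band-limited in spatial frequency by
multiplying the centered 2D Fourier transform with a circularly symmetric
radial filter, smoothed with a Gaussian kernel and min-max normalized to
[0, 1].  The filtered image is normalized (range for letters, maximum for
noise), rectified, and quantized to the display range via ``x*127 + 127``.

Frequencies are handled in cycles/degree with an explicit pixels-per-degree
(ppd) parameter; cutoffs are converted to cycles/pixel internally and must
not exceed the Nyquist frequency (ppd/2 cpd).  The exact radial profile of
the original filter is not published; the default here is a
difference-of-discs annulus ``[f_low, f_high]`` (an approximation), and the
profile is pluggable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandpassSpec:
    """Radial bandpass parameters.

    center_sf    : passband center, cpd
    ppd          : display resolution, pixels per degree of visual angle
    filter_width : fractional half-width; default cutoffs are
                   ``center_sf * (1 -/+ filter_width)``
    f_low/f_high : explicit radial cutoffs (cpd), overriding the width rule
    smooth_sd    : Gaussian smoothing SD in pixels (letters: 3;
                   noise: ppd/10)
    """

    center_sf: float
    ppd: float
    filter_width: float = 0.2
    f_low: float | None = None
    f_high: float | None = None
    smooth_sd: float | None = None

    @property
    def nyquist(self) -> float:
        """Highest representable SF, cpd: one cycle per two pixels."""
        return self.ppd / 2.0

    def cutoffs(self) -> tuple[float, float]:
        lo = self.f_low if self.f_low is not None else self.center_sf * (1 - self.filter_width)
        hi = self.f_high if self.f_high is not None else self.center_sf * (1 + self.filter_width)
        if not 0 < lo < hi:
            raise ValueError(f"need 0 < f_low < f_high, got ({lo}, {hi})")
        if hi > self.nyquist:
            raise ValueError(f"f_high={hi} cpd exceeds Nyquist {self.nyquist} cpd")
        return lo, hi

    def smoothing(self, kind: str) -> float:
        if self.smooth_sd is not None:
            return self.smooth_sd
        return 3.0 if kind == "letter" else self.ppd / 10.0


def annulus_profile(radius_cpd: np.ndarray, f_low: float, f_high: float) -> np.ndarray:
    """Default radial profile: indicator of the [f_low, f_high] annulus."""
    return ((radius_cpd >= f_low) & (radius_cpd <= f_high)).astype(float)


def make_bandpass_filter(
    shape: tuple[int, int],
    spec: BandpassSpec,
    kind: str = "noise",
    radial_profile: Callable[[np.ndarray, float, float], np.ndarray] | None = None,
) -> np.ndarray:
    """Circularly symmetric frequency-domain filter, smoothed and min-max
    normalized to [0, 1], laid out for a centered (fftshift-ed) spectrum."""
    lo, hi = spec.cutoffs()
    fy = np.fft.fftshift(np.fft.fftfreq(shape[0]))  # cycles/pixel
    fx = np.fft.fftshift(np.fft.fftfreq(shape[1]))
    radius = np.hypot(fy[:, None], fx[None, :]) * spec.ppd  # cpd
    profile = (radial_profile or annulus_profile)(radius, lo, hi)
    if profile.max() == 0:
        raise ValueError("passband falls between frequency samples; enlarge the image")
    smoothed = gaussian_filter(profile, spec.smoothing(kind))
    rng = smoothed.max() - smoothed.min()
    if rng == 0:
        raise ValueError("degenerate filter: constant after smoothing")
    return (smoothed - smoothed.min()) / rng


def filter_image(image: np.ndarray, spec: BandpassSpec, kind: str = "noise") -> np.ndarray:
    """Bandpass-filter a grayscale image and quantize for display.

    Pipeline: complement (letters only) -> centered FFT -> multiply by the
    normalized filter -> inverse FFT (real part) -> subtract the minimum and
    divide by the range (letters) or the maximum (noise) -> rectify ->
    ``x*127 + 127`` -> clip to [0, 255], uint8.
    """
    if kind not in ("letter", "noise"):
        raise ValueError("kind must be 'letter' or 'noise'")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be single-channel grayscale")
    if kind == "letter":  # letters black-on-white -> white-on-black
        img = img.max() - img
    filt = make_bandpass_filter(img.shape, spec, kind)
    spectrum = np.fft.fftshift(np.fft.fft2(img))
    out = np.fft.ifft2(np.fft.ifftshift(spectrum * filt)).real
    out = out - out.min()
    denom = (out.max() - out.min()) if kind == "letter" else out.max()
    if denom == 0:  # DC-only input: nothing but a flat field survives
        out = np.zeros_like(out)
    else:
        out = out / denom
    out = np.abs(out) * 127.0 + 127.0
    clipped = np.mean((out < 0) | (out > 255))
    if clipped:
        logger.info("filter_image: %.3f%% of pixels clipped to [0, 255]", 100 * clipped)
    return np.clip(out, 0, 255).astype(np.uint8)


def filter_image_file(
    path_in: str, path_out: str, spec: BandpassSpec, kind: str = "noise"
) -> np.ndarray:
    """Read a grayscale PNG/TIFF, filter it, write the 8-bit result."""
    img = iio.imread(path_in)
    if img.ndim == 3:  # collapse identical channels; reject true color
        if np.ptp(img, axis=2).max() == 0:
            img = img[..., 0]
        else:
            raise ValueError(f"{path_in} is not grayscale")
    out = filter_image(img, spec, kind)
    iio.imwrite(path_out, out)
    return out
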