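"""AFM/TEM-derived numerics: helical pitch, tip dilation, dimension stats.

The helical repeat of a cylinder is read from the power spectrum of an axial
height profile (linear detrend, Hann window); a twisted fibril shows peaks
at the fundamental repeat and its second order.  Apparent widths measured by
a finite spherical tip are corrected with the geometric dilation model: a
tip of radius R imaging a step of height h broadens each edge by
√(2Rh − h²) while the step is shallower than the tip (h < R), and by R once
the tip's equator takes over (h ≥ R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, periodogram

from .errors import DomainError, NoPeriodicityError


@dataclass(frozen=True)
class HeightProfile:
    """Height (nm) sampled uniformly along the fibril axis (position in nm)."""

    position: np.ndarray
    height: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        h = np.asarray(self.height, dtype=float)
        if pos.shape != h.shape or pos.ndim != 1:
            raise DomainError("position and height must be equal-length 1-D arrays")
        if len(pos) < 64:
            raise DomainError("spectral analysis needs at least 64 samples")
        steps = np.diff(pos)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise DomainError("profile must be uniformly sampled")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "height", h)

    @property
    def step(self) -> float:
        return float(self.position[1] - self.position[0])


def pitch_from_profile(profile: HeightProfile, alpha: float = 0.05) -> dict:
    """Periodicities of an axial height profile by 1-D Fourier analysis.

    Returns the detected peak periods sorted by spectral power (most
    prominent first) and the fundamental repeat — the largest significant
    period.  Peak frequencies are refined by parabolic interpolation of the
    log-power spectrum.

    Significance uses the exponential null of periodogram ordinates: with
    the noise mean estimated robustly as median/ln 2, a peak is significant
    when its power exceeds (median/ln 2)·ln(N/alpha), the level a
    noise-only spectrum of N bins exceeds anywhere with probability alpha.
    Raises NoPeriodicityError when no peak is significant.
    """
    freqs, power = periodogram(
        profile.height,
        fs=1.0 / profile.step,
        window="hann",
        detrend="linear",
    )
    freqs, power = freqs[1:], power[1:]  # drop DC
    noise_floor = float(np.median(power))
    threshold = (noise_floor / np.log(2.0)) * np.log(len(power) / alpha)
    peaks, _ = find_peaks(power, height=threshold if noise_floor > 0 else None)
    if noise_floor == 0.0 or len(peaks) == 0:
        raise NoPeriodicityError("no spectral peak above the noise floor")
    df = freqs[1] - freqs[0]
    refined = []
    for i in peaks:
        f = freqs[i]
        if 0 < i < len(power) - 1 and np.all(power[i - 1 : i + 2] > 0):
            a, b, c = np.log(power[i - 1 : i + 2])
            denom = a - 2 * b + c
            if denom != 0:
                f = f + np.clip(0.5 * (a - c) / denom, -1, 1) * df
        refined.append((1.0 / f, float(power[i])))
    refined.sort(key=lambda t: t[1], reverse=True)
    periods = [p for p, _ in refined]
    return {
        "fundamental": max(periods),
        "periods": periods,
        "powers": [w for _, w in refined],
    }


@dataclass(frozen=True)
class WidthCorrection:
    corrected: float
    broadening: float
    under_resolved: bool


def tip_width_correction(
    measured: float, feature_height: float, tip_radius: float
) -> WidthCorrection:
    """Correct a measured width for finite-tip dilation (all nm).

    Broadening b = 2√(2·R·h − h²) for h < R, else 2R; corrected width is
    max(measured − b, 0), flagged under-resolved when the clamp engages.
    """
    if measured < 0 or feature_height <= 0 or tip_radius < 0:
        raise DomainError("measured/tip radius must be >= 0 and height > 0")
    h, r = feature_height, tip_radius
    if h < r:
        broadening = 2.0 * np.sqrt(2.0 * r * h - h * h)
    else:
        broadening = 2.0 * r
    corrected = measured - broadening
    if corrected < 0:
        return WidthCorrection(0.0, broadening, True)
    return WidthCorrection(float(corrected), float(broadening), False)


@dataclass(frozen=True)
class DimensionSample:
    """A set of measured fibril dimensions (width/height/length), nm."""

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("width", "height", "length"):
            raise DomainError(f"unknown dimension kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise DomainError("empty dimension sample")
        if np.any(v <= 0):
            raise DomainError("dimensions must be positive")
        object.__setattr__(self, "values", v)


def dimension_stats(sample: DimensionSample) -> dict:
    """Descriptive statistics with Freedman–Diaconis histogram binning.

    The standard deviation is the population value (ddof=0), so a single
    measurement reports sd 0.
    """
    v = sample.values
    counts, edges = np.histogram(v, bins="fd" if v.size > 1 else 1)
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=0)),
        "median": float(np.median(v)),
        "histogram_counts": counts,
        "histogram_edges": edges,
    }
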