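"""CD/FTIR numeric procedures: MRE conversion, two-state melts, isodichroic
point detection, second-derivative band picking, and CAC breakpoint fitting.

The melt model is the two-state van't Hoff equilibrium with linear folded
and unfolded baselines,

    y(T) = (1 - f)(a_f + b_f T) + f (a_u + b_u T),
    f(T) = 1 / (1 + exp[(ΔH_vH / R)(1/T - 1/T_M)])      (T in kelvin),

fitted by nonlinear least squares; the model-free transition midpoint is the
extremum of the Savitzky–Golay first derivative, and both are reported.  The
critical aggregation concentration (CAC) is the breakpoint of a continuous
two-segment linear fit to a reporter-dye titration, preferred over a single
line only when it buys a meaningful drop in the sum of squared errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    DomainError,
    IllDefinedIsodichroicError,
    InsufficientDataError,
    IsodichroicNotFoundError,
    NoTransitionError,
    ResampleRequiredError,
)

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.31446e-3
KELVIN = 273.15


@dataclass(frozen=True)
class SeriesCurve:
    """A generic ordered (x, y) measurement series with unit tags."""

    x: np.ndarray
    y: np.ndarray
    x_units: str = ""
    y_units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise DomainError("x and y must be equal-length 1-D arrays")
        if len(x) and not np.all(np.diff(x) > 0):
            raise DomainError("x grid must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({self.x_units or "x": self.x, self.y_units or "y": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, x_units: str = "", y_units: str = "") -> "SeriesCurve":
        df = pd.read_csv(path)
        return cls(
            df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
            x_units or df.columns[0], y_units or df.columns[1],
        )


def mre_convert(
    signal_mdeg: float | np.ndarray,
    concentration: float,
    pathlength: float,
    n_units: int,
) -> float | np.ndarray:
    """Mean residue ellipticity, deg·cm²·dmol⁻¹·res⁻¹.

    MRE = mdeg / (10 × pathlength[cm] × concentration[mol/L] × n_units).
    n_units defaults to the residue count by convention; pass N−1 to
    normalise per peptide bond instead.
    """
    if concentration <= 0 or pathlength <= 0 or n_units <= 0:
        raise DomainError("concentration, pathlength and n_units must be positive")
    return np.asarray(signal_mdeg, dtype=float) / (
        10.0 * pathlength * concentration * n_units
    ) if np.ndim(signal_mdeg) else signal_mdeg / (
        10.0 * pathlength * concentration * n_units
    )


def two_state_curve(
    temps_c: np.ndarray,
    t_m: float,
    dh_vh: float,
    a_f: float,
    b_f: float,
    a_u: float,
    b_u: float,
) -> np.ndarray:
    """Two-state van't Hoff melt signal at temperatures in °C."""
    t_k = np.asarray(temps_c, dtype=float) + KELVIN
    f = 1.0 / (1.0 + np.exp((dh_vh / R_GAS) * (1.0 / t_k - 1.0 / (t_m + KELVIN))))
    return (1.0 - f) * (a_f + b_f * temps_c) + f * (a_u + b_u * temps_c)


@dataclass(frozen=True)
class MeltFit:
    """Two-state melt fit: model T_M and the model-free derivative midpoint."""

    t_m: float                 # °C, from the van't Hoff fit
    dh_vh: float               # kJ/mol
    folded_baseline: tuple[float, float]    # intercept, slope
    unfolded_baseline: tuple[float, float]
    derivative_t_m: float      # °C, Savitzky–Golay first-derivative extremum
    residual_norm: float

    @property
    def midpoint_discrepancy(self) -> float:
        return abs(self.t_m - self.derivative_t_m)


def _sg_window(n: int, preferred: int = 9) -> int:
    w = min(preferred, n if n % 2 else n - 1)
    return max(w, 5)


def _derivative_t_m(curve: SeriesCurve) -> float:
    t, y = curve.x, curve.y
    window = _sg_window(len(t))
    step = float(np.mean(np.diff(t)))
    dy = savgol_filter(y, window, polyorder=3, deriv=1, delta=step)
    i = int(np.argmax(np.abs(dy)))
    # parabolic refinement of the |dy| extremum on the interior grid
    if 0 < i < len(t) - 1:
        a, b, c = np.abs(dy[i - 1 : i + 2])
        denom = a - 2 * b + c
        if denom != 0:
            i_frac = 0.5 * (a - c) / denom
            return float(t[i] + np.clip(i_frac, -1, 1) * step)
    return float(t[i])


def fit_two_state_melt(curve: SeriesCurve) -> MeltFit:
    """Fit the two-state van't Hoff melt model to a thermal denaturation curve.

    Raises NoTransitionError when the curve has no detectable sigmoidal
    transition (flat or purely linear signal).
    """
    if len(curve) < 5:
        raise InsufficientDataError("melt fit needs at least 5 points")
    t, y = curve.x, curve.y
    amp = float(np.ptp(y))
    span = float(t[-1] - t[0])
    if amp == 0.0:
        raise NoTransitionError("constant signal: no transition")
    window = _sg_window(len(t))
    step = float(np.mean(np.diff(t)))
    dy = savgol_filter(y, window, polyorder=3, deriv=1, delta=step)
    # a sigmoid concentrates slope: its peak derivative times the span far
    # exceeds the total amplitude, unlike a straight line (equality)
    if np.max(np.abs(dy)) * span < 1.5 * amp:
        raise NoTransitionError("flat first derivative: no transition detected")
    d_tm = _derivative_t_m(curve)

    n_edge = max(3, len(t) // 5)
    fit_f = np.polyfit(t[:n_edge], y[:n_edge], 1)
    fit_u = np.polyfit(t[-n_edge:], y[-n_edge:], 1)

    params = Parameters()
    params.add("t_m", value=d_tm, min=t[0], max=t[-1])
    params.add("dh_vh", value=200.0, min=1.0, max=5000.0)
    params.add("a_f", value=fit_f[1])
    params.add("b_f", value=fit_f[0])
    params.add("a_u", value=fit_u[1])
    params.add("b_u", value=fit_u[0])

    def residual(p):
        return y - two_state_curve(
            t, p["t_m"].value, p["dh_vh"].value,
            p["a_f"].value, p["b_f"].value, p["a_u"].value, p["b_u"].value,
        )

    result = minimize(residual, params)
    v = result.params.valuesdict()
    return MeltFit(
        t_m=float(v["t_m"]),
        dh_vh=float(v["dh_vh"]),
        folded_baseline=(float(v["a_f"]), float(v["b_f"])),
        unfolded_baseline=(float(v["a_u"]), float(v["b_u"])),
        derivative_t_m=d_tm,
        residual_norm=float(np.linalg.norm(result.residual)),
    )


def find_isodichroic(
    spectra: list[SeriesCurve], tolerance: float = 2.0
) -> dict[str, float]:
    """Isodichroic wavelength of a temperature family of spectra.

    Finds the sign-change crossings of each consecutive pair of spectra by
    linear interpolation and returns the median crossing wavelength with its
    spread.  A two-state family crosses at one shared wavelength.
    """
    if len(spectra) < 2:
        raise InsufficientDataError("need at least 2 spectra")
    grid = spectra[0].x
    for s in spectra[1:]:
        if len(s.x) != len(grid) or not np.allclose(s.x, grid):
            raise ResampleRequiredError("spectra must share a common wavelength grid")
    scale = max(float(np.ptp(s.y)) for s in spectra) or 1.0
    crossings: list[float] = []
    for s1, s2 in zip(spectra[:-1], spectra[1:]):
        diff = s2.y - s1.y
        if np.max(np.abs(diff)) < 1e-9 * scale:
            continue  # degenerate pair, no information
        sign = np.where(diff >= 0, 1, -1)  # exact zeros count once
        for i in np.nonzero(np.diff(sign) != 0)[0]:
            frac = diff[i] / (diff[i] - diff[i + 1])
            crossings.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    if not crossings:
        raise IsodichroicNotFoundError("no spectral crossings found")
    crossings = np.asarray(crossings)
    spread = float(crossings.max() - crossings.min())
    if spread > tolerance:
        raise IllDefinedIsodichroicError(
            f"crossing spread {spread:.2f} nm exceeds tolerance {tolerance} nm"
        )
    return {"wavelength": float(np.median(crossings)), "spread": spread,
            "n_crossings": len(crossings)}


#: Amide-region assignment windows, cm⁻¹ (editable).
DEFAULT_BAND_TABLE = (
    (1623.0, 1625.0, "intermolecular β-strand"),
    (1634.0, 1638.0, "antiparallel β-sheet marker"),
    (1687.0, 1691.0, "antiparallel β-sheet marker"),
    (1649.0, 1651.0, "α-helix"),
    (1665.0, 1668.0, "β-turn"),
    (1540.0, 1550.0, "amide II (turns)"),
)


def second_derivative_bands(
    spectrum: SeriesCurve,
    window: int = 9,
    polyorder: int = 3,
    band_table=DEFAULT_BAND_TABLE,
    assignment_pad: float = 1.0,
    prominence_fraction: float = 0.05,
) -> list[tuple[float, str]]:
    """Band positions from Savitzky–Golay second-derivative minima.

    Bands are local minima of the second derivative (maxima of −d²y/dν̃²)
    with prominence above the given fraction of the second-derivative range,
    refined by parabolic interpolation and labelled via the assignment table.
    """
    if window % 2 == 0 or window <= polyorder:
        raise DomainError("window must be odd and greater than polyorder")
    steps = np.diff(spectrum.x)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ResampleRequiredError("spectrum grid is not uniform; resample first")
    step = float(steps[0])
    d2 = savgol_filter(spectrum.y, window, polyorder, deriv=2, delta=step)
    rng = float(np.ptp(d2))
    if rng == 0.0:
        return []
    peaks, _ = find_peaks(-d2, prominence=prominence_fraction * rng)
    bands = []
    for i in peaks:
        pos = spectrum.x[i]
        if 0 < i < len(d2) - 1:
            a, b, c = -d2[i - 1 : i + 2]
            denom = a - 2 * b + c
            if denom != 0:
                pos = pos + np.clip(0.5 * (a - c) / denom, -1, 1) * step
        label = "unassigned"
        for lo, hi, name in band_table:
            if lo - assignment_pad <= pos <= hi + assignment_pad:
                label = name
                break
        bands.append((float(pos), label))
    return bands


@dataclass(frozen=True)
class CacFit:
    """Two-segment titration fit: breakpoint = critical aggregation conc."""

    breakpoint: float | None        # µM; None when a single segment suffices
    slope_low: float
    slope_high: float
    sse: float
    single_segment_preferred: bool


def _hinge_fit(x: np.ndarray, y: np.ndarray, c: float, w: np.ndarray):
    below = np.minimum(x - c, 0.0)
    above = np.maximum(x - c, 0.0)
    design = np.column_stack([np.ones_like(x), below, above])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    sse = float(np.sum(w * (design @ beta - y) ** 2))
    return beta, sse


def fit_cac_breakpoint(
    titration: SeriesCurve,
    min_improvement: float = 0.05,
    weighting: str = "relative",
) -> CacFit:
    """Continuous two-segment piecewise-linear fit of a reporter titration.

    The breakpoint is searched over the interior concentration grid with
    log-spaced refinement between neighbouring grid points; candidates must
    have a steeper upper than lower segment.  A single line is preferred
    when the two-segment fit improves the SSE by less than min_improvement.

    Fluorescence readings scatter in proportion to their own level, so the
    default is inverse-variance weighting with sd proportional to |y|
    (``weighting="relative"``); pass ``"ols"`` for unweighted least squares.
    """
    if len(titration) < 6:
        raise InsufficientDataError("CAC fit needs at least 6 concentrations")
    if weighting not in ("relative", "ols"):
        raise DomainError(f"weighting must be 'relative' or 'ols', got {weighting!r}")
    x, y = titration.x, titration.y
    if weighting == "relative":
        w = 1.0 / np.maximum(np.abs(y), 1e-9 * max(float(np.max(np.abs(y))), 1.0)) ** 2
    else:
        w = np.ones_like(y)
    design1 = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    beta1, *_ = np.linalg.lstsq(design1 * sw[:, None], y * sw, rcond=None)
    sse1 = float(np.sum(w * (design1 @ beta1 - y) ** 2))
    line_slope = float(beta1[1])

    candidates = list(x[1:-1])
    best = None
    for c in candidates:
        beta, sse = _hinge_fit(x, y, c, w)
        if beta[2] <= beta[1]:
            continue
        if best is None or sse < best[1]:
            best = (c, sse, beta)
    if best is not None:
        # log-spaced refinement between the neighbours of the best grid point
        i = int(np.searchsorted(x, best[0]))
        lo, hi = x[max(i - 1, 0)], x[min(i + 1, len(x) - 1)]
        for c in np.geomspace(max(lo, 1e-12), hi, 41):
            if not x[0] < c < x[-1]:
                continue
            beta, sse = _hinge_fit(x, y, c, w)
            if beta[2] <= beta[1]:
                continue
            if sse < best[1]:
                best = (c, sse, beta)

    # absolute floor keeps the exactly-linear (sse ~ 0) case on a single line
    floor = 1e-12 * float(np.sum(w * y**2) + 1.0)
    if best is None or (sse1 - best[1]) < min_improvement * sse1 + floor:
        return CacFit(
            breakpoint=None,
            slope_low=line_slope,
            slope_high=line_slope,
            sse=sse1,
            single_segment_preferred=True,
        )
    c, sse, beta = best
    return CacFit(
        breakpoint=float(c),
        slope_low=float(beta[1]),
        slope_high=float(beta[2]),
        sse=sse,
        single_segment_preferred=False,
    )
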