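"""Seeded synthetic-data generators and the named scenario registry.

Every tabular input the analysis modules consume can be generated here:
two-state melt curves, reporter-dye titrations with a concentration
breakpoint, periodic AFM height profiles, cell tracks (Brownian, ballistic
or persistent random walk), and two-state CD spectra families sharing an
isodichroic point.  Generators are pure functions of (parameters, seed) —
the same call is byte-identical every time.  Scenario parameter sets
emulating the published measurement conditions live in ``scenarios.toml``.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import DomainError
from .imaging import HeightProfile
from .spectro import SeriesCurve, two_state_curve
from .tracks import TrackSet


def gen_melt(
    t_min: float,
    t_max: float,
    step: float,
    t_m: float,
    dh_vh: float,
    a_f: float,
    b_f: float,
    a_u: float,
    b_u: float,
    noise_sd: float,
    seed: int,
) -> SeriesCurve:
    """Two-state van't Hoff melt curve with seeded Gaussian noise."""
    if not t_min < t_m < t_max:
        raise DomainError(f"T_M = {t_m} must lie inside [{t_min}, {t_max}]")
    rng = np.random.default_rng(seed)
    temps = np.arange(t_min, t_max + step / 2, step)
    y = two_state_curve(temps, t_m, dh_vh, a_f, b_f, a_u, b_u)
    y = y + rng.normal(0.0, noise_sd, size=temps.shape) if noise_sd > 0 else y
    return SeriesCurve(temps, y, x_units="degC", y_units="signal")


def gen_titration(
    c_min: float,
    c_max: float,
    fold: float,
    breakpoint: float,
    y0: float,
    slope_low: float,
    slope_high: float,
    noise_fraction: float,
    seed: int,
) -> SeriesCurve:
    """Continuous two-segment titration over a geometric dilution series.

    Concentrations are a serial dilution from c_max down by the given fold
    factor (so a 1.56–100 µM two-fold series is 100, 50, 25, 12.5, ...,
    1.5625), returned in ascending order.  Noise is multiplicative Gaussian,
    sd = noise_fraction of each point's signal (fluorescence readings
    scatter relative to their own level).
    """
    concs = []
    c = c_max
    while c >= c_min * (1 - 1e-6):
        concs.append(c)
        c /= fold
    concs = np.asarray(sorted(concs))
    if not concs[0] <= breakpoint <= concs[-1]:
        raise DomainError("breakpoint outside the concentration series")
    y = y0 + np.where(
        concs <= breakpoint,
        slope_low * (concs - breakpoint),
        slope_high * (concs - breakpoint),
    )
    rng = np.random.default_rng(seed)
    if noise_fraction > 0:
        y = y * (1.0 + rng.normal(0.0, noise_fraction, size=y.shape))
    return SeriesCurve(concs, y, x_units="uM", y_units="fluorescence")


def gen_profile(
    length: float,
    step: float,
    period: float,
    amplitude: float,
    second_harmonic: float,
    noise_sd: float,
    seed: int,
) -> HeightProfile:
    """Sinusoidal axial height profile with optional second harmonic."""
    if period <= 2 * step:
        raise DomainError("period must exceed twice the sampling step")
    rng = np.random.default_rng(seed)
    pos = np.arange(0.0, length, step)
    h = amplitude * np.sin(2 * np.pi * pos / period)
    if second_harmonic:
        h = h + second_harmonic * np.sin(4 * np.pi * pos / period)
    if noise_sd > 0:
        h = h + rng.normal(0.0, noise_sd, size=pos.shape)
    return HeightProfile(pos, h)


def gen_tracks(
    n_tracks: int,
    n_steps: int,
    dt: float,
    mode: str,
    seed: int,
    speed: float = 1.0,
    diffusivity: float = 0.5,
    persistence_time: float = 10.0,
) -> TrackSet:
    """Seeded 2-D cell tracks.

    modes: ``ballistic`` (constant velocity, random heading), ``brownian``
    (step sd per axis √(2DΔt)), ``prw`` (persistent random walk with
    exponentially correlated velocity, correlation time persistence_time).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps + 1) * dt
    tracks = {}
    for i in range(n_tracks):
        if mode == "ballistic":
            theta = rng.uniform(0, 2 * np.pi)
            v = speed * np.array([np.cos(theta), np.sin(theta)])
            xy = np.outer(t, v)
        elif mode == "brownian":
            steps = rng.normal(0.0, np.sqrt(2 * diffusivity * dt), size=(n_steps, 2))
            xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        elif mode == "prw":
            rho = np.exp(-dt / persistence_time)
            sigma_v = speed / np.sqrt(2.0)
            v = rng.normal(0.0, sigma_v, size=2)
            xy = [np.zeros(2)]
            for _ in range(n_steps):
                xy.append(xy[-1] + v * dt)
                v = rho * v + np.sqrt(1 - rho**2) * rng.normal(0.0, sigma_v, size=2)
            xy = np.asarray(xy)
        else:
            raise DomainError(f"unknown track mode {mode!r}")
        tracks[i] = np.column_stack([t, xy])
    return TrackSet(tracks)


def gen_spectra_family(
    wl_min: float,
    wl_max: float,
    step: float,
    crossing: float,
    n_spectra: int,
    tilt_slope: float,
    noise_sd: float,
    seed: int,
) -> list[SeriesCurve]:
    """Two-state CD spectra family sharing one exact crossing wavelength.

    Spectra are linear mixtures y_k = α_k·B1 + (1−α_k)·B2 of a folded basis
    B1 (β-helix-like: positive band near 195 nm, trough near 216 nm) and an
    unfolded basis B2 = B1 + s·(λ − λ_c), so every pair crosses only at λ_c.
    """
    if n_spectra < 2:
        raise DomainError("need at least 2 spectra")
    rng = np.random.default_rng(seed)
    wl = np.arange(wl_min, wl_max + step / 2, step)
    b1 = 12.0 * np.exp(-(((wl - 195.0) / 7.0) ** 2)) - 11.0 * np.exp(
        -(((wl - 216.0) / 12.0) ** 2)
    )
    g = tilt_slope * (wl - crossing)
    spectra = []
    for k in range(n_spectra):
        alpha = 1.0 - k / (n_spectra - 1)
        y = b1 + (1.0 - alpha) * g
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=wl.shape)
        spectra.append(
            SeriesCurve(wl, y, x_units="nm", y_units="MRE", meta={"fraction": alpha})
        )
    return spectra


_GENERATORS = {
    "melt": gen_melt,
    "titration": gen_titration,
    "profile": gen_profile,
    "tracks": gen_tracks,
    "spectra_family": gen_spectra_family,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully serialized generator invocation."""

    name: str
    generator: str
    params: dict
    seed: int


def _load_registry() -> dict:
    text = resources.files("betahelix").joinpath("scenarios.toml").read_text()
    return tomllib.loads(text)


def list_scenarios() -> list[str]:
    return [k for k in _load_registry() if k != "version"]


def get_scenario(name: str) -> ScenarioSpec:
    registry = _load_registry()
    if name not in registry or name == "version":
        raise KeyError(f"unknown scenario {name!r}; known: {list_scenarios()}")
    entry = registry[name]
    return ScenarioSpec(name, entry["generator"], dict(entry["params"]), entry["seed"])


def generate_scenario(name: str, seed: int | None = None):
    """Generate a registry scenario, optionally overriding its seed."""
    spec = get_scenario(name)
    gen = _GENERATORS[spec.generator]
    return gen(**spec.params, seed=spec.seed if seed is None else seed)
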