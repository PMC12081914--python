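"""Bragg-law conversions and harmonic (order) assignment of d-spacings.

Fiber-diffraction peak lists carry a mixture of fundamentals and their
higher-order reflections (order n appears at d/n).  `assign_harmonics`
reproduces the order bookkeeping used to group the observed spacings into
families; `model_spacings` turns the geometric solenoid parameters into the
periodicities they predict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .builder import GeometryParams, build_rung
from .errors import DomainError
from .rung import RungLayout

#: Cu-Kα wavelength, Å.
CU_KA = 1.5406


def d_to_two_theta(d: float, wavelength: float = CU_KA) -> float:
    """2θ (degrees) for a d-spacing (Å): 2θ = 2·arcsin(λ/2d)."""
    if d <= wavelength / 2:
        raise DomainError(
            f"d = {d} Å is unreachable: must exceed λ/2 = {wavelength / 2:.4f} Å"
        )
    return 2.0 * math.degrees(math.asin(wavelength / (2.0 * d)))


def two_theta_to_d(two_theta: float, wavelength: float = CU_KA) -> float:
    """d-spacing (Å) for a scattering angle 2θ (degrees)."""
    if not 0.0 < two_theta < 180.0:
        raise DomainError(f"2θ must be in (0, 180) degrees, got {two_theta}")
    return wavelength / (2.0 * math.sin(math.radians(two_theta / 2.0)))


@dataclass(frozen=True)
class Peak:
    d: float
    intensity: float = 1.0
    two_theta: float | None = None


@dataclass(frozen=True)
class PeakList:
    """Diffraction peaks (d in Å) with the instrument wavelength."""

    peaks: tuple[Peak, ...]
    wavelength: float = CU_KA

    def __post_init__(self) -> None:
        converted = []
        for p in self.peaks:
            if not isinstance(p, Peak):
                p = Peak(*p) if isinstance(p, (tuple, list)) else Peak(float(p))
            if p.d <= 0:
                raise DomainError(f"d-spacing must be positive, got {p.d}")
            if p.two_theta is not None:
                expected = d_to_two_theta(p.d, self.wavelength)
                if abs(expected - p.two_theta) > 0.05:
                    raise DomainError(
                        f"peak d={p.d} Å and 2θ={p.two_theta}° disagree with "
                        f"Bragg's law by more than 0.05°"
                    )
            converted.append(p)
        object.__setattr__(self, "peaks", tuple(converted))

    @classmethod
    def from_d(cls, d_values, wavelength: float = CU_KA) -> "PeakList":
        return cls(tuple(Peak(float(d)) for d in d_values), wavelength)

    @classmethod
    def from_two_theta(cls, angles, wavelength: float = CU_KA) -> "PeakList":
        return cls(
            tuple(
                Peak(two_theta_to_d(a, wavelength), two_theta=a) for a in angles
            ),
            wavelength,
        )


DEFAULT_ORDERS = frozenset({2, 3, 4, 5})


@dataclass(frozen=True)
class HarmonicFamily:
    """A fundamental d-spacing with its assigned higher-order members."""

    fundamental: float
    members: tuple[tuple[float, int], ...]  # (d, assigned order n)
    tolerance: float

    def __post_init__(self) -> None:
        for d, n in self.members:
            if abs(self.fundamental / d - n) > self.tolerance * n + 1e-12:
                raise DomainError(
                    f"member d={d} is not order {n} of {self.fundamental} "
                    f"within {self.tolerance:.1%}"
                )


def assign_harmonics(
    pl: PeakList,
    tol: float = 0.02,
    orders: frozenset[int] = DEFAULT_ORDERS,
) -> list[HarmonicFamily]:
    """Greedy order assignment from the largest d-spacing down.

    Each candidate fundamental collects every smaller peak whose d ratio
    rounds to an allowed order within the relative tolerance.  A peak may
    serve in several families (e.g. one spacing being both n=2 and n=3 of
    two different fundamentals).  Only families with members are returned,
    in descending fundamental order.
    """
    if len(pl.peaks) < 2:
        return []
    ds = sorted({p.d for p in pl.peaks}, reverse=True)
    families = []
    for fundamental in ds:
        members = []
        for d in ds:
            if d >= fundamental:
                continue
            ratio = fundamental / d
            n = round(ratio)
            if n in orders and abs(ratio - n) <= tol * n:
                members.append((d, n))
        if members:
            families.append(
                HarmonicFamily(fundamental, tuple(members), tol)
            )
    return families


def model_spacings(
    params: GeometryParams, layout: RungLayout | None = None
) -> dict[str, float]:
    """Model-predicted periodicities, Å, labelled by their origin.

    Includes the axial rise h and its low multiples (stacks of 2-4 strands),
    the maximum Cα span of one rung, and the √3·n_s·δ trimer diameter.
    """
    h = params.rise * 10.0
    out = {
        "axial_rise": h,
        "two_strand_repeat": 2 * h,
        "three_strand_repeat": 3 * h,
        "four_strand_repeat": 4 * h,
        "trimer_diameter": math.sqrt(3.0) * params.side_length * 10.0,
    }
    if layout is not None:
        pts = build_rung(layout, params)
        span = max(
            math.dist(pts[i], pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        )
        out["rung_span"] = span * 10.0
    return out
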