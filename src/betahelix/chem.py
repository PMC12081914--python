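"""Peptide mass, charge and complexation arithmetic.

Covers the identity checks done by electrospray LCMS (monoisotopic masses and
[M + zH]z+ ions), Henderson–Hasselbalch net charge and isoelectric point,
peptide:nucleic-acid charge ratios, and dye-exclusion encapsulation
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError, InvalidSequenceError, PiUndefinedError
from .rung import validate_sequence

#: Monoisotopic residue masses (Da), standard 20 amino acids.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Average residue masses (Da).
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.0153
#: Proton mass used for m/z; reproduces the printed expected values to 0.01.
PROTON = 1.00728
#: C-terminal amidation (-OH -> -NH2) mass shift.
AMIDE_MONO = -0.98402
AMIDE_AVG = -0.985

#: EMBOSS-style pKa values; configurable because pI conventions vary.
DEFAULT_PKA = {
    "nterm": 8.6, "cterm": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide chain with its C-terminal chemistry (free acid or amide)."""

    sequence: str
    cterm: str = "acid"
    nterm: str = "amine"

    def __post_init__(self) -> None:
        seq = validate_sequence(self.sequence)
        if not seq:
            raise InvalidSequenceError("empty sequence")
        object.__setattr__(self, "sequence", seq)
        if self.cterm not in ("acid", "amide"):
            raise DomainError(f"cterm must be 'acid' or 'amide', got {self.cterm!r}")
        if self.nterm != "amine":
            raise DomainError(f"only free-amine N-termini supported, got {self.nterm!r}")


def peptide_mass(spec: PeptideSpec) -> dict[str, float]:
    """Monoisotopic and average mass (Da) of a peptide.

    Mass = sum of residue masses + water; a C-terminal amide subtracts
    0.98402 Da (monoisotopic) / 0.985 Da (average) relative to the free acid.
    """
    mono = sum(MONOISOTOPIC[a] for a in spec.sequence) + WATER_MONO
    avg = sum(AVERAGE[a] for a in spec.sequence) + WATER_AVG
    if spec.cterm == "amide":
        mono += AMIDE_MONO
        avg += AMIDE_AVG
    return {"monoisotopic": mono, "average": avg}


def mz(mass: float, z: int) -> float:
    """m/z of the [M + zH]z+ ion."""
    if z < 1:
        raise DomainError(f"charge state must be >= 1, got {z}")
    return (mass + z * PROTON) / z


def mass_from_mz(observed_mz: float, z: int) -> float:
    """Neutral mass implied by an observed [M + zH]z+ ion.

    Validation hook for candidate rung sequences: a candidate's monoisotopic
    mass should reproduce the observed assembly ions within ~0.01 per charge.
    """
    if z < 1:
        raise DomainError(f"charge state must be >= 1, got {z}")
    return observed_mz * z - z * PROTON


@dataclass(frozen=True)
class ChargeContext:
    """pH and the pKa table used for Henderson–Hasselbalch sums."""

    pH: float
    pKa_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self) -> None:
        if not 0 < self.pH < 14:
            raise DomainError(f"pH must be in (0, 14), got {self.pH}")
        missing = [g for g in ("nterm", "cterm", *_ACIDIC, *_BASIC)
                   if g not in self.pKa_table]
        if missing:
            raise DomainError(f"pKa table missing groups: {missing}")


def _net_charge(spec: PeptideSpec, pH: float, pka: dict[str, float]) -> float:
    positive = [pka["nterm"]] + [pka[a] for a in spec.sequence if a in _BASIC]
    negative = [pka[a] for a in spec.sequence if a in _ACIDIC]
    if spec.cterm == "acid":
        negative.append(pka["cterm"])
    z = sum(1.0 / (1.0 + 10 ** (pH - k)) for k in positive)
    z -= sum(1.0 / (1.0 + 10 ** (k - pH)) for k in negative)
    return z


def net_charge_and_pi(spec: PeptideSpec, ctx: ChargeContext) -> dict[str, float]:
    """Net charge at ctx.pH and the isoelectric point (bisection to 0.01 pH)."""
    pka = ctx.pKa_table
    charge = _net_charge(spec, ctx.pH, pka)
    lo, hi = 1e-4, 14 - 1e-4
    z_lo, z_hi = _net_charge(spec, lo, pka), _net_charge(spec, hi, pka)
    if z_lo <= 0 or z_hi >= 0:
        raise PiUndefinedError(
            "net charge does not cross zero between pH 0 and 14; pI undefined"
        )
    while hi - lo > 0.01:
        mid = 0.5 * (lo + hi)
        if _net_charge(spec, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return {"net_charge": charge, "pI": 0.5 * (lo + hi)}


@dataclass(frozen=True)
class ComplexSpec:
    """A peptide / nucleic-acid electrostatic complex.

    Charge ratio CR compares peptide amino groups (P) to nucleic-acid
    phosphate groups (N).  An siRNA duplex of two n-mers contributes
    2*(n-1) backbone phosphates by default (overhang chemistry aside).
    """

    peptide_mol: float
    positive_groups: int
    nucleic_mol: float
    phosphates: int

    def __post_init__(self) -> None:
        if self.peptide_mol <= 0 or self.nucleic_mol <= 0:
            raise DomainError("molar amounts must be positive")
        if self.positive_groups < 1 or self.phosphates < 1:
            raise DomainError("group counts must be >= 1")


def duplex_phosphates(n_bases: int) -> int:
    """Backbone phosphate count of a duplex of two n-mers: 2*(n-1)."""
    if n_bases < 2:
        raise DomainError(f"duplex strand length must be >= 2, got {n_bases}")
    return 2 * (n_bases - 1)


def charge_ratio(cs: ComplexSpec) -> float:
    """CR = (peptide mol x positive groups) / (nucleic mol x phosphates)."""
    return (cs.peptide_mol * cs.positive_groups) / (cs.nucleic_mol * cs.phosphates)


def encapsulation_efficiency(
    f_complex: float, f_free: float, f_background: float
) -> float:
    """Fraction of nucleic acid encapsulated, from dye-intercalation signals.

    EE = 1 - (F_complex - F_background) / (F_free - F_background), clamped to
    [0, 1].  F_free is the signal of uncomplexed nucleic acid.
    """
    if f_free <= f_background:
        raise DomainError(
            "degenerate assay: free-nucleic-acid signal does not exceed background"
        )
    ee = 1.0 - (f_complex - f_background) / (f_free - f_background)
    return min(1.0, max(0.0, ee))
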