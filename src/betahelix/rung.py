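"""Sequence-level design grammar for one triangular β-helical rung.

A rung is an 18-residue unit folding into an equilateral triangle of three
six-residue β-strands joined by turns.  Left-handed β-helix strands carry the
conserved hexapeptide repeat [LIV]-[GAED]-X-X-[STAV]-X (or the looser
[LIV]-G-X-X-X-X).  The design rules checked here are the ones that make the
rung self-assembly-competent: proline caps on both termini forming the
non-covalent third turn, two G-N-N covalent turns feeding asparagine ladders,
a single solvent-exposed tryptophan on the trimer interface, two lysines kept
off the inward-pointing core, and a hydrophobic fraction capped at 1:1.5
(hydrophobic : other) to avoid cytotoxicity.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

from Bio import SeqIO

from .errors import InvalidSequenceError, LayoutError

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic set; P, G and Y are counted as non-hydrophobic.
DEFAULT_HYDROPHOBIC = frozenset("ACFILMVW")

#: Synthetic design-compliant example rung (NOT a published sequence): proline
#: caps, two GNN turns at 5-7 and 11-13, W9 on the interface side, K3/K15 off
#: the core, six hydrophobic residues.
EXAMPLE_RUNG_SEQUENCE = "PIKAGNNAWVGNNIKSTP"

_HEXAPEPTIDE_PATTERNS = (
    ("LIV-GAED", re.compile(r"[LIV][GAED]..[STAV].")),
    ("LIV-G", re.compile(r"[LIV]G....")),
)

_KEY_ROLE_RESIDUE = {
    "tryptophan_interface": "W",
    "asn_ladder_1": "N",
    "asn_ladder_2": "N",
    "lysine_1": "K",
    "lysine_2": "K",
    "nterm_pro": "P",
    "cterm_pro": "P",
}

#: Ladder roles -> the key positions stacking vertically across rungs.
LADDER_ROLES = {
    "asn": ("asn_ladder_1", "asn_ladder_2"),
    "lys": ("lysine_1", "lysine_2"),
    "trp": ("tryptophan_interface",),
    "pro": ("nterm_pro", "cterm_pro"),
}

DEFAULT_SIDE_SPANS = ((1, 6), (7, 12), (13, 18))
DEFAULT_TURN_SPANS = ((5, 6, 7), (11, 12, 13))

DEFAULT_KEY_POSITIONS = {
    "tryptophan_interface": 9,
    "asn_ladder_1": 6,
    "asn_ladder_2": 7,
    "lysine_1": 3,
    "lysine_2": 15,
    "nterm_pro": 1,
    "cterm_pro": 18,
}


def validate_sequence(sequence: str) -> str:
    """Uppercase and validate a one-letter amino-acid string."""
    seq = sequence.strip().upper()
    for pos, letter in enumerate(seq, start=1):
        if letter not in STANDARD_AA:
            raise InvalidSequenceError(
                f"non-standard residue {letter!r} at position {pos}"
            )
    return seq


def read_sequence(source: str | Path) -> str:
    """Accept a plain sequence string, a FASTA string, or a FASTA file path."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(str(source)).is_file()
    ):
        records = list(SeqIO.parse(str(source), "fasta"))
        if len(records) != 1:
            raise InvalidSequenceError(
                f"expected a single FASTA record, found {len(records)}"
            )
        return validate_sequence(str(records[0].seq))
    text = str(source)
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(StringIO(text), "fasta"))
        if len(records) != 1:
            raise InvalidSequenceError(
                f"expected a single FASTA record, found {len(records)}"
            )
        return validate_sequence(str(records[0].seq))
    return validate_sequence(text)


@dataclass(frozen=True)
class MotifMatch:
    """One hexapeptide-repeat window match (1-based start)."""

    pattern_id: str
    start: int
    matched_text: str


def find_hexapeptide_repeats(sequence: str) -> list[MotifMatch]:
    """Scan all six-residue windows for the hexapeptide repeat patterns.

    Overlapping windows are reported, and a window matching both patterns
    yields two matches at the same start.
    """
    seq = validate_sequence(sequence)
    matches: list[MotifMatch] = []
    for start in range(len(seq) - 5):
        window = seq[start : start + 6]
        for pattern_id, pattern in _HEXAPEPTIDE_PATTERNS:
            if pattern.fullmatch(window):
                matches.append(MotifMatch(pattern_id, start + 1, window))
    return matches


@dataclass(frozen=True)
class RungLayout:
    """An 18-residue rung sequence annotated with side/turn/vertex roles.

    Indexing is 1-based throughout, matching residue numbering such as W9.
    """

    sequence: str
    side_spans: tuple[tuple[int, int], ...] = DEFAULT_SIDE_SPANS
    turn_spans: tuple[tuple[int, int, int], ...] = DEFAULT_TURN_SPANS
    interface_side: int = 2
    key_positions: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_KEY_POSITIONS)
    )

    def __post_init__(self) -> None:
        seq = validate_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) != 18:
            raise LayoutError(f"rung sequence must have 18 residues, got {len(seq)}")
        covered: list[int] = []
        for lo, hi in self.side_spans:
            if hi - lo != 5:
                raise LayoutError(f"side span {lo}-{hi} does not hold six residues")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, 19)):
            raise LayoutError("side spans must partition positions 1-18")
        seen: set[int] = set()
        for span in self.turn_spans:
            if len(span) != 3 or any(not 1 <= i <= 18 for i in span):
                raise LayoutError(f"turn span {span} outside positions 1-18")
            if seen & set(span):
                raise LayoutError("turn spans overlap")
            seen |= set(span)
        if not 1 <= self.interface_side <= len(self.side_spans):
            raise LayoutError(f"interface_side {self.interface_side} out of range")
        for role, index in self.key_positions.items():
            expected = _KEY_ROLE_RESIDUE.get(role)
            if expected is None:
                raise LayoutError(f"unknown key-position role {role!r}")
            if not 1 <= index <= 18:
                raise LayoutError(f"key position {role} index {index} out of range")
            if seq[index - 1] != expected:
                raise LayoutError(
                    f"key position {role} expects {expected} at {index}, "
                    f"found {seq[index - 1]}"
                )

    def residue(self, index: int) -> str:
        """Residue letter at a 1-based position."""
        return self.sequence[index - 1]

    def side_of(self, index: int) -> int:
        """1-based side number containing a residue position."""
        for side, (lo, hi) in enumerate(self.side_spans, start=1):
            if lo <= index <= hi:
                return side
        raise LayoutError(f"position {index} not on any side")


def default_core_positions(layout: RungLayout) -> frozenset[int]:
    """Inward-pointing (core) positions: hexapeptide anchor offsets 1 and 5.

    In the [LIV]-[GAED]-X-X-[STAV]-X repeat the first and fifth residues are
    the core-facing anchors, so each six-residue side contributes its first
    and fifth position.
    """
    core = set()
    for lo, _hi in layout.side_spans:
        core.add(lo)
        core.add(lo + 4)
    return frozenset(core)


@dataclass(frozen=True)
class RuleVerdict:
    passed: bool
    message: str


@dataclass(frozen=True)
class DesignReport:
    """Per-rule verdicts for the rung design grammar."""

    rules: dict[str, RuleVerdict]
    hydrophobic_ratio: tuple[int, int]

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.rules.values())

    def to_json(self) -> str:
        payload = {
            "passed": self.passed,
            "hydrophobic_ratio": list(self.hydrophobic_ratio),
            "rules": {
                name: {"passed": v.passed, "message": v.message}
                for name, v in self.rules.items()
            },
        }
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        width = max(len(name) for name in self.rules)
        lines = [
            f"{name:<{width}}  {'PASS' if v.passed else 'FAIL'}  {v.message}"
            for name, v in self.rules.items()
        ]
        lines.append(
            f"{'overall':<{width}}  {'PASS' if self.passed else 'FAIL'}  "
            f"hydrophobic:other = "
            f"{self.hydrophobic_ratio[0]}:{self.hydrophobic_ratio[1]}"
        )
        return "\n".join(lines)


def check_design(
    layout: RungLayout,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
    core_positions: frozenset[int] | None = None,
) -> DesignReport:
    """Evaluate the rung design rules and return a per-rule report.

    The hydrophobic-ratio rule passes when hydrophobic : other does not exceed
    1 : 1.5, i.e. at most 18/2.5 -> 7 hydrophobic residues in an 18-mer.
    """
    seq = layout.sequence
    if core_positions is None:
        core_positions = default_core_positions(layout)
    rules: dict[str, RuleVerdict] = {}

    rules["length"] = RuleVerdict(len(seq) == 18, f"{len(seq)} residues")

    term_ok = seq[0] == "P" and seq[17] == "P"
    rules["terminal_prolines"] = RuleVerdict(
        term_ok, f"positions 1/18 are {seq[0]}/{seq[17]}"
    )

    turn_reads = ["".join(layout.residue(i) for i in span) for span in layout.turn_spans]
    rules["gnn_turns"] = RuleVerdict(
        all(r == "GNN" for r in turn_reads), f"turns read {', '.join(turn_reads)}"
    )

    trp_positions = [i for i, a in enumerate(seq, start=1) if a == "W"]
    trp_key = layout.key_positions.get("tryptophan_interface")
    trp_ok = (
        len(trp_positions) == 1
        and trp_positions[0] == trp_key
        and layout.side_of(trp_key) == layout.interface_side
    )
    rules["tryptophan_interface"] = RuleVerdict(
        trp_ok,
        f"W at {trp_positions or 'none'}, interface side {layout.interface_side}",
    )

    lys_positions = [i for i, a in enumerate(seq, start=1) if a == "K"]
    lys_in_core = sorted(set(lys_positions) & set(core_positions))
    lys_ok = len(lys_positions) >= 2 and not lys_in_core
    rules["lysines_off_core"] = RuleVerdict(
        lys_ok, f"K at {lys_positions}, in-core {lys_in_core or 'none'}"
    )

    n_hydro = sum(1 for a in seq if a in hydrophobic_set)
    n_other = len(seq) - n_hydro
    # hydrophobic/total <= 1/2.5  <=>  n_hydro <= 18/2.5
    rules["hydrophobic_ratio"] = RuleVerdict(
        n_hydro * 2.5 <= len(seq),
        f"{n_hydro}:{n_other} (limit 1:1.5)",
    )

    return DesignReport(rules=rules, hydrophobic_ratio=(n_hydro, n_other))


def ladder_map(
    layout: RungLayout, n_rungs: int
) -> dict[str, list[tuple[int, int]]]:
    """Vertical ladder stacks: role -> [(rung index, residue index), ...].

    Each ladder role (asn, lys, trp, pro) stacks its key positions at the same
    residue index in every rung, one entry per rung per position.
    """
    if n_rungs < 1:
        raise ValueError(f"n_rungs must be >= 1, got {n_rungs}")
    ladders: dict[str, list[tuple[int, int]]] = {}
    for role, keys in LADDER_ROLES.items():
        entries: list[tuple[int, int]] = []
        for key in keys:
            if key not in layout.key_positions:
                continue
            index = layout.key_positions[key]
            entries.extend((rung, index) for rung in range(1, n_rungs + 1))
        ladders[role] = entries
    return ladders
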