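"""Idealized Cα models of the β-helix and its trimeric cylinder.

One rung is an equilateral triangle of side n_s·δ traced at uniform arc
length δ (18 Cα positions, six per side); consecutive rungs are related by a
screw transform (axial rise h, twist τ = 360·h/P about the cylinder axis,
negative sense for a left-handed helix).  The trimer is three helices related
by exact 120° rotations, each with its interface vertex (between sides 1 and
2, flanked by the N6/N7 turn and adjoining W9) at a small radial clearance v
from the shared axis.

Cα positions are placed with a half-step phase: the first residue of each
side sits δ/2 past the corner, so every triangle vertex falls midway between
its two flanking residues.  This puts the terminal prolines symmetrically
about the non-covalent turn vertex and N6/N7 about the interface vertex.
Units are nm throughout; PDB export converts to Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .rung import RungLayout

ATOM_COLUMNS = ["chain", "rung", "resi", "aa", "x", "y", "z"]


@dataclass(frozen=True)
class GeometryParams:
    """Geometric parameters of the idealized solenoid.

    spacing          per-residue Cα spacing δ along the strand, nm
    residues_per_side  residues in one β-strand side, n_s
    rise             axial rise h between consecutive rungs, nm
    pitch            helical pitch P of the assembled cylinder, nm
    handedness       'left' or 'right'; left = negative twist with +z
    vertex_clearance radial offset v of the interface vertex from the axis, nm
    """

    spacing: float = 0.34
    residues_per_side: int = 6
    rise: float = 0.47
    pitch: float = 28.5
    handedness: str = "left"
    vertex_clearance: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.spacing < 1:
            raise DomainError(f"spacing must be in (0, 1) nm, got {self.spacing}")
        if self.rise <= 0:
            raise DomainError(f"rise must be positive, got {self.rise}")
        if self.pitch <= self.rise:
            raise DomainError("pitch must exceed the axial rise")
        if self.residues_per_side < 2:
            raise DomainError("need at least 2 residues per side")
        if self.vertex_clearance < 0:
            raise DomainError("vertex clearance must be non-negative")
        if self.handedness not in ("left", "right"):
            raise DomainError(f"handedness must be 'left' or 'right'")

    @property
    def side_length(self) -> float:
        """Triangle side s = n_s·δ, nm."""
        return self.residues_per_side * self.spacing

    @property
    def twist_per_rung(self) -> float:
        """Unsigned twist per rung τ = 360·h/P, degrees."""
        return 360.0 * self.rise / self.pitch

    @property
    def signed_twist(self) -> float:
        """Twist per rung with the handedness sign (left = negative)."""
        return -self.twist_per_rung if self.handedness == "left" else self.twist_per_rung


@dataclass(frozen=True)
class SolenoidModel:
    """Labelled Cα coordinates of an n-rung helix or C3 trimer (nm)."""

    atoms: pd.DataFrame
    params: GeometryParams
    layout: RungLayout
    n_chains: int
    n_rungs: int

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy()

    def labels(self) -> list[tuple[str, int, int]]:
        return list(
            zip(self.atoms["chain"], self.atoms["rung"], self.atoms["resi"])
        )

    def select(self, chain=None, rung=None, resi=None) -> pd.DataFrame:
        out = self.atoms
        for col, want in (("chain", chain), ("rung", rung), ("resi", resi)):
            if want is None:
                continue
            if isinstance(want, (set, frozenset, list, tuple)):
                out = out[out[col].isin(want)]
            else:
                out = out[out[col] == want]
        return out


def build_rung(layout: RungLayout, params: GeometryParams) -> np.ndarray:
    """18 Cα positions in the z=0 plane, ordered by residue index.

    The interface vertex (between sides 1 and 2) lies on the +x axis at
    radius vertex_clearance, nearest the origin; the triangle opens toward
    +x with its bisector along x.
    """
    n = len(layout.sequence)
    s = params.side_length
    v1 = np.array([params.vertex_clearance, 0.0])
    half = math.radians(30.0)
    v2 = v1 + s * np.array([math.cos(half), math.sin(half)])
    v3 = v1 + s * np.array([math.cos(half), -math.sin(half)])
    # perimeter runs side1 (v3 -> v1), side2 (v1 -> v2), side3 (v2 -> v3)
    corners = (v3, v1, v2, v3)
    points = np.empty((n, 2))
    for i in range(n):
        arc = (i + 0.5) * params.spacing
        side = min(int(arc // s), 2)
        t = (arc - side * s) / s
        points[i] = corners[side] * (1 - t) + corners[side + 1] * t
    return np.hstack([points, np.zeros((n, 1))])


def _rotz(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_helix(
    layout: RungLayout, params: GeometryParams, n_rungs: int
) -> SolenoidModel:
    """Stack n_rungs copies of the base rung with the screw transform."""
    if n_rungs < 1:
        raise DomainError(f"n_rungs must be >= 1, got {n_rungs}")
    base = build_rung(layout, params)
    frames = []
    for k in range(n_rungs):
        coords = base @ _rotz(k * params.signed_twist).T
        coords[:, 2] += k * params.rise
        frames.append(
            pd.DataFrame(
                {
                    "chain": "A",
                    "rung": k + 1,
                    "resi": np.arange(1, len(layout.sequence) + 1),
                    "aa": list(layout.sequence),
                    "x": coords[:, 0],
                    "y": coords[:, 1],
                    "z": coords[:, 2],
                }
            )
        )
    atoms = pd.concat(frames, ignore_index=True)
    return SolenoidModel(atoms, params, layout, n_chains=1, n_rungs=n_rungs)


def build_trimer(
    layout: RungLayout, params: GeometryParams, n_rungs: int
) -> SolenoidModel:
    """Three helices related by exact 120° rotations about the z axis."""
    single = build_helix(layout, params, n_rungs)
    frames = []
    for i, chain in enumerate("ABC"):
        df = single.atoms.copy()
        coords = df[["x", "y", "z"]].to_numpy() @ _rotz(120.0 * i).T
        df["chain"] = chain
        df[["x", "y", "z"]] = coords
        frames.append(df)
    atoms = pd.concat(frames, ignore_index=True)
    return SolenoidModel(atoms, params, layout, n_chains=3, n_rungs=n_rungs)


def predicted_diameter(spacing: float = 0.34, residues_per_side: int = 6) -> float:
    """Estimated cylinder diameter √3·(n_s·δ), reported to 0.1 nm.

    Twice the vertex-to-opposite-side height of the vertex-at-axis packing of
    three perfect equilateral triangular units.
    """
    if spacing <= 0:
        raise DomainError(f"spacing must be positive, got {spacing}")
    return round(math.sqrt(3.0) * residues_per_side * spacing, 1)


def mass_per_length(model: SolenoidModel, chain_mass: float) -> float:
    """(n_chains x n_rungs x chain mass) / axial extent, Da per nm."""
    z = model.atoms["z"].to_numpy()
    extent = float(z.max() - z.min())
    if extent <= 0:
        raise DomainError("axial extent is zero (single-rung model)")
    return model.n_chains * model.n_rungs * chain_mass / extent
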