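"""Coordinate analyses: distance maps, Kabsch RMSD, Rg, dihedrals.

These re-create the standard desk-side analyses applied to solenoid models
and MD-style Cα snapshots: dense Euclidean distance maps with region
averaging, least-squares superposition, radius of gyration, backbone φ/ψ
dihedrals with Ramachandran-region classification, and the mean axial rise
of a built model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .builder import SolenoidModel
from .errors import DomainError, EmptyRegionError

#: Dense-matrix guard: distance maps are desk-scale objects.
MAX_ATOMS = 20_000

Label = tuple[str, int, int]  # (chain, rung, residue index)


@dataclass(frozen=True)
class DistanceMap:
    """Pairwise Cα distance matrix (nm) with (chain, rung, resi) labels."""

    labels: tuple[Label, ...]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(self.labels, names=["chain", "rung", "resi"])
        return pd.DataFrame(self.matrix, index=index, columns=index)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _coerce(model_or_coords, labels=None):
    if isinstance(model_or_coords, SolenoidModel):
        return model_or_coords.coords(), tuple(model_or_coords.labels())
    coords = np.asarray(model_or_coords, dtype=float)
    if labels is None:
        labels = tuple(("A", 1, i + 1) for i in range(len(coords)))
    return coords, tuple(labels)


def distance_map(model_or_coords, labels=None) -> DistanceMap:
    """Full symmetric Euclidean Cα distance matrix in nm."""
    coords, labels = _coerce(model_or_coords, labels)
    if len(coords) < 2:
        raise DomainError("distance map needs at least 2 atoms")
    if len(coords) > MAX_ATOMS:
        raise DomainError(
            f"{len(coords)} atoms exceeds the {MAX_ATOMS}-atom dense-map limit"
        )
    if len(set(labels)) != len(labels):
        raise DomainError("duplicate atom labels")
    return DistanceMap(labels, squareform(pdist(coords)))


@dataclass(frozen=True)
class RegionSpec:
    """Two label selectors and the statistic taken over their cross pairs.

    Selectors are either callables on (chain, rung, resi) labels or dicts of
    per-field constraints, e.g. ``{"resi": 9}`` or ``{"chain": {"A", "B"}}``.
    """

    name: str
    select_a: Callable[[Label], bool] | dict
    select_b: Callable[[Label], bool] | dict
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "min", "max"):
            raise DomainError(f"unknown statistic {self.statistic!r}")


def _matches(selector, label: Label) -> bool:
    if callable(selector):
        return bool(selector(label))
    fields = {"chain": label[0], "rung": label[1], "resi": label[2]}
    for key, want in selector.items():
        value = fields[key]
        if isinstance(want, (set, frozenset, list, tuple, range)):
            if value not in want:
                return False
        elif value != want:
            return False
    return True


def region_stats(dmap: DistanceMap, spec: RegionSpec) -> float:
    """Statistic over all A x B cross pairs, self-pairs excluded."""
    idx_a = [i for i, lab in enumerate(dmap.labels) if _matches(spec.select_a, lab)]
    idx_b = [i for i, lab in enumerate(dmap.labels) if _matches(spec.select_b, lab)]
    values = [
        dmap.matrix[i, j] for i in idx_a for j in idx_b if i != j
    ]
    if not values:
        raise EmptyRegionError(f"region {spec.name!r} selected no atom pairs")
    values = np.asarray(values)
    return float({"mean": values.mean, "min": values.min, "max": values.max}[
        spec.statistic
    ]())


def kabsch_rmsd(coords_a, coords_b) -> dict:
    """Optimal least-squares superposition of two equal-length Cα sets.

    Returns the RMSD after superposition together with the proper rotation
    (det = +1; an improper optimum is corrected by flipping the smallest
    singular direction) and the translation mapping B onto A.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 3 or a.shape[1] != 3:
        raise DomainError("need >= 3 points of dimension 3")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    u, s, vt = np.linalg.svd(b0.T @ a0)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rotation = u @ flip @ vt
    aligned = b0 @ rotation
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - a0) ** 2, axis=1))))
    translation = ca - cb @ rotation
    return {"rmsd": rmsd, "rotation": rotation, "translation": translation}


def radius_of_gyration(coords) -> float:
    """Unweighted sqrt(mean squared distance from the centroid), nm."""
    c = np.asarray(coords, dtype=float)
    if c.ndim == 1:
        c = c[None, :]
    if len(c) == 0:
        raise DomainError("radius of gyration needs at least one point")
    centered = c - c.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(residues: Iterable[dict | None]) -> pd.DataFrame:
    """Per-residue (φ, ψ) from N/CA/C backbone coordinates.

    Input is a sequence of per-residue mappings with keys "N", "CA", "C"
    (None marks a residue with missing atoms; a warning is issued and the
    dihedrals spanning it are left undefined).  The first φ and last ψ are
    NaN by definition.
    """
    res = list(residues)
    n = len(res)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    if any(r is None for r in res):
        warnings.warn("residues with missing backbone atoms skipped", stacklevel=2)
    for i, r in enumerate(res):
        if r is None:
            continue
        prev_r = res[i - 1] if i > 0 else None
        next_r = res[i + 1] if i < n - 1 else None
        if prev_r is not None:
            phi[i] = dihedral(prev_r["C"], r["N"], r["CA"], r["C"])
        if next_r is not None:
            psi[i] = dihedral(r["N"], r["CA"], r["C"], next_r["N"])
    return pd.DataFrame({"phi": phi, "psi": psi})


#: Rectangular Ramachandran regions, degrees.  The β region wraps in ψ.
RAMA_REGIONS = {
    "beta": {"phi": (-180.0, -45.0), "psi": ((45.0, 180.0), (-180.0, -150.0))},
    "right_alpha": {"phi": (-160.0, -20.0), "psi": ((-120.0, 45.0),)},
    "left_handed": {"phi": (20.0, 125.0), "psi": ((-45.0, 90.0),)},
}


def rama_classify(phi: float, psi: float, regions: dict | None = None) -> str:
    """Classify a (φ, ψ) pair into beta / right_alpha / left_handed / other."""
    if not (-180.0 <= phi <= 180.0 and -180.0 <= psi <= 180.0):
        raise DomainError("angles must lie in [-180, 180] degrees")
    regions = RAMA_REGIONS if regions is None else regions
    for label, box in regions.items():
        lo, hi = box["phi"]
        if label == "left_handed":
            phi_ok = lo < phi <= hi
        else:
            phi_ok = lo <= phi <= hi
        if not phi_ok:
            continue
        for plo, phi_hi in box["psi"]:
            if label == "right_alpha":
                if plo <= psi < phi_hi:
                    return label
            elif plo <= psi <= phi_hi:
                return label
    return "other"


def measure_axial_rise(model: SolenoidModel) -> float:
    """Mean Δz between equivalent Cα atoms of consecutive rungs, nm."""
    if model.n_rungs < 2:
        raise DomainError("axial rise needs at least 2 rungs")
    deltas = []
    for (_chain, _resi), group in model.atoms.groupby(["chain", "resi"]):
        z = group.sort_values("rung")["z"].to_numpy()
        deltas.extend(np.diff(z))
    return float(np.mean(deltas))
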