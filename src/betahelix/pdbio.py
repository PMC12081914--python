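"""PDB import/export for Cα (and backbone) coordinate sets, via gemmi.

Model coordinates are kept in nm internally; PDB files use Å.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import pandas as pd

from .builder import ATOM_COLUMNS, SolenoidModel

NM_TO_ANGSTROM = 10.0

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_ONE_LETTER = {v: k for k, v in _THREE_LETTER.items()}


def write_pdb(model: SolenoidModel, path: str | Path) -> None:
    """Write a Cα-only model as strict PDB v3.3 ATOM records (coordinates Å).

    Residue serial within a chain is (rung - 1) * 18 + residue index.
    """
    structure = gemmi.Structure()
    structure.name = "betahelix model"
    gmodel = gemmi.Model("1")
    n_per_rung = len(model.layout.sequence)
    for chain_id, chain_df in model.atoms.groupby("chain", sort=True):
        chain = gemmi.Chain(str(chain_id))
        for row in chain_df.itertuples():
            residue = gemmi.Residue()
            residue.name = _THREE_LETTER[row.aa]
            residue.seqid = gemmi.SeqId((row.rung - 1) * n_per_rung + row.resi, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.pos = gemmi.Position(
                row.x * NM_TO_ANGSTROM,
                row.y * NM_TO_ANGSTROM,
                row.z * NM_TO_ANGSTROM,
            )
            residue.add_atom(atom)
            chain.add_residue(residue)
        gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_ca(path: str | Path) -> pd.DataFrame:
    """Read the Cα subset of an arbitrary PDB file (coordinates in nm).

    Returns a DataFrame with the model atom columns; the rung index is left
    at 1 for externally produced files (no rung annotation in plain PDB).
    """
    structure = gemmi.read_structure(str(path))
    rows = []
    for gmodel in structure:
        for chain in gmodel:
            for residue in chain:
                for atom in residue:
                    if atom.name != "CA":
                        continue
                    rows.append(
                        {
                            "chain": chain.name,
                            "rung": 1,
                            "resi": residue.seqid.num,
                            "aa": _ONE_LETTER.get(residue.name, "X"),
                            "x": atom.pos.x / NM_TO_ANGSTROM,
                            "y": atom.pos.y / NM_TO_ANGSTROM,
                            "z": atom.pos.z / NM_TO_ANGSTROM,
                        }
                    )
        break  # first model only
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def read_backbone(path: str | Path) -> list[dict[str, tuple[float, float, float]]]:
    """Read per-residue N/CA/C backbone coordinates (nm) from a PDB file.

    Residues missing any of the three atoms are returned as None entries so
    the dihedral routine can skip across gaps.
    """
    structure = gemmi.read_structure(str(path))
    residues: list[dict | None] = []
    for gmodel in structure:
        for chain in gmodel:
            for residue in chain:
                entry = {}
                for name in ("N", "CA", "C"):
                    atom = residue.find_atom(name, "*")
                    if atom is None:
                        entry = None
                        break
                    entry[name] = (
                        atom.pos.x / NM_TO_ANGSTROM,
                        atom.pos.y / NM_TO_ANGSTROM,
                        atom.pos.z / NM_TO_ANGSTROM,
                    )
                residues.append(entry)
        break
    return residues
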