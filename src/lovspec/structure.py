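"""Edge-to-edge chromophore–residue distances from PDB coordinates.

"Edge-to-edge" is implemented as the minimum heavy-atom pair distance
between two atom selections — by default the FMN isoalloxazine ring system
on one side and the aromatic ring system of a candidate electron-donor side
chain (Tyr phenol + OH, Trp indole) on the other. The atom sets are
configurable since conventions differ between studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from lovspec.errors import ParseError, ValidationError

#: isoalloxazine ring heavy atoms of FMN (PDB chemical-component names)
ISOALLOXAZINE_ATOMS = frozenset(
    {
        "N1", "C2", "N3", "C4", "C4A", "N5", "C5A",
        "C6", "C7", "C8", "C9", "C9A", "N10", "C10",
    }
)

#: tyrosine phenol ring carbons plus the hydroxyl oxygen
TYR_RING_ATOMS = frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"})

#: tryptophan indole ring heavy atoms
TRP_RING_ATOMS = frozenset(
    {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}
)

_DEFAULT_ATOM_SETS = {"FMN": ISOALLOXAZINE_ATOMS, "TYR": TYR_RING_ATOMS, "TRP": TRP_RING_ATOMS}


def parse_structure(path: str | Path) -> pd.DataFrame:
    """Atom table from a PDB file via Biopython.

    Columns: chain, resnum, resname, atom, element, x, y, z (Å),
    is_hydrogen. For disordered atoms the 'A' alternate location (or the
    first available) is kept; hydrogens are flagged, not dropped.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Atom import DisorderedAtom

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not a parseable PDB file ({exc})") from exc

    rows = []
    model = next(structure.get_models(), None)
    if model is None:
        raise ParseError(f"{path}: no models in file")
    for chain in model:
        for residue in chain:
            for atom in residue:
                if isinstance(atom, DisorderedAtom) or atom.is_disordered():
                    child = (
                        atom.disordered_get("A")
                        if atom.disordered_has_id("A")
                        else atom.disordered_get_list()[0]
                    )
                else:
                    child = atom
                element = (child.element or "").strip().upper()
                x, y, z = child.coord
                rows.append(
                    {
                        "chain": chain.id,
                        "resnum": residue.id[1],
                        "resname": residue.get_resname().strip(),
                        "atom": child.get_name().strip(),
                        "element": element,
                        "x": float(x),
                        "y": float(y),
                        "z": float(z),
                        "is_hydrogen": element in ("H", "D"),
                    }
                )
    if not rows:
        raise ParseError(f"{path}: no atoms found")
    return pd.DataFrame(rows)


@dataclass
class AtomSelection:
    """A set of atoms: optional chain / residue filters plus an atom-name set.

    ``atom_names=None`` selects every (heavy) atom of the matching residues;
    hydrogens are excluded unless ``include_hydrogens`` is set.
    """

    resname: str | None = None
    resnum: int | None = None
    chain: str | None = None
    atom_names: frozenset[str] | None = None
    include_hydrogens: bool = False
    label: str = ""

    def apply(self, atoms: pd.DataFrame) -> pd.DataFrame:
        mask = np.ones(len(atoms), dtype=bool)
        if self.chain is not None:
            mask &= atoms["chain"].to_numpy() == self.chain
        if self.resnum is not None:
            mask &= atoms["resnum"].to_numpy() == self.resnum
        if self.resname is not None:
            mask &= atoms["resname"].to_numpy() == self.resname
        if self.atom_names is not None:
            mask &= atoms["atom"].isin(self.atom_names).to_numpy()
        if not self.include_hydrogens:
            mask &= ~atoms["is_hydrogen"].to_numpy()
        subset = atoms[mask]
        if subset.empty:
            raise ValidationError(f"selection {self.describe()} matches no atoms")
        return subset

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = [p for p in (self.chain, self.resname, self.resnum) if p is not None]
        return ":".join(str(p) for p in parts) or "<all atoms>"


def default_selection(
    resname: str, resnum: int | None = None, chain: str | None = None
) -> AtomSelection:
    """Selection with the conventional ring-atom set for FMN/TYR/TRP (falls
    back to all heavy atoms for other residues)."""
    return AtomSelection(
        resname=resname,
        resnum=resnum,
        chain=chain,
        atom_names=_DEFAULT_ATOM_SETS.get(resname.upper()),
    )


@dataclass
class EdgeDistance:
    distance: float  # Å
    atom_a: str
    atom_b: str
    selection_a: str
    selection_b: str


def edge_to_edge(
    a: AtomSelection, b: AtomSelection, atoms: pd.DataFrame
) -> EdgeDistance:
    """Minimum pairwise distance between two selections, with the achieving
    atom pair."""
    sub_a = a.apply(atoms)
    sub_b = b.apply(atoms)
    coords_a = sub_a[["x", "y", "z"]].to_numpy()
    coords_b = sub_b[["x", "y", "z"]].to_numpy()
    dists = cdist(coords_a, coords_b)
    i, j = np.unravel_index(np.argmin(dists), dists.shape)
    row_a = sub_a.iloc[int(i)]
    row_b = sub_b.iloc[int(j)]
    return EdgeDistance(
        distance=float(dists[i, j]),
        atom_a=f"{row_a.resname}{row_a.resnum}:{row_a.atom}",
        atom_b=f"{row_b.resname}{row_b.resnum}:{row_b.atom}",
        selection_a=a.describe(),
        selection_b=b.describe(),
    )
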