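"""Protein structure model: parsing, numbering, and sequence extraction.

Structures are read with gemmi (PDB and mmCIF) and reduced to a plain
polymer-only representation: ordered residues with their atoms, one chain
label each, and a numbering offset that reconciles file numbering with the
numbering used in reports (e.g. a mature protein numbered from 23 after
removal of a 22-residue signal peptide).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Standard 20 amino acids, three-letter to one-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    """A single atom: label, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    """One polymer residue identified by (chain_id, seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        """Field-style identifier, e.g. ``D59`` (one-letter code + seq number)."""
        return f"{self.one_letter}{self.seq_number}"


@dataclass
class Structure:
    """An ordered list of polymer residues plus a report-numbering offset.

    ``numbering_offset`` records the cumulative shift applied by
    :func:`renumber` relative to the numbering found in the source file.
    """

    id: str
    residues: list[Residue] = field(default_factory=list)
    numbering_offset: int = 0

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen


def _select_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to the first."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
        elif a.occ > by_name[a.name].occ:
            by_name[a.name] = a
    return [by_name[n] for n in order]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a polymer-only :class:`Structure`.

    Waters, ions and other non-amino-acid heterogens are dropped; for altloc
    duplicates the highest-occupancy conformer is kept (ties: first seen).
    Only the first model of a multi-model file is read (use
    :func:`bridgeforge.flex.read_trajectory` for trajectories).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValidationError(f"unknown structure format: {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc

    st.setup_entities()
    out = Structure(id=st.name or path.stem)
    if len(st) == 0:
        raise ParseError(f"{path.name}: no polymer residues found")
    model = st[0]
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            atoms = _select_altloc(list(res))
            residue = Residue(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=res.name.upper(),
                atoms=[
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        altloc=(a.altloc or "").strip("\x00").strip(),
                    )
                    for a in atoms
                ],
            )
            out.residues.append(residue)
    if not out.residues:
        raise ParseError(f"{path.name}: no polymer residues found")
    _check_unique(out)
    return out


def _check_unique(structure: Structure) -> None:
    seen = set()
    for r in structure.residues:
        key = (r.chain_id, r.seq_number, r.insertion_code)
        if key in seen:
            raise ValidationError(f"duplicate residue identifier {key}")
        seen.add(key)


def extract_sequence(structure: Structure) -> str:
    """One-letter sequence, in residue order; nonstandard residues become X."""
    if not structure.residues:
        raise ValidationError("cannot extract a sequence from an empty structure")
    return "".join(r.one_letter for r in structure.residues)


def renumber(structure: Structure, offset: int) -> Structure:
    """Return a copy with every residue number shifted by ``offset``.

    The shift is recorded in ``numbering_offset`` so the operation is
    invertible: ``renumber(renumber(s, k), -k)`` equals ``s``.
    """
    out = copy.deepcopy(structure)
    for r in out.residues:
        r.seq_number += offset
    out.numbering_offset = structure.numbering_offset + offset
    return out


def write_pdb(structure: Structure) -> str:
    """Render the structure as minimal PDB ATOM records (single model)."""
    lines = []
    serial = 0
    for r in structure.residues:
        for a in r.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{(a.altloc or ' '):1s}{r.res_name:>3s} "
                f"{r.chain_id[:1]:1s}{r.seq_number:4d}{(r.insertion_code or ' '):1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
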