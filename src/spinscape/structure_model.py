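"""Protein structure container and PDB input/output.

A deliberately small coordinate/topology model: ordered heavy atoms with a
residue index, enough for attachment-frame superposition and hard-sphere
clash detection. Parsing and serialisation are delegated to gemmi.

Conventions (documented, configurable where noted):

* altloc: the highest-occupancy alternate location is kept; ties resolve
  to the alphabetically first altloc identifier (so 'A' wins).
* hydrogens (and deuterium) are dropped by default — clash cutoffs are
  heavy-atom-scale and crystal/predicted models are typically H-free.
* HETATM waters and monoatomic ions are dropped; other heteroatoms are
  kept as part of the excluded volume.
* residue numbering follows the file verbatim; sites are addressed as
  ``(chain, resnum)`` or ``"A:28"`` strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "PDBParseError",
    "MAIN_CHAIN_NAMES",
    "parse_site",
    "read_pdb",
    "write_pdb",
    "get_site_atoms",
]

MAIN_CHAIN_NAMES = ("N", "CA", "C", "O")

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a usable structure."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: name, element, position (Å) and residue identity."""

    name: str
    element: str
    coords: np.ndarray
    residue_id: tuple[str, int, str]  # (chain, resnum, insertion code)
    resname: str = ""
    het: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)

    @property
    def is_main_chain(self) -> bool:
        return self.name in MAIN_CHAIN_NAMES


def parse_site(site) -> tuple[str, int, str]:
    """Normalise a site address to ``(chain, resnum, icode)``.

    Accepts ``"A:28"``, ``("A", 28)`` or ``("A", 28, "")``.
    """
    if isinstance(site, str):
        chain, _, num = site.partition(":")
        if not num:
            raise ValueError(f"site {site!r}: expected 'CHAIN:RESNUM'")
        return chain, int(num), ""
    site = tuple(site)
    if len(site) == 2:
        return str(site[0]), int(site[1]), ""
    if len(site) == 3:
        return str(site[0]), int(site[1]), str(site[2])
    raise ValueError(f"cannot interpret site address {site!r}")


@dataclass
class ProteinStructure:
    """Ordered atom list plus a residue lookup table."""

    atoms: list[AtomRecord]
    name: str = ""
    _residues: dict[tuple[str, int, str], list[int]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self):
        if not self._residues:
            for i, atom in enumerate(self.atoms):
                self._residues.setdefault(atom.residue_id, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residue_ids(self) -> list[tuple[str, int, str]]:
        return list(self._residues)

    def residue_atoms(self, site) -> list[AtomRecord]:
        """All atoms of a residue, in file order."""
        rid = parse_site(site)
        if rid not in self._residues:
            raise KeyError(f"residue {rid} not found in structure")
        return [self.atoms[i] for i in self._residues[rid]]

    def residue_atom_indices(self, site) -> list[int]:
        rid = parse_site(site)
        if rid not in self._residues:
            raise KeyError(f"residue {rid} not found in structure")
        return list(self._residues[rid])

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)


def _validate_coordinate_columns(path: Path) -> None:
    # gemmi silently zero-fills malformed coordinate fields; pre-scan so the
    # error can name the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    text = line[lo:hi].strip()
                    try:
                        float(text)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}: malformed coordinate field {text!r} "
                            f"on line {lineno}"
                        ) from None


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to first altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key = (-atom.occ, atom.altloc or "~")
        prev_key = (-prev.occ, prev.altloc or "~")
        if key < prev_key:
            by_name[atom.name] = atom
    # preserve file order of first occurrence
    seen: list[gemmi.Atom] = []
    names_done = set()
    for atom in residue:
        if atom.name not in names_done:
            seen.append(by_name[atom.name])
            names_done.add(atom.name)
    return seen


def read_pdb(path, keep_hydrogens: bool = False) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only the first model of a multi-model file is used. Waters and
    monoatomic HETATM ions are dropped; hydrogens are dropped unless
    ``keep_hydrogens``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_coordinate_columns(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no parsable ATOM/HETATM records")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            if het:
                if residue.name in _WATER_NAMES:
                    continue
                if len(residue) == 1 and residue[0].element.is_metal:
                    continue  # monoatomic ion
            for atom in _select_altlocs(residue):
                elem = atom.element.name
                if not keep_hydrogens and elem in ("H", "D"):
                    continue
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=elem,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_id=(chain.name, residue.seqid.num, residue.seqid.icode.strip()),
                        resname=residue.name,
                        het=het,
                    )
                )
    if not atoms:
        raise PDBParseError(f"{path}: no parsable ATOM/HETATM records")
    return ProteinStructure(atoms=atoms, name=path.stem)


def _gemmi_model(atoms: list[AtomRecord], num: int) -> gemmi.Model:
    # gemmi's add_residue/add_chain copy their argument, so residues and
    # chains must be fully populated before insertion
    grouped: dict[str, dict[tuple[str, int, str], list[AtomRecord]]] = {}
    for rec in atoms:
        grouped.setdefault(rec.residue_id[0], {}).setdefault(rec.residue_id, []).append(rec)

    model = gemmi.Model(num)
    for chain_name, residues in grouped.items():
        chain = gemmi.Chain(chain_name)
        for (_, resnum, icode), recs in residues.items():
            res = gemmi.Residue()
            res.name = recs[0].resname or "UNK"
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            res.het_flag = "H" if recs[0].het else "A"
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.name
                atom.element = gemmi.Element(rec.element)
                atom.pos = gemmi.Position(*rec.coords)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    return model


def write_pdb(obj, path) -> None:
    """Write a :class:`ProteinStructure` or a rotamer ensemble to PDB.

    Ensembles (anything exposing ``to_atom_record_models()``) are written
    as MODEL/ENDMDL blocks, one model per conformer.
    """
    if hasattr(obj, "to_atom_record_models"):
        models = obj.to_atom_record_models()
    elif isinstance(obj, ProteinStructure):
        if len(obj) == 0:
            raise ValueError("refusing to write an empty structure")
        models = [obj.atoms]
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    if not models:
        raise ValueError("refusing to write an empty ensemble")

    st = gemmi.Structure()
    for i, atom_list in enumerate(models, start=1):
        st.add_model(_gemmi_model(atom_list, i))
    st.write_pdb(str(path))


def get_site_atoms(
    structure: ProteinStructure, site, selection: str = "main_chain"
) -> list[AtomRecord]:
    """Atoms of a labelling site.

    ``selection='main_chain'`` returns exactly N, CA, C, O in that order
    (raising if any is absent); ``selection='all'`` returns every heavy
    atom of the residue in file order.
    """
    atoms = structure.residue_atoms(site)
    if selection == "all":
        return atoms
    if selection != "main_chain":
        raise ValueError(f"unknown selection {selection!r}")
    by_name = {a.name: a for a in atoms}
    missing = [n for n in MAIN_CHAIN_NAMES if n not in by_name]
    if missing:
        raise KeyError(
            f"residue {parse_site(site)} lacks main-chain atom(s) {missing}"
        )
    return [by_name[n] for n in MAIN_CHAIN_NAMES]


def site_main_chain_coords(structure: ProteinStructure, site) -> np.ndarray:
    """(4, 3) array of the site's N, CA, C, O coordinates."""
    return np.array([a.coords for a in get_site_atoms(structure, site)])
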