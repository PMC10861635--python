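"""Rotamer ensembles: accepted label conformers at a site (or site pair)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_model import AtomRecord

__all__ = ["RotamerEnsemble"]


@dataclass
class RotamerEnsemble:
    """Accepted conformers of one label at one site (or dHis site pair).

    Attributes
    ----------
    label : label name.
    sites : tuple of site residue ids ((chain, resnum, icode)).
    atom_names, elements : per-atom metadata shared by all conformers.
    dihedrals : (n_conf, n_chi) chi vectors, degrees.
    coords : (n_conf, n_atoms, 3) coordinates in the protein frame, Å.
    spin_centers : (n_conf, 3) spin-center positions.
    weights : per-conformer probabilities (non-negative, unit sum).
    meta : provenance (settings, seed, trial counts, ...).
    """

    label: str
    sites: tuple
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    dihedrals: np.ndarray
    coords: np.ndarray
    spin_centers: np.ndarray
    weights: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spin_centers = np.asarray(self.spin_centers, dtype=float)
        n = len(self.coords)
        if self.weights is None:
            self.weights = (
                np.full(n, 1.0 / n) if n else np.zeros(0)
            )
        self.weights = np.asarray(self.weights, dtype=float)
        if n:
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights must have positive sum")
            self.weights = self.weights / total

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def to_atom_record_models(self) -> list[list[AtomRecord]]:
        """One AtomRecord list per conformer, for MODEL/ENDMDL PDB output."""
        if self.is_empty:
            return []
        resname = self.label[:3].upper() or "LBL"
        models = []
        for conf in self.coords:
            models.append(
                [
                    AtomRecord(
                        name=name,
                        element=elem,
                        coords=xyz,
                        residue_id=("X", 1, ""),
                        resname=resname,
                        het=True,
                    )
                    for name, elem, xyz in zip(self.atom_names, self.elements, conf)
                ]
            )
        return models
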