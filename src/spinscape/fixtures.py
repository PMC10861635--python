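"""Synthetic test structures: ideal polyalanine scaffolds and clash cages.

These stand-ins let the whole labelling pipeline run without downloading
any real structure. They are explicitly synthetic: an ideal-geometry
polyalanine backbone (helix phi = -57, psi = -47; strand phi = -119,
psi = 113) with a CB on every residue, cysteine mutation sites for
monopedal labels, and double-histidine (dHis) motifs — full ideal
imidazole side chains at i,i+4 (helix) or i,i+2 (strand) spacing, the
geometries used for bipedal chelate labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._zmatrix import place_atom
from .structure_model import AtomRecord, ProteinStructure

__all__ = ["FixtureSpec", "make_fixture", "make_cage"]

_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-119.0, 113.0)}
_DHIS_SPACING = {"helix": 4, "strand": 2}

# ideal backbone internal coordinates (Å, degrees)
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.530,
    "N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5,
    "N-CA-CB": 110.5, "OMEGA": 180.0,
}
# improper N-C-CA-CB placing CB for an L-amino acid
_CB_IMPROPER = 122.6


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic structure.

    ``cys_sites`` are residue numbers mutated to cysteine (CB-only side
    chain; the label supplies everything beyond CB). ``dhis_sites`` are
    (i, j) residue-number pairs mutated to histidine with full imidazoles;
    j - i must equal 4 on a helix and 2 on a strand, mirroring the
    standard dHis motifs.
    """

    topology: str = "helix"  # helix | strand | two_chain
    length: int = 30
    cys_sites: tuple[int, ...] = ()
    dhis_sites: tuple[tuple[int, int], ...] = ()
    chain_separation: float = 30.0  # Å, two_chain only
    rng_seed: int = 0

    def __post_init__(self):
        base = "strand" if self.topology == "two_chain" else self.topology
        if base not in _PHI_PSI:
            raise ValueError(f"unknown topology {self.topology!r}")
        for pos in self.cys_sites:
            if not 1 <= pos <= self.length:
                raise ValueError(f"cys site {pos} outside [1, {self.length}]")
        spacing = _DHIS_SPACING[base]
        for i, j in self.dhis_sites:
            if self.topology != "two_chain" and j - i != spacing:
                raise ValueError(
                    f"dHis pair ({i},{j}): {self.topology} motif requires "
                    f"i,i+{spacing} spacing"
                )
            for pos in (i, j):
                if not 1 <= pos <= self.length:
                    raise ValueError(f"dHis site {pos} outside [1, {self.length}]")


def _backbone(phi: float, psi: float, length: int) -> list[dict]:
    """Ideal backbone N/CA/C/O/CB for ``length`` residues."""
    # seed the first residue in a canonical frame
    n0 = np.zeros(3)
    ca0 = np.array([_B["N-CA"], 0.0, 0.0])
    theta = math.radians(_B["N-CA-C"])
    c0 = ca0 + _B["CA-C"] * np.array([-math.cos(theta), math.sin(theta), 0.0])

    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, length):
        prev = residues[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], _B["C-N"], _B["CA-C-N"], psi)
        ca = place_atom(prev["CA"], prev["C"], n, _B["N-CA"], _B["C-N-CA"], _B["OMEGA"])
        c = place_atom(prev["C"], n, ca, _B["CA-C"], _B["N-CA-C"], phi)
        residues.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: anti to the next residue's N (dihedral psi + 180)
    for res in residues:
        res["O"] = place_atom(
            res["N"], res["CA"], res["C"], _B["C-O"], _B["CA-C-O"], psi + 180.0
        )
        res["CB"] = place_atom(
            res["N"], res["C"], res["CA"], _B["CA-CB"], _B["N-CA-CB"], _CB_IMPROPER
        )
    return residues


def _his_side_chain(res: dict) -> dict:
    """Ideal imidazole (CG, ND1, CE1, NE2, CD2) on an existing CB."""
    chi1, chi2 = -60.0, 90.0
    cg = place_atom(res["N"], res["CA"], res["CB"], 1.50, 114.0, chi1)
    nd1 = place_atom(res["CA"], res["CB"], cg, 1.37, 126.0, chi2)
    ce1 = place_atom(res["CB"], cg, nd1, 1.37, 108.0, 180.0)
    ne2 = place_atom(cg, nd1, ce1, 1.37, 108.0, 0.0)
    cd2 = place_atom(nd1, ce1, ne2, 1.37, 108.0, 0.0)
    return {"CG": cg, "ND1": nd1, "CE1": ce1, "NE2": ne2, "CD2": cd2}


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
             "CG": "C", "ND1": "N", "CE1": "C", "NE2": "N", "CD2": "C"}


def make_fixture(spec: FixtureSpec) -> ProteinStructure:
    """Build the synthetic structure described by ``spec``.

    Deterministic for a given spec (the seed is reserved for future
    perturbation options; ideal geometry needs no randomness).
    """
    base = "strand" if spec.topology == "two_chain" else spec.topology
    phi, psi = _PHI_PSI[base]
    his_positions = {p for pair in spec.dhis_sites for p in pair}

    chains = [("A", np.zeros(3))]
    if spec.topology == "two_chain":
        chains.append(("B", np.array([0.0, 0.0, spec.chain_separation])))

    atoms: list[AtomRecord] = []
    for chain_name, offset in chains:
        residues = _backbone(phi, psi, spec.length)
        for i, res in enumerate(residues, start=1):
            if i in his_positions:
                resname = "HIS"
                res = {**res, **_his_side_chain(res)}
            elif i in spec.cys_sites:
                resname = "CYS"
            else:
                resname = "ALA"
            for name in ("N", "CA", "C", "O", "CB", "CG", "ND1", "CE1", "NE2", "CD2"):
                if name not in res:
                    continue
                atoms.append(
                    AtomRecord(
                        name=name,
                        element=_ELEMENTS[name],
                        coords=np.asarray(res[name]) + offset,
                        residue_id=(chain_name, i, ""),
                        resname=resname,
                    )
                )
    return ProteinStructure(atoms=atoms, name=f"{spec.topology}_{spec.length}")


def make_cage(
    site: np.ndarray, spacing: float = 2.0, radius: float = 10.0
) -> ProteinStructure:
    """Spherical shell of dummy carbon atoms centred on ``site``.

    With ``spacing`` below the clash cutoff the shell guarantees a clash
    for any label conformer that reaches it — the worst-case steric
    fixture. A spacing wide enough for a label to slip through (above the
    usual 3.4 Å cutoff) triggers a warning.
    """
    site = np.asarray(site, dtype=float)
    if spacing > 3.4:
        warnings.warn(
            f"cage spacing {spacing} Å exceeds the tight clash cutoff; the "
            "shell may be porous",
            stacklevel=2,
        )
    n = max(8, int(math.ceil(4.0 * math.pi * radius**2 / spacing**2)))
    # Fibonacci sphere: near-uniform point spacing
    k = np.arange(n) + 0.5
    phi_angle = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    rho = np.sqrt(1.0 - z**2)
    points = site + radius * np.column_stack(
        [rho * np.cos(phi_angle), rho * np.sin(phi_angle), z]
    )
    atoms = [
        AtomRecord(
            name="C",
            element="C",
            coords=p,
            residue_id=("Z", i + 1, ""),
            resname="DUM",
            het=True,
        )
        for i, p in enumerate(points)
    ]
    return ProteinStructure(atoms=atoms, name="cage")
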