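"""Rigid-body superposition, rmsd penalties and hard-sphere clash counting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_model import MAIN_CHAIN_NAMES, ProteinStructure, parse_site

__all__ = [
    "RigidTransform",
    "superpose",
    "site_rmsd",
    "count_clashes",
    "count_clashes_batch",
    "clash_exclusion_mask",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def superpose(mobile, target) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    Returns the optimal proper rigid transform and the residual rmsd in Å.
    Point sets must be equal-length, at least 3 points, and non-collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"point-set shapes differ: {mobile.shape} vs {target.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[0] < 3 or mobile.shape[1] != 3:
        raise ValueError("need at least 3 points of dimension 3")
    mob_c = mobile - mobile.mean(axis=0)
    tgt_c = target - target.mean(axis=0)
    for pts in (mob_c, tgt_c):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(tgt_c, mob_c)
    rmsd = rssd / np.sqrt(mobile.shape[0])
    r = rot.as_matrix()
    t = target.mean(axis=0) - r @ mobile.mean(axis=0)
    return RigidTransform(r, t), float(rmsd)


def site_rmsd(label_foot, site_main_chain) -> float:
    """Plain coordinate rmsd between two ordered 4-atom sets (no re-fitting).

    This is the genetic-search penalty: both sets must be ordered
    N, CA, C, O and expressed in the same (protein) frame.
    """
    a = np.asarray(label_foot, dtype=float)
    b = np.asarray(site_main_chain, dtype=float)
    if a.shape[-2:] != (4, 3) or b.shape[-2:] != (4, 3):
        raise ValueError("site_rmsd expects 4 atoms of dimension 3")
    d2 = np.sum((a - b) ** 2, axis=-1)
    return np.sqrt(np.mean(d2, axis=-1))


def _protein_coords(protein, exclusions) -> np.ndarray:
    if isinstance(protein, ProteinStructure):
        coords = protein.coords()
    else:
        coords = np.asarray(protein, dtype=float)
    if coords.size == 0:
        return coords.reshape(0, 3)
    if exclusions is not None:
        excl = np.asarray(list(exclusions) if isinstance(exclusions, (set, frozenset)) else exclusions)
        if excl.dtype == bool:
            coords = coords[~excl]
        elif excl.size:
            mask = np.ones(len(coords), dtype=bool)
            mask[excl.astype(int)] = False
            coords = coords[mask]
    return coords


def count_clashes(label_atoms, protein, cutoff: float, exclusions=None) -> int:
    """Number of (label atom, protein atom) pairs closer than ``cutoff`` Å.

    ``exclusions`` is a collection of protein atom indices left out of the
    count (by default the caller excludes the labelled residues and the
    main-chain atoms of their sequence neighbours). The distance test is
    strict (< cutoff). Empty inputs give 0.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    label_atoms = np.asarray(label_atoms, dtype=float).reshape(-1, 3)
    coords = _protein_coords(protein, exclusions)
    if len(label_atoms) == 0 or len(coords) == 0:
        return 0
    tree = cKDTree(coords)
    n = 0
    for point, neighbours in zip(
        label_atoms, tree.query_ball_point(label_atoms, cutoff)
    ):
        if neighbours:
            d = np.linalg.norm(coords[neighbours] - point, axis=1)
            n += int(np.count_nonzero(d < cutoff))
    return n


def count_clashes_batch(
    label_coords: np.ndarray, protein, cutoff: float, exclusions=None,
    chunk: int = 256,
) -> np.ndarray:
    """Clash counts for a batch of conformers.

    ``label_coords`` has shape (K, L, 3); returns an integer array (K,).
    Computed with chunked dense distance evaluation, which outperforms
    per-conformer tree queries for the modest protein sizes involved.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    label_coords = np.asarray(label_coords, dtype=float)
    coords = _protein_coords(protein, exclusions)
    k = label_coords.shape[0]
    counts = np.zeros(k, dtype=int)
    if len(coords) == 0 or label_coords.size == 0:
        return counts
    cut2 = cutoff * cutoff
    for start in range(0, k, chunk):
        block = label_coords[start : start + chunk]  # (b, L, 3)
        d2 = np.sum(
            (block[:, :, None, :] - coords[None, None, :, :]) ** 2, axis=-1
        )
        counts[start : start + chunk] = np.count_nonzero(d2 < cut2, axis=(1, 2))
    return counts


def clash_exclusion_mask(structure: ProteinStructure, sites) -> np.ndarray:
    """Default protein-atom exclusion set for clash counting at given sites.

    Excluded: every atom of each labelled residue, plus the main-chain
    atoms (N, CA, C, O) of its two sequence neighbours — the label is
    covalently attached there and would otherwise self-clash.
    Returns a boolean mask over ``structure.atoms`` (True = excluded).
    """
    mask = np.zeros(len(structure), dtype=bool)
    for site in sites:
        chain, resnum, icode = parse_site(site)
        mask[structure.residue_atom_indices((chain, resnum, icode))] = True
        for neighbour in (resnum - 1, resnum + 1):
            try:
                idx = structure.residue_atom_indices((chain, neighbour, ""))
            except KeyError:
                continue
            for i in idx:
                if structure.atoms[i].name in MAIN_CHAIN_NAMES:
                    mask[i] = True
    return mask
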