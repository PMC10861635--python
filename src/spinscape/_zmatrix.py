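"""Internal-coordinate (z-matrix) machinery.

Label conformers are parameterised by their rotatable chi dihedrals; all
other internal coordinates (bond lengths, bond angles, non-rotatable
dihedrals) are fixed. Coordinates are reconstructed with the natural
extension reference frame (NeRF) construction, one atom at a time, so a
chi rotation moves exactly the atoms built after the rotated bond and
every rigid fragment keeps its internal geometry to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ZEntry", "place_atom", "dihedral_angle", "build_coords"]


@dataclass(frozen=True)
class ZEntry:
    """One z-matrix row: atom placed relative to three earlier atoms.

    The dihedral actually applied is ``dihedral + angles[chi]`` (degrees)
    when ``chi`` is not None, so the all-zero chi vector reproduces the
    reference geometry exactly.
    """

    name: str
    element: str
    refs: tuple[str, str, str]  # (a, b, c); new atom bonds to c
    bond: float  # Å, |new - c|
    angle: float  # degrees, b-c-new
    dihedral: float  # degrees, a-b-c-new (reference value)
    chi: int | None = None


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d with |d-c|=bond, angle(b,c,d), dihedral(a,b,c,d).

    All of a, b, c may carry leading batch dimensions; ``dihedral_deg`` may
    be a scalar or an array broadcastable to the batch shape.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)

    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)

    d_bc = -bond * np.cos(theta)
    d_m = bond * np.sin(theta) * np.cos(phi)
    d_n = bond * np.sin(theta) * np.sin(phi)
    if np.ndim(phi):
        d_m = d_m[..., None]
        d_n = d_n[..., None]
        return c + d_bc * bc + d_m * m + d_n * n
    return c + d_bc * bc + d_m * m + d_n * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees (IUPAC sign convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def build_coords(
    seed_atoms: list[tuple[str, np.ndarray]],
    zmatrix: tuple[ZEntry, ...],
    angles: np.ndarray,
) -> np.ndarray:
    """Build cartesian coordinates for seed atoms + z-matrix atoms.

    Parameters
    ----------
    seed_atoms : the first three atoms as (name, xyz) pairs.
    zmatrix : remaining atoms in build order.
    angles : chi vector in degrees, shape ``(n_chi,)`` or ``(K, n_chi)``
        for a batch of K conformers.

    Returns
    -------
    coords of shape ``(n_atoms, 3)`` or ``(K, n_atoms, 3)``.
    """
    angles = np.asarray(angles, dtype=float)
    batched = angles.ndim == 2
    k = angles.shape[0] if batched else 1

    index = {name: i for i, (name, _) in enumerate(seed_atoms)}
    n_total = len(seed_atoms) + len(zmatrix)
    coords = np.empty((k, n_total, 3))
    for i, (_, xyz) in enumerate(seed_atoms):
        coords[:, i] = np.asarray(xyz, dtype=float)

    pos = len(seed_atoms)
    for entry in zmatrix:
        ia, ib, ic = (index[r] for r in entry.refs)
        if entry.chi is None:
            phi = entry.dihedral
        else:
            phi = entry.dihedral + (angles[:, entry.chi] if batched else angles[entry.chi])
        coords[:, pos] = place_atom(
            coords[:, ia], coords[:, ib], coords[:, ic], entry.bond, entry.angle, phi
        )
        index[entry.name] = pos
        pos += 1

    return coords if batched else coords[0]
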