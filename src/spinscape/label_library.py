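"""Spin-label templates.

Each template is an idealized all-heavy-atom model of the label as
attached to the protein: the three attachment-frame atoms mimic the
labelling residue's N, CA, CB and are superposed onto them to place a
conformer; the rotatable chi dihedrals parameterise the conformer.

Monopedal, cysteine-conjugated nitroxides:

* MTSL — methanethiosulfonate spin label; mixed disulfide linker to a
  gem-tetramethyl pyrroline-N-oxyl ring; five chi dihedrals.
* MPSL — maleimido-proxyl; thioether to a succinimide ring carrying a
  pyrrolidine-N-oxyl (proxyl) ring; four chi dihedrals.
* IPSL — iodoacetamido-proxyl; thioether-acetamide linker (planar
  trans-amide held rigid) to a proxyl ring; five chi dihedrals.
* IDSL — imidazoline-N-oxyl disulfide label, modelled after conjugation
  as the mixed disulfide (one nitroxide arm on the cysteine); four chi
  dihedrals.

Bipedal label:

* CUNTA — Cu(II)-nitrilotriacetate chelated by a double-histidine (dHis)
  motif. The template spans His1 side chain -> imidazole -> Cu (octahedral,
  both Cu-N(imidazole) donors at 2.00 Å, cis) -> NTA cap and second
  imidazole -> His2 side chain -> main-chain mimic atoms of the second
  labelling site (the "second foot", ordered N, CA, C, O). Seven chi
  dihedrals: His1 chi1/chi2, ring twists about both Cu-N donor axes, His2
  chi2/chi1 (traversed outward), and the foot carbonyl dihedral.

Reference geometries are built from idealized internal coordinates
(standard bond lengths, regular planar rings); no claim is made that they
coincide atom-for-atom with any particular published template. The spin
center is the N-O bond midpoint for nitroxides and the Cu atom for CUNTA,
the standard convention in pulse dipolar EPR modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._zmatrix import ZEntry, build_coords

__all__ = [
    "LabelTemplate",
    "BipedalTemplate",
    "LABEL_NAMES",
    "get_label",
    "set_dihedrals",
    "template_to_text",
    "template_from_text",
]

LABEL_NAMES = ("MTSL", "MPSL", "IPSL", "IDSL", "CUNTA")


@dataclass(frozen=True)
class LabelTemplate:
    """Immutable label definition in a local reference frame."""

    name: str
    seed_atoms: tuple[tuple[str, str, tuple[float, float, float]], ...]
    zmatrix: tuple[ZEntry, ...]
    ring_closures: tuple[tuple[str, str], ...]
    attachment_frame: tuple[str, str, str]
    spin_center_rule: str
    clash_exclude: frozenset[str] = frozenset()

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.seed_atoms) + tuple(
            e.name for e in self.zmatrix
        )

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e for _, e, _ in self.seed_atoms) + tuple(
            e.element for e in self.zmatrix
        )

    @property
    def n_chi(self) -> int:
        chis = {e.chi for e in self.zmatrix if e.chi is not None}
        return len(chis)

    @property
    def bonds(self) -> tuple[tuple[str, str], ...]:
        """Covalent bonds: seed chain + z-matrix attachment bonds + closures."""
        seed_names = [n for n, _, _ in self.seed_atoms]
        out = [(seed_names[0], seed_names[1]), (seed_names[1], seed_names[2])]
        out += [(e.refs[2], e.name) for e in self.zmatrix]
        out += list(self.ring_closures)
        return tuple(out)

    @property
    def is_bipedal(self) -> bool:
        return False

    def atom_index(self, name: str) -> int:
        return self.atom_names.index(name)

    def reference_coords(self) -> np.ndarray:
        return self.build(np.zeros(self.n_chi))

    def build(self, angles: np.ndarray) -> np.ndarray:
        """Cartesian coordinates for a chi vector (or batch of vectors)."""
        angles = np.asarray(angles, dtype=float)
        if angles.shape[-1] != self.n_chi:
            raise ValueError(
                f"{self.name}: expected {self.n_chi} dihedral angles, "
                f"got {angles.shape[-1]}"
            )
        seeds = [(n, np.array(xyz)) for n, _, xyz in self.seed_atoms]
        return build_coords(seeds, self.zmatrix, angles)

    def spin_center(self, coords: np.ndarray) -> np.ndarray:
        """Evaluate the spin-center rule on built coordinates (batch-safe)."""
        rule = self.spin_center_rule
        if rule.startswith("midpoint(") and rule.endswith(")"):
            n1, o1 = (s.strip() for s in rule[9:-1].split(","))
            i, j = self.atom_index(n1), self.atom_index(o1)
            return 0.5 * (coords[..., i, :] + coords[..., j, :])
        if rule.startswith("atom(") and rule.endswith(")"):
            i = self.atom_index(rule[5:-1].strip())
            return coords[..., i, :]
        raise ValueError(f"unrecognised spin-center rule {rule!r}")


@dataclass(frozen=True)
class BipedalTemplate(LabelTemplate):
    """Label anchored at two residues; carries a second-foot atom set."""

    second_foot_atoms: tuple[str, str, str, str] = ()
    coordination_geometry: str = "octahedral"

    @property
    def is_bipedal(self) -> bool:
        return True

    def foot_indices(self) -> list[int]:
        return [self.atom_index(n) for n in self.second_foot_atoms]


def _seed_frame() -> tuple[tuple[str, str, tuple[float, float, float]], ...]:
    """Idealized N, CA, CB of the labelling residue (the attachment frame)."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    theta = math.radians(110.5)
    cb = ca + 1.53 * (math.cos(theta) * np.array([-1.0, 0.0, 0.0])
                      + math.sin(theta) * np.array([0.0, 1.0, 0.0]))
    return (
        ("N", "N", tuple(n)),
        ("CA", "C", tuple(ca)),
        ("CB", "C", tuple(cb)),
    )


def _mtsl() -> LabelTemplate:
    z = [
        ZEntry("SG", "S", ("N", "CA", "CB"), 1.810, 114.0, -60.0, 0),
        ZEntry("SD", "S", ("CA", "CB", "SG"), 2.040, 104.0, 180.0, 1),
        ZEntry("CE", "C", ("CB", "SG", "SD"), 1.800, 100.0, 180.0, 2),
        ZEntry("C3", "C", ("SG", "SD", "CE"), 1.500, 112.0, 180.0, 3),
        # pyrroline ring C3-C4-C5-N1-C2 (regular planar pentagon, closes exactly)
        ZEntry("C4", "C", ("SD", "CE", "C3"), 1.460, 126.0, 90.0, 4),
        ZEntry("C5", "C", ("CE", "C3", "C4"), 1.460, 108.0, 180.0),
        ZEntry("N1", "N", ("C3", "C4", "C5"), 1.460, 108.0, 0.0),
        ZEntry("C2", "C", ("C4", "C5", "N1"), 1.460, 108.0, 0.0),
        ZEntry("O1", "O", ("C4", "C5", "N1"), 1.280, 126.0, 180.0),
        # gem-dimethyls on C5 and C2
        ZEntry("C8", "C", ("C3", "C4", "C5"), 1.530, 110.0, 120.0),
        ZEntry("C9", "C", ("C3", "C4", "C5"), 1.530, 110.0, -120.0),
        ZEntry("C6", "C", ("C5", "N1", "C2"), 1.530, 110.0, 120.0),
        ZEntry("C7", "C", ("C5", "N1", "C2"), 1.530, 110.0, -120.0),
    ]
    return LabelTemplate(
        name="MTSL",
        seed_atoms=_seed_frame(),
        zmatrix=tuple(z),
        ring_closures=(("C2", "C3"),),
        attachment_frame=("N", "CA", "CB"),
        spin_center_rule="midpoint(N1,O1)",
        clash_exclude=frozenset({"N", "CA", "CB"}),
    )


def _mpsl() -> LabelTemplate:
    z = [
        ZEntry("SG", "S", ("N", "CA", "CB"), 1.810, 114.0, -60.0, 0),
        ZEntry("C1", "C", ("CA", "CB", "SG"), 1.820, 100.0, 180.0, 1),
        # succinimide ring C1-CM1-NM-CM2-CHM with two carbonyl oxygens
        ZEntry("CM1", "C", ("CB", "SG", "C1"), 1.470, 126.0, 120.0, 2),
        ZEntry("NM", "N", ("SG", "C1", "CM1"), 1.470, 108.0, 180.0),
        ZEntry("CM2", "C", ("C1", "CM1", "NM"), 1.470, 108.0, 0.0),
        ZEntry("CHM", "C", ("CM1", "NM", "CM2"), 1.470, 108.0, 0.0),
        ZEntry("OM1", "O", ("SG", "C1", "CM1"), 1.230, 126.0, 180.0),
        ZEntry("OM2", "O", ("CM1", "NM", "CM2"), 1.230, 126.0, 180.0),
        # planar imide N -> proxyl ring (rigid in-plane attachment)
        ZEntry("C3P", "C", ("C1", "CM1", "NM"), 1.450, 126.0, 180.0),
        # proxyl ring C3P-C4P-C5P-N1-C2P
        ZEntry("C4P", "C", ("CM1", "NM", "C3P"), 1.490, 126.0, 90.0, 3),
        ZEntry("C5P", "C", ("NM", "C3P", "C4P"), 1.490, 108.0, 180.0),
        ZEntry("N1", "N", ("C3P", "C4P", "C5P"), 1.490, 108.0, 0.0),
        ZEntry("C2P", "C", ("C4P", "C5P", "N1"), 1.490, 108.0, 0.0),
        ZEntry("O1", "O", ("C4P", "C5P", "N1"), 1.280, 126.0, 180.0),
        ZEntry("C6", "C", ("C3P", "C4P", "C5P"), 1.530, 110.0, 120.0),
        ZEntry("C7", "C", ("C3P", "C4P", "C5P"), 1.530, 110.0, -120.0),
        ZEntry("C8", "C", ("C5P", "N1", "C2P"), 1.530, 110.0, 120.0),
        ZEntry("C9", "C", ("C5P", "N1", "C2P"), 1.530, 110.0, -120.0),
    ]
    return LabelTemplate(
        name="MPSL",
        seed_atoms=_seed_frame(),
        zmatrix=tuple(z),
        ring_closures=(("CHM", "C1"), ("C2P", "C3P")),
        attachment_frame=("N", "CA", "CB"),
        spin_center_rule="midpoint(N1,O1)",
        clash_exclude=frozenset({"N", "CA", "CB"}),
    )


def _ipsl() -> LabelTemplate:
    z = [
        ZEntry("SG", "S", ("N", "CA", "CB"), 1.810, 114.0, -60.0, 0),
        ZEntry("CI", "C", ("CA", "CB", "SG"), 1.820, 100.0, 180.0, 1),
        ZEntry("CC", "C", ("CB", "SG", "CI"), 1.520, 112.0, 180.0, 2),
        ZEntry("NAM", "N", ("SG", "CI", "CC"), 1.340, 115.0, 180.0, 3),
        ZEntry("OC", "O", ("NAM", "CI", "CC"), 1.230, 121.0, 180.0),
        # planar trans-amide, held rigid
        ZEntry("C3P", "C", ("CI", "CC", "NAM"), 1.450, 122.0, 180.0),
        ZEntry("C4P", "C", ("CC", "NAM", "C3P"), 1.490, 126.0, 90.0, 4),
        ZEntry("C5P", "C", ("NAM", "C3P", "C4P"), 1.490, 108.0, 180.0),
        ZEntry("N1", "N", ("C3P", "C4P", "C5P"), 1.490, 108.0, 0.0),
        ZEntry("C2P", "C", ("C4P", "C5P", "N1"), 1.490, 108.0, 0.0),
        ZEntry("O1", "O", ("C4P", "C5P", "N1"), 1.280, 126.0, 180.0),
        ZEntry("C6", "C", ("C3P", "C4P", "C5P"), 1.530, 110.0, 120.0),
        ZEntry("C7", "C", ("C3P", "C4P", "C5P"), 1.530, 110.0, -120.0),
        ZEntry("C8", "C", ("C5P", "N1", "C2P"), 1.530, 110.0, 120.0),
        ZEntry("C9", "C", ("C5P", "N1", "C2P"), 1.530, 110.0, -120.0),
    ]
    return LabelTemplate(
        name="IPSL",
        seed_atoms=_seed_frame(),
        zmatrix=tuple(z),
        ring_closures=(("C2P", "C3P"),),
        attachment_frame=("N", "CA", "CB"),
        spin_center_rule="midpoint(N1,O1)",
        clash_exclude=frozenset({"N", "CA", "CB"}),
    )


def _idsl() -> LabelTemplate:
    z = [
        ZEntry("SG", "S", ("N", "CA", "CB"), 1.810, 114.0, -60.0, 0),
        ZEntry("SD", "S", ("CA", "CB", "SG"), 2.040, 104.0, 180.0, 1),
        ZEntry("C4I", "C", ("CB", "SG", "SD"), 1.760, 100.0, 180.0, 2),
        # imidazoline ring C4I-N3-C2I-N1-C5I
        ZEntry("N3", "N", ("SG", "SD", "C4I"), 1.400, 126.0, 90.0, 3),
        ZEntry("C2I", "C", ("SD", "C4I", "N3"), 1.400, 108.0, 180.0),
        ZEntry("N1", "N", ("C4I", "N3", "C2I"), 1.400, 108.0, 0.0),
        ZEntry("C5I", "C", ("N3", "C2I", "N1"), 1.400, 108.0, 0.0),
        ZEntry("O1", "O", ("N3", "C2I", "N1"), 1.280, 126.0, 180.0),
        ZEntry("C6", "C", ("C4I", "N3", "C2I"), 1.530, 110.0, 120.0),
        ZEntry("C7", "C", ("C4I", "N3", "C2I"), 1.530, 110.0, -120.0),
        ZEntry("C8", "C", ("C2I", "N1", "C5I"), 1.530, 110.0, 120.0),
        ZEntry("C9", "C", ("C2I", "N1", "C5I"), 1.530, 110.0, -120.0),
    ]
    return LabelTemplate(
        name="IDSL",
        seed_atoms=_seed_frame(),
        zmatrix=tuple(z),
        ring_closures=(("C5I", "C4I"),),
        attachment_frame=("N", "CA", "CB"),
        spin_center_rule="midpoint(N1,O1)",
        clash_exclude=frozenset({"N", "CA", "CB"}),
    )


def _cunta() -> BipedalTemplate:
    z = [
        # His1 side chain and imidazole (ring CG1-ND1-CE1-NE2-CD2)
        ZEntry("CG1", "C", ("N", "CA", "CB"), 1.500, 114.0, -60.0, 0),
        ZEntry("ND1", "N", ("CA", "CB", "CG1"), 1.370, 126.0, 90.0, 1),
        ZEntry("CE1", "C", ("CB", "CG1", "ND1"), 1.370, 108.0, 180.0),
        ZEntry("NE2", "N", ("CG1", "ND1", "CE1"), 1.370, 108.0, 0.0),
        ZEntry("CD2", "C", ("ND1", "CE1", "NE2"), 1.370, 108.0, 0.0),
        # Cu in the imidazole plane along the NE2 lone pair, 2.00 A
        ZEntry("CU", "Cu", ("ND1", "CE1", "NE2"), 2.000, 126.0, 180.0),
        # octahedral cis coordination: NTA amine N and the second imidazole
        # NE2 both at 90 degrees from the first donor; chi 2 twists the
        # whole cap about the NE2-Cu axis
        ZEntry("N10", "N", ("CE1", "NE2", "CU"), 2.040, 90.0, 0.0, 2),
        ZEntry("NE2B", "N", ("N10", "NE2", "CU"), 2.000, 90.0, 90.0),
        # NTA arms (rigid cap): three acetate arms on N10
        ZEntry("C1N", "C", ("NE2", "CU", "N10"), 1.490, 109.0, 60.0),
        ZEntry("C2N", "C", ("NE2", "CU", "N10"), 1.490, 109.0, 180.0),
        ZEntry("C3N", "C", ("NE2", "CU", "N10"), 1.490, 109.0, -60.0),
        ZEntry("CC1", "C", ("CU", "N10", "C1N"), 1.520, 110.0, -60.0),
        ZEntry("OA1", "O", ("N10", "C1N", "CC1"), 1.250, 120.0, 0.0),
        ZEntry("OB1", "O", ("N10", "C1N", "CC1"), 1.250, 120.0, 180.0),
        ZEntry("CC2", "C", ("CU", "N10", "C2N"), 1.520, 110.0, -60.0),
        ZEntry("OA2", "O", ("N10", "C2N", "CC2"), 1.250, 120.0, 0.0),
        ZEntry("OB2", "O", ("N10", "C2N", "CC2"), 1.250, 120.0, 180.0),
        ZEntry("CC3", "C", ("CU", "N10", "C3N"), 1.520, 110.0, -60.0),
        ZEntry("OA3", "O", ("N10", "C3N", "CC3"), 1.250, 120.0, 0.0),
        ZEntry("OB3", "O", ("N10", "C3N", "CC3"), 1.250, 120.0, 180.0),
        # second imidazole (ring NE2B-CE1B-ND1B-CGB-CD2B); chi 3 twists it
        # about the Cu-NE2B donor axis
        ZEntry("CE1B", "C", ("NE2", "CU", "NE2B"), 1.370, 126.0, 90.0, 3),
        ZEntry("ND1B", "N", ("CU", "NE2B", "CE1B"), 1.370, 108.0, 180.0),
        ZEntry("CGB", "C", ("NE2B", "CE1B", "ND1B"), 1.370, 108.0, 0.0),
        ZEntry("CD2B", "C", ("CE1B", "ND1B", "CGB"), 1.370, 108.0, 0.0),
        # His2 side chain outward to the second-foot main-chain mimic
        ZEntry("CBB", "C", ("CE1B", "ND1B", "CGB"), 1.500, 126.0, 180.0),
        ZEntry("CA2", "C", ("ND1B", "CGB", "CBB"), 1.530, 114.0, 90.0, 4),
        ZEntry("N2", "N", ("CGB", "CBB", "CA2"), 1.458, 110.5, 180.0, 5),
        ZEntry("C2", "C", ("CGB", "CBB", "CA2"), 1.525, 110.5, -58.0, 5),
        ZEntry("O2", "O", ("N2", "CA2", "C2"), 1.231, 120.5, 133.0, 6),
    ]
    return BipedalTemplate(
        name="CUNTA",
        seed_atoms=_seed_frame(),
        zmatrix=tuple(z),
        ring_closures=(("CD2", "CG1"), ("CD2B", "NE2B")),
        attachment_frame=("N", "CA", "CB"),
        spin_center_rule="atom(CU)",
        clash_exclude=frozenset({"N", "CA", "CB", "N2", "CA2", "C2", "O2"}),
        second_foot_atoms=("N2", "CA2", "C2", "O2"),
        coordination_geometry="octahedral",
    )


_BUILDERS = {
    "MTSL": _mtsl,
    "MPSL": _mpsl,
    "IPSL": _ipsl,
    "IDSL": _idsl,
    "CUNTA": _cunta,
}


@lru_cache(maxsize=None)
def get_label(name: str) -> LabelTemplate:
    """Return the built-in template for a label name (case-insensitive)."""
    key = name.upper()
    if key not in _BUILDERS:
        raise KeyError(
            f"unknown label {name!r}; available: {', '.join(LABEL_NAMES)}"
        )
    return _BUILDERS[key]()


def set_dihedrals(template: LabelTemplate, angles) -> np.ndarray:
    """Coordinates of all label atoms at the given chi angles (degrees).

    ``angles`` are offsets from the reference conformer: the all-zero
    vector reproduces the reference coordinates exactly.
    """
    return template.build(np.asarray(angles, dtype=float))


# ---------------------------------------------------------------------------
# plain-text serialisation so users can define their own labels

def template_to_text(t: LabelTemplate) -> str:
    lines = [f"label {t.name}"]
    lines.append(f"spin_center {t.spin_center_rule}")
    lines.append("frame " + " ".join(t.attachment_frame))
    if t.clash_exclude:
        lines.append("clash_exclude " + " ".join(sorted(t.clash_exclude)))
    if isinstance(t, BipedalTemplate):
        lines.append("foot " + " ".join(t.second_foot_atoms))
        lines.append(f"coordination {t.coordination_geometry}")
    for name, elem, xyz in t.seed_atoms:
        lines.append(
            f"seed {name} {elem} {xyz[0]:.17g} {xyz[1]:.17g} {xyz[2]:.17g}"
        )
    for e in t.zmatrix:
        chi = "-" if e.chi is None else str(e.chi)
        lines.append(
            f"zatom {e.name} {e.element} {e.refs[0]} {e.refs[1]} {e.refs[2]} "
            f"{e.bond:.17g} {e.angle:.17g} {e.dihedral:.17g} {chi}"
        )
    for a, b in t.ring_closures:
        lines.append(f"bond {a} {b}")
    return "\n".join(lines) + "\n"


def template_from_text(text: str) -> LabelTemplate:
    name = ""
    spin_rule = ""
    frame: tuple[str, ...] = ()
    clash_exclude: frozenset[str] = frozenset()
    foot: tuple[str, ...] = ()
    coordination = ""
    seeds: list[tuple[str, str, tuple[float, float, float]]] = []
    zmat: list[ZEntry] = []
    closures: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, *rest = line.split()
        if key == "label":
            name = rest[0]
        elif key == "spin_center":
            spin_rule = rest[0]
        elif key == "frame":
            frame = tuple(rest)
        elif key == "clash_exclude":
            clash_exclude = frozenset(rest)
        elif key == "foot":
            foot = tuple(rest)
        elif key == "coordination":
            coordination = rest[0]
        elif key == "seed":
            seeds.append((rest[0], rest[1], (float(rest[2]), float(rest[3]), float(rest[4]))))
        elif key == "zatom":
            chi = None if rest[8] == "-" else int(rest[8])
            zmat.append(
                ZEntry(rest[0], rest[1], (rest[2], rest[3], rest[4]),
                       float(rest[5]), float(rest[6]), float(rest[7]), chi)
            )
        elif key == "bond":
            closures.append((rest[0], rest[1]))
        else:
            raise ValueError(f"unrecognised template line: {raw!r}")
    common = dict(
        name=name,
        seed_atoms=tuple(seeds),
        zmatrix=tuple(zmat),
        ring_closures=tuple(closures),
        attachment_frame=(frame[0], frame[1], frame[2]),
        spin_center_rule=spin_rule,
        clash_exclude=clash_exclude,
    )
    if foot:
        return BipedalTemplate(
            second_foot_atoms=(foot[0], foot[1], foot[2], foot[3]),
            coordination_geometry=coordination or "octahedral",
            **common,
        )
    return LabelTemplate(**common)
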