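"""Accessible-volume rotamer sampling for monopedal (Cys-attached) labels.

The sampler is deliberately energy-blind: chi dihedrals are drawn
uniformly, the conformer is placed by superposing the label's attachment
frame onto the site's N, CA, CB, and it is kept iff its hard-sphere clash
count against the protein stays within the preset. The accepted set is an
estimate of the label's sterically accessible volume; weights are uniform
because the excluded-volume model has no energy to weight by.

Presets follow the standard convention:

* Tight — 0 clashes allowed at a 3.4 Å inter-atom cutoff;
* Loose — up to 15 clashes at a 2.0 Å cutoff.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .ensemble import RotamerEnsemble
from .geometry import clash_exclusion_mask, count_clashes_batch, superpose
from .label_library import LabelTemplate
from .structure_model import ProteinStructure, parse_site

__all__ = [
    "SearchSettings",
    "TIGHT",
    "LOOSE",
    "sample_monopedal",
    "acceptance_rate",
    "grid_monopedal",
]

_PRESETS = {"tight": (3.4, 0), "loose": (2.0, 15)}


@dataclass(frozen=True)
class SearchSettings:
    """Clash preset and sampling budget for accessible-volume search."""

    preset: str = "tight"
    cutoff: float = 3.4  # Å, hard-sphere inter-atom distance
    max_clashes: int = 0
    n_trials: int = 3000
    rng_seed: int = 0

    def __post_init__(self):
        if self.preset in _PRESETS:
            cutoff, max_clashes = _PRESETS[self.preset]
            object.__setattr__(self, "cutoff", cutoff)
            object.__setattr__(self, "max_clashes", max_clashes)
        elif self.preset != "custom":
            raise ValueError(
                f"unknown preset {self.preset!r}; use 'tight', 'loose' or 'custom'"
            )
        if self.cutoff <= 0 or self.max_clashes < 0 or self.n_trials < 0:
            raise ValueError("invalid search settings")

    @staticmethod
    def from_preset(name: str, n_trials: int = 3000, rng_seed: int = 0) -> "SearchSettings":
        return SearchSettings(preset=name.lower(), n_trials=n_trials, rng_seed=rng_seed)


TIGHT = SearchSettings(preset="tight")
LOOSE = SearchSettings(preset="loose")

_MAX_FRAME_FIT_RMSD = 0.1  # Å; attachment-frame superposition must be near-exact


def _attachment_transform(structure, site, template):
    """Superpose the template frame onto the site's N, CA, CB."""
    rid = parse_site(site)
    atoms = {a.name: a for a in structure.residue_atoms(rid)}
    missing = [n for n in template.attachment_frame if n not in atoms]
    if "CB" in missing:
        raise ValueError(
            f"site {rid} lacks a CB atom (glycine?); model a CB before labelling"
        )
    if missing:
        raise ValueError(f"site {rid} lacks attachment atoms {missing}")
    target = np.array([atoms[n].coords for n in template.attachment_frame])
    ref = template.reference_coords()
    mobile = np.array([ref[template.atom_index(n)] for n in template.attachment_frame])
    transform, fit_rmsd = superpose(mobile, target)
    if fit_rmsd > _MAX_FRAME_FIT_RMSD:
        warnings.warn(
            f"attachment-frame fit rmsd {fit_rmsd:.3f} Å at {rid} exceeds "
            f"{_MAX_FRAME_FIT_RMSD} Å; the site geometry is unusual",
            stacklevel=2,
        )
    return transform, fit_rmsd


def _clash_atom_indices(template) -> list[int]:
    return [
        i for i, n in enumerate(template.atom_names) if n not in template.clash_exclude
    ]


def _evaluate_conformers(structure, sites, template, angles, settings):
    """Place conformers for the given chi matrix and return accept data."""
    transform, fit_rmsd = _attachment_transform(structure, sites[0], template)
    coords = transform.apply(template.build(angles))
    exclusion = clash_exclusion_mask(structure, sites)
    clash_idx = _clash_atom_indices(template)
    clashes = count_clashes_batch(
        coords[:, clash_idx, :], structure, settings.cutoff, exclusions=exclusion
    )
    accepted = clashes <= settings.max_clashes
    return coords, clashes, accepted, fit_rmsd


def sample_monopedal(
    structure: ProteinStructure,
    site,
    label: LabelTemplate,
    settings: SearchSettings = TIGHT,
) -> RotamerEnsemble:
    """Random accessible-volume sampling of a monopedal label at a Cys site.

    Draws ``settings.n_trials`` chi vectors uniformly on [-180, 180)°,
    keeps non-clashing conformers, and returns them with uniform weights.
    Deterministic for a fixed ``settings.rng_seed``. An empty result is a
    warning (buried site), not an error.
    """
    if label.is_bipedal:
        raise ValueError(f"label {label.name} is bipedal; use run_bipedal")
    rng = np.random.default_rng(settings.rng_seed)
    angles = rng.uniform(-180.0, 180.0, size=(settings.n_trials, label.n_chi))
    coords, clashes, accepted, fit_rmsd = _evaluate_conformers(
        structure, [site], label, angles, settings
    )
    kept = np.flatnonzero(accepted)
    if kept.size == 0:
        warnings.warn(
            f"no accepted rotamers for {label.name} at {parse_site(site)} "
            f"under preset {settings.preset!r}; the site is likely buried",
            stacklevel=2,
        )
    conf_coords = coords[kept]
    return RotamerEnsemble(
        label=label.name,
        sites=(parse_site(site),),
        atom_names=label.atom_names,
        elements=label.elements,
        dihedrals=angles[kept],
        coords=conf_coords,
        spin_centers=label.spin_center(conf_coords)
        if kept.size
        else np.zeros((0, 3)),
        meta={
            "settings": settings,
            "n_trials": settings.n_trials,
            "n_accepted": int(kept.size),
            "frame_fit_rmsd": fit_rmsd,
            "clash_counts": clashes[kept],
        },
    )


def grid_monopedal(
    structure: ProteinStructure,
    site,
    label: LabelTemplate,
    settings: SearchSettings = TIGHT,
    step: float = 30.0,
) -> RotamerEnsemble:
    """Exhaustive accessible-volume enumeration on a regular chi grid.

    Enumerates every combination of chi angles at ``step``-degree spacing
    (an independent, sampling-free estimate of the accessible volume, used
    as the oracle against random sampling).
    """
    axis = np.arange(-180.0, 180.0, step)
    grid = np.array(list(itertools.product(axis, repeat=label.n_chi)))
    coords, clashes, accepted, fit_rmsd = _evaluate_conformers(
        structure, [site], label, grid, settings
    )
    kept = np.flatnonzero(accepted)
    conf_coords = coords[kept]
    return RotamerEnsemble(
        label=label.name,
        sites=(parse_site(site),),
        atom_names=label.atom_names,
        elements=label.elements,
        dihedrals=grid[kept],
        coords=conf_coords,
        spin_centers=label.spin_center(conf_coords)
        if kept.size
        else np.zeros((0, 3)),
        meta={
            "settings": replace(settings, n_trials=len(grid)),
            "n_trials": len(grid),
            "n_accepted": int(kept.size),
            "frame_fit_rmsd": fit_rmsd,
        },
    )


def acceptance_rate(ensemble: RotamerEnsemble, settings: SearchSettings = None) -> float:
    """Accepted / attempted conformers, in [0, 1].

    A low rate flags a buried site. ``settings`` defaults to the settings
    recorded in the ensemble metadata.
    """
    n_trials = (settings or ensemble.meta.get("settings")).n_trials
    if not n_trials:
        raise ValueError("n_trials is zero; no sampling was performed")
    return len(ensemble) / n_trials
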