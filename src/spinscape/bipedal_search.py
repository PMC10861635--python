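"""Genetic conformer search for bipedal (dHis-anchored) labels.

A bipedal label bridges two residues, so its chi angles cannot be drawn
independently: the far end of the label must coincide with the main-chain
atoms of the second labelling site. The search anchors the label at site 1
by frame superposition, scores each trial conformation by the plain
coordinate rmsd between the label's second-foot atoms and site 2's
N, CA, C, O (the penalty), and evolves a population:

1. generate ``population_size`` random-chi trial conformations (8000 by
   default);
2. rank by penalty and eliminate the worst ``elimination_fraction``
   (5% by default, i.e. 400 conformations at defaults);
3. replace the discarded conformations with offspring of the survivors
   (a random survivor copied with wrapped Gaussian mutation of each chi;
   optional uniform crossover between two survivors);
4. repeat until the converged-conformer count stalls or the generation
   budget is spent.

Because survivors are carried over unchanged, the best penalty is
non-increasing (elitism). Hard-sphere clash filtering is applied to the
final sub-threshold conformers only; the evolution itself is ranked by the
purely geometric penalty (clash filtering during evolution is available
behind a flag for experimentation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .accessible_volume import LOOSE, SearchSettings, _attachment_transform, _clash_atom_indices
from .ensemble import RotamerEnsemble
from .geometry import clash_exclusion_mask, count_clashes_batch, site_rmsd
from .label_library import BipedalTemplate
from .structure_model import ProteinStructure, parse_site, site_main_chain_coords

__all__ = ["GASettings", "GAState", "init_population", "evolve", "run_bipedal"]


@dataclass(frozen=True)
class GASettings:
    """Genetic-search configuration."""

    population_size: int = 8000
    elimination_fraction: float = 0.05
    max_generations: int = 100
    penalty_accept: float = 0.5  # Å; second-foot rmsd for a conformer to count
    mutation_sigma: float = 15.0  # degrees, per chi, wrapped
    crossover: bool = False
    clash: SearchSettings = LOOSE
    clash_during_evolution: bool = False
    patience: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.elimination_fraction < 1:
            raise ValueError("elimination_fraction must be in (0, 1)")
        if self.penalty_accept <= 0:
            raise ValueError("penalty_accept must be positive")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")

    @property
    def n_replaced(self) -> int:
        return int(self.elimination_fraction * self.population_size)


@dataclass
class GAState:
    """Population state of the genetic search."""

    angles: np.ndarray  # (population_size, n_chi), degrees
    penalties: np.ndarray  # (population_size,), Å
    generation: int
    settings: GASettings
    rng: np.random.Generator
    template: BipedalTemplate
    transform: object  # RigidTransform placing the label at site 1
    target_foot: np.ndarray  # (4, 3) site-2 main chain N, CA, C, O
    structure: ProteinStructure
    sites: tuple
    frame_fit_rmsd: float = 0.0
    history: list = field(default_factory=list)  # (gen, best, median, n_converged)

    @property
    def best_penalty(self) -> float:
        return float(self.penalties.min())

    def n_converged(self) -> int:
        return int(np.count_nonzero(self.penalties < self.settings.penalty_accept))

    def _log(self):
        self.history.append(
            (self.generation, self.best_penalty, float(np.median(self.penalties)),
             self.n_converged())
        )


def _wrap_degrees(a: np.ndarray) -> np.ndarray:
    return (a + 180.0) % 360.0 - 180.0


def _penalties_for(state: GAState, angles: np.ndarray) -> np.ndarray:
    coords = state.transform.apply(state.template.build(angles))
    foot = coords[:, state.template.foot_indices(), :]
    pen = np.asarray(site_rmsd(foot, state.target_foot))
    if state.settings.clash_during_evolution:
        clash_idx = _clash_atom_indices(state.template)
        exclusion = clash_exclusion_mask(state.structure, state.sites)
        clashes = count_clashes_batch(
            coords[:, clash_idx, :], state.structure,
            state.settings.clash.cutoff, exclusions=exclusion,
        )
        pen = np.where(clashes <= state.settings.clash.max_clashes, pen, np.inf)
    return pen


def init_population(
    structure: ProteinStructure,
    site1,
    site2,
    template: BipedalTemplate,
    settings: GASettings = GASettings(),
    initial_angles: np.ndarray | None = None,
) -> GAState:
    """Anchor the label at site 1 and create the initial random population.

    ``initial_angles`` optionally seeds the first rows of the population
    with given chi vectors (useful for constructed test cases).
    """
    rid1, rid2 = parse_site(site1), parse_site(site2)
    if rid1 == rid2:
        raise ValueError("the two labelling sites must be distinct")
    if not template.is_bipedal:
        raise ValueError(f"label {template.name} is not bipedal")
    target_foot = site_main_chain_coords(structure, rid2)
    transform, fit_rmsd = _attachment_transform(structure, rid1, template)
    rng = np.random.default_rng(settings.rng_seed)
    angles = rng.uniform(
        -180.0, 180.0, size=(settings.population_size, template.n_chi)
    )
    if initial_angles is not None:
        initial_angles = np.atleast_2d(np.asarray(initial_angles, dtype=float))
        angles[: len(initial_angles)] = initial_angles
    state = GAState(
        angles=angles,
        penalties=np.empty(settings.population_size),
        generation=0,
        settings=settings,
        rng=rng,
        template=template,
        transform=transform,
        target_foot=target_foot,
        structure=structure,
        sites=(rid1, rid2),
        frame_fit_rmsd=fit_rmsd,
    )
    state.penalties = _penalties_for(state, angles)
    state._log()
    return state


def evolve(state: GAState) -> GAState:
    """One generation: eliminate the worst fraction, replace with offspring.

    Mutates and returns ``state``. Exactly
    ``floor(elimination_fraction * population_size)`` worst-penalty
    conformations are replaced; survivors are untouched, so the best
    penalty cannot increase.
    """
    s = state.settings
    n_kill = s.n_replaced
    order = np.argsort(state.penalties, kind="stable")
    survivors = order[: len(order) - n_kill]
    doomed = order[len(order) - n_kill :]

    # rank-weighted parent selection (better-ranked survivors breed more;
    # e-folding over the top 10%) with mutation scale proportional to the
    # parent's penalty: coarse moves for poor parents, fine refinement near
    # converged ones. A fixed uniform-parent / fixed-sigma operator stalls
    # well above chemically meaningful foot coincidence.
    rank_w = np.exp(-np.arange(len(survivors)) / (0.1 * len(survivors)))
    rank_w /= rank_w.sum()
    parents = survivors[state.rng.choice(len(survivors), size=n_kill, p=rank_w)]
    children = state.angles[parents].copy()
    if s.crossover:
        partners = survivors[state.rng.choice(len(survivors), size=n_kill, p=rank_w)]
        take = state.rng.random(children.shape) < 0.5
        children = np.where(take, children, state.angles[partners])
    sigma = np.clip(
        5.0 * state.penalties[parents], 0.2, s.mutation_sigma
    )[:, None]  # degrees per Å of parent penalty
    children = _wrap_degrees(
        children + state.rng.normal(0.0, 1.0, size=children.shape) * sigma
    )

    state.angles[doomed] = children
    state.penalties[doomed] = _penalties_for(state, children)
    state.generation += 1
    state._log()
    return state


def run_bipedal(
    structure: ProteinStructure,
    site1,
    site2,
    template: BipedalTemplate,
    settings: GASettings = GASettings(),
    symmetric: bool = False,
) -> RotamerEnsemble:
    """Full genetic search returning the converged, clash-filtered ensemble.

    Runs :func:`evolve` until ``max_generations`` or until the number of
    sub-threshold conformers has not increased for ``patience``
    generations. The returned conformers all satisfy
    ``penalty < penalty_accept`` and the clash constraint of the chosen
    preset; the spin center is the Cu atom; weights are uniform.
    With ``symmetric=True`` the search is repeated with the sites swapped
    and the two ensembles pooled.
    """
    state = init_population(structure, site1, site2, template, settings)
    best_count = state.n_converged()
    stall = 0
    while state.generation < settings.max_generations:
        evolve(state)
        count = state.n_converged()
        if count > best_count:
            best_count = count
            stall = 0
        else:
            stall += 1
            if stall >= settings.patience and best_count > 0:
                break

    accepted = np.flatnonzero(state.penalties < settings.penalty_accept)
    coords = state.transform.apply(state.template.build(state.angles[accepted])) \
        if accepted.size else np.zeros((0, len(template.atom_names), 3))
    if accepted.size:
        exclusion = clash_exclusion_mask(structure, state.sites)
        clashes = count_clashes_batch(
            coords[:, _clash_atom_indices(template), :],
            structure,
            settings.clash.cutoff,
            exclusions=exclusion,
        )
        keep = clashes <= settings.clash.max_clashes
        accepted = accepted[keep]
        coords = coords[keep]

    ensemble = RotamerEnsemble(
        label=template.name,
        sites=state.sites,
        atom_names=template.atom_names,
        elements=template.elements,
        dihedrals=state.angles[accepted],
        coords=coords,
        spin_centers=template.spin_center(coords)
        if accepted.size
        else np.zeros((0, 3)),
        meta={
            "settings": settings,
            "generations": state.generation,
            "best_penalty": state.best_penalty,
            "penalties": state.penalties[accepted],
            "frame_fit_rmsd": state.frame_fit_rmsd,
            "history": list(state.history),
        },
    )
    if ensemble.is_empty:
        warnings.warn(
            f"bipedal search at {state.sites} found no conformer with "
            f"second-foot rmsd < {settings.penalty_accept} Å that passes the "
            f"clash filter (best achieved penalty {state.best_penalty:.2f} Å)",
            stacklevel=2,
        )
    if symmetric:
        swapped = run_bipedal(
            structure, site2, site1, template, settings, symmetric=False
        )
        ensemble = _pool(ensemble, swapped)
    return ensemble


def _pool(a: RotamerEnsemble, b: RotamerEnsemble) -> RotamerEnsemble:
    if a.is_empty:
        return b
    if b.is_empty:
        return a
    return RotamerEnsemble(
        label=a.label,
        sites=a.sites,
        atom_names=a.atom_names,
        elements=a.elements,
        dihedrals=np.concatenate([a.dihedrals, b.dihedrals]),
        coords=np.concatenate([a.coords, b.coords]),
        spin_centers=np.concatenate([a.spin_centers, b.spin_centers]),
        meta={"pooled_from": (a.meta, b.meta)},
    )
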