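# Methods

## Scope and model

spinscape predicts spin–spin distance distributions for pulse dipolar EPR
(PDS) by in-silico site-directed spin labelling of protein structures. It
implements two conformer-generation models and the analytics to compare
the resulting distributions:

1. **Accessible-volume sampling (monopedal labels).** A cysteine-attached
   nitroxide label (MTSL, MPSL, IPSL, IDSL) is treated as a rigid-geometry
   chain whose only degrees of freedom are its rotatable chi dihedrals.
   Chi vectors are drawn uniformly on [−180°, 180°), the conformer is
   placed by least-squares superposition of the label's N/CA/CB attachment
   frame onto the site residue, and it is accepted iff its hard-sphere
   clash count against the protein stays within the preset. The model is
   deliberately energy-blind: the accepted set estimates the sterically
   accessible volume, and weights are uniform because there is no energy
   to weight by. This is the excluded-volume philosophy, in contrast to
   rotamer-library approaches that rank conformers by Lennard-Jones and
   internal energies.

2. **Genetic conformer search (bipedal labels).** A bipedal label such as
   the Cu(II)–nitrilotriacetate complex chelated by a double-histidine
   (dHis) motif is anchored at *two* residues, so chi angles cannot be
   drawn independently: the far end of the label must coincide with the
   main-chain atoms of the second site. The search anchors the label at
   site 1, scores each trial conformation by the plain (no re-fitting)
   coordinate rmsd between the label's four second-foot atoms and site 2's
   N, CA, C, O, and evolves a population of 8000 trial conformations:
   each generation the worst 5% (400 at defaults) are eliminated and
   replaced by offspring of the survivors. Survivors are never modified,
   so the best penalty is non-increasing (elitism).

## Hard-sphere clash model

A clash is a (label heavy atom, protein heavy atom) pair closer than a
single distance cutoff; per-element van-der-Waals radii are not used
because the presets are specified as one cutoff. Presets:

| preset | cutoff | allowed clashes |
|--------|--------|-----------------|
| Tight  | 3.4 Å  | 0               |
| Loose  | 2.0 Å  | 15              |

Loose is strictly weaker than Tight (any conformer with no pair under
3.4 Å has no pair under 2.0 Å), which the monotonicity tests exploit.
Excluded from the count: all atoms of the labelled residue(s) and the
main-chain atoms of their two sequence neighbours (the label is
covalently attached there), plus the label's own frame-mimic and
foot-mimic atoms, which coincide with protein atoms by construction.
Exclusions are configurable. Pair counting (not per-label-atom counting)
is used; single-conformer queries go through a k-d tree, batched
evaluation through chunked dense distances, and the two are
cross-checked against a naive double loop in the test suite.

## Label templates

Templates are idealized all-heavy-atom models defined by a seed frame
(N, CA, CB of the labelling residue) plus a z-matrix; coordinates are
rebuilt with the natural-extension-reference-frame construction, so a chi
rotation moves exactly the atoms distal to the rotated bond and every
rigid fragment is preserved to machine precision. Rings are regular
planar polygons (which close exactly), bond lengths are standard organic
values, and the Cu(II) center is octahedral with both Cu–N(imidazole)
donors at 2.00 Å in cis positions. These geometries are self-consistent
and testable; no claim is made that they reproduce any particular
published template atom-for-atom. Users can supply their own labels
through a plain-text template format (documented in the README).

Chi counts by topology: MTSL 5, MPSL 4, IPSL 5 (the amide is held planar
trans), IDSL 4 (modelled after conjugation as the mixed disulfide), and
CuNTA 7. The CuNTA dihedral set is His1 chi1/chi2, ring twists about
*both* Cu–N donor axes, His2 chi2/chi1 traversed outward, and the foot
carbonyl dihedral. The two extra twists relative to the minimal
"chi pairs + one twist" parameterisation are deliberate: with a single
twist the second imidazole cannot be oriented independently of the NTA
cap, and without the carbonyl dihedral the foot oxygen cannot match the
psi-dependent carbonyl direction of an arbitrary target residue — both
leave the attainable second-foot rmsd well above the 0.5 Å acceptance
threshold even on geometrically ideal dHis motifs.

Spin centers follow the standard PDS convention: the N–O bond midpoint
for nitroxides, the Cu atom for CuNTA.

## Genetic-search operator and termination

The replacement operator is the design-open part of the search.
spinscape copies a survivor chosen with rank-weighted probability
(exponential in penalty rank, e-folding over the top 10% of survivors)
and perturbs every chi with wrapped Gaussian noise whose scale is
proportional to the parent's penalty (5°/Å, clipped to [0.2°,
`mutation_sigma` = 15°]). The proportional scale makes offspring of poor
parents explore coarsely while offspring of near-converged parents refine
locally; a uniform-parent, fixed-σ operator was tried first and stalls
around 0.6–1.0 Å best penalty on a fixture whose true geometric floor is
0.03 Å. Optional uniform crossover between two survivors is available
behind a flag (off by default). Ties in the penalty ranking are broken
by stable sort order, keeping runs bit-reproducible.

Termination: a generation budget (default 100) plus a patience rule —
stop when the count of sub-threshold conformers (penalty below
`penalty_accept` = 0.5 Å, a chemically meaningful coincidence for four
main-chain atoms) has not increased for 5 generations. The returned
ensemble keeps only sub-threshold conformers that also pass the clash
preset; clash filtering during evolution is available behind a flag but
off by default, because the ranking penalty is purely geometric.

## Distance distributions and statistics

The distribution between two ensembles is the weighted mixture of all
pairwise spin-center distances, each contributing a Gaussian kernel
(default σ = 1.0 Å) evaluated on a regular grid (default 10–100 Å in
0.5 Å steps, the typical PDS range) and renormalised to unit trapezoidal
area. The exact pre-gridding weighted sample mean and standard deviation
are stored in the distribution metadata; grid-based statistics
(quadrature mean, standard-deviation width, FWHM by linear interpolation
of the half-maximum crossings) agree with them to within the grid
resolution. For multimodal densities the FWHM uses the outermost
half-maximum crossings and the result is flagged.

"Width" is reported as the standard deviation, with FWHM alongside —
the field uses both and the choice is documented rather than implied.
Δ mean is simulated minus experimental (positive = the model
overestimates the distance). Distribution rmsd resamples both densities
onto a shared grid (union of ranges, finer step), renormalises each, and
takes the root-mean-square point difference; global rmsd is the
root-mean-square of paired mean (or width) differences across
constructs/labels. Experimental distributions are read from two-column
text; an r axis whose maximum is below 15 is interpreted as nanometres
and converted.

## Synthetic fixtures

The fixture generator emulates the *geometry* of labelling sites, not any
real protein: ideal polyalanine backbones (helix φ = −57°, ψ = −47°;
strand φ = −119°, ψ = 113°; L-configuration CB on every residue),
cysteine mutation sites, and dHis motifs with full ideal imidazoles at
i,i+4 (helix) or i,i+2 (strand) spacing — the standard motif spacings.
A two-chain variant separates two strands by 30 Å to provide a
guaranteed-infeasible bipedal pair, and a Fibonacci-sphere "cage" of
dummy atoms provides a guaranteed-clashing environment. What passing
tests on these fixtures shows: the samplers, penalty, clash model and
statistics behave correctly on known geometry. What they do not show:
prediction accuracy on real proteins, which depends on side-chain
packing, backbone relaxation on mutation, and label-surface interactions
that the excluded-volume model ignores by design.

## Numerical choices and problem sizes

* Monopedal trials default to 3000, which stabilises ensemble mean
  spin-center positions on helix-sized sites; the exhaustive-grid oracle
  enumerates 30° steps (12⁵ ≈ 249k conformers for MTSL) and agrees with
  random sampling to < 0.5 Å in mean spin-center position.
* The genetic search is validated at its default 8000-conformer
  population; module tests use 2000 to stay fast, a size at which the
  fixed test seed still converges below the 0.5 Å threshold.
* Attachment-frame superposition uses Kabsch (via SVD-based alignment);
  a fit rmsd above 0.1 Å triggers a warning about unusual site geometry.
* Degenerate inputs fail loudly: collinear point sets in superposition,
  glycine sites without CB, empty ensembles in distribution construction,
  all-zero densities, grids that clip more than 1% of the pair weight.
  An empty *result* (buried site, unbridgeable pair) is a warning, not an
  error.
* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical ensembles.

## Known limitations

* Rotamer weights are uniform; no Boltzmann weighting, no temperature
  dependence.
* The hard-sphere model has a single cutoff for all element pairs.
* Label template geometries are idealized; absolute conformer coordinates
  carry that idealization even though ensemble-level statistics are
  robust to it.
* The two-site search treats the protein as rigid; backbone relaxation
  around the labelling sites is not modelled.
* Dipolar time traces, background correction and regularisation-based
  inversion of experimental data are out of scope; experimental
  distributions are consumed as already-processed files.
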