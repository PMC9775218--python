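# Methods

This note records the models, conventions, numerical choices and known
limitations of dimersolv. Units: lengths in nm, temperatures in K, energies
in kT inside the estimators and kJ/mol at I/O boundaries, with
R = 0.0083144621 kJ mol⁻¹ K⁻¹ and a default temperature of 298 K
(kT = 2.4777 kJ/mol).

## Topology model

Atoms carry a *role* — backbone N/H/Cα/C/O, side-chain Cβ, generic
side-chain atom, water O/H, urea atom — inferred from (atom name, residue
name) by a fixed table (`dimersolv.topology.infer_role`); inference is a
pure function of those two strings, and unknown peptide atoms fall back to
`sc_other` with a logged warning. Boxes are orthorhombic only; triclinic
input raises an explicit unsupported-feature error rather than being
silently wrapped. PDB and GRO files are read and written through
MDAnalysis; extended-XYZ uses a small self-contained dialect with a
`Lattice=` record and coordinates in nm. GRO has no chain field, so chains
are recovered from residue-index resets on reading.

## Reaction coordinate

ξ is the minimum-image distance between the mass-weighted centroids of the
two peptide chains. By default the centroid uses *all* atoms of a chain;
`mass_weighted=False` gives geometric centers, and arbitrary selections are
accepted, because which atom set defines a peptide COM is a modelling
choice that should stay auditable per run. Selections are assumed whole
(not wrapped across the periodic boundary), which the generators guarantee.

## WHAM

Binned WHAM with default bin width 0.01 nm. Bins with zero total counts are
excluded from the profile instead of being assigned infinite free energy —
exclusion avoids fabricating values where nothing was sampled. Windows must
form a single connected component through shared occupied bins; otherwise a
connectivity error names the ξ gap. Convergence requires
max_i |Δf_i| < tol with tol = 1e-7 kT (max 10⁵ iterations); the iteration
is two matrix–vector products per sweep on the precomputed bias matrix, so
even bootstrap replication is cheap. The returned profile is defined up to
a constant.

**Entropy (Jacobian) correction.** `w'(ξ) = w(ξ) + 2RT ln(ξ/1 nm)`. The
implicit 1 nm reference length only adds a constant, which the tail shift
absorbs, so the choice of reference is immaterial.

**Zero at long range.** The profile is shifted so the mean over the last
10% of the grid (at least one bin) is exactly zero. A tail *average* is the
default rather than the single last point because the last bin is the
noisiest; `tail_fraction` exposes the choice.

**Errors.** Bayesian bootstrap with Dirichlet(1,…,1) weights over whole
windows: windows are the natural resampling unit because frames within a
window are autocorrelated, while separate windows come from independent
runs. Each replicate reruns WHAM and re-applies the requested corrections;
the per-bin standard deviation across replicates is the error. Replicates
that fail to converge are dropped with a warning and at least 80% must
succeed. Limitation: in bins dominated by a single window the window-level
weights understate the within-window sampling noise, so 3σ bands can dip
below nominal coverage there; frame-level, autocorrelation-aware weighting
is deliberately out of scope for v1. Statistical inefficiency of window
series is likewise not estimated — the generators produce effectively
independent samples; for real MD input the user should subsample to
roughly independent frames first.

**Binding depth.** Global minimum of the corrected, shifted profile, ties
broken toward smaller ξ. A profile that never goes negative is still
reported but flagged repulsive (association replaced by a repulsive state).
Whether published ΔW percentages compare depths or whole profiles is
ambiguous in general, so the operation reports depths and leaves ratios to
the caller.

## BAR

The self-consistent Bennett equation is solved by bisection on a bracket
seeded by the two exponential-averaging (Zwanzig) estimates and expanded
geometrically until the monotone residual changes sign; monotonicity makes
convergence unconditional, and the residual tolerance is 1e-12 kT. The
standard error is Bennett's asymptotic variance. λ-path free energies sum
per-pair estimates with errors combined in quadrature, treating windows as
independent simulations. The estimator is protocol-agnostic: it never needs
to know the λ spacing, only the forward/reverse energy-difference samples
of each adjacent pair. Transfer free energies are the plain difference
urea-solution minus water, with quadrature error propagation.

## Secondary structure (DSSP-lite)

Backbone N–H···O=C bonds are scored with the Kabsch–Sander energy
(27.888 kcal Å/mol prefactor, distances in Å) and accepted below
−0.5 kcal/mol (−2.09 kJ/mol). Classes: E (β sheet; isolated bridges folded
into E, matching the usual "β-sheet" aggregation of reported fractions),
G (3₁₀ helix, two consecutive i→i+3 turns), H (α helix, two consecutive
i→i+4 turns), T (bare turn, residues strictly between the bonded pair),
C (everything else). Precedence when patterns overlap: H > G > E > T > C.
π-helices and bends are omitted — they do not occur in the target systems'
reported structures. Parallel/antiparallel bridges use the standard
pattern definitions, with same-chain bridges requiring |i−j| > 2.
Residues without an amide H (proline; missing atoms) simply cannot donate —
logged, not fatal. The H-bond search does not apply periodic wrapping; the
fixtures and typical peptide boxes keep chains whole and far from images.
Fraction profiles pool residues × frames at each ξ (per-frame averaging
first is available by calling the classifier per frame).

## RDFs, coordination numbers and maps

RDFs use minimum-image pair histograms normalized by the ideal-gas shell
count at the B-group density; r_max must stay below half the smallest box
length. CN integrates ρ g(r) 4πr² by the trapezoid rule with the endpoint
interpolated onto r_cut — on an ideal-gas fixture this matches (4/3)πr³ρ
and direct pair counting to well under 1%. The first-shell radius is the
first local minimum of the (optionally moving-average-smoothed) RDF after
its first maximum, ties toward smaller r; a monotone g(r) raises an error
prompting an explicit cutoff, with 0.55 nm as the documented fallback.
First-shell radii are intended to be computed once (e.g. from a monomer
ensemble) and frozen across ξ so maps remain comparable along the path.

Per-residue maps count solvent within the shell radius of each residue's
reference site — Cβ, or Cα for glycine — averaged over the same residue in
the two chains and over frames at each ξ. Hydration maps (water and urea
solution alike) are normalized by the residue's maximum *water* CN;
urea maps by the residue's own maximum; `normalize_by` exposes both.
Urea is counted per molecule through its designated carbon atom, not per
atom. O–N neighbor maps count interpeptide backbone carbonyl–amino pairs
within 0.35 nm inclusive (r ≤ 3.5 Å, implemented on squared distances so
the boundary is exact), counting all qualifying pairs — when one O has two
N neighbors both count — in both chain directions, averaged over the two
chains. ξ keys are expected to come from binning frame-wise COM distances
with the PMF bin width so maps and PMFs share an axis.

Nonbonded profiles sum 4ε[(σ/r)¹² − (σ/r)⁶] + f_elec q_i q_j / r over
interchain (or intrachain) pairs with Lorentz–Berthelot combining,
f_elec = 138.935 kJ nm mol⁻¹ e⁻², minimum image and no cutoff — adequate
for the toy systems it targets; Ewald-class electrostatics are out of
scope.

## Synthetic generators

The generators stand in for the molecular-dynamics layer; they produce the
study conditions downstream stages are validated under.

- **Biased 1-D sampling.** For harmonic potential + harmonic bias the
  stationary density is Gaussian and sampled exactly (no dynamics).
  Otherwise an ensemble of overdamped-Langevin walkers (Euler–Maruyama,
  D = 1 in kT units) is propagated with dt chosen so dt·max|U″| ≤ 0.01
  over the thermally accessible range (U ≤ U_min + 25 kT), burn-in of ten
  relaxation times and thinning of three relaxation times between recorded
  samples; tabulated domains get reflecting walls. A long run passes a
  Kolmogorov–Smirnov test at α = 0.01 (n = 10⁵) against the numerically
  normalized Boltzmann density.
- **Dimer scenes.** Two identical 11-residue bead chains (N, H, Cα, C, O,
  Cβ per residue; Cβ omitted for glycine; default sequence AGSIAAATGFV)
  related by a rigid translation, so the COM separation is exact. Solvent
  beads are rejection-sampled strictly inside the target residue's first
  shell and strictly outside every other shell (4%/4% radial margins), so
  counting on the emitted frame reproduces the requested counts exactly and
  map tests are deterministic rather than Poisson-noisy. Optional bulk
  padding to fixed per-species totals lets a ξ series share one topology.
  Unachievable requests (overlapping exclusive shells, full boxes) raise a
  capacity error after a bounded number of attempts.
- **Work samples.** Forward ~ N(ΔG + σ²/2, σ²) and reverse
  ~ N(−ΔG + σ²/2, σ²) in kT, which satisfy the Crooks relation
  ln[P_f(W)/P_r(−W)] = W − ΔG exactly.
- **Motif fixtures.** Idealized backbone placements whose Kabsch–Sander
  pattern is the requested motif: an antiparallel pair whose paired
  residues exchange mutual H-bonds (every pair an antiparallel bridge), a
  three-residue-per-turn cylinder with all i+3→i bonds, and an extended
  strand with alternating carbonyl/amide orientations and no bonds.

What the generators do *not* emulate: force-field energetics, solvent
structure beyond prescribed shell counts, conformational flexibility,
hydrogen-bond dynamics, or finite sampling correlation structure of real
MD. Passing tests therefore demonstrate estimator and bookkeeping
correctness under known ground truth — not that any particular force field
or sampling protocol is adequate for a real peptide.

## Orchestration

`run_demo(seed, output_dir)` exercises every stage on synthetic ground
truth (21-window harmonic PMF with bootstrap errors; a radial double-well
PMF with entropy correction, tail shift and binding depth; BAR on the
Crooks fixture; scene-series hydration/urea maps; β-ladder classification
and O–N contacts; Rg and interchain energy profiles), asserting each
recovery property and writing TSVs rounded to 6 significant digits at
write time so reruns with the same seed are byte-identical across
platforms. The run report records per-stage status, parameters, wall-clock
and SHA-256 checksums of outputs. Demo problem sizes (2000 samples/window,
30 bootstrap replicates, 1200-sample radial windows) are chosen so the
whole demo completes in seconds while keeping every assertion comfortably
inside its statistical tolerance; the test suite and acceptance script use
the full 5000-sample/50-replicate conditions. Configuration files are flat
YAML validated fail-closed: unknown keys are rejected by name and all
problems are reported together.

All randomness flows from one explicit integer seed per call; there is no
global random state anywhere in the package.
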