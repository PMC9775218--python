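# dimersolv

Analysis toolkit for studying how co-solvents (urea in particular) modulate
the association of short amphiphilic peptides, built around the workflow
used for umbrella-sampling studies of peptide "dimers": potentials of mean
force from biased simulations, alchemical solvation free energies, and
per-residue solvation and contact maps along the association pathway. The
motivating system is the C-terminal segment of the nonamyloid-β component
(NAC) of α-synuclein (residues 85–95, AGSIAAATGFV), whose aggregation is
implicated in Parkinson's disease, together with homo-peptide models (Ile,
Gly, Ser) that isolate hydrophobic, backbone and hydrophilic contributions.

The package is aimed at simulators who want the *analysis* layer — the
estimators, the maps and the classifiers — decoupled from any particular MD
engine, with every stage testable against synthetic trajectories whose
ground truth is known exactly.

## What it computes

**Potential of mean force.** For umbrella windows with harmonic biases
`u_i(ξ) = k_i/2 (ξ − ξ_i)²` along the peptide–peptide COM distance
ξ = r_COM–COM, the weighted histogram analysis method (WHAM) solves

    p_j ∝ Σ_i n_ij / Σ_i N_i exp[β(f_i − u_i(ξ_j))],
    f_i = −kT ln Σ_j p_j exp[−β u_i(ξ_j)],

self-consistently, giving `W(ξ) = −kT ln p(ξ)` up to a constant. The radial
Jacobian (entropy) term `+2RT ln ξ` removes the r² growth of the sampling
volume, the profile is shifted to zero free energy at the longest
separations, and per-bin errors come from a Bayesian bootstrap that draws
Dirichlet(1,…,1) weights over whole windows.

**Solvation free energies.** The Bennett acceptance ratio (BAR) solves

    Σ_f 1/(1 + e^{M + W_f − ΔF}) = Σ_r 1/(1 + e^{−M + W_r + ΔF}),
    M = ln(n_f/n_r),

for each λ pair; pair estimates sum along the path, and water → urea
transfer free energies are `ΔΔG_hyd = ΔG_solv(urea) − ΔG_hyd(water)`.

**Structure and solvation along ξ.** Radius-of-gyration distributions; a
DSSP-lite secondary-structure classifier driven by the Kabsch–Sander
hydrogen-bond energy `E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
kcal/mol (bond accepted when E < −0.5 kcal/mol = −2.09 kJ/mol); interpeptide
backbone O–N neighbor maps (pairs within 3.5 Å); RDF-based coordination
numbers `CN = ρ ∫ g(r) 4πr² dr`; and per-residue hydration / urea solvation
maps normalized by each residue's maximum water coordination number (or its
own maximum, for urea maps).

**Synthetic ground truth.** `dimersolv.toy` generates every input with a
known answer: exact Gaussian or overdamped-Langevin sampling from analytic
1-D potentials, bead-model dimer scenes with exact first-shell solvent
counts, Crooks-consistent forward/reverse work samples with known ΔG, and
backbone geometries with prescribed hydrogen-bond ladders.

## Worked example

`examples/01_pmf_from_umbrella_windows.py` builds 21 umbrella windows
(centers −1.0 … 1.0 nm, spring 100 kT/nm², 5000 samples each) over the
known profile `G(ξ) = ½·10·ξ²` kT and recovers it:

```
bins: 249, windows: 21
recovery RMS vs analytic PMF: 0.047 kT  (sampling noise; < 0.15 kT)
3-sigma bootstrap bands cover the truth at 96.0% of bins
```

The RMS is the residual between the WHAM estimate and the analytic curve
after removing the arbitrary constant; the coverage line says the bootstrap
error bars account for that residual. The other examples print BAR
estimates against the generator's ΔG, transfer free energies from tabulated
solvation data, motif classifications (`EEEEEEEEEEEE` for the β ladder),
and the dehydration-on-contact signature recovered exactly from
constructed dimer scenes.

A thin CLI wraps the same functions
(`dimersolv pmf|bar|rg|ss|rdf|maps|contacts|energy-profile|demo|validate`);
`dimersolv demo --seed 7 --out out/` runs every stage end-to-end on
synthetic data with ground-truth assertions and writes deterministic TSVs
plus a provenance report.

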