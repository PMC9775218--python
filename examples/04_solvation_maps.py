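"""Hydration / urea solvation maps and interpeptide O-N contacts.

Builds bead-model peptide dimers at a series of COM separations with exactly
controlled first-shell solvent counts (a dehydration-on-contact water
profile and a urea-depletion profile), then recovers those profiles with the
map machinery, and counts interpeptide backbone O-N neighbors on a
beta-sheet ladder.
"""

import dimersolv as ds

xi_series = (1.0, 1.4, 1.8, 2.2, 2.6)
water_steps = (2, 3, 4, 5, 6)  # waters in each residue's first shell
urea_steps = (0, 1, 2, 3, 3)  # urea depleted at contact

frames_by_xi = {}
top0 = None
for k, xi in enumerate(xi_series):
    spec = ds.DimerSceneSpec(
        com_separation=xi, box=(8.0, 8.0, 8.0), seed=10 + k,
        shell_counts={"water": [water_steps[k]] * 11, "urea": [urea_steps[k]] * 11},
        total_counts={"water": 150, "urea": 80},
    )
    top, traj = ds.build_dimer_scene(spec)
    top0 = top0 or top
    frames_by_xi[xi] = [(traj.frames[0], traj.boxes[0])]

hyd = ds.hydration_map(top0, frames_by_xi, "water", "water_max", 0.55)
ure = ds.hydration_map(top0, frames_by_xi, "urea", "own_max", 0.55)
print("hydration map, residue 1 row (normalized by its max water CN):")
print("  xi:", list(hyd.values.columns))
print("  CN:", [round(v, 2) for v in hyd.values.loc[1]])
print("urea map, residue 1 row (normalized by its own max):")
print("  CN:", [round(v, 2) for v in ure.values.loc[1]])
# A row falling below 1 toward small xi is the dehydration (or urea
# depletion) signature of peptide association.

btop, btraj = ds.generate_secondary_structure_fixture("beta_pair", 6)
cm = ds.on_neighbor_map(btop, {0.4: [(btraj.frames[0], btraj.boxes[0])]})
print("\nO-N neighbors per residue on the beta ladder (cutoff 0.35 nm):",
      cm.values[0.4].tolist())
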