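"""Synthetic generators: sampling distributions, Crooks consistency, exact
scene construction and motif fixtures."""

import numpy as np
import pytest
from scipy import integrate, stats

import dimersolv as ds
from dimersolv.errors import CapacityError, DegenerateInputError


class TestBiasedSampling:
    def test_harmonic_plus_bias_is_exact_gaussian(self):
        """U = 1/2 k xi^2 (k=10) with bias k_b=100 at xi0=0.5: posterior mean
        k_b xi0/(k+k_b) = 0.4545 nm and variance 1/(k+k_b)."""
        n = 50_000
        s = ds.sample_biased_window(
            ds.AnalyticPotential("harmonic", (10.0, 0.0)), 0.5, 100.0, n, seed=1
        )
        mean, var = 100.0 * 0.5 / 110.0, 1.0 / 110.0
        assert abs(s.mean() - mean) < 3 * np.sqrt(var / n)
        assert abs(s.var() - var) < 3 * var * np.sqrt(2.0 / (n - 1))

    def test_flat_tabulated_zero_bias_is_uniform(self):
        flat = ds.AnalyticPotential("tabulated", (0.0, 1.0, 0.0, 0.0))
        s = ds.sample_biased_window(flat, 0.0, 0.0, 10_000, seed=12)
        assert s.min() >= 0.0 and s.max() <= 1.0
        assert stats.kstest(s, "uniform").pvalue > 0.01

    def test_double_well_wells_equally_occupied(self, double_well_samples):
        _, s = double_well_samples
        ratio = (s > 0).mean() / (s < 0).mean()
        assert abs(ratio - 1.0) < 0.05

    def test_stationary_distribution_matches_boltzmann(self, double_well_samples):
        """Empirical distribution of a long Langevin run vs the numerically
        normalized exp(-U) density (KS at alpha = 0.01)."""
        pot, s = double_well_samples
        x = np.linspace(-3.0, 3.0, 4001)
        dens = np.exp(-pot.u(x))
        dens /= integrate.trapezoid(dens, x)
        cdf = integrate.cumulative_trapezoid(dens, x, initial=0.0)
        res = stats.kstest(s, lambda v: np.interp(v, x, cdf))
        assert res.pvalue > 0.01

    def test_unnormalizable_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            ds.sample_biased_window(
                ds.AnalyticPotential("harmonic", (0.0, 0.0)), 0.0, 0.0, 10, seed=0
            )


class TestWorkSamples:
    def test_near_zero_sigma_gives_near_zero_samples(self):
        spec = ds.WorkSampleSpec(0.0, 1e-9, 100, 100, seed=5)
        fwd, rev = ds.generate_work_samples(spec)
        assert np.all(np.abs(fwd) < 1e-7) and np.all(np.abs(rev) < 1e-7)

    def test_forward_mean_is_dg_plus_half_sigma_sq(self):
        spec = ds.WorkSampleSpec(2.0, 1.0, 10_000, 10_000, seed=6)
        fwd, _ = ds.generate_work_samples(spec)
        assert abs(fwd.mean() - 2.5) < 3.0 / np.sqrt(10_000)

    def test_crooks_relation_by_direct_binning(self):
        """ln[P_f(W)/P_r(-W)] vs W must have slope 1 and intercept -dG."""
        dg = 2.0
        spec = ds.WorkSampleSpec(dg, 1.0, 200_000, 200_000, seed=7)
        fwd, rev = ds.generate_work_samples(spec)
        edges = np.linspace(1.0, 4.0, 16)
        width = edges[1] - edges[0]
        centers = 0.5 * (edges[:-1] + edges[1:])
        # normalize by the full sample count, not the in-range count, so the
        # two truncated histograms remain comparable densities
        pf = np.histogram(fwd, bins=edges)[0] / (fwd.size * width)
        pr = np.histogram(-rev, bins=edges)[0] / (rev.size * width)
        ok = (pf > 0) & (pr > 0)
        y = np.log(pf[ok] / pr[ok])
        fit = stats.linregress(centers[ok], y)
        assert abs(fit.slope - 1.0) < 3 * fit.stderr
        assert abs(fit.intercept + dg) < 3 * fit.intercept_stderr

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            ds.WorkSampleSpec(0.0, 0.0, 10, 10)
        with pytest.raises(ValueError):
            ds.WorkSampleSpec(0.0, 1.0, 1, 10)


class TestDimerScene:
    def test_shell_counts_and_com_separation_exact(self):
        counts = [5, 4, 3, 2, 1, 0, 1, 2, 3, 4, 5]
        spec = ds.DimerSceneSpec(
            com_separation=2.7, box=(9.0, 9.0, 9.0), seed=9,
            shell_counts={"water": counts},
        )
        top, traj = ds.build_dimer_scene(spec)
        a, b = top.select(chain_id="A"), top.select(chain_id="B")
        d = ds.com_distance(top, traj.frames[0], traj.boxes[0], a, b)
        assert abs(d - 2.7) < 1e-6
        fb = {2.7: [(traj.frames[0], traj.boxes[0])]}
        raw = ds.solvation.coordination_map(top, fb, "water", 0.55)
        assert raw[2.7].tolist() == [float(c) for c in counts]

    def test_same_seed_is_byte_identical_different_seed_same_counts(self):
        kw = dict(
            com_separation=1.5, box=(8.0, 8.0, 8.0),
            shell_counts={"water": [3] * 11},
        )
        _, t1 = ds.build_dimer_scene(ds.DimerSceneSpec(seed=1, **kw))
        _, t2 = ds.build_dimer_scene(ds.DimerSceneSpec(seed=1, **kw))
        top3, t3 = ds.build_dimer_scene(ds.DimerSceneSpec(seed=2, **kw))
        assert np.array_equal(t1.frames[0], t2.frames[0])
        assert not np.array_equal(t1.frames[0], t3.frames[0])
        fb = {1.5: [(t3.frames[0], t3.boxes[0])]}
        raw = ds.solvation.coordination_map(top3, fb, "water", 0.55)
        assert raw[1.5].tolist() == [3.0] * 11

    def test_glycine_residues_have_no_cb(self):
        top, _ = ds.build_dimer_scene(ds.DimerSceneSpec(com_separation=1.5))
        # NAC-terminal sequence AGSIAAATGFV: glycines at positions 2 and 9
        for rid in (2, 9):
            assert top.select(role=ds.Role.SC_CB, chain_id="A", residue_index=rid).size == 0
        assert top.select(role=ds.Role.SC_CB, chain_id="A", residue_index=1).size == 1

    def test_unplaceable_shell_raises_capacity_error(self):
        # overlapping same-residue shells across the two chains leave no
        # admissible region for an exclusive placement
        spec = ds.DimerSceneSpec(
            n_residues_per_chain=2, sequence="AA", com_separation=0.02,
            box=(4.0, 4.0, 4.0), shell_counts={"water": [1, 0]},
        )
        with pytest.raises(CapacityError):
            ds.build_dimer_scene(spec)

    def test_total_counts_below_shell_requests_rejected(self):
        with pytest.raises(ValueError):
            ds.DimerSceneSpec(
                com_separation=1.5, shell_counts={"water": [3] * 11},
                total_counts={"water": 10},
            )


class TestSecondaryStructureFixtures:
    def test_beta_pair_ladder_energies_below_threshold(self, beta_fixture):
        """Every paired residue exchanges mutual N-H...O=C bonds with
        E < -0.5 kcal/mol (verified by direct energy evaluation)."""
        top, traj = beta_fixture
        bonds, keys = ds.structure.find_hbonds(top, traj.frames[0])
        inter = [
            b for b in bonds if keys[b.donor][0] != keys[b.acceptor][0]
        ]
        assert len(inter) == 12  # 6 pairs x 2 directions
        assert all(b.energy < -0.5 for b in inter)

    def test_helix_310_has_all_i_plus_3_bonds(self):
        top, traj = ds.generate_secondary_structure_fixture("helix_310", 7)
        bonds, keys = ds.structure.find_hbonds(top, traj.frames[0])
        got = {(keys[b.donor][1], keys[b.acceptor][1]) for b in bonds}
        expected = {(i + 3, i) for i in range(1, 5)}
        assert expected <= got
        assert all(b.energy < -0.5 for b in bonds)

    def test_coil_has_no_hbonds(self):
        top, traj = ds.generate_secondary_structure_fixture("coil", 8)
        bonds, _ = ds.structure.find_hbonds(top, traj.frames[0])
        assert bonds == []

    def test_unsupported_motif_rejected(self):
        with pytest.raises(ValueError):
            ds.generate_secondary_structure_fixture("pi_helix", 6)
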