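"""RDFs, coordination numbers, solvation/contact maps, nonbonded profiles."""

import numpy as np
import pytest

import dimersolv as ds
from dimersolv.errors import (
    GeometryError,
    NoMinimumError,
    ParameterizationError,
    SelectionError,
)
from dimersolv.geometry import random_rotation
from dimersolv.solvation import RDFResult


class TestRdf:
    def test_ideal_gas_is_flat(self, ideal_gas_frames):
        top, frames, n_a, n_b, box = ideal_gas_frames
        res = ds.rdf(
            top, frames, top.select(role=ds.Role.SC_CB),
            top.select(role=ds.Role.WATER_O), r_max=1.4, bin_width=0.025,
        )
        sel = (res.r >= 0.35) & (res.r <= 0.45 * box[0])
        assert np.abs(res.g[sel] - 1.0).max() < 0.02

    def test_single_pair_lands_in_its_bin(self):
        top = ds.Topology.from_atoms(["CB", "OW"], [1, 1], ["ALA", "HOH"], ["A", "W"])
        frame = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.5]])
        res = ds.rdf(
            top, [(frame, np.full(3, 6.0))], np.array([0]), np.array([1]),
            r_max=1.0, bin_width=0.01,
        )
        assert res.counts.sum() == 1
        assert res.counts[np.digitize(0.5, np.arange(0, 1.0, 0.01)) - 1] == 1

    def test_bin_doubling_conserves_counts(self, ideal_gas_frames):
        top, frames, *_ = ideal_gas_frames
        a = top.select(role=ds.Role.SC_CB)
        b = top.select(role=ds.Role.WATER_O)
        fine = ds.rdf(top, frames, a, b, r_max=1.2, bin_width=0.01)
        coarse = ds.rdf(top, frames, a, b, r_max=1.2, bin_width=0.02)
        assert fine.counts.sum() == coarse.counts.sum()
        assert np.allclose(fine.counts.reshape(-1, 2).sum(axis=1), coarse.counts)

    def test_r_max_beyond_half_box_rejected(self, ideal_gas_frames):
        top, frames, *_ = ideal_gas_frames
        with pytest.raises(GeometryError):
            ds.rdf(top, frames, top.select(role=ds.Role.SC_CB),
                   top.select(role=ds.Role.WATER_O), r_max=2.0)

    def test_overlapping_groups_rejected(self, ideal_gas_frames):
        top, frames, *_ = ideal_gas_frames
        sel = top.select(role=ds.Role.SC_CB)
        with pytest.raises(SelectionError):
            ds.rdf(top, frames, sel, sel, r_max=1.0)


class TestCoordinationNumber:
    def test_ideal_gas_matches_closed_form(self, ideal_gas_frames):
        """CN of a uniform gas is (4/3) pi r^3 rho, within 1%."""
        top, frames, n_a, n_b, box = ideal_gas_frames
        res = ds.rdf(top, frames, top.select(role=ds.Role.SC_CB),
                     top.select(role=ds.Role.WATER_O), r_max=1.4, bin_width=0.01)
        for r_cut in (0.5, 0.8, 1.2):
            cn = ds.coordination_number(res, r_cut)
            ref = 4.0 / 3.0 * np.pi * r_cut**3 * res.rho
            assert abs(cn - ref) / ref < 0.01

    def test_integration_agrees_with_direct_counting(self, ideal_gas_frames):
        """CN via rho*g*4*pi*r^2 quadrature vs direct pair counting on the
        same ensemble (independent oracle)."""
        top, frames, n_a, n_b, box = ideal_gas_frames
        a = top.select(role=ds.Role.SC_CB)
        b = top.select(role=ds.Role.WATER_O)
        res = ds.rdf(top, frames, a, b, r_max=1.4, bin_width=0.01)
        r_cut = 0.9
        cn = ds.coordination_number(res, r_cut)
        direct = np.mean([
            np.count_nonzero(
                ds.geometry.pair_sq_distances(f[a], f[b], bx) <= r_cut**2
            ) / len(a)
            for f, bx in frames
        ])
        assert abs(cn - direct) / direct < 0.01

    def test_zero_density_gives_zero(self):
        res = RDFResult(r=np.linspace(0.01, 1, 100), g=np.ones(100), rho=0.0,
                        counts=np.zeros(100))
        assert ds.coordination_number(res, 0.5) == 0.0

    def test_monotone_in_cutoff(self, ideal_gas_frames):
        top, frames, *_ = ideal_gas_frames
        res = ds.rdf(top, frames, top.select(role=ds.Role.SC_CB),
                     top.select(role=ds.Role.WATER_O), r_max=1.4, bin_width=0.02)
        cns = [ds.coordination_number(res, rc) for rc in np.linspace(0.1, 1.3, 15)]
        assert np.all(np.diff(cns) >= 0)

    def test_cutoff_beyond_grid_rejected(self, ideal_gas_frames):
        top, frames, *_ = ideal_gas_frames
        res = ds.rdf(top, frames, top.select(role=ds.Role.SC_CB),
                     top.select(role=ds.Role.WATER_O), r_max=1.0)
        with pytest.raises(ValueError):
            ds.coordination_number(res, 1.3)


class TestFirstMinimum:
    @staticmethod
    def _curve(s=0.003):
        r = np.arange(0.005, 1.0, 0.01)
        g = 1 + np.exp(-((r - 0.3) ** 2) / s) - 0.5 * np.exp(-((r - 0.5) ** 2) / s)
        return RDFResult(r=r, g=g, rho=1.0, counts=np.zeros_like(r))

    def test_constructed_curve_minimum_at_half_nm(self):
        assert ds.first_minimum(self._curve()) == pytest.approx(0.5, abs=0.011)

    def test_flat_rdf_raises(self):
        res = RDFResult(r=np.linspace(0.01, 1, 50), g=np.ones(50), rho=1.0,
                        counts=np.zeros(50))
        with pytest.raises(NoMinimumError):
            ds.first_minimum(res)

    def test_smoothing_is_identity_on_smooth_data(self):
        a = ds.first_minimum(self._curve(), smooth_window=1)
        b = ds.first_minimum(self._curve(), smooth_window=3)
        assert a == pytest.approx(b, abs=0.011)


class TestSolvationMaps:
    def test_dehydration_profile_recovered_exactly(self, scene_series):
        """Generator-specified counts {2,3,4,5} over xi give the normalized
        row {0.4, 0.6, 0.8, 1.0} exactly."""
        top, frames_by_xi, xi_series, water_steps = scene_series
        m = ds.hydration_map(top, frames_by_xi, "water", "water_max", 0.55)
        expected = np.array(water_steps) / max(water_steps)
        assert np.array_equal(
            m.values.to_numpy(), np.tile(expected, (11, 1))
        )
        assert np.array_equal(m.norm_constants.to_numpy(), np.full(11, 5.0))

    def test_own_max_bounds_values_by_one(self, scene_series):
        top, frames_by_xi, *_ = scene_series
        m = ds.hydration_map(top, frames_by_xi, "water", "own_max", 0.55)
        assert np.nanmax(m.values.to_numpy()) <= 1.0

    def test_map_invariant_under_rotation_and_chain_relabel(self, scene_series):
        top, frames_by_xi, xi_series, _ = scene_series
        xi0 = xi_series[0]
        frame, box = frames_by_xi[xi0][0]
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        center = box / 2
        rotated = (frame - center) @ rot.T + center
        base = ds.hydration_map(top, {xi0: [(frame, box)]}, "water", "own_max", 0.55)
        moved = ds.hydration_map(top, {xi0: [(rotated, box)]}, "water", "own_max", 0.55)
        assert np.array_equal(base.values.to_numpy(), moved.values.to_numpy())
        # relabel chains A<->B by reordering atoms
        n_a = len(top.select(chain_id="A"))
        n_b = len(top.select(chain_id="B"))
        order = np.concatenate([
            np.arange(n_a, n_a + n_b), np.arange(n_a), np.arange(n_a + n_b, len(top)),
        ])
        top2 = ds.Topology([top.atoms[i] for i in order])
        swapped = ds.hydration_map(
            top2, {xi0: [(frame[order], box)]}, "water", "own_max", 0.55
        )
        assert np.array_equal(base.values.to_numpy(), swapped.values.to_numpy())


class TestOnNeighborMap:
    @staticmethod
    def _two_residue_pair(dz):
        """Minimal two-chain system with one backbone O-N pair dz apart."""
        names = ["N", "CA", "C", "O", "N", "CA", "C", "O"]
        resids = [1, 1, 1, 1, 1, 1, 1, 1]
        chains = ["A"] * 4 + ["B"] * 4
        top = ds.Topology.from_atoms(names, resids, ["ALA"] * 8, chains)
        # A's O sits at z = 0 and B's N at z = dz so their separation is the
        # exact floating-point literal dz (boundary-rule check)
        frame = np.array([
            [1.0, 1.0, 1.0], [1.2, 1.0, 1.0], [1.4, 1.0, 1.0], [1.4, 1.2, 0.0],
            [1.4, 1.2, dz], [1.6, 3.0, 1.0], [1.8, 3.0, 1.0], [1.8, 3.2, 1.0],
        ])
        return top, {1.0: [(frame, np.full(3, 10.0))]}

    def test_pair_at_exactly_the_cutoff_counts(self):
        top, fb = self._two_residue_pair(0.35)
        m = ds.on_neighbor_map(top, fb, cutoff=0.35)
        assert m.values.loc[1, 1.0] == 1.0

    def test_pair_beyond_cutoff_gives_zero(self):
        top, fb = self._two_residue_pair(0.351)
        m = ds.on_neighbor_map(top, fb, cutoff=0.35)
        assert np.all(m.values.to_numpy() == 0.0)

    def test_beta_ladder_counts(self, beta_fixture):
        top, traj = beta_fixture
        m = ds.on_neighbor_map(top, {0.4: [(traj.frames[0], traj.boxes[0])]})
        assert np.all(m.values.to_numpy() == 2.0)


class TestNonbondedProfile:
    @staticmethod
    def _pair_system(r, q=(1.0, -1.0), sigma=0.3, eps=0.0):
        top = ds.Topology.from_atoms(["CA", "CA"], [1, 1], ["ALA", "ALA"], ["A", "B"])
        frame = np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0 + r]])
        fb = {r: [(frame, np.full(3, 10.0))]}
        return top, fb, np.array(q), np.full(2, sigma), np.full(2, eps)

    def test_unit_charges_at_one_nm(self):
        top, fb, q, s, e = self._pair_system(1.0)
        prof = ds.nonbonded_energy_profile(top, fb, q, s, e)
        assert prof.iloc[0] == pytest.approx(-138.935, abs=1e-9)

    def test_lj_zero_at_sigma_and_minimum_at_r_min(self):
        top, fb, q, s, e = self._pair_system(0.3, q=(0.0, 0.0), eps=0.7)
        assert ds.nonbonded_energy_profile(top, fb, q, s, e).iloc[0] == pytest.approx(0.0, abs=1e-12)
        r_min = 2.0 ** (1.0 / 6.0) * 0.3
        top, fb, q, s, e = self._pair_system(r_min, q=(0.0, 0.0), eps=0.7)
        assert ds.nonbonded_energy_profile(top, fb, q, s, e).iloc[0] == pytest.approx(-0.7, abs=1e-9)

    def test_missing_parameters_listed(self):
        top, fb, q, s, e = self._pair_system(1.0)
        q = np.array([np.nan, -1.0])
        with pytest.raises(ParameterizationError, match="charges"):
            ds.nonbonded_energy_profile(top, fb, q, s, e)
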