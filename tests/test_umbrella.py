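"""WHAM, entropy correction, tail shift, bootstrap errors, binding depth."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dimersolv as ds
from dimersolv.errors import ConnectivityError, ConvergenceError
from dimersolv.units import R_KJ_PER_MOL_K, kt_in_kj_per_mol

KT298 = kt_in_kj_per_mol(298.0)


def _aligned_rms_kt(profile, ref_fn, mask):
    resid = profile.w[mask] / KT298 - ref_fn(profile.xi[mask])
    resid = resid - resid.mean()
    return np.sqrt(np.mean(resid**2)), resid


class TestWham:
    def test_single_unbiased_window_reduces_to_log_histogram(self, harmonic_potential):
        samples = ds.sample_biased_window(harmonic_potential, 0.0, 0.0, 100_000, seed=31)
        win = ds.UmbrellaWindow(0.0, 0.0, samples)
        profile, _ = ds.wham([win], bin_width=0.01)
        hist, edges = np.histogram(samples, bins=np.arange(
            np.floor(samples.min() / 0.01) * 0.01, samples.max() + 0.02, 0.01))
        ref = -np.log(hist[hist > 0])
        w_kt = profile.w / KT298
        assert np.allclose(w_kt - w_kt.min(), ref - ref.min(), atol=1e-9)
        # and the log-histogram recovers the analytic potential
        mask = profile.n_eff >= 100
        rms, _ = _aligned_rms_kt(profile, harmonic_potential.u, mask)
        assert rms < 0.1

    def test_21_window_harmonic_recovery(self, wham21, harmonic_potential):
        """Reconstructed PMF matches 1/2 * 10 * xi^2 to < 0.15 kT RMS."""
        profile, _ = wham21
        mask = np.abs(profile.xi) <= 1.0
        rms, _ = _aligned_rms_kt(profile, harmonic_potential.u, mask)
        assert rms < 0.15

    def test_identical_windows_get_identical_offsets(self, harmonic_potential):
        s = ds.sample_biased_window(harmonic_potential, 0.2, 100.0, 4000, seed=32)
        w1 = ds.UmbrellaWindow(0.2, 100.0 * KT298, s)
        w2 = ds.UmbrellaWindow(0.2, 100.0 * KT298, s.copy())
        _, f = ds.wham([w1, w2])
        assert abs(f[1] - f[0]) < 1e-6

    def test_window_permutation_invariance(self, windows21, wham21):
        profile, _ = wham21
        back, _ = ds.wham(windows21[::-1], bin_width=0.01)
        assert np.allclose(back.xi, profile.xi)
        assert np.allclose(back.w, profile.w, atol=1e-4)

    def test_window_splitting_invariance(self, windows21):
        profile, _ = ds.wham(windows21, bin_width=0.01)
        first = windows21[0]
        half = first.samples.size // 2
        split = [
            ds.UmbrellaWindow(first.center, first.spring_k, first.samples[:half]),
            ds.UmbrellaWindow(first.center, first.spring_k, first.samples[half:]),
            *windows21[1:],
        ]
        again, _ = ds.wham(split, bin_width=0.01)
        assert np.allclose(again.w, profile.w, atol=5e-3)

    def test_disconnected_windows_raise_naming_the_gap(self, harmonic_potential):
        w1 = ds.UmbrellaWindow(
            0.0, 500 * KT298,
            ds.sample_biased_window(harmonic_potential, 0.0, 500.0, 1000, seed=33),
        )
        w2 = ds.UmbrellaWindow(
            5.0, 500 * KT298,
            ds.sample_biased_window(
                ds.AnalyticPotential("harmonic", (10.0, 5.0)), 5.0, 500.0, 1000, seed=34
            ),
        )
        with pytest.raises(ConnectivityError, match="gap"):
            ds.wham([w1, w2])

    def test_non_convergence_reports_residual(self, windows21):
        with pytest.raises(ConvergenceError):
            ds.wham(windows21, max_iter=2)


class TestEntropyCorrection:
    def test_values_at_one_and_two_nm(self):
        profile = ds.PMFProfile(
            xi=np.array([1.0, 2.0]), w=np.zeros(2), err=None, n_eff=np.ones(2)
        )
        out = ds.entropy_correct(profile, temperature=298.0)
        assert out.w[0] == 0.0  # ln 1 = 0
        expected = 2.0 * R_KJ_PER_MOL_K * 298.0 * np.log(2.0)
        assert out.w[1] == pytest.approx(expected, abs=1e-12)
        assert round(expected, 3) == 3.435  # kJ/mol

    def test_correction_monotone_in_xi(self):
        xi = np.linspace(0.3, 3.0, 50)
        profile = ds.PMFProfile(xi=xi, w=np.zeros(50), err=None, n_eff=np.ones(50))
        out = ds.entropy_correct(profile)
        assert np.all(np.diff(out.w) > 0)

    def test_nonpositive_xi_rejected(self):
        profile = ds.PMFProfile(
            xi=np.array([-0.5, 1.0]), w=np.zeros(2), err=None, n_eff=np.ones(2)
        )
        with pytest.raises(ValueError):
            ds.entropy_correct(profile)


class TestTailShift:
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_affine_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        profile = ds.PMFProfile(
            xi=np.linspace(0.5, 2.5, n), w=rng.normal(4.2, 2.0, n),
            err=None, n_eff=np.ones(n),
        )
        once = ds.shift_to_zero_tail(profile, 0.1)
        twice = ds.shift_to_zero_tail(once, 0.1)
        n_tail = max(1, int(round(0.1 * n)))
        assert abs(once.w[-n_tail:].mean()) < 1e-12
        assert np.allclose(once.w, twice.w, atol=1e-12)
        assert np.allclose(np.diff(once.w), np.diff(profile.w))

    def test_constant_profile_becomes_zero(self):
        profile = ds.PMFProfile(
            xi=np.linspace(1, 2, 11), w=np.full(11, 7.7), err=None, n_eff=np.ones(11)
        )
        assert np.allclose(ds.shift_to_zero_tail(profile).w, 0.0)


class TestBindingDepth:
    def test_boundary_minimum(self):
        xi = np.linspace(0.5, 2.5, 21)
        profile = ds.PMFProfile(xi=xi, w=xi**2, err=None, n_eff=np.ones(21))
        d = ds.binding_depth(profile)
        assert d.xi_min == pytest.approx(0.5)

    def test_exact_tie_prefers_smaller_xi(self):
        xi = np.linspace(0.5, 2.5, 5)
        w = np.array([0.0, -3.0, 1.0, -3.0, 0.0])
        d = ds.binding_depth(
            ds.PMFProfile(xi=xi, w=w, err=None, n_eff=np.ones(5))
        )
        assert d.xi_min == pytest.approx(xi[1])
        assert not d.repulsive

    def test_all_positive_profile_flagged_repulsive(self):
        xi = np.linspace(0.5, 2.5, 5)
        d = ds.binding_depth(
            ds.PMFProfile(xi=xi, w=xi + 1, err=None, n_eff=np.ones(5))
        )
        assert d.repulsive

    def test_harmonic_fixture_depth_near_analytic_minimum(
        self, wham21, boot_err21, harmonic_potential
    ):
        profile, _ = wham21
        d = ds.binding_depth(profile)
        assert abs(d.xi_min) <= 0.05  # analytic minimum at 0
        i = int(np.argmin(profile.w))
        assert boot_err21[i] >= 0


class TestBayesianBootstrap:
    def test_fixed_seed_is_bit_reproducible(self, windows21, boot_err21):
        again = ds.bayesian_bootstrap(windows21, n_boot=50, seed=202, tail_fraction=None)
        assert np.array_equal(again, boot_err21)

    def test_errors_shrink_with_window_size(self, harmonic_potential):
        def err_for(n, seed):
            wins = ds.toy.harmonic_window_set(
                harmonic_potential, np.arange(-0.5, 0.51, 0.1), 100.0, n, seed=seed
            )
            e = ds.bayesian_bootstrap(wins, n_boot=30, seed=40, tail_fraction=None)
            return np.median(e)

        assert err_for(4000, 41) < err_for(250, 42)

    def test_three_sigma_bands_cover_analytic_curve(
        self, wham21, boot_err21, harmonic_potential
    ):
        profile, _ = wham21
        mask = np.abs(profile.xi) <= 1.0
        _, resid = _aligned_rms_kt(profile, harmonic_potential.u, mask)
        err_kt = boot_err21[mask] / KT298
        covered = np.abs(resid) <= 3.0 * err_kt
        assert covered.mean() >= 0.95
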