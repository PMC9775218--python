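"""Shared fixtures: the expensive synthetic ensembles are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import dimersolv as ds

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

HARMONIC_K = 10.0  # kT/nm^2
BIAS_K = 100.0  # kT/nm^2
N_PER_WINDOW = 5000
WINDOW_SEED = 101
BOOT_SEED = 202


@pytest.fixture(scope="session")
def harmonic_potential() -> ds.AnalyticPotential:
    return ds.AnalyticPotential("harmonic", (HARMONIC_K, 0.0))


@pytest.fixture(scope="session")
def windows21(harmonic_potential) -> list[ds.UmbrellaWindow]:
    """21 umbrella windows, centers -1.0 ... 1.0 nm step 0.1, over the
    harmonic ground truth, exact Gaussian sampling."""
    centers = np.round(np.arange(-1.0, 1.0001, 0.1), 10)
    return ds.toy.harmonic_window_set(
        harmonic_potential, centers, BIAS_K, N_PER_WINDOW, seed=WINDOW_SEED
    )


@pytest.fixture(scope="session")
def wham21(windows21):
    return ds.wham(windows21, bin_width=0.01)


@pytest.fixture(scope="session")
def boot_err21(windows21) -> np.ndarray:
    return ds.bayesian_bootstrap(
        windows21, n_boot=50, seed=BOOT_SEED, tail_fraction=None
    )


@pytest.fixture(scope="session")
def double_well_samples() -> tuple[ds.AnalyticPotential, np.ndarray]:
    """Long unbiased Langevin run over a symmetric double well."""
    pot = ds.AnalyticPotential("double_well", (2.0, 1.0))
    return pot, ds.sample_biased_window(pot, 0.0, 0.0, 100_000, seed=11)


@pytest.fixture(scope="session")
def beta_fixture():
    return ds.generate_secondary_structure_fixture("beta_pair", 6)


@pytest.fixture(scope="session")
def scene_series():
    """Dimer scenes over a xi series with a dehydration-on-contact water
    profile {2,3,4,5} and a shared topology (bulk-padded solvent)."""
    xi_series = (1.0, 1.5, 2.0, 2.5)
    water_steps = (2, 3, 4, 5)
    frames_by_xi = {}
    top0 = None
    for k, xi in enumerate(xi_series):
        spec = ds.DimerSceneSpec(
            com_separation=xi,
            box=(8.0, 8.0, 8.0),
            seed=300 + k,
            shell_counts={"water": [water_steps[k]] * 11},
            total_counts={"water": 130},
        )
        top, traj = ds.build_dimer_scene(spec)
        if top0 is None:
            top0 = top
        frames_by_xi[xi] = [(traj.frames[0], traj.boxes[0])]
    return top0, frames_by_xi, xi_series, water_steps


@pytest.fixture(scope="session")
def ideal_gas_frames():
    """Uniform 'solvent' around uniform reference atoms: g(r) = 1 exactly in
    expectation. 60 frames, 50 A-atoms x 8000 B-atoms, 3 nm box."""
    rng = np.random.default_rng(77)
    box = np.full(3, 3.0)
    n_a, n_b = 50, 8000
    names = ["CB"] * n_a + ["OW"] * n_b
    resids = list(range(1, n_a + 1)) + list(range(1, n_b + 1))
    resnames = ["ALA"] * n_a + ["HOH"] * n_b
    chains = ["A"] * n_a + ["W"] * n_b
    top = ds.Topology.from_atoms(names, resids, resnames, chains)
    frames = [(rng.random((n_a + n_b, 3)) * box, box) for _ in range(60)]
    return top, frames, n_a, n_b, box
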