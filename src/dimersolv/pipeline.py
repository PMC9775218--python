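"""Orchestration: run configuration, provenance report and the end-to-end
synthetic demo exercising every analysis stage against its ground truth."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bar as bar_mod
from . import solvation, structure, toy, umbrella
from .errors import ConfigError, DimersolvError
from .units import DEFAULT_TEMPERATURE, kt_in_kj_per_mol

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Flat declarative run configuration (YAML)."""

    temperature: float = DEFAULT_TEMPERATURE
    bin_width: float = 0.01
    tol: float = 1e-7
    max_iter: int = 100_000
    n_boot: int = 50
    tail_fraction: float = 0.1
    apply_entropy: bool = True
    contact_cutoff: float = 0.35
    shell_radius: float = 0.55
    normalize_by: str = "water_max"
    seed: int = 0
    output_dir: str = "out"
    windows: str | None = None  # glob of window-series files

    _KNOWN = (
        "temperature bin_width tol max_iter n_boot tail_fraction apply_entropy "
        "contact_cutoff shell_radius normalize_by seed output_dir windows"
    ).split()


def validate_config(path: str | Path) -> RunConfig:
    """Parse + validate a config file; unknown keys are rejected (fail
    closed) and all problems are reported together."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    errors: list[str] = []
    for key in data:
        if key not in RunConfig._KNOWN:
            errors.append(f"unknown key {key!r}")
    cfg = RunConfig(**{k: v for k, v in data.items() if k in RunConfig._KNOWN})
    if cfg.temperature <= 0:
        errors.append(f"temperature must be > 0, got {cfg.temperature}")
    if cfg.bin_width <= 0:
        errors.append("bin_width must be > 0")
    if not 0 < cfg.tail_fraction <= 0.5:
        errors.append("tail_fraction must be in (0, 0.5]")
    if cfg.n_boot < 2:
        errors.append("n_boot must be >= 2")
    if cfg.contact_cutoff <= 0 or cfg.shell_radius <= 0:
        errors.append("cutoffs must be positive")
    if cfg.normalize_by not in ("water_max", "own_max"):
        errors.append("normalize_by must be 'water_max' or 'own_max'")
    if cfg.windows is not None:
        base = Path(path).parent
        import glob

        if not glob.glob(str(base / cfg.windows)) and not glob.glob(cfg.windows):
            errors.append(f"windows glob {cfg.windows!r} matches no files")
    if errors:
        raise ConfigError(f"{path}: " + "; ".join(errors))
    return cfg


# --------------------------------------------------------------------------
# run report


@dataclass
class StageRecord:
    name: str
    status: str
    seconds: float
    parameters: dict
    outputs: dict  # filename -> sha256


@dataclass
class RunReport:
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "stages": [asdict(s) for s in self.stages]},
                indent=2,
            )
            + "\n"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


# --------------------------------------------------------------------------
# demo


def run_demo(seed: int = 0, output_dir: str | Path = "demo_out") -> RunReport:
    """Exercise every stage on synthetic ground truth, asserting the
    module-level recovery properties, and write deterministic TSV/JSON
    outputs. Raises DimersolvError naming the failed property on any
    violation."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=seed)
    ss = np.random.SeedSequence(seed)
    sub = [int(s) for s in ss.generate_state(8)]

    def stage(name: str, params: dict, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn() or {}
        except AssertionError as exc:
            report.stages.append(
                StageRecord(name, f"failed: {exc}", time.perf_counter() - t0, params, {})
            )
            report.to_json(out / "run_report.json")
            raise DimersolvError(f"demo stage {name!r} failed: {exc}") from exc
        rec = StageRecord(
            name,
            "ok",
            round(time.perf_counter() - t0, 3),
            params,
            {p.name: _sha256(p) for p in outputs},
        )
        report.stages.append(rec)
        logger.info("stage %s: ok (%.2fs)", name, rec.seconds)

    # -- PMF recovery on the harmonic fixture -------------------------------
    def pmf_stage():
        pot = toy.AnalyticPotential("harmonic", (10.0, 0.0))
        centers = np.round(np.arange(-1.0, 1.0001, 0.1), 10)
        windows = toy.harmonic_window_set(pot, centers, 100.0, 2000, seed=sub[0])
        profile, _ = umbrella.wham(windows, bin_width=0.01)
        err = umbrella.bayesian_bootstrap(
            windows, n_boot=30, seed=sub[1], tail_fraction=None
        )
        kt = kt_in_kj_per_mol(profile.temperature)
        mask = np.abs(profile.xi) <= 1.0
        w_kt = profile.w[mask] / kt
        ref = pot.u(profile.xi[mask])
        resid = w_kt - ref
        resid -= resid.mean()
        rms = float(np.sqrt(np.mean(resid**2)))
        assert rms < 0.15, f"harmonic PMF recovery RMS {rms:.3f} kT >= 0.15 kT"
        df = pd.DataFrame(
            {"xi": profile.xi, "w_kj_mol": profile.w, "err_kj_mol": err,
             "n_eff": profile.n_eff}
        ).set_index("xi")
        _write_tsv(out / "pmf_harmonic.tsv", df)
        return [out / "pmf_harmonic.tsv"]

    stage("pmf_harmonic", {"n_windows": 21, "n_per_window": 2000}, pmf_stage)

    # -- radial PMF with entropy correction + tail shift --------------------
    def radial_stage():
        pot = toy.AnalyticPotential("double_well", (6.0, 1.2))
        centers = np.round(np.arange(0.5, 2.2001, 0.1), 10)
        windows = toy.harmonic_window_set(pot, centers, 150.0, 1200, seed=sub[2])
        profile, _ = umbrella.wham(windows, bin_width=0.01)
        profile = umbrella.entropy_correct(profile)
        profile = umbrella.shift_to_zero_tail(profile, 0.1)
        depth = umbrella.binding_depth(profile)
        df = pd.DataFrame(
            {"xi": profile.xi, "w_kj_mol": profile.w, "n_eff": profile.n_eff}
        ).set_index("xi")
        _write_tsv(out / "pmf_radial.tsv", df)
        (out / "pmf_radial_summary.json").write_text(
            json.dumps(
                {"xi_min_nm": round(depth.xi_min, 6),
                 "w_min_kj_mol": round(depth.w_min, 6),
                 "repulsive": depth.repulsive},
                indent=2,
            )
            + "\n"
        )
        return [out / "pmf_radial.tsv", out / "pmf_radial_summary.json"]

    stage("pmf_radial", {"potential": "double_well(6, 1.2)"}, radial_stage)

    # -- BAR on the Crooks fixture ------------------------------------------
    def bar_stage():
        spec = toy.WorkSampleSpec(2.0, 1.0, 4000, 4000, seed=sub[3])
        fwd, rev = toy.generate_work_samples(spec)
        res = bar_mod.bar_pair(bar_mod.LambdaPair(fwd, rev))
        err = abs(res.df - spec.delta_g_true)
        assert err <= 3 * res.se, (
            f"BAR estimate {res.df:.4f} kT off truth {spec.delta_g_true} "
            f"by {err:.4f} > 3*SE={3 * res.se:.4f}"
        )
        kt = kt_in_kj_per_mol(DEFAULT_TEMPERATURE)
        (out / "bar.json").write_text(
            json.dumps(
                {"delta_f_kt": round(res.df, 6), "se_kt": round(res.se, 6),
                 "delta_g_kj_mol": round(res.df * kt, 6),
                 "truth_kt": spec.delta_g_true},
                indent=2,
            )
            + "\n"
        )
        return [out / "bar.json"]

    stage("bar", {"delta_g_true_kt": 2.0, "sigma": 1.0, "n": 4000}, bar_stage)

    # -- dimer scenes: hydration / urea maps --------------------------------
    xi_series = (1.0, 1.4, 1.8, 2.2, 2.6)
    water_steps = (2, 3, 4, 5, 6)  # dehydration on contact
    urea_steps = (0, 1, 2, 3, 3)  # urea depletion on contact

    def maps_stage():
        scenes = {}
        for k, xi in enumerate(xi_series):
            spec = toy.DimerSceneSpec(
                com_separation=xi,
                box=(8.0, 8.0, 8.0),
                seed=sub[4] + k,
                shell_counts={
                    "water": [water_steps[k]] * 11,
                    "urea": [urea_steps[k]] * 11,
                },
                total_counts={"water": 150, "urea": 80},
            )
            top, traj = toy.build_dimer_scene(spec)
            scenes[xi] = (top, [(traj.frames[0], traj.boxes[0])])
        top0 = scenes[xi_series[0]][0]
        frames_by_xi = {xi: scenes[xi][1] for xi in xi_series}
        hyd = solvation.hydration_map(
            top0, frames_by_xi, "water", "water_max", shell_radii=0.55
        )
        ure = solvation.hydration_map(
            top0, frames_by_xi, "urea", "own_max", shell_radii=0.55
        )
        exp_w = np.array(water_steps) / max(water_steps)
        exp_u = np.array(urea_steps) / max(urea_steps)
        assert np.allclose(hyd.values.to_numpy(), exp_w[None, :], atol=0), (
            "hydration map does not equal the generator's normalized profile"
        )
        assert np.allclose(ure.values.to_numpy(), exp_u[None, :], atol=0), (
            "urea map does not equal the generator's normalized profile"
        )
        hyd.to_tsv(out / "hydration_map.tsv")
        ure.to_tsv(out / "urea_map.tsv")
        return [out / "hydration_map.tsv", out / "urea_map.tsv"]

    stage(
        "solvation_maps",
        {"xi": list(xi_series), "water": list(water_steps), "urea": list(urea_steps)},
        maps_stage,
    )

    # -- secondary structure + O-N contacts on the beta fixture -------------
    def ss_stage():
        top, traj = toy.generate_secondary_structure_fixture("beta_pair", 6)
        bound = traj.frames[0]
        apart = bound.copy()
        b_idx = top.select(chain_id="B")
        apart[b_idx] += np.array([0.0, 2.0, 0.0])  # pull the strands apart
        frames_by_xi = {
            0.4: [(bound, traj.boxes[0])],
            2.4: [(apart, traj.boxes[0])],
        }
        profile = structure.ss_fraction_profile(top, {k: [f for f, _ in v] for k, v in frames_by_xi.items()})
        assert np.allclose(profile.sum(axis=1), 1.0), "SS fractions do not sum to 1"
        assert profile.loc[0.4, "E"] == 1.0, "bound beta pair should be all E"
        assert profile.loc[2.4, "C"] == 1.0, "separated strands should be all coil"
        contacts = solvation.on_neighbor_map(top, frames_by_xi, cutoff=0.35)
        assert np.all(contacts.values[0.4].to_numpy() == 2.0), (
            "each paired residue should have 2 interchain O-N neighbors"
        )
        assert np.all(contacts.values[2.4].to_numpy() == 0.0), (
            "separated strands should have no O-N neighbors"
        )
        _write_tsv(out / "ss_fractions.tsv", profile)
        contacts.to_tsv(out / "on_contacts.tsv")
        return [out / "ss_fractions.tsv", out / "on_contacts.tsv"]

    stage("secondary_structure", {"motif": "beta_pair", "n": 6}, ss_stage)

    # -- Rg + nonbonded energy profile on the scenes ------------------------
    def rg_energy_stage():
        spec = toy.DimerSceneSpec(com_separation=1.5, box=(8.0, 8.0, 8.0), seed=sub[5])
        top, traj = toy.build_dimer_scene(spec)
        rg = structure.radius_of_gyration(top, traj, top.select(chain_id="A"))
        n_at = len(top)
        charges = np.zeros(n_at)
        from .topology import Role

        charges[top.select(role=Role.BB_O)] = -0.5
        charges[top.select(role=Role.BB_N)] = +0.5
        sigma = np.full(n_at, 0.3)
        eps = np.full(n_at, 0.4)
        frames_by_xi = {}
        for k, xi in enumerate(xi_series):
            s = toy.DimerSceneSpec(com_separation=xi, box=(8.0, 8.0, 8.0), seed=sub[6] + k)
            t2, tr2 = toy.build_dimer_scene(s)
            frames_by_xi[xi] = [(tr2.frames[0], tr2.boxes[0])]
        energy = solvation.nonbonded_energy_profile(
            top, frames_by_xi, charges, sigma, eps, scope="interchain"
        )
        df = pd.DataFrame({"rg_nm": rg})
        _write_tsv(out / "rg.tsv", df)
        _write_tsv(out / "interchain_energy.tsv", energy.to_frame("u_kj_mol"))
        return [out / "rg.tsv", out / "interchain_energy.tsv"]

    stage("rg_energy", {"xi": list(xi_series)}, rg_energy_stage)

    report.to_json(out / "run_report.json")
    return report
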