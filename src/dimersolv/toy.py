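"""Synthetic ground-truth generators.

Every downstream stage is exercised on data produced here with known
analytic answers: biased 1-D sampling from a known potential (stands in for
umbrella-sampling MD), bead-model peptide dimers with exactly controlled
first-shell solvent counts (stands in for solvated umbrella configurations),
forward/reverse work samples obeying the Crooks relation with known ΔG
(stands in for alchemical λ windows), and idealized backbone geometries with
prescribed hydrogen-bond ladders (fixtures for the secondary-structure
classifier).

Energies are in kT and lengths in nm throughout; all randomness flows from
one explicit integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import CapacityError, DegenerateInputError
from .topology import ONE_TO_THREE, Atom, Role, Topology, Trajectory, infer_element, infer_role
from .umbrella import UmbrellaWindow
from .units import DEFAULT_TEMPERATURE, kt_in_kj_per_mol

NAC_TERM_SEQUENCE = "AGSIAAATGFV"  # C-terminal NAC segment, residues 85-95


# --------------------------------------------------------------------------
# analytic potentials


@dataclass(frozen=True)
class AnalyticPotential:
    """1-D potential in kT units over a coordinate in nm.

    forms:
      harmonic:    parameters (k, x0)        U = k/2 (x-x0)^2
      double_well: parameters (a, b)         U = a (x^2-b^2)^2
      tabulated:   parameters (xmin, xmax, u_0 ... u_{m-1})
                   linear interpolation on m evenly spaced knots; +inf
                   outside [xmin, xmax]
    """

    form: Literal["harmonic", "double_well", "tabulated"]
    parameters: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.parameters)
        object.__setattr__(self, "parameters", p)
        if self.form == "harmonic":
            if len(p) != 2 or p[0] < 0:
                raise ValueError("harmonic needs parameters (k >= 0, x0)")
        elif self.form == "double_well":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("double_well needs parameters (a > 0, b > 0)")
        elif self.form == "tabulated":
            if len(p) < 4 or p[1] <= p[0]:
                raise ValueError(
                    "tabulated needs (xmin, xmax, >=2 knot values) with xmax > xmin"
                )
        else:
            raise ValueError(f"unknown potential form {self.form!r}")

    @property
    def domain(self) -> tuple[float, float] | None:
        if self.form == "tabulated":
            return self.parameters[0], self.parameters[1]
        return None

    def _knots(self) -> tuple[np.ndarray, np.ndarray]:
        xmin, xmax, *u = self.parameters
        return np.linspace(xmin, xmax, len(u)), np.asarray(u)

    def u(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            k, x0 = self.parameters
            return 0.5 * k * (x - x0) ** 2
        if self.form == "double_well":
            a, b = self.parameters
            return a * (x**2 - b**2) ** 2
        xk, uk = self._knots()
        out = np.interp(x, xk, uk)
        return np.where((x < xk[0]) | (x > xk[-1]), np.inf, out)

    def du(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            k, x0 = self.parameters
            return k * (x - x0)
        if self.form == "double_well":
            a, b = self.parameters
            return 4.0 * a * x * (x**2 - b**2)
        xk, uk = self._knots()
        slopes = np.diff(uk) / np.diff(xk)
        idx = np.clip(np.searchsorted(xk, x, side="right") - 1, 0, len(slopes) - 1)
        return slopes[idx]


# --------------------------------------------------------------------------
# biased 1-D sampling


def _biased(potential: AnalyticPotential, center: float, k_b: float):
    def u(x):
        return potential.u(x) + 0.5 * k_b * (np.asarray(x) - center) ** 2

    def du(x):
        return potential.du(x) + k_b * (np.asarray(x) - center)

    return u, du


def sample_biased_window(
    potential: AnalyticPotential,
    bias_center: float,
    bias_k: float,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    n_walkers: int = 256,
) -> np.ndarray:
    """Draw n samples from exp(-[U(x) + k_b/2 (x - x0)^2]) (energies in kT).

    For a harmonic U with a harmonic bias the stationary density is an exact
    Gaussian and is sampled directly (no dynamics). Otherwise an ensemble of
    overdamped-Langevin (Euler-Maruyama) walkers is propagated with an
    automatically chosen time step (dt * max|U_b''| <= 0.01 over the
    thermally accessible range), burn-in of ten relaxation times and thinning
    of three relaxation times between recorded samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bias_k < 0:
        raise ValueError("bias_k must be >= 0")
    rng = np.random.default_rng(seed)
    if potential.form == "harmonic":
        k, x0 = potential.parameters
        ktot = k + bias_k
        if ktot <= 0:
            raise DegenerateInputError(
                "flat unbounded potential with no bias is unnormalizable"
            )
        mean = (k * x0 + bias_k * bias_center) / ktot
        return rng.normal(mean, 1.0 / np.sqrt(ktot), size=n)

    u_b, du_b = _biased(potential, bias_center, bias_k)
    dom = potential.domain
    if dom is not None:
        lo, hi = dom
    else:
        half = 8.0 + 4.0 / np.sqrt(bias_k) if bias_k > 0 else 12.0
        ctr = bias_center if bias_k > 0 else 0.0
        lo, hi = ctr - half, ctr + half
    grid = np.linspace(lo, hi, 4001)
    ug = u_b(grid)
    if not np.any(np.isfinite(ug)):
        raise DegenerateInputError("potential is non-finite over the whole domain")
    i0 = int(np.nanargmin(np.where(np.isfinite(ug), ug, np.nan)))
    x_start = grid[i0]
    if not np.isfinite(u_b(x_start)):
        raise DegenerateInputError(f"non-finite potential at start point {x_start}")
    # thermally accessible range: u_b <= u_min + 25 kT
    acc = np.isfinite(ug) & (ug <= ug[i0] + 25.0)
    span = grid[acc]
    width = max(span.max() - span.min(), 1e-6)
    h = grid[1] - grid[0]
    curv = np.abs(np.diff(ug[acc], 2)) / h**2 if acc.sum() > 2 else np.array([0.0])
    curv_max = float(curv.max()) if curv.size else 0.0
    if curv_max > 1e-9:
        dt = 0.01 / curv_max
        tau = 1.0 / max(curv_max * 0.05, 1.0 / (0.5 * width**2))
        # relaxation time from the curvature near the start minimum
        j = np.searchsorted(grid, x_start)
        j = np.clip(j, 1, len(grid) - 2)
        c_min = (ug[j - 1] - 2 * ug[j] + ug[j + 1]) / h**2
        if np.isfinite(c_min) and c_min > 1e-9:
            tau = 1.0 / c_min
    else:  # flat potential: diffusive relaxation over the box
        dt = (width / 30.0) ** 2 / 2.0
        tau = width**2 / 2.0
    burn = int(np.ceil(10.0 * tau / dt))
    thin = max(1, int(np.ceil(3.0 * tau / dt)))

    n_walkers = min(n_walkers, max(1, n))
    x = np.full(n_walkers, x_start) + 0.05 * width * rng.standard_normal(n_walkers)
    if dom is not None:
        x = np.clip(x, lo, hi)
    sq2dt = np.sqrt(2.0 * dt)
    n_rec = int(np.ceil(n / n_walkers))
    out = np.empty((n_rec, n_walkers))
    total = burn + n_rec * thin
    chunk = 20_000
    step = 0
    rec = 0
    next_record = burn + thin
    while step < total:
        m = min(chunk, total - step)
        noise = rng.standard_normal((m, n_walkers))
        for s in range(m):
            x = x - dt * du_b(x) + sq2dt * noise[s]
            if dom is not None:  # reflecting walls at the tabulated domain
                x = np.where(x < lo, 2 * lo - x, x)
                x = np.where(x > hi, 2 * hi - x, x)
                x = np.clip(x, lo, hi)
            step += 1
            if step == next_record:
                out[rec] = x
                rec += 1
                next_record += thin
    return out.reshape(-1)[:n]


def harmonic_window_set(
    potential: AnalyticPotential,
    centers: Sequence[float],
    bias_k_kt: float,
    n_per_window: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Umbrella windows over ``potential`` at the given centers, with the
    bias spring given in kT/nm^2 and stored on the window in kJ/mol/nm^2."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(len(centers))]
    kt = kt_in_kj_per_mol(temperature)
    return [
        UmbrellaWindow(
            center=float(c),
            spring_k=bias_k_kt * kt,
            samples=sample_biased_window(
                potential, float(c), bias_k_kt, n_per_window, temperature, sd
            ),
            temperature=temperature,
        )
        for c, sd in zip(centers, seeds)
    ]


# --------------------------------------------------------------------------
# Crooks-consistent work samples


@dataclass(frozen=True)
class WorkSampleSpec:
    """Gaussian forward/reverse work distributions with known ΔG (kT).

    forward ~ N(ΔG + σ²/2, σ²) and reverse ~ N(-ΔG + σ²/2, σ²) satisfy the
    Crooks fluctuation relation ln[P_f(W)/P_r(-W)] = W - ΔG exactly.
    """

    delta_g_true: float
    sigma: float
    n_forward: int
    n_reverse: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_forward < 2 or self.n_reverse < 2:
            raise ValueError("sample counts must be >= 2")


def generate_work_samples(spec: WorkSampleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse energy-difference samples (kT) per the spec."""
    rng = np.random.default_rng(spec.seed)
    half = 0.5 * spec.sigma**2
    fwd = rng.normal(spec.delta_g_true + half, spec.sigma, spec.n_forward)
    rev = rng.normal(-spec.delta_g_true + half, spec.sigma, spec.n_reverse)
    return fwd, rev


# --------------------------------------------------------------------------
# bead-model dimer scenes


#: per-residue backbone/side-chain bead template, offsets in nm from the
#: residue center; CB omitted for glycine
_RESIDUE_TEMPLATE = (
    ("N", (-0.125, 0.050, 0.0)),
    ("H", (-0.125, 0.150, 0.0)),
    ("CA", (0.000, 0.000, 0.0)),
    ("C", (0.125, 0.050, 0.0)),
    ("O", (0.125, 0.173, 0.0)),
    ("CB", (0.000, -0.153, 0.0)),
)

_RESIDUE_SPACING = 0.38  # nm, CA-CA


@dataclass(frozen=True)
class DimerSceneSpec:
    """Two bead peptides at a controlled COM separation with exact per-residue
    first-shell solvent counts for each species ("water", "urea")."""

    n_residues_per_chain: int = 11
    com_separation: float = 1.5
    box: tuple[float, float, float] = (8.0, 8.0, 8.0)
    seed: int = 0
    sequence: str = NAC_TERM_SEQUENCE
    shell_radius: float = 0.55
    shell_counts: Mapping[str, Sequence[int]] = field(default_factory=dict)
    #: optional total bead count per species; the remainder after shell
    #: placement is put in the bulk (outside every shell), letting a series
    #: of scenes with different shell counts share one topology
    total_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.com_separation <= 0:
            raise ValueError("com_separation must be > 0")
        if len(self.sequence) != self.n_residues_per_chain:
            raise ValueError("sequence length must match n_residues_per_chain")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.com_separation >= min(self.box) / 2:
            raise ValueError("com_separation must be below half the box length")
        for species, counts in self.shell_counts.items():
            if species not in ("water", "urea"):
                raise ValueError(f"unknown solvent species {species!r}")
            if len(counts) != self.n_residues_per_chain:
                raise ValueError(f"{species} counts must have one entry per residue")
            if any(c < 0 for c in counts):
                raise ValueError("target shell counts must be >= 0")
        for species, total in self.total_counts.items():
            in_shells = 2 * sum(self.shell_counts.get(species, ()))
            if total < in_shells:
                raise ValueError(
                    f"total_counts[{species!r}]={total} below the {in_shells} "
                    "beads already requested in shells"
                )
        extent = (self.n_residues_per_chain - 1) * _RESIDUE_SPACING
        if extent + 2 * (self.shell_radius + 0.2) > self.box[0]:
            raise ValueError("box too small for the chains plus shell cutoff")


def _chain_coords(n_res: int, sequence: str) -> tuple[list[tuple[str, int, str]], np.ndarray]:
    atoms: list[tuple[str, int, str]] = []
    coords: list[tuple[float, float, float]] = []
    for i in range(n_res):
        resname = ONE_TO_THREE[sequence[i]]
        c = i * _RESIDUE_SPACING
        for name, (dx, dy, dz) in _RESIDUE_TEMPLATE:
            if name == "CB" and resname == "GLY":
                continue
            atoms.append((name, i + 1, resname))
            coords.append((c + dx, dy, dz))
    return atoms, np.asarray(coords)


def build_dimer_scene(spec: DimerSceneSpec) -> tuple[Topology, Trajectory]:
    """Deterministically build a two-chain bead dimer plus solvent.

    The two chains are identical up to a rigid z-translation so their COM
    distance equals ``spec.com_separation`` exactly. Each requested solvent
    bead is rejection-sampled to lie strictly inside the first shell of its
    target residue's reference site (CB; CA for glycine) and strictly outside
    every other residue's shell, so counting on the emitted frame returns the
    target counts exactly.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    n_res = spec.n_residues_per_chain
    chain_atoms, chain_xyz = _chain_coords(n_res, spec.sequence)
    extent = (n_res - 1) * _RESIDUE_SPACING
    base = np.array([box[0] / 2 - extent / 2, box[1] / 2, box[2] / 2])
    shift_a = base + np.array([0.0, 0.0, -spec.com_separation / 2])
    shift_b = base + np.array([0.0, 0.0, +spec.com_separation / 2])
    xyz_a = chain_xyz + shift_a
    xyz_b = chain_xyz + shift_b

    # reference sites (CB, or CA for glycine) per chain per residue
    def ref_sites(xyz: np.ndarray) -> np.ndarray:
        sites = []
        k = 0
        for i in range(n_res):
            resname = ONE_TO_THREE[spec.sequence[i]]
            names = [nm for nm, _ in _RESIDUE_TEMPLATE if not (nm == "CB" and resname == "GLY")]
            block = xyz[k : k + len(names)]
            target = "CA" if resname == "GLY" else "CB"
            sites.append(block[names.index(target)])
            k += len(names)
        return np.asarray(sites)

    sites = np.concatenate([ref_sites(xyz_a), ref_sites(xyz_b)])  # (2*n_res, 3)
    r = spec.shell_radius
    solvent: dict[str, list[np.ndarray]] = {"water": [], "urea": []}
    max_tries = 20_000
    for species in ("water", "urea"):
        counts = spec.shell_counts.get(species)
        if counts is None:
            continue
        for chain_offset in (0, n_res):
            for i in range(n_res):
                target = sites[chain_offset + i]
                others = np.delete(sites, chain_offset + i, axis=0)
                placed = 0
                tries = 0
                while placed < counts[i]:
                    tries += 1
                    if tries > max_tries:
                        raise CapacityError(
                            f"cannot place {counts[i]} {species} beads in the shell "
                            f"of residue {i + 1} (chain {'B' if chain_offset else 'A'}): "
                            "shells too crowded for the requested counts"
                        )
                    vec = rng.standard_normal(3)
                    vec /= np.linalg.norm(vec)
                    rad = 0.96 * r * rng.random() ** (1.0 / 3.0)
                    pos = target + rad * vec
                    d = pos[None, :] - others
                    d -= box * np.round(d / box)
                    if np.min(np.einsum("ij,ij->i", d, d)) > (1.04 * r) ** 2:
                        solvent[species].append(np.mod(pos, box))
                        placed += 1
    # bulk padding: uniform in the box, strictly outside every shell
    for species in ("water", "urea"):
        total = spec.total_counts.get(species)
        if total is None:
            continue
        n_bulk = total - len(solvent[species])
        placed = 0
        tries = 0
        while placed < n_bulk:
            tries += 1
            if tries > max_tries * max(1, n_bulk):
                raise CapacityError(
                    f"cannot place {n_bulk} bulk {species} beads outside the shells"
                )
            pos = rng.random(3) * box
            d = pos[None, :] - sites
            d -= box * np.round(d / box)
            if np.min(np.einsum("ij,ij->i", d, d)) > (1.04 * r) ** 2:
                solvent[species].append(pos)
                placed += 1

    atoms: list[Atom] = []
    coords: list[np.ndarray] = [xyz_a, xyz_b]
    for chain_id, xyz in (("A", xyz_a), ("B", xyz_b)):
        for name, rid, resname in chain_atoms:
            atoms.append(
                Atom(name, infer_element(name), infer_role(name, resname), rid, resname, chain_id)
            )
    for j, pos in enumerate(solvent["water"], start=1):
        atoms.append(Atom("OW", "O", Role.WATER_O, j, "HOH", "W"))
    for j, pos in enumerate(solvent["urea"], start=1):
        atoms.append(Atom("C", "C", Role.UREA, j, "URE", "U"))
    if solvent["water"]:
        coords.append(np.asarray(solvent["water"]))
    if solvent["urea"]:
        coords.append(np.asarray(solvent["urea"]))
    frame = np.concatenate(coords)
    return Topology(atoms), Trajectory(frames=[frame], boxes=[box])


# --------------------------------------------------------------------------
# secondary-structure fixtures


def _backbone_chain(
    placements: list[dict[str, np.ndarray]], chain_id: str, resname: str = "ALA"
) -> tuple[list[Atom], np.ndarray]:
    atoms, coords = [], []
    for i, res in enumerate(placements, start=1):
        for name in ("N", "H", "CA", "C", "O"):
            atoms.append(
                Atom(name, infer_element(name), infer_role(name, resname), i, resname, chain_id)
            )
            coords.append(res[name])
    return atoms, np.asarray(coords)


def generate_secondary_structure_fixture(
    motif: Literal["beta_pair", "helix_310", "coil"], n_residues: int = 6
) -> tuple[Topology, Trajectory]:
    """Idealized backbone geometries whose Kabsch-Sander H-bond pattern is
    the requested motif.

    beta_pair: two antiparallel ``n_residues``-long strands whose paired
    residues exchange mutual N-H...O=C bonds (an antiparallel bridge ladder).
    helix_310: a single chain on a three-residue-per-turn cylinder with every
    i+3 -> i hydrogen bond present. coil: an extended strand with alternating
    carbonyl/amide orientations and no qualifying hydrogen bonds.
    """
    if n_residues < 4:
        raise ValueError("n_residues must be >= 4")
    spacing = 0.70  # nm between residue centers along a strand
    box = np.full(3, 50.0)
    origin = np.array([10.0, 10.0, 10.0])

    def strand_residue(c: float, direction: float, flip: float, y0: float):
        return {
            "N": origin + np.array([c - 0.19 * direction, y0, 0.0]),
            "H": origin + np.array([c - 0.19 * direction, y0 + 0.10 * flip, 0.0]),
            "CA": origin + np.array([c, y0, 0.0]),
            "C": origin + np.array([c + 0.19 * direction, y0, 0.0]),
            "O": origin + np.array([c + 0.19 * direction, y0 + 0.123 * flip, 0.0]),
        }

    if motif == "beta_pair":
        res_a = [strand_residue(i * spacing, +1.0, +1.0, 0.0) for i in range(n_residues)]
        res_b = [
            strand_residue((n_residues - 1 - j) * spacing, -1.0, -1.0, 0.413)
            for j in range(n_residues)
        ]
        atoms_a, xyz_a = _backbone_chain(res_a, "A")
        atoms_b, xyz_b = _backbone_chain(res_b, "B")
        top = Topology(atoms_a + atoms_b)
        frame = np.concatenate([xyz_a, xyz_b])
    elif motif == "helix_310":
        rho, rise = 0.20, 0.19  # nm
        res = []
        for i in range(n_residues):
            th = np.deg2rad(120.0 * i)
            ca = origin + np.array([rho * np.cos(th), rho * np.sin(th), rise * i])
            res.append(
                {
                    "N": ca + np.array([0.0, 0.0, -0.10]),
                    "H": ca + np.array([0.0, 0.0, -0.20]),
                    "CA": ca,
                    "C": ca + np.array([0.0, 0.0, 0.10]),
                    "O": ca + np.array([0.0, 0.0, 0.223]),
                }
            )
        atoms, frame = _backbone_chain(res, "A")
        top = Topology(atoms)
    elif motif == "coil":
        res = [
            strand_residue(i * spacing, +1.0, (-1.0) ** i, 0.0) for i in range(n_residues)
        ]
        atoms, frame = _backbone_chain(res, "A")
        top = Topology(atoms)
    else:
        raise ValueError(f"unsupported motif {motif!r}")
    return top, Trajectory(frames=[frame], boxes=[box])
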