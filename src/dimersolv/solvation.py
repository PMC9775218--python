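"""Radial distribution functions, coordination numbers, hydration and urea
solvation maps, interpeptide O-N neighbor maps and nonbonded energy profiles
along the reaction coordinate.

The per-residue maps follow the umbrella-sampling analysis: for every COM
separation xi, the coordination number of solvent around each residue's
reference site (CB; CA for glycine) is averaged over the same residue in the
two peptides, then normalized either by that residue's maximum hydration in
water (hydration maps) or by its own maximum (urea maps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChainCountError,
    GeometryError,
    NoMinimumError,
    ParameterizationError,
    SelectionError,
)
from .geometry import pair_sq_distances
from .topology import Role, Topology, require_nonempty
from .units import F_ELEC

#: fallback first-shell radius (nm) when an RDF has no interior minimum
DEFAULT_SHELL_RADIUS = 0.55

FrameSet = Sequence[tuple[np.ndarray, np.ndarray]]  # [(frame, box), ...]


# --------------------------------------------------------------------------
# RDF and coordination numbers


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, nm
    g: np.ndarray
    rho: float  # reference (B-group) number density, nm^-3
    counts: np.ndarray  # raw pair counts per shell (summed over frames)


def rdf(
    topology: Topology,
    frames: FrameSet,
    group_a: np.ndarray,
    group_b: np.ndarray,
    r_max: float,
    bin_width: float = 0.005,
) -> RDFResult:
    """Pair-distance histogram g(r) between two disjoint groups, normalized
    by the ideal-gas shell count at the B-group density (minimum image)."""
    group_a = require_nonempty(np.asarray(group_a), "group_a")
    group_b = require_nonempty(np.asarray(group_b), "group_b")
    if np.intersect1d(group_a, group_b).size:
        raise SelectionError("RDF groups must be disjoint")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    rho_sum = 0.0
    for frame, box in frames:
        if r_max >= min(box) / 2:
            raise GeometryError(
                f"r_max={r_max} exceeds half the smallest box length {min(box) / 2}"
            )
        d2 = pair_sq_distances(frame[group_a], frame[group_b], box)
        d = np.sqrt(d2.ravel())
        counts += np.histogram(d, bins=edges)[0]
        rho_sum += len(group_b) / np.prod(box)
    n_frames = len(frames)
    rho = rho_sum / n_frames
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = len(group_a) * rho * shell_vol * n_frames
    g = counts / ideal
    return RDFResult(r=0.5 * (edges[:-1] + edges[1:]), g=g, rho=rho, counts=counts)


def coordination_number(result: RDFResult, r_cut: float) -> float:
    """CN = rho * integral_0^{r_cut} g(r) 4 pi r^2 dr (trapezoid, with the
    endpoint interpolated onto r_cut)."""
    r, g = result.r, result.g
    if r_cut > r[-1] + (r[1] - r[0]) / 2 or r_cut <= 0:
        raise ValueError(f"r_cut={r_cut} outside the RDF grid")
    integrand = 4.0 * np.pi * r**2 * g * result.rho
    mask = r <= r_cut
    rs = np.concatenate([[0.0], r[mask]])
    ys = np.concatenate([[0.0], integrand[mask]])
    if r[mask].size and r_cut > r[mask][-1] and r_cut <= r[-1]:
        y_end = np.interp(r_cut, r, integrand)
        rs = np.concatenate([rs, [r_cut]])
        ys = np.concatenate([ys, [y_end]])
    return float(np.trapezoid(ys, rs))


def first_minimum(result: RDFResult, smooth_window: int = 1) -> float:
    """First local minimum of the (moving-average smoothed) g(r) after the
    first interior maximum; ties break toward smaller r."""
    g = result.g
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")
    i_max = None
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1]:
            i_max = i
            break
    if i_max is None:
        raise NoMinimumError("g(r) has no interior maximum; supply an explicit cutoff")
    for i in range(i_max + 1, len(g) - 1):
        if g[i] < g[i - 1] and g[i] <= g[i + 1]:
            return float(result.r[i])
    raise NoMinimumError(
        "g(r) has no interior minimum after its first maximum; supply an explicit cutoff"
    )


# --------------------------------------------------------------------------
# per-residue maps


@dataclass
class ResidueMap:
    """residue x xi matrix of (normalized) coordination/contact values."""

    values: pd.DataFrame  # index: residue 1..n, columns: xi
    norm_constants: pd.Series | None = None  # per-residue normalization
    raw: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g")


def _reference_sites(topology: Topology, chain_id: str) -> dict[int, int | None]:
    """Residue -> atom index of the map reference site (CB, CA for glycine)."""
    sites: dict[int, int | None] = {}
    for rid in topology.residues(chain_id):
        cb = topology.select(role=Role.SC_CB, chain_id=chain_id, residue_index=rid)
        if cb.size:
            sites[rid] = int(cb[0])
            continue
        ca = topology.select(role=Role.BB_CA, chain_id=chain_id, residue_index=rid)
        sites[rid] = int(ca[0]) if ca.size else None
    return sites


def _two_peptide_chains(topology: Topology) -> tuple[str, str]:
    chains = topology.peptide_chain_ids()
    if len(chains) != 2:
        raise ChainCountError(f"need exactly two peptide chains, found {chains}")
    return chains[0], chains[1]


def _solvent_selection(topology: Topology, solvent: str) -> np.ndarray:
    """Water is counted by its oxygen; urea by one designated carbon per
    molecule (so molecules, not atoms, are counted)."""
    if solvent == "water":
        return topology.select(role=Role.WATER_O)
    if solvent == "urea":
        idx = topology.select(role=Role.UREA)
        return np.array(
            [i for i in idx if str(topology.names[i]).upper().startswith("C")],
            dtype=int,
        )
    raise ValueError(f"unknown solvent {solvent!r}")


def coordination_map(
    topology: Topology,
    frames_by_xi: Mapping[float, FrameSet],
    solvent: str,
    shell_radii: Mapping[int, float] | float = DEFAULT_SHELL_RADIUS,
) -> pd.DataFrame:
    """Raw per-residue, per-xi solvent coordination numbers, averaged over
    the two chains and over frames. Residues without a reference site are
    reported as NaN."""
    chain_a, chain_b = _two_peptide_chains(topology)
    sites_a = _reference_sites(topology, chain_a)
    sites_b = _reference_sites(topology, chain_b)
    residues = sorted(sites_a)
    solv = _solvent_selection(topology, solvent)
    out = {}
    for xi in sorted(frames_by_xi):
        col = []
        for rid in residues:
            radius = (
                shell_radii.get(rid, DEFAULT_SHELL_RADIUS)
                if isinstance(shell_radii, Mapping)
                else float(shell_radii)
            )
            acc: list[float] = []
            for frame, box in frames_by_xi[xi]:
                for site in (sites_a.get(rid), sites_b.get(rid)):
                    if site is None:
                        continue
                    if solv.size == 0:
                        acc.append(0.0)
                        continue
                    d2 = pair_sq_distances(frame[[site]], frame[solv], box)[0]
                    acc.append(float(np.count_nonzero(d2 <= radius * radius)))
            col.append(np.mean(acc) if acc else np.nan)
        out[xi] = col
    df = pd.DataFrame(out, index=pd.Index(residues, name="residue"))
    df.columns.name = "xi"
    return df


def hydration_map(
    topology: Topology,
    frames_by_xi: Mapping[float, FrameSet],
    solvent: str = "water",
    normalize_by: str = "water_max",
    shell_radii: Mapping[int, float] | float = DEFAULT_SHELL_RADIUS,
    water_reference: pd.DataFrame | None = None,
) -> ResidueMap:
    """Normalized solvation map CN_i^norm(xi).

    ``normalize_by='water_max'`` divides each residue's row by that residue's
    maximum *water* coordination number (the convention for hydration maps in
    both solvents); ``'own_max'`` divides by the row's own maximum (the
    convention for urea solvation maps). ``water_reference`` supplies the raw
    water map when normalizing a non-water species by water_max.
    """
    raw = coordination_map(topology, frames_by_xi, solvent, shell_radii)
    if normalize_by == "own_max":
        norm = raw.max(axis=1)
    elif normalize_by == "water_max":
        if solvent == "water":
            ref = raw
        elif water_reference is not None:
            ref = water_reference
        else:
            ref = coordination_map(topology, frames_by_xi, "water", shell_radii)
        norm = ref.max(axis=1)
    else:
        raise ValueError("normalize_by must be 'water_max' or 'own_max'")
    safe = norm.replace(0.0, np.nan)
    values = raw.div(safe, axis=0)
    return ResidueMap(values=values, norm_constants=norm, raw=raw)


def on_neighbor_map(
    topology: Topology,
    frames_by_xi: Mapping[float, FrameSet],
    cutoff: float = 0.35,
) -> ResidueMap:
    """Interpeptide backbone carbonyl-amino (O-N) neighbor counts per residue
    and xi. A pair at exactly the cutoff counts (r <= cutoff, the 3.5 A
    rule). Counts both O(A)-N(B) and N(A)-O(B) pairs and averages the same
    residue over the two chains."""
    chain_a, chain_b = _two_peptide_chains(topology)
    residues = sorted(set(topology.residues(chain_a)) | set(topology.residues(chain_b)))
    sel = {
        (cid, role): topology.select(role=role, chain_id=cid)
        for cid in (chain_a, chain_b)
        for role in (Role.BB_O, Role.BB_N)
    }
    cut2 = cutoff * cutoff
    out = {}
    for xi in sorted(frames_by_xi):
        per_res = {rid: 0.0 for rid in residues}
        n_frames = len(frames_by_xi[xi])
        for frame, box in frames_by_xi[xi]:
            for (c1, r1), (c2, r2) in (
                ((chain_a, Role.BB_O), (chain_b, Role.BB_N)),
                ((chain_a, Role.BB_N), (chain_b, Role.BB_O)),
            ):
                ia, ib = sel[(c1, r1)], sel[(c2, r2)]
                if not (ia.size and ib.size):
                    continue
                d2 = pair_sq_distances(frame[ia], frame[ib], box)
                hits = np.argwhere(d2 <= cut2)
                for k, m in hits:
                    per_res[int(topology.resids[ia[k]])] += 1.0
                    per_res[int(topology.resids[ib[m]])] += 1.0
        # each contact was attributed to one residue on each chain; averaging
        # over the two chains divides by 2, and by the number of frames
        out[xi] = [per_res[rid] / (2.0 * n_frames) for rid in residues]
    df = pd.DataFrame(out, index=pd.Index(residues, name="residue"))
    df.columns.name = "xi"
    return ResidueMap(values=df)


# --------------------------------------------------------------------------
# nonbonded energy profiles


def nonbonded_energy_profile(
    topology: Topology,
    frames_by_xi: Mapping[float, FrameSet],
    charges: np.ndarray,
    lj_sigma: np.ndarray,
    lj_epsilon: np.ndarray,
    scope: str = "interchain",
) -> pd.Series:
    """Mean LJ + Coulomb energy (kJ/mol) vs xi over peptide-atom pairs.

    U = sum over pairs 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6]
        + f_elec q_i q_j / r,
    with Lorentz-Berthelot combining, minimum image, no cutoff (toy systems).
    ``scope`` selects interchain pairs or the intrachain pairs of both chains.
    """
    charges = np.asarray(charges, dtype=float)
    lj_sigma = np.asarray(lj_sigma, dtype=float)
    lj_epsilon = np.asarray(lj_epsilon, dtype=float)
    chain_a, chain_b = _two_peptide_chains(topology)
    ia = topology.select(chain_id=chain_a)
    ib = topology.select(chain_id=chain_b)
    scope_atoms = np.concatenate([ia, ib])
    for arr, what in ((charges, "charges"), (lj_sigma, "sigma"), (lj_epsilon, "epsilon")):
        if arr.shape[0] != len(topology):
            raise ParameterizationError(f"{what} must have one value per atom")
        bad = scope_atoms[~np.isfinite(arr[scope_atoms])]
        if bad.size:
            names = [f"{topology.chain_ids[i]}:{topology.names[i]}" for i in bad[:8]]
            raise ParameterizationError(f"missing {what} for atoms {names}")
    if scope == "interchain":
        pairs = [(ia, ib)]
    elif scope == "intrachain":
        pairs = [(ia, ia), (ib, ib)]
    else:
        raise ValueError("scope must be 'interchain' or 'intrachain'")

    def pair_energy(frame, box, idx1, idx2) -> float:
        d2 = pair_sq_distances(frame[idx1], frame[idx2], box)
        same = idx1 is idx2
        if same:
            iu, ju = np.triu_indices(len(idx1), k=1)
            r = np.sqrt(d2[iu, ju])
            qi, qj = charges[idx1][iu], charges[idx2][ju]
            si = 0.5 * (lj_sigma[idx1][iu] + lj_sigma[idx2][ju])
            ei = np.sqrt(lj_epsilon[idx1][iu] * lj_epsilon[idx2][ju])
        else:
            r = np.sqrt(d2.ravel())
            qi = np.repeat(charges[idx1], len(idx2))
            qj = np.tile(charges[idx2], len(idx1))
            si = 0.5 * (
                np.repeat(lj_sigma[idx1], len(idx2)) + np.tile(lj_sigma[idx2], len(idx1))
            )
            ei = np.sqrt(
                np.repeat(lj_epsilon[idx1], len(idx2))
                * np.tile(lj_epsilon[idx2], len(idx1))
            )
        sr6 = (si / r) ** 6
        lj = 4.0 * ei * (sr6**2 - sr6)
        coul = F_ELEC * qi * qj / r
        return float(np.sum(lj + coul))

    out = {}
    for xi in sorted(frames_by_xi):
        vals = [
            sum(pair_energy(frame, box, i1, i2) for i1, i2 in pairs)
            for frame, box in frames_by_xi[xi]
        ]
        out[xi] = float(np.mean(vals))
    s = pd.Series(out).sort_index()
    s.index.name = "xi"
    return s
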