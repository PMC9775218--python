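"""Radius of gyration and DSSP-lite secondary structure.

The classifier implements the Kabsch-Sander electrostatic hydrogen-bond
energy

    E = 27.888 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,  r in Angstrom,

with the -0.5 kcal/mol (-2.09 kJ/mol) acceptance threshold, and assigns the
classes E (beta sheet/bridge, isolated bridges folded into E), G (3-10
helix), H (alpha helix), T (turn) and C (coil) from the bond patterns.
Precedence when patterns overlap: H > G > E > T > C. Pi-helices and bends
are omitted; proline cannot donate (no amide H present in the topology).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, SelectionError
from .geometry import center_of_mass, minimum_image
from .topology import Role, Topology, Trajectory, require_nonempty
from .units import HB_ENERGY_THRESHOLD_KCAL, KS_PREFACTOR, NM_TO_ANGSTROM

SS_CLASSES = ("E", "G", "H", "T", "C")


# --------------------------------------------------------------------------
# radius of gyration


def radius_of_gyration(
    topology: Topology,
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame Rg (nm): sqrt(sum m_i |r_i - r_COM|^2 / sum m_i).

    The selection is assumed whole (not wrapped across the boundary).
    """
    if selection is None:
        selection = np.arange(len(topology))
    selection = require_nonempty(np.asarray(selection), "Rg selection")
    masses = topology.masses[selection] if mass_weighted else np.ones(len(selection))
    out = np.empty(len(trajectory))
    for k, (frame, _box) in enumerate(trajectory):
        pos = frame[selection]
        com = center_of_mass(pos, masses)
        d2 = np.sum((pos - com) ** 2, axis=1)
        out[k] = np.sqrt(np.sum(masses * d2) / masses.sum())
    return out


def rg_distribution(
    series: np.ndarray, bin_width: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram of an Rg series (integrates to 1).

    Returns (bin centers, density)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise SelectionError("empty Rg series")
    lo = np.floor(series.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((series.max() - lo) / bin_width + 1e-12)))
    if series.max() >= lo + n_bins * bin_width:
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(series, bins=edges)
    density = counts / (counts.sum() * bin_width)
    return 0.5 * (edges[:-1] + edges[1:]), density


# --------------------------------------------------------------------------
# Kabsch-Sander hydrogen bonds


def kabsch_sander_energy(
    c: np.ndarray, o: np.ndarray, n: np.ndarray, h: np.ndarray
) -> float:
    """H-bond energy (kcal/mol) of acceptor C=O with donor N-H, positions
    in nm."""
    pts = np.asarray([c, o, n, h], dtype=float) * NM_TO_ANGSTROM
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite atom position")
    iu, ju = np.triu_indices(4, k=1)
    if np.min(np.linalg.norm(pts[iu] - pts[ju], axis=1)) <= 0.1:  # 0.01 nm
        raise GeometryError("near-coincident atoms in H-bond geometry")
    r_on = np.linalg.norm(pts[1] - pts[2])
    r_ch = np.linalg.norm(pts[0] - pts[3])
    r_oh = np.linalg.norm(pts[1] - pts[3])
    r_cn = np.linalg.norm(pts[0] - pts[2])
    return float(KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


@dataclass(frozen=True)
class HBond:
    """Backbone N-H...O=C bond: donor/acceptor are global residue indices
    into the classifier's (chain, residue) table."""

    donor: int
    acceptor: int
    energy: float


@dataclass
class _ResidueTable:
    keys: list[tuple[str, int]]  # (chain_id, residue_index) in atom order
    coords: dict[Role, list[np.ndarray | None]]

    @classmethod
    def build(cls, topology: Topology, frame: np.ndarray) -> "_ResidueTable":
        keys: list[tuple[str, int]] = []
        index: dict[tuple[str, int], int] = {}
        bb_roles = (Role.BB_N, Role.BB_H, Role.BB_CA, Role.BB_C, Role.BB_O)
        coords: dict[Role, list[np.ndarray | None]] = {r: [] for r in bb_roles}
        for i, a in enumerate(topology.atoms):
            if a.role not in bb_roles:
                continue
            key = (a.chain_id, a.residue_index)
            if key not in index:
                index[key] = len(keys)
                keys.append(key)
                for r in bb_roles:
                    coords[r].append(None)
            coords[a.role][index[key]] = frame[i]
        return cls(keys=keys, coords=coords)

    def same_chain_offset(self, i: int, j: int) -> int | None:
        ci, ri = self.keys[i]
        cj, rj = self.keys[j]
        return (rj - ri) if ci == cj else None


def find_hbonds(
    topology: Topology,
    frame: np.ndarray,
    threshold: float = HB_ENERGY_THRESHOLD_KCAL,
) -> tuple[list[HBond], list[tuple[str, int]]]:
    """All backbone N-H...O=C bonds with E < threshold (kcal/mol), intra- and
    interchain. Residues lacking an amide H (e.g. proline) cannot donate.

    Returns (bonds, residue keys) where bonds index into the key list.
    """
    table = _ResidueTable.build(topology, frame)
    keys = table.keys
    n_res = len(keys)
    bonds: list[HBond] = []
    for d in range(n_res):
        nd = table.coords[Role.BB_N][d]
        hd = table.coords[Role.BB_H][d]
        if nd is None or hd is None:
            continue
        for a in range(n_res):
            if a == d:
                continue
            off = table.same_chain_offset(a, d)
            if off is not None and abs(off) < 1:
                continue
            ca = table.coords[Role.BB_C][a]
            oa = table.coords[Role.BB_O][a]
            if ca is None or oa is None:
                continue
            if np.linalg.norm(oa - nd) > 0.70:  # beyond any bonding distance
                continue
            e = kabsch_sander_energy(ca, oa, nd, hd)
            if e < threshold:
                bonds.append(HBond(donor=d, acceptor=a, energy=e))
    return bonds, keys


def assign_secondary_structure(
    topology: Topology,
    frame: np.ndarray,
    threshold: float = HB_ENERGY_THRESHOLD_KCAL,
) -> pd.Series:
    """One-letter class per residue (index: (chain, residue)) for one frame."""
    bonds, keys = find_hbonds(topology, frame, threshold)
    n_res = len(keys)
    chain_of = [k[0] for k in keys]
    resid_of = [k[1] for k in keys]

    def same_chain(i: int, j: int) -> bool:
        return chain_of[i] == chain_of[j]

    hb = {(b.donor, b.acceptor) for b in bonds}

    def hbond(donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in hb

    # n-turns: acceptor i, donor i+n within one chain
    turns = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            j = i + n
            if same_chain(i, j) and resid_of[j] - resid_of[i] == n and hbond(j, i):
                turns[n][i] = True

    cls = np.array(["C"] * n_res, dtype=object)

    def set_class(idx: int, letter: str) -> None:
        order = {c: k for k, c in enumerate(("H", "G", "E", "T", "C"))}
        if order[letter] < order[cls[idx]]:
            cls[idx] = letter

    # turns (T) between the bonded residues
    for n in (3, 4, 5):
        for i in np.flatnonzero(turns[n]):
            for k in range(i + 1, i + n):
                set_class(k, "T")

    # bridges -> E; same-chain bridges require |i-j| > 2
    for i in range(n_res):
        for j in range(n_res):
            if i == j:
                continue
            if same_chain(i, j) and abs(resid_of[i] - resid_of[j]) <= 2:
                continue

            def nb(k: int, d: int) -> int | None:
                m = k + d
                if 0 <= m < n_res and same_chain(k, m):
                    return m
                return None

            im, ip = nb(i, -1), nb(i, 1)
            jm, jp = nb(j, -1), nb(j, 1)
            parallel = (
                im is not None and ip is not None and hbond(im, j) and hbond(j, ip)
            ) or (
                jm is not None and jp is not None and hbond(jm, i) and hbond(i, jp)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                im is not None
                and jp is not None
                and ip is not None
                and jm is not None
                and hbond(im, jp)
                and hbond(jm, ip)
            )
            if parallel or anti:
                set_class(i, "E")
                set_class(j, "E")

    # helices: two consecutive n-turns
    for i in range(n_res - 1):
        if turns[3][i] and turns[3][i + 1]:
            for k in range(i + 1, i + 4):
                set_class(k, "G")
        if turns[4][i] and turns[4][i + 1]:
            for k in range(i + 1, i + 5):
                set_class(k, "H")

    return pd.Series(cls, index=pd.MultiIndex.from_tuples(keys, names=["chain", "resid"]))


def ss_fraction_profile(
    topology: Topology,
    frames_by_xi: Mapping[float, Sequence[np.ndarray]],
    threshold: float = HB_ENERGY_THRESHOLD_KCAL,
) -> pd.DataFrame:
    """Per-class fractions vs COM separation, pooling residues x frames at
    each xi. Rows sum to 1."""
    rows = {}
    for xi in sorted(frames_by_xi):
        counts = dict.fromkeys(SS_CLASSES, 0)
        total = 0
        for frame in frames_by_xi[xi]:
            ss = assign_secondary_structure(topology, frame, threshold)
            for letter in ss:
                counts[letter] += 1
                total += 1
        rows[xi] = {c: counts[c] / total for c in SS_CLASSES}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "xi"
    return df
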