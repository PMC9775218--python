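"""Structure, trajectory and umbrella-window file I/O.

PDB and GRO go through MDAnalysis; extended-XYZ (with a ``Lattice=`` box
record in the comment line) is a small self-contained dialect written and
parsed here, with coordinates in nm. Window series are two-column plain
text (time, xi/nm) with ``# key = value`` header metadata, matching common
pull-output layouts.

Chain handling: PDB carries chain IDs natively; GRO has no chain field, so
on reading chains are inferred from residue-index resets (each reset starts
a new chain labelled A, B, C, ...).
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from .errors import ConfigError, ParseError, StructuralError, UnsupportedFeatureError
from .topology import Role, Topology, Trajectory
from .umbrella import UmbrellaWindow
from .units import DEFAULT_TEMPERATURE

_CHAIN_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"pdb", "gro"}:
        return suffix
    if suffix in {"xyz", "extxyz"}:
        return "extxyz"
    raise ParseError(f"cannot infer format from {path!r}; pass format=")


def _check_box(dimensions, path) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise StructuralError(f"{path}: no periodic box record (CRYST1/box line)")
    dims = np.asarray(dimensions, dtype=float)
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise UnsupportedFeatureError(
            f"{path}: triclinic boxes are unsupported (angles {dims[3:]})"
        )
    return dims[:3] / 10.0  # Angstrom -> nm


def _chains_from_resid_resets(resids) -> list[str]:
    chains, k = [], 0
    prev = None
    for rid in resids:
        if prev is not None and rid < prev:
            k += 1
        chains.append(_CHAIN_LABELS[k % len(_CHAIN_LABELS)])
        prev = rid
    return chains


def read_structure(
    path: str | Path, fmt: str | None = None
) -> tuple[Topology, Trajectory]:
    """Read a structure/trajectory file into (Topology, Trajectory).

    Roles are inferred from atom/residue names; coordinates come back in nm
    (PDB/GRO Angstrom values are divided by 10).
    """
    fmt = _infer_format(path, fmt)
    if fmt == "extxyz":
        return _read_extxyz(path)
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (ValueError, OSError, EOFError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    resids = [int(r) for r in atoms.resids]
    resnames = [str(r) for r in atoms.resnames]
    if hasattr(atoms, "chainIDs") and any(str(c).strip() for c in atoms.chainIDs):
        chains = [str(c).strip() or "A" for c in atoms.chainIDs]
    else:
        chains = _chains_from_resid_resets(resids)
    top = Topology.from_atoms(names, resids, resnames, chains)
    frames, boxes = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.positions.shape[0] != len(top):
                raise StructuralError(
                    f"{path}: atom count changes across frames"
                )
            frames.append(ts.positions.astype(float) / 10.0)
            boxes.append(_check_box(ts.dimensions, path))
    traj = Trajectory(frames=frames, boxes=boxes)
    traj.check_against(top)
    return top, traj


def write_structure(
    path: str | Path,
    topology: Topology,
    trajectory: Trajectory,
    fmt: str | None = None,
) -> None:
    """Write a topology + trajectory as PDB, GRO or extended-XYZ.

    Solvent (water/urea) atoms are emitted as HETATM records in PDB.
    """
    fmt = _infer_format(path, fmt)
    trajectory.check_against(topology)
    if fmt == "extxyz":
        _write_extxyz(path, topology, trajectory)
        return
    import MDAnalysis as mda

    n = len(topology)
    # group consecutive atoms into residues
    res_keys: list[tuple[str, int, str]] = []
    atom_resindex = np.empty(n, dtype=int)
    for i, a in enumerate(topology.atoms):
        key = (a.chain_id, a.residue_index, a.residue_name)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    seg_keys = list(dict.fromkeys(k[0] for k in res_keys))
    residue_segindex = np.array([seg_keys.index(k[0]) for k in res_keys])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(res_keys),
            n_segments=len(seg_keys),
            atom_resindex=atom_resindex,
            residue_segindex=residue_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
        u.add_TopologyAttr("masses", topology.masses)
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("chainIDs", [a.chain_id[:1] for a in topology.atoms])
        u.add_TopologyAttr("segids", seg_keys)
        solvent = {Role.WATER_O, Role.WATER_H, Role.UREA}
        u.add_TopologyAttr(
            "record_types",
            ["HETATM" if a.role in solvent else "ATOM" for a in topology.atoms],
        )
        if len(trajectory) == 1 or fmt == "gro":
            u.atoms.positions = trajectory.frames[0] * 10.0
            u.dimensions = np.concatenate([trajectory.boxes[0] * 10.0, [90, 90, 90]])
            u.atoms.write(str(path))
        else:
            with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
                for frame, box in trajectory:
                    u.atoms.positions = frame * 10.0
                    u.dimensions = np.concatenate([box * 10.0, [90, 90, 90]])
                    w.write(u.atoms)


# --------------------------------------------------------------------------
# extended-XYZ (own dialect, nm)

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _write_extxyz(path, topology: Topology, trajectory: Trajectory) -> None:
    lines: list[str] = []
    for frame, box in trajectory:
        lines.append(str(len(topology)))
        lat = f"{box[0]:.6f} 0 0 0 {box[1]:.6f} 0 0 0 {box[2]:.6f}"
        lines.append(
            f'Lattice="{lat}" '
            "Properties=species:S:1:pos:R:3:name:S:1:resid:I:1:resname:S:1:chain:S:1 "
            "units=nm"
        )
        for a, (x, y, z) in zip(topology.atoms, frame):
            lines.append(
                f"{a.element} {x:.6f} {y:.6f} {z:.6f} "
                f"{a.name} {a.residue_index} {a.residue_name} {a.chain_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_extxyz(path) -> tuple[Topology, Trajectory]:
    raw = Path(path).read_text().splitlines()
    i = 0
    frames, boxes = [], []
    names: list[str] | None = None
    resids: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n = int(raw[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        if i + 1 >= len(raw):
            raise ParseError(f"{path}:{i + 2}: missing comment line")
        m = _LATTICE_RE.search(raw[i + 1])
        if not m:
            raise ParseError(f"{path}:{i + 2}: no Lattice= record")
        lat = np.array([float(v) for v in m.group(1).split()]).reshape(3, 3)
        if not np.allclose(lat - np.diag(np.diag(lat)), 0.0):
            raise UnsupportedFeatureError(f"{path}:{i + 2}: triclinic box unsupported")
        box = np.diag(lat)
        frame = np.empty((n, 3))
        frame_names, frame_resids, frame_resnames, frame_chains = [], [], [], []
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(raw):
                raise ParseError(f"{path}:{ln + 1}: truncated frame")
            parts = raw[ln].split()
            if len(parts) < 8:
                raise ParseError(f"{path}:{ln + 1}: expected 8 columns, got {len(parts)}")
            try:
                frame[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
                frame_resids.append(int(parts[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{ln + 1}: {exc}") from exc
            frame_names.append(parts[4])
            frame_resnames.append(parts[6])
            frame_chains.append(parts[7])
        if names is None:
            names, resids = frame_names, frame_resids
            resnames, chains = frame_resnames, frame_chains
        elif frame_names != names:
            raise StructuralError(f"{path}: atom identities change across frames")
        frames.append(frame)
        boxes.append(box)
        i += 2 + n
    if names is None:
        raise ParseError(f"{path}: empty file")
    top = Topology.from_atoms(names, resids, resnames, chains)
    return top, Trajectory(frames=frames, boxes=boxes)


# --------------------------------------------------------------------------
# umbrella-window series

_HEADER_RE = re.compile(
    r"^[#@]\s*(center|k|temperature)\s*=\s*([-+0-9.eE]+)", re.IGNORECASE
)


def read_window_series(path: str | Path) -> UmbrellaWindow:
    """Read one umbrella window: ``# center/k[/temperature] = value`` header
    plus two numeric columns (time, xi in nm). Comment lines start with
    ``#`` or ``@``."""
    meta: dict[str, float] = {}
    samples: list[float] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(("#", "@")):
            m = _HEADER_RE.match(s)
            if m:
                meta[m.group(1).lower()] = float(m.group(2))
            continue
        parts = s.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected two columns")
        try:
            samples.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
    for key in ("center", "k"):
        if key not in meta:
            raise ConfigError(f"{path}: header metadata '{key}' missing")
    if not samples:
        raise ParseError(f"{path}: no data rows")
    return UmbrellaWindow(
        center=meta["center"],
        spring_k=meta["k"],
        samples=np.asarray(samples),
        temperature=meta.get("temperature", DEFAULT_TEMPERATURE),
    )


def write_window_series(path: str | Path, window: UmbrellaWindow) -> None:
    lines = [
        f"# center = {window.center:.6g}",
        f"# k = {window.spring_k:.6g}",
        f"# temperature = {window.temperature:.6g}",
        "# time(ps) xi(nm)",
    ]
    for t, x in enumerate(window.samples):
        lines.append(f"{float(t):.1f} {x:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")
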