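"""Role-labelled topology and trajectory containers.

Atoms carry a *role* describing what they are for the analyses: backbone
N/H/CA/C/O, side-chain CB, generic side-chain atom, water oxygen/hydrogen or
urea atom. Roles are inferred from (atom name, residue name) by a fixed
mapping table, so inference is a pure function of those two strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

from .errors import SelectionError, StructuralError

logger = logging.getLogger(__name__)


class Role(str, Enum):
    BB_N = "bb_N"
    BB_H = "bb_H"
    BB_CA = "bb_CA"
    BB_C = "bb_C"
    BB_O = "bb_O"
    SC_CB = "sc_CB"
    SC_OTHER = "sc_other"
    WATER_O = "water_O"
    WATER_H = "water_H"
    UREA = "urea_atom"


WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP4", "SPC", "H2O"}
UREA_RESNAMES = {"URE", "URA", "UREA"}

#: peptide atom-name -> role mapping (applied when the residue is not solvent)
_PEPTIDE_ROLE_TABLE = {
    "N": Role.BB_N,
    "H": Role.BB_H,
    "HN": Role.BB_H,
    "CA": Role.BB_CA,
    "C": Role.BB_C,
    "O": Role.BB_O,
    "CB": Role.SC_CB,
}

#: simple per-element masses, u
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "S": "SER", "I": "ILE", "T": "THR",
    "F": "PHE", "V": "VAL", "L": "LEU", "P": "PRO", "C": "CYS",
    "M": "MET", "N": "ASN", "Q": "GLN", "D": "ASP", "E": "GLU",
    "K": "LYS", "R": "ARG", "H": "HIS", "W": "TRP", "Y": "TYR",
}


def infer_element(atom_name: str) -> str:
    """First alphabetic character of the stripped atom name, upper-cased."""
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def infer_role(atom_name: str, residue_name: str) -> Role:
    """Pure mapping (atom name, residue name) -> Role.

    Unknown peptide atoms map to ``sc_other``; a warning is logged by
    :func:`Topology.from_atoms` the first time such a name is seen.
    """
    an = atom_name.strip().upper()
    rn = residue_name.strip().upper()
    if rn in WATER_RESNAMES:
        return Role.WATER_O if an.startswith("O") else Role.WATER_H
    if rn in UREA_RESNAMES:
        return Role.UREA
    return _PEPTIDE_ROLE_TABLE.get(an, Role.SC_OTHER)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    role: Role
    residue_index: int  # 1-based within its chain
    residue_name: str
    chain_id: str

    @property
    def mass(self) -> float:
        return ELEMENT_MASSES.get(self.element, 12.011)


@dataclass
class Topology:
    """Ordered list of role-labelled atoms with vectorised column views."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        self.names = np.array([a.name for a in self.atoms], dtype=object)
        # role column stores plain string values so numpy comparisons work
        self.roles = np.array([a.role.value for a in self.atoms], dtype=object)
        self.resids = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.resnames = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.chain_ids = np.array([a.chain_id for a in self.atoms], dtype=object)
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        # residue indices must be non-decreasing within each chain
        for cid in dict.fromkeys(self.chain_ids):
            r = self.resids[self.chain_ids == cid]
            if np.any(np.diff(r) < 0):
                raise StructuralError(
                    f"residue indices decrease within chain {cid!r}"
                )
        # every bb_O needs a bb_C in the same residue
        for cid, rid in {
            (a.chain_id, a.residue_index) for a in self.atoms if a.role == Role.BB_O
        }:
            sel = (self.chain_ids == cid) & (self.resids == rid)
            if Role.BB_C.value not in set(self.roles[sel]):
                raise StructuralError(
                    f"residue {rid} of chain {cid!r} has a bb_O but no bb_C"
                )
        unknown = {
            a.name
            for a in self.atoms
            if a.role == Role.SC_OTHER and a.residue_name.upper() not in WATER_RESNAMES
        }
        if unknown:
            logger.warning("atoms mapped to role sc_other: %s", sorted(unknown))
        self._n = n

    @classmethod
    def from_atoms(
        cls,
        names: Sequence[str],
        resids: Sequence[int],
        resnames: Sequence[str],
        chain_ids: Sequence[str],
    ) -> "Topology":
        atoms = [
            Atom(
                name=str(nm),
                element=infer_element(str(nm)),
                role=infer_role(str(nm), str(rn)),
                residue_index=int(ri),
                residue_name=str(rn),
                chain_id=str(ci),
            )
            for nm, ri, rn, ci in zip(names, resids, resnames, chain_ids, strict=True)
        ]
        return cls(atoms)

    def __len__(self) -> int:
        return self._n

    def select(
        self,
        role: Role | Sequence[Role] | None = None,
        chain_id: str | None = None,
        residue_index: int | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given filters."""
        mask = np.ones(self._n, dtype=bool)
        if role is not None:
            roles = [role] if isinstance(role, Role) else list(role)
            mask &= np.isin(self.roles, [r.value for r in roles])
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if residue_index is not None:
            mask &= self.resids == residue_index
        return np.flatnonzero(mask)

    def peptide_chain_ids(self) -> list[str]:
        """Chains that carry backbone roles, in order of first appearance."""
        bb = {Role.BB_N, Role.BB_CA, Role.BB_C, Role.BB_O}
        out: list[str] = []
        for a in self.atoms:
            if a.role in bb and a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str) -> list[int]:
        """Sorted residue indices of one chain."""
        return sorted(set(self.resids[self.chain_ids == chain_id].tolist()))


@dataclass
class Trajectory:
    """Ordered frames of coordinates (nm) with orthorhombic box lengths (nm)."""

    frames: list[np.ndarray] = field(default_factory=list)
    boxes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        self.boxes = [np.asarray(b, dtype=float) for b in self.boxes]
        if len(self.frames) != len(self.boxes):
            raise StructuralError("frames and boxes differ in length")
        for f, b in zip(self.frames, self.boxes):
            if f.ndim != 2 or f.shape[1] != 3:
                raise StructuralError("each frame must be an (n, 3) array")
            if b.shape != (3,) or np.any(b <= 0):
                raise StructuralError("box lengths must be three positive values")
        n0 = {f.shape[0] for f in self.frames}
        if len(n0) > 1:
            raise StructuralError(f"atom count varies across frames: {sorted(n0)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        return iter(zip(self.frames, self.boxes))

    def check_against(self, topology: Topology) -> None:
        for f in self.frames:
            if f.shape[0] != len(topology):
                raise StructuralError(
                    f"frame has {f.shape[0]} atoms, topology has {len(topology)}"
                )


def require_nonempty(indices: np.ndarray, what: str) -> np.ndarray:
    if len(indices) == 0:
        raise SelectionError(f"empty selection: {what}")
    return indices
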