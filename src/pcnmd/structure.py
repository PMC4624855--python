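"""Typed in-memory model of structures, trajectories and atom selections.

A :class:`Structure` is an ordered list of atoms with chain/residue identity
and Å coordinates; an :class:`Ensemble` couples a reference structure with a
stack of coordinate frames and picosecond timestamps.  Residue identity is
the file's own ``(chain, res_seq, i_code)`` key — author numbering is never
rewritten; a sequential 0-based node index is derived on demand for network
work.  HETATM records are kept on the atom list but excluded from residue
accounting, which covers protein residues only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    SelectionEmptyError,
    SelectionSyntaxError,
)

ResidueKey = tuple[str, int, str]  # (chain, res_seq, i_code)


@dataclass
class AtomRecord:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    alt_loc: str
    chain: str
    res_seq: int
    i_code: str
    res_name: str
    coords: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetero: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.res_seq, self.i_code)


@dataclass
class Residue:
    chain: str
    res_seq: int
    i_code: str
    res_name: str
    atom_indices: list[int] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.res_seq, self.i_code)


class Structure:
    """Ordered atoms plus residue/chain bookkeeping derived from them."""

    def __init__(self, atoms: list[AtomRecord]):
        self.atoms = list(atoms)
        self._residues: list[Residue] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(A, 3) float array of Å coordinates, in atom order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure carrying replacement coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({len(self.atoms)}, 3)"
            )
        atoms = []
        for a, xyz in zip(self.atoms, coords):
            atoms.append(
                AtomRecord(
                    a.serial, a.name, a.element, a.alt_loc, a.chain,
                    a.res_seq, a.i_code, a.res_name, np.array(xyz),
                    a.occupancy, a.b_factor, a.hetero,
                )
            )
        return Structure(atoms)

    @property
    def residues(self) -> list[Residue]:
        """Protein residues (non-HETATM), in order of first appearance."""
        if self._residues is None:
            seen: dict[ResidueKey, Residue] = {}
            ordered: list[Residue] = []
            for i, a in enumerate(self.atoms):
                if a.hetero:
                    continue
                key = a.residue_key
                if key not in seen:
                    res = Residue(a.chain, a.res_seq, a.i_code, a.res_name)
                    seen[key] = res
                    ordered.append(res)
                seen[key].atom_indices.append(i)
            self._residues = ordered
        return self._residues

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance (protein atoms)."""
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def ca_index(self, residue: Residue) -> int | None:
        """Atom index of the residue's α-carbon, or None."""
        for i in residue.atom_indices:
            if self.atoms[i].name == "CA":
                return i
        return None


@dataclass
class Ensemble:
    """A reference structure plus F coordinate frames with ps timestamps."""

    reference: Structure
    frames: np.ndarray  # (F, A, 3) Å
    times: np.ndarray  # (F,) ps, strictly increasing

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[1] != len(self.reference):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != reference "
                f"atom count {len(self.reference)}"
            )
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("times length must equal number of frames")
        if self.n_frames >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        return self.reference.with_coords(self.frames[i])

    def subset(self, indices: np.ndarray) -> "Ensemble":
        """Restrict the ensemble to the given atom indices."""
        idx = np.asarray(indices, dtype=int)
        ref = Structure([self.reference.atoms[i] for i in idx])
        return Ensemble(ref, self.frames[:, idx, :], self.times.copy())


@dataclass
class Selection:
    """A resolved atom selection: expression plus sorted unique indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def empty(self) -> bool:
        return len(self.indices) == 0


_RESID_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _clause_mask(structure: Structure, clause: str) -> np.ndarray:
    parts = clause.split(None, 1)
    if len(parts) != 2:
        raise SelectionSyntaxError(f"cannot parse clause {clause!r}")
    keyword, arg = parts[0].lower(), parts[1].strip()
    n = len(structure.atoms)
    mask = np.zeros(n, dtype=bool)
    if keyword == "chain":
        wanted = {c.strip() for c in arg.split(",") if c.strip()}
        if not wanted:
            raise SelectionSyntaxError("chain clause lists no chains")
        for i, a in enumerate(structure.atoms):
            mask[i] = a.chain in wanted
    elif keyword == "resid":
        m = _RESID_RE.match(arg)
        if not m:
            raise SelectionSyntaxError(f"bad resid range {arg!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionSyntaxError(f"resid range {arg!r} is reversed")
        for i, a in enumerate(structure.atoms):
            mask[i] = lo <= a.res_seq <= hi
    elif keyword == "name":
        wanted = {w.strip() for w in arg.split(",") if w.strip()}
        if not wanted:
            raise SelectionSyntaxError("name clause lists no atom names")
        for i, a in enumerate(structure.atoms):
            mask[i] = a.name in wanted
    else:
        raise SelectionSyntaxError(f"unknown selection keyword {keyword!r}")
    return mask


def select(structure: Structure, expression: str) -> Selection:
    """Resolve a selection expression against a structure.

    Grammar: ``chain <id>[,<id>...]``, ``resid <a>[-<b>]``, ``name <atom>``,
    clauses joined with ``and``.  The result is deterministic: indices are
    unique and sorted in atom order.  An empty result is legal but carries
    ``empty=True`` so callers can flag it.
    """
    expr = expression.strip()
    if not expr:
        raise SelectionSyntaxError("empty selection expression")
    mask = np.ones(len(structure.atoms), dtype=bool)
    for clause in re.split(r"\s+and\s+", expr):
        mask &= _clause_mask(structure, clause)
    return Selection(expression, np.flatnonzero(mask))


def require_nonempty(sel: Selection, what: str = "selection") -> Selection:
    if sel.empty:
        raise SelectionEmptyError(f"{what} {sel.expression!r} matched no atoms")
    return sel
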