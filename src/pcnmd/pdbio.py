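"""Fixed-column PDB v3.3 reading and writing.

Handles single-model structures, multi-model trajectory ensembles, and
writing structures with per-residue values planted in the b-factor field
(the standard vehicle for painting per-residue energies onto a 3D viewer).

Only ATOM/HETATM/MODEL/ENDMDL records are interpreted; everything else is
passed over.  altLoc alternatives are collapsed to the highest-occupancy
record, ties resolved in favour of altLoc ``A``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .errors import (
    EmptyInputError,
    FormattingOverflowError,
    MappingError,
    PDBParseError,
    StructuralMismatchError,
)
from .structure import AtomRecord, Ensemble, Structure

_COORD_SLICES = [slice(30, 38), slice(38, 46), slice(46, 54)]


def _infer_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    line = line.rstrip("\n").ljust(80)
    record = line[:6].strip()
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # some writers overflow this field; not load-bearing
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    res_name = line[17:20].strip()
    chain = line[21].strip()
    try:
        res_seq = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"bad residue number {line[22:26]!r}", lineno) from exc
    i_code = line[26].strip()
    xyz = []
    for sl in _COORD_SLICES:
        text = line[sl].strip()
        try:
            value = float(text)
        except ValueError as exc:
            raise PDBParseError(f"bad coordinate field {text!r}", lineno) from exc
        if not np.isfinite(value):
            raise PDBParseError(f"non-finite coordinate {text!r}", lineno)
        xyz.append(value)
    try:
        occupancy = float(line[54:60].strip() or 1.0)
    except ValueError:
        occupancy = 1.0
    # b-factor nominally occupies columns 61-66, but %6.2f output of large
    # per-residue energies (e.g. -129.00) legitimately runs long; extend
    # the field while the overflow continues the number
    end = 66
    while end < len(line) and line[end] in "0123456789.":
        end += 1
    try:
        b_factor = float(line[60:end].strip() or 0.0)
    except ValueError:
        b_factor = 0.0
    element = line[76:78].strip().upper()
    if not element:
        element = _infer_element(name)
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        alt_loc=alt_loc,
        chain=chain,
        res_seq=res_seq,
        i_code=i_code,
        res_name=res_name,
        coords=np.array(xyz, dtype=float),
        occupancy=occupancy,
        b_factor=b_factor,
        hetero=(record == "HETATM"),
    )


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one record per atom site: highest occupancy, ties -> altLoc A."""
    best: dict[tuple, tuple[int, AtomRecord]] = {}
    order: list[tuple] = []
    for pos, a in enumerate(atoms):
        if not a.alt_loc:
            key = ("solo", pos)
        else:
            key = (a.chain, a.res_seq, a.i_code, a.res_name, a.name)
        if key not in best:
            best[key] = (pos, a)
            order.append(key)
        else:
            _, incumbent = best[key]
            better = a.occupancy > incumbent.occupancy or (
                a.occupancy == incumbent.occupancy
                and a.alt_loc == "A"
                and incumbent.alt_loc != "A"
            )
            if better:
                best[key] = (best[key][0], a)
    return [best[k][1] for k in order]


def read_pdb(text: str) -> Structure:
    """Parse single-model PDB content into a :class:`Structure`.

    Raises :class:`PDBParseError` (with the line number) on malformed
    coordinate fields, :class:`EmptyInputError` when no ATOM/HETATM records
    are present, and rejects content with more than one MODEL block.
    """
    atoms: list[AtomRecord] = []
    n_models = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            n_models += 1
            if n_models > 1:
                raise PDBParseError(
                    "multiple MODEL blocks; use read_multimodel_pdb", lineno
                )
        elif rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise EmptyInputError("no ATOM/HETATM records found")
    return Structure(_resolve_altlocs(atoms))


def read_multimodel_pdb(
    text: str, time_start: float = 0.0, time_stride: float = 10.0
) -> Ensemble:
    """Parse a multi-model PDB into an :class:`Ensemble`.

    The first model becomes the reference structure.  Timestamps are
    ``time_start + i * time_stride`` ps (defaults 0 and 10 ps, the usual
    trajectory output spacing).  All models must agree on atom count and
    ordering; a mismatch raises :class:`StructuralMismatchError` naming the
    offending model (1-based).
    """
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                models.append(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = []
            atoms = current
            atoms.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise EmptyInputError("no models with ATOM/HETATM records found")
    reference = Structure(_resolve_altlocs(models[0]))
    n_atoms = len(reference)
    frames = np.empty((len(models), n_atoms, 3), dtype=float)
    for m, atoms in enumerate(models):
        resolved = _resolve_altlocs(atoms)
        if len(resolved) != n_atoms:
            raise StructuralMismatchError(
                f"model {m + 1} has {len(resolved)} atoms, expected {n_atoms}"
            )
        frames[m] = [a.coords for a in resolved]
    times = time_start + time_stride * np.arange(len(models))
    return Ensemble(reference, frames, times)


def _format_atom_line(a: AtomRecord, serial: int, b_factor: float) -> str:
    record = "HETATM" if a.hetero else "ATOM"
    if len(a.name) >= 4:
        name = a.name[:4]
    else:
        name = f" {a.name:<3s}"
    head = (
        f"{record:<6s}{serial:>5d} {name:<4s}{a.alt_loc[:1] or ' ':1s}"
        f"{a.res_name:>3s} {a.chain[:1] or ' ':1s}{a.res_seq:>4d}"
        f"{a.i_code[:1] or ' ':1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{b_factor:6.2f}"
    )
    # keep the element symbol anchored at columns 77-78 even when a large
    # b-factor overflows its 6-column field
    return head.ljust(76) + f"{a.element:>2s}"


def write_pdb(structure: Structure) -> str:
    """Serialise a structure as fixed-column PDB text."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        lines.append(_format_atom_line(a, i, a.b_factor))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_multimodel_pdb(ensemble: Ensemble) -> str:
    """Serialise an ensemble as MODEL/ENDMDL-delimited PDB text."""
    lines = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        frame = ensemble.frame_structure(f)
        for i, a in enumerate(frame.atoms, start=1):
            lines.append(_format_atom_line(a, i, a.b_factor))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


_B_MIN, _B_MAX = -999.99, 9999.99

ResidueValueTable = (
    Mapping[tuple[str, int], float] | Iterable[tuple[str, int, float]]
)


def _as_residue_value_map(table: ResidueValueTable) -> dict[tuple[str, int], float]:
    if isinstance(table, Mapping):
        return {(c, int(r)): float(v) for (c, r), v in table.items()}
    return {(c, int(r)): float(v) for c, r, v in table}


def write_pdb_with_bfactor(
    structure: Structure, residue_values: ResidueValueTable
) -> str:
    """Write PDB text with per-residue values in the b-factor columns.

    Every atom of a listed residue carries that residue's value (``%6.2f``);
    atoms of unlisted residues get 0.00.  Values outside the fixed-width
    field range raise :class:`FormattingOverflowError`; a key that matches
    no residue raises :class:`MappingError`.
    """
    values = _as_residue_value_map(residue_values)
    known = {(r.chain, r.res_seq) for r in structure.residues}
    known |= {(a.chain, a.res_seq) for a in structure.atoms}
    for key, v in values.items():
        if key not in known:
            raise MappingError(f"residue {key} not found in structure")
        if not (_B_MIN <= v <= _B_MAX):
            raise FormattingOverflowError(
                f"value {v} for residue {key} outside [{_B_MIN}, {_B_MAX}]"
            )
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        b = values.get((a.chain, a.res_seq), 0.0)
        lines.append(_format_atom_line(a, i, b))
    lines.append("END")
    return "\n".join(lines) + "\n"
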