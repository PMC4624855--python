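"""Interface statistics and binding-energy bookkeeping.

This module covers the analysis layer around an MM-PBSA-style calculation:

* Shrake–Rupley solvent-accessible surface area (SASA) with golden-spiral
  sphere sampling, Bondi radii and a 1.4 Å water probe;
* the apolar solvation term G_apolar = γ·SASA (γ = 0.022 kJ/mol·Å²);
* protein–protein interface atom-contact counts per frame (3.5 Å cutoff),
  reported as mean ± sd over the trajectory;
* geometric hydrogen-bond detection with per-trajectory occupancy;
* the binding-energy ledger ΔE_binding = E_complex − (E_receptor +
  E_ligand), combined per term over externally supplied energy tables
  (the polar-solvation and vacuum force-field terms are ingested, never
  computed here — entropy is deliberately absent, which is why the result
  is labelled ΔE rather than ΔG);
* per-residue decomposition painted into the PDB b-factor field for
  viewer-based hot-spot maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    MappingError,
    ParameterError,
    RadiusError,
    SchemaError,
    SelectionOverlapError,
)
from .structure import Ensemble, Selection, Structure, require_nonempty

#: Bondi van der Waals radii, Å
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

#: surface-tension coefficient for the apolar solvation term, kJ/(mol·Å²)
DEFAULT_GAMMA = 0.022

H_COVALENT_CUTOFF = 1.25  # Å; X–H bond detection for donor assignment


def golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _atom_radii(structure: Structure, radii: dict[str, float] | None) -> np.ndarray:
    table = dict(BONDI_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    out = np.empty(len(structure))
    for i, a in enumerate(structure.atoms):
        r = table.get(a.element.upper())
        if r is None:
            raise RadiusError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.name} in {a.res_name} {a.chain}{a.res_seq})"
            )
        out[i] = r
    return out


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å² (Shrake–Rupley).

    Each atom's expanded sphere (r + probe) is sampled with ``n_points``
    golden-spiral points; the accessible area is the unoccluded fraction
    times 4π(r+probe)².  960 points keep the sphere-quadrature error
    below ~1%.
    """
    if probe <= 0:
        raise ParameterError("probe radius must be > 0")
    if n_points < 10:
        raise ParameterError("n_points too small for a meaningful estimate")
    coords = structure.coords
    r_exp = _atom_radii(structure, radii) + probe
    n = len(structure)
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    r_max = r_exp.max()
    for i in range(n):
        pts = coords[i] + r_exp[i] * sphere
        neighbours = tree.query_ball_point(coords[i], r_exp[i] + r_max)
        neighbours = [j for j in neighbours if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > r_exp[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * r_exp[i] ** 2
    return areas


def apolar_term(total_sasa: float, gamma: float = DEFAULT_GAMMA) -> float:
    """Apolar solvation energy G_apolar = γ·SASA, kJ/mol."""
    if total_sasa < 0:
        raise ParameterError(f"SASA must be >= 0, got {total_sasa}")
    return gamma * total_sasa


@dataclass
class InterfaceReport:
    """Per-frame interface contact counts with trajectory mean ± sd."""

    counts: np.ndarray  # per frame
    cutoff: float
    group_a: str
    group_b: str
    mode: str = "atoms"

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def sd(self) -> float:
        return float(self.counts.std(ddof=0))


def interface_contacts(
    ensemble: Ensemble,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 3.5,
    mode: str = "atoms",
) -> InterfaceReport:
    """Count interface contacts between two atom groups, per frame.

    ``mode="atoms"`` counts atom pairs within the cutoff (mindist-style
    semantics, which is what makes trajectory means non-integer);
    ``mode="residues"`` counts residue pairs whose minimum atom distance
    is within the cutoff.
    """
    require_nonempty(group_a, "group A")
    require_nonempty(group_b, "group B")
    if mode not in ("atoms", "residues"):
        raise ParameterError(f"unknown contact mode {mode!r}")
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise SelectionOverlapError("interface groups must be disjoint")
    ref = ensemble.reference
    res_of = {}
    if mode == "residues":
        key_of_atom = {i: a.residue_key for i, a in enumerate(ref.atoms)}
        res_of = key_of_atom
    counts = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        xa = ensemble.frames[f][group_a.indices]
        xb = ensemble.frames[f][group_b.indices]
        tree = cKDTree(xb)
        pairs = tree.query_ball_point(xa, cutoff)
        if mode == "atoms":
            counts[f] = sum(len(hits) for hits in pairs)
        else:
            seen = set()
            for ia, hits in zip(group_a.indices, pairs):
                for hb in hits:
                    seen.add((res_of[ia], res_of[group_b.indices[hb]]))
            counts[f] = len(seen)
    return InterfaceReport(
        counts=counts,
        cutoff=cutoff,
        group_a=group_a.expression,
        group_b=group_b.expression,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HBond:
    """One interface hydrogen bond with its trajectory occupancy."""

    donor_index: int
    hydrogen_index: int | None
    acceptor_index: int
    occupancy: float
    donor_label: str
    acceptor_label: str
    partners: tuple[str, str]  # (group A residue, group B residue)

    def __str__(self) -> str:  # Table-style "Donor-res/Acceptor-res"
        return f"{self.partners[0]}/{self.partners[1]} ({self.occupancy:.2f})"


def _residue_label(atom) -> str:
    return f"{atom.res_name.title()}{atom.res_seq}"


def _polar_atoms(structure: Structure, indices: np.ndarray) -> list[int]:
    return [
        int(i)
        for i in indices
        if structure.atoms[i].element.upper() in ("N", "O")
    ]


def _bonded_hydrogens(structure: Structure) -> dict[int, list[int]]:
    """Map polar heavy atom index -> covalently bound hydrogen indices."""
    coords = structure.coords
    hydrogens = [
        i for i, a in enumerate(structure.atoms) if a.element.upper() == "H"
    ]
    heavies = [
        i for i, a in enumerate(structure.atoms) if a.element.upper() in ("N", "O")
    ]
    out: dict[int, list[int]] = {i: [] for i in heavies}
    if not hydrogens or not heavies:
        return out
    tree = cKDTree(coords[heavies])
    for h in hydrogens:
        dist, j = tree.query(coords[h])
        if dist <= H_COVALENT_CUTOFF:
            out[heavies[j]].append(h)
    return out


def detect_hbonds(
    ensemble: Ensemble,
    group_a: Selection,
    group_b: Selection,
    d_max: float = 3.5,
    angle_max: float = 30.0,
    occupancy_min: float = 0.5,
    mode: str = "auto",
) -> list[HBond]:
    """Interface hydrogen bonds with occupancy over the trajectory.

    A donor–acceptor pair is bonded in a frame when the heavy-atom
    distance is ≤ ``d_max`` and (when hydrogens are present) the D–H···A
    deviation from linearity is ≤ ``angle_max`` degrees.  ``mode`` picks
    the criterion: ``"hydrogen"`` requires explicit hydrogens,
    ``"heavy"`` uses distance only, ``"auto"`` uses hydrogens when the
    structure has any.  Bonds with occupancy ≥ ``occupancy_min`` are
    returned sorted by decreasing occupancy; donors are sought in both
    groups, acceptors in the opposite group.
    """
    require_nonempty(group_a, "group A")
    require_nonempty(group_b, "group B")
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise SelectionOverlapError("H-bond groups must be disjoint")
    ref = ensemble.reference
    polar_a = _polar_atoms(ref, group_a.indices)
    polar_b = _polar_atoms(ref, group_b.indices)
    if not polar_a or not polar_b:
        warnings.warn("no polar atoms in one of the groups; no H-bonds possible")
        return []
    h_of = _bonded_hydrogens(ref)
    has_h = any(h_of.get(i) for i in polar_a + polar_b)
    if mode == "auto":
        use_h = has_h
    elif mode == "hydrogen":
        if not has_h:
            warnings.warn("no hydrogens found; hydrogen mode detects nothing")
        use_h = True
    elif mode == "heavy":
        use_h = False
    else:
        raise ParameterError(f"unknown H-bond mode {mode!r}")

    # candidate (donor, acceptor) pairs, donor from either group; the
    # heavy-atom criterion is directionless, so one orientation suffices
    candidates: list[tuple[int, int, bool]] = []  # (donor, acceptor, a_is_donor)
    directions = (
        ((polar_a, polar_b, True), (polar_b, polar_a, False))
        if use_h
        else ((polar_a, polar_b, True),)
    )
    for donors, acceptors, a_is_donor in directions:
        for d in donors:
            if use_h and not h_of.get(d):
                continue
            for a in acceptors:
                candidates.append((d, a, a_is_donor))
    if not candidates:
        warnings.warn("no donor candidates with bound hydrogens")
        return []

    f_total = ensemble.n_frames
    hits = np.zeros(len(candidates), dtype=int)
    best_h: list[int | None] = [None] * len(candidates)
    cos_max = np.cos(np.deg2rad(angle_max))
    for f in range(f_total):
        xyz = ensemble.frames[f]
        for c, (d, a, _) in enumerate(candidates):
            if np.linalg.norm(xyz[d] - xyz[a]) > d_max:
                continue
            if not use_h:
                hits[c] += 1
                continue
            bonded = False
            for h in h_of.get(d, []):
                dh = xyz[h] - xyz[d]
                ha = xyz[a] - xyz[h]
                denom = np.linalg.norm(dh) * np.linalg.norm(ha)
                if denom == 0:
                    continue
                # deviation from linear D–H···A is the angle between the
                # D->H and H->A directions
                if float(dh @ ha) / denom >= cos_max:
                    bonded = True
                    best_h[c] = h
                    break
            if bonded:
                hits[c] += 1
    bonds: list[HBond] = []
    for c, (d, a, a_is_donor) in enumerate(candidates):
        occ = hits[c] / f_total
        if occ < occupancy_min or occ == 0:
            continue
        donor_atom, acceptor_atom = ref.atoms[d], ref.atoms[a]
        donor_label = _residue_label(donor_atom)
        acceptor_label = _residue_label(acceptor_atom)
        partners = (
            (donor_label, acceptor_label) if a_is_donor else (acceptor_label, donor_label)
        )
        bonds.append(
            HBond(
                donor_index=d,
                hydrogen_index=best_h[c],
                acceptor_index=a,
                occupancy=float(occ),
                donor_label=donor_label,
                acceptor_label=acceptor_label,
                partners=partners,
            )
        )
    bonds.sort(key=lambda b: (-b.occupancy, b.donor_index, b.acceptor_index))
    return bonds


# ---------------------------------------------------------------------------
# binding-energy ledger
# ---------------------------------------------------------------------------


@dataclass
class EnergyTerms:
    """Named energy terms of one species, kJ/mol, with provenance tags."""

    terms: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.terms:
            self.provenance.setdefault(name, "external")

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


@dataclass
class BindingEnergy:
    """Per-term Δ(complex − receptor − ligand) and their sum.

    Labelled ΔE_binding, not ΔG: no entropic term enters the ledger.
    """

    per_term: dict[str, float]
    label: str = "dE_binding"

    @property
    def total(self) -> float:
        return float(sum(self.per_term.values()))


def binding_energy(
    complex_terms: EnergyTerms,
    receptor_terms: EnergyTerms,
    ligand_terms: EnergyTerms,
) -> BindingEnergy:
    """Combine species energy tables into the binding-energy ledger.

    All three inputs must carry the same term names; a mismatch raises
    :class:`SchemaError` naming the missing terms.
    """
    keys = set(complex_terms.terms)
    for name, other in (("receptor", receptor_terms), ("ligand", ligand_terms)):
        missing = keys ^ set(other.terms)
        if missing:
            raise SchemaError(
                f"term set mismatch with {name}: {sorted(missing)}"
            )
    per_term = {
        t: complex_terms.terms[t] - receptor_terms.terms[t] - ligand_terms.terms[t]
        for t in complex_terms.terms
    }
    return BindingEnergy(per_term=per_term)


def read_energy_terms_tsv(text: str) -> tuple[EnergyTerms, EnergyTerms, EnergyTerms]:
    """Parse a `term  complex  receptor  ligand` TSV into three term sets."""
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    required = {"term", "complex", "receptor", "ligand"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"energy TSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for col in ("complex", "receptor", "ligand"):
        out.append(
            EnergyTerms({str(t): float(v) for t, v in zip(df["term"], df[col])})
        )
    return out[0], out[1], out[2]


def annotate_decomposition(
    structure: Structure,
    residue_energies,
) -> Structure:
    """Copy of the structure with per-residue energies in the b-factors.

    ``residue_energies`` maps ``(chain, res_seq)`` to kJ/mol (or is an
    iterable of ``(chain, res_seq, value)`` rows).  Negative values are
    stabilising.  Atoms of unlisted residues get 0.0; a key matching no
    residue raises :class:`MappingError`.
    """
    from .pdbio import _as_residue_value_map

    values = _as_residue_value_map(residue_energies)
    known = {(a.chain, a.res_seq) for a in structure.atoms}
    unknown = set(values) - known
    if unknown:
        raise MappingError(f"residues not in structure: {sorted(unknown)}")
    atoms = []
    for a in structure.atoms:
        b = values.get((a.chain, a.res_seq), 0.0)
        atoms.append(
            type(a)(
                a.serial, a.name, a.element, a.alt_loc, a.chain, a.res_seq,
                a.i_code, a.res_name, a.coords.copy(), a.occupancy, b, a.hetero,
            )
        )
    return Structure(atoms)
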