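"""SASA, apolar solvation, interface contacts, hydrogen bonds and the
binding-energy ledger."""

import numpy as np
import pytest

from pcnmd import (
    EnergyTerms,
    FixtureSpec,
    annotate_decomposition,
    apolar_term,
    binding_energy,
    detect_hbonds,
    interface_contacts,
    make_backbone,
    read_energy_terms_tsv,
    read_pdb,
    sasa,
    select,
    write_pdb,
)
from pcnmd.errors import (
    ParameterError,
    RadiusError,
    SchemaError,
    SelectionOverlapError,
)
from pcnmd.structure import Ensemble, Structure

from conftest import make_atom, static_ensemble


def single_atom_structure(element="C", name="CA"):
    return Structure([make_atom(1, name, element, "A", 1, [0.0, 0, 0])])


class TestSasa:
    def test_isolated_sphere_analytic(self):
        areas = sasa(single_atom_structure(), probe=1.4, n_points=960)
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_distant_atoms_fully_exposed(self):
        s = Structure(
            [
                make_atom(1, "CA", "C", "A", 1, [0, 0, 0]),
                make_atom(2, "CA", "C", "A", 2, [100.0, 0, 0]),
            ]
        )
        areas = sasa(s)
        full = 4 * np.pi * 3.1**2
        assert np.allclose(areas, full, rtol=0.01)

    def test_accuracy_improves_with_point_count(self):
        s = single_atom_structure()
        full = 4 * np.pi * 3.1**2
        # a lone sphere is exact at any point count; occlusion is not
        s2 = Structure(
            [
                make_atom(1, "CA", "C", "A", 1, [0, 0, 0]),
                make_atom(2, "CA", "C", "A", 2, [3.0, 0, 0]),
            ]
        )
        coarse = sasa(s2, n_points=96)[0]
        fine = sasa(s2, n_points=4000)[0]
        mid = sasa(s2, n_points=960)[0]
        assert abs(mid - fine) < abs(coarse - fine) + 1e-9
        assert sasa(s)[0] == pytest.approx(full, rel=0.01)

    def test_unknown_element_rejected(self):
        s = single_atom_structure(element="XX")
        with pytest.raises(RadiusError):
            sasa(s)

    def test_matches_biotite_total_on_helix(self):
        import biotite.structure as struc

        s = make_backbone(FixtureSpec(kind="helix", n_residues=10))
        arr = struc.AtomArray(len(s.atoms))
        for i, a in enumerate(s.atoms):
            arr.coord[i] = a.coords
            arr.chain_id[i] = a.chain
            arr.res_id[i] = a.res_seq
            arr.res_name[i] = a.res_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        ours = sasa(s, n_points=960).sum()
        theirs = np.nansum(
            struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
        )
        assert ours == pytest.approx(theirs, rel=0.01)

    def test_complex_sasa_bounded_by_sum_of_parts(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            a = make_backbone(
                FixtureSpec(kind="coil", n_residues=6, seed=int(rng.integers(1000)))
            )
            b = make_backbone(
                FixtureSpec(kind="coil", n_residues=6, seed=int(rng.integers(1000)))
            )
            shift = rng.uniform(4.0, 12.0, size=3)
            b_atoms = []
            for i, atom in enumerate(b.atoms):
                moved = make_atom(
                    100 + i, atom.name, atom.element, "B", atom.res_seq,
                    atom.coords + shift,
                )
                b_atoms.append(moved)
            b_shifted = Structure(b_atoms)
            combined = Structure(a.atoms + b_atoms)
            total = sasa(combined).sum()
            parts = sasa(a).sum() + sasa(b_shifted).sum()
            assert total <= parts + 1e-6


class TestApolarTerm:
    def test_gamma_arithmetic(self):
        assert apolar_term(1000.0) == pytest.approx(22.0)

    def test_zero_area(self):
        assert apolar_term(0.0) == 0.0

    def test_negative_area_rejected(self):
        with pytest.raises(ParameterError):
            apolar_term(-1.0)

    def test_binding_apolar_negative_when_surface_buried(self):
        # docked two-body fixture: two strands in contact range
        a = make_backbone(FixtureSpec(kind="strand", n_residues=8))
        b_atoms = [
            make_atom(100 + i, at.name, at.element, "B", at.res_seq,
                      at.coords + np.array([0.0, 5.0, 0.0]))
            for i, at in enumerate(a.atoms)
        ]
        b = Structure(b_atoms)
        combined = Structure(a.atoms + b_atoms)
        delta = apolar_term(sasa(combined).sum()) - (
            apolar_term(sasa(a).sum()) + apolar_term(sasa(b).sum())
        )
        assert delta < 0


class TestInterfaceContacts:
    def _pair_ensemble(self, distance):
        s = Structure(
            [
                make_atom(1, "CA", "C", "A", 1, [0, 0, 0]),
                make_atom(2, "CA", "C", "B", 1, [distance, 0, 0]),
            ]
        )
        return static_ensemble(s, n_frames=3)

    def test_pair_inside_cutoff(self):
        ens = self._pair_ensemble(3.4)
        rep = interface_contacts(
            ens, select(ens.reference, "chain A"), select(ens.reference, "chain B")
        )
        assert rep.mean == 1.0
        assert rep.sd == 0.0

    def test_pair_outside_cutoff(self):
        ens = self._pair_ensemble(3.6)
        rep = interface_contacts(
            ens, select(ens.reference, "chain A"), select(ens.reference, "chain B")
        )
        assert rep.mean == 0.0

    def test_boundary_is_inclusive(self):
        ens = self._pair_ensemble(3.5)
        rep = interface_contacts(
            ens, select(ens.reference, "chain A"), select(ens.reference, "chain B")
        )
        assert rep.mean == 1.0

    def test_two_frame_mean_and_sd(self):
        # frame 0: 2 pairs in range; frame 1: 4 pairs
        atoms = [
            make_atom(1, "C1", "C", "A", 1, [0, 0, 0]),
            make_atom(2, "C2", "C", "A", 1, [0, 10, 0]),
            make_atom(3, "C3", "C", "B", 1, [3.0, 0, 0]),
            make_atom(4, "C4", "C", "B", 1, [-3.0, 0, 0]),
        ]
        s = Structure(atoms)
        f0 = s.coords
        f1 = f0.copy()
        # move A2 between the two B atoms: within 3.5 Å of both
        f1[1] = [0.0, 0.5, 0.0]
        ens = Ensemble(s, np.array([f0, f1]), [0.0, 10.0])
        rep = interface_contacts(
            ens, select(s, "chain A"), select(s, "chain B")
        )
        assert list(rep.counts) == [2, 4]
        assert rep.mean == pytest.approx(3.0)
        assert rep.sd == pytest.approx(1.0)

    def test_symmetric_in_groups(self, helix20):
        rng = np.random.default_rng(7)
        coords = helix20.coords + rng.normal(scale=0.1, size=(1, len(helix20), 3))
        ens = Ensemble(helix20, coords, [0.0])
        ga = select(helix20, "resid 1-10")
        gb = select(helix20, "resid 11-20")
        ab = interface_contacts(ens, ga, gb, cutoff=5.0)
        ba = interface_contacts(ens, gb, ga, cutoff=5.0)
        assert list(ab.counts) == list(ba.counts)

    def test_overlapping_groups_rejected(self, helix20):
        ens = static_ensemble(helix20)
        sel = select(helix20, "name CA")
        with pytest.raises(SelectionOverlapError):
            interface_contacts(ens, sel, sel)

    def test_residue_mode_counts_pairs_once(self):
        # two atoms of the same A residue both near one B atom: one
        # residue pair but two atom pairs
        atoms = [
            make_atom(1, "C1", "C", "A", 1, [0, 0, 0]),
            make_atom(2, "C2", "C", "A", 1, [1.0, 0, 0]),
            make_atom(3, "C3", "C", "B", 1, [2.0, 0, 0]),
        ]
        s = Structure(atoms)
        ens = static_ensemble(s, n_frames=1)
        ga, gb = select(s, "chain A"), select(s, "chain B")
        assert interface_contacts(ens, ga, gb, mode="atoms").mean == 2.0
        assert interface_contacts(ens, ga, gb, mode="residues").mean == 1.0


class TestHbonds:
    def _nho_system(self, d=2.9, deviation_deg=10.0, frames_bonded=None,
                    n_frames=1):
        """N-H donor in chain A, O acceptor in chain B."""
        n = np.array([0.0, 0, 0])
        h = np.array([1.0, 0, 0])
        theta = np.deg2rad(deviation_deg)
        o = np.array([d * np.cos(theta / 2), d * np.sin(theta / 2), 0.0])
        atoms = [
            make_atom(1, "N", "N", "A", 1, n),
            make_atom(2, "H", "H", "A", 1, h),
            make_atom(3, "O", "O", "B", 1, o, res_name="GLU"),
        ]
        s = Structure(atoms)
        frames = np.repeat(s.coords[None], n_frames, axis=0)
        if frames_bonded is not None:
            for f in range(n_frames):
                if f not in frames_bonded:
                    frames[f, 2] = [20.0, 0, 0]  # move acceptor away
        return Ensemble(s, frames, 10.0 * np.arange(n_frames))

    def test_good_geometry_full_occupancy(self):
        ens = self._nho_system(d=2.9, deviation_deg=10.0)
        bonds = detect_hbonds(
            ens, select(ens.reference, "chain A"), select(ens.reference, "chain B")
        )
        assert len(bonds) == 1
        assert bonds[0].occupancy == 1.0
        assert bonds[0].partners == ("Ala1", "Glu1")

    def test_low_occupancy_filtered(self):
        ens = self._nho_system(frames_bonded={0, 1}, n_frames=10)
        ga = select(ens.reference, "chain A")
        gb = select(ens.reference, "chain B")
        assert detect_hbonds(ens, ga, gb) == []
        bonds = detect_hbonds(ens, ga, gb, occupancy_min=0.1)
        assert len(bonds) == 1
        assert bonds[0].occupancy == pytest.approx(0.2)

    def test_long_distance_absent(self):
        ens = self._nho_system(d=3.6)
        bonds = detect_hbonds(
            ens, select(ens.reference, "chain A"), select(ens.reference, "chain B")
        )
        assert bonds == []

    def test_bent_geometry_rejected(self):
        ens = self._nho_system(d=2.9, deviation_deg=80.0)
        bonds = detect_hbonds(
            ens, select(ens.reference, "chain A"), select(ens.reference, "chain B")
        )
        assert bonds == []

    def test_heavy_atom_mode_ignores_angle(self):
        ens = self._nho_system(d=2.9, deviation_deg=80.0)
        bonds = detect_hbonds(
            ens,
            select(ens.reference, "chain A"),
            select(ens.reference, "chain B"),
            mode="heavy",
        )
        assert len(bonds) == 1

    def test_no_polar_atoms_warns_and_returns_empty(self):
        atoms = [
            make_atom(1, "C1", "C", "A", 1, [0, 0, 0]),
            make_atom(2, "C2", "C", "B", 1, [3.0, 0, 0]),
        ]
        s = Structure(atoms)
        ens = static_ensemble(s, n_frames=1)
        with pytest.warns(UserWarning):
            bonds = detect_hbonds(ens, select(s, "chain A"), select(s, "chain B"))
        assert bonds == []


class TestBindingEnergy:
    def test_total_arithmetic(self):
        be = binding_energy(
            EnergyTerms({"E": -100.0}),
            EnergyTerms({"E": -60.0}),
            EnergyTerms({"E": -30.0}),
        )
        assert be.total == pytest.approx(-10.0)

    def test_exactly_additive_parts_give_zero(self):
        be = binding_energy(
            EnergyTerms({"vdw": -3.0, "elec": 2.0}),
            EnergyTerms({"vdw": -1.0, "elec": 1.5}),
            EnergyTerms({"vdw": -2.0, "elec": 0.5}),
        )
        assert all(v == pytest.approx(0.0) for v in be.per_term.values())
        assert be.total == pytest.approx(0.0)

    def test_per_term_sums_equal_total_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            terms = [f"t{i}" for i in range(int(rng.integers(2, 6)))]
            tables = [
                EnergyTerms({t: float(rng.normal(scale=100)) for t in terms})
                for _ in range(3)
            ]
            be = binding_energy(*tables)
            assert be.total == pytest.approx(sum(be.per_term.values()), abs=1e-9)
            expect = tables[0].total - tables[1].total - tables[2].total
            assert be.total == pytest.approx(expect, abs=1e-9)

    def test_linearity_under_scaling(self):
        tables = [
            EnergyTerms({"a": 10.0, "b": -4.0}),
            EnergyTerms({"a": 3.0, "b": -1.0}),
            EnergyTerms({"a": 2.0, "b": -0.5}),
        ]
        be = binding_energy(*tables)
        scaled = binding_energy(
            *[EnergyTerms({k: 3.0 * v for k, v in t.terms.items()}) for t in tables]
        )
        for k in be.per_term:
            assert scaled.per_term[k] == pytest.approx(3.0 * be.per_term[k])

    def test_term_mismatch_rejected(self):
        with pytest.raises(SchemaError, match="elec"):
            binding_energy(
                EnergyTerms({"vdw": 1.0, "elec": 2.0}),
                EnergyTerms({"vdw": 1.0}),
                EnergyTerms({"vdw": 1.0, "elec": 2.0}),
            )

    def test_tsv_round_trip(self):
        text = "term\tcomplex\treceptor\tligand\nvdw\t-100\t-60\t-30\n"
        cx, rec, lig = read_energy_terms_tsv(text)
        be = binding_energy(cx, rec, lig)
        assert be.per_term["vdw"] == pytest.approx(-10.0)


class TestAnnotateDecomposition:
    def test_listed_residues_carry_values(self, helix20):
        annotated = annotate_decomposition(
            helix20, [("A", 3, -171.0), ("A", 7, -190.0)]
        )
        for a in annotated.atoms:
            if a.res_seq == 3:
                assert a.b_factor == -171.0
            elif a.res_seq == 7:
                assert a.b_factor == -190.0
            else:
                assert a.b_factor == 0.0

    def test_round_trip_through_pdb_two_decimals(self, helix20):
        annotated = annotate_decomposition(helix20, [("A", 2, -129.0)])
        parsed = read_pdb(write_pdb(annotated))
        values = {a.res_seq: a.b_factor for a in parsed.atoms}
        assert values[2] == pytest.approx(-129.0, abs=0.005)

    def test_unknown_residue_rejected(self, helix20):
        from pcnmd.errors import MappingError

        with pytest.raises(MappingError):
            annotate_decomposition(helix20, [("A", 999, -1.0)])
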