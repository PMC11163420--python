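"""Spin arrays, sheet lattices, contacts and PDB output."""

import numpy as np
import pytest

from sheetnmr.geometry import (
    CSAParameters,
    EmptySelectionError,
    InvalidLabelError,
    SALT_BRIDGE_LABELS,
    SpinSite,
    SpinSystem,
    build_linear_spin_array,
    build_sheet_model,
    extract_spin_system,
    predict_contacts,
    write_model_pdb,
)


class TestLinearArray:
    def test_eight_carbon_array(self):
        sys = build_linear_spin_array(8, 5.0, ["C13"])
        assert len(sys) == 8
        assert set(sys.isotopes) == {"C13"}
        np.testing.assert_allclose(sys.positions[:, 0], np.arange(8) * 5.0)
        np.testing.assert_allclose(sys.positions[:, 1:], 0.0)

    def test_alternating_heteronuclear_array(self):
        sys = build_linear_spin_array(8, 4.0, ["C13", "N15"])
        assert sys.isotopes == ("C13", "N15") * 4
        d = np.diff(sys.positions[:, 0])
        np.testing.assert_allclose(d, 4.0)

    def test_two_spin_pair(self):
        sys = build_linear_spin_array(2, 5.0, ["C13", "N15"])
        assert sys.isotopes == ("C13", "N15")
        assert sys.distance("s0", "s1") == pytest.approx(5.0)

    @pytest.mark.parametrize("spacing", [0.0, -1.0])
    def test_nonpositive_spacing_rejected(self, spacing):
        with pytest.raises(ValueError, match="spacing"):
            build_linear_spin_array(4, spacing, ["C13"])

    def test_csa_attached_to_carbons_only(self):
        csa = CSAParameters(-75.0, 0.75)
        sys = build_linear_spin_array(4, 5.0, ["C13", "N15"], csa=csa)
        assert all(
            (s.csa is not None) == (s.isotope == "C13") for s in sys.sites
        )


class TestSpinSystemInvariants:
    def test_distance_symmetry(self):
        sys = build_linear_spin_array(5, 4.0, ["C13", "N15"])
        d = sys.distance_matrix()
        np.testing.assert_allclose(d, d.T)

    def test_duplicate_ids_rejected(self):
        a = SpinSite("x", "C13", np.zeros(3))
        b = SpinSite("x", "C13", np.array([5.0, 0, 0]))
        with pytest.raises(ValueError, match="unique"):
            SpinSystem((a, b))

    def test_too_close_sites_rejected(self):
        a = SpinSite("a", "C13", np.zeros(3))
        b = SpinSite("b", "C13", np.array([0.3, 0, 0]))
        with pytest.raises(ValueError, match="0.5"):
            SpinSystem((a, b))

    def test_json_round_trip(self):
        csa = CSAParameters(-75.0, 0.75, 10.0, 20.0, 30.0)
        sys = build_linear_spin_array(3, 4.0, ["C13", "N15"], csa=csa)
        again = SpinSystem.from_dict(sys.to_dict())
        np.testing.assert_allclose(again.positions, sys.positions)
        assert again.isotopes == sys.isotopes
        assert again.sites[0].csa == csa


class TestSheetModel:
    def test_parallel_in_register_co_distance(self):
        model = build_sheet_model("parallel", "none", n_strands=10)
        f4 = sorted(model.label_atoms(["F4 CO"]), key=lambda a: a.strand)
        for a, b in zip(f4, f4[1:]):
            assert np.linalg.norm(a.position - b.position) == pytest.approx(5.0)

    def test_antiparallel_direction_alternates(self):
        model = build_sheet_model("antiparallel", "none", n_strands=6)
        dirs = [model.strand_direction(0, s)[0] for s in range(6)]
        assert dirs == [1.0, -1.0, 1.0, -1.0, 1.0, -1.0]

    def test_antiparallel_f4co_f8n_within_5A(self):
        model = build_sheet_model("antiparallel", "none", n_strands=4)
        f4 = model.label_atoms(["F4 CO"])
        f8 = model.label_atoms(["F8 N"])
        dmin = min(
            np.linalg.norm(a.position - b.position)
            for a in f4
            for b in f8
            if a.strand != b.strand
        )
        assert dmin <= 5.0 + 1e-9

    def test_salt_bridge_preset_distance(self):
        model = build_sheet_model(
            "antiparallel", "none", n_strands=4, labels=SALT_BRIDGE_LABELS
        )
        nz = model.label_atoms(["K3 NZ"])
        cd = model.label_atoms(["E9 CD"])
        dmin = min(
            np.linalg.norm(a.position - b.position)
            for a in nz
            for b in cd
            if a.strand != b.strand
        )
        assert dmin == pytest.approx(4.0)

    def test_registry_shift_translates_reversed_strands(self):
        base = build_sheet_model("antiparallel", "none", n_strands=2)
        shifted = build_sheet_model(
            "antiparallel", "none", n_strands=2, registry_shift=2
        )
        a0 = {a.site_id: a for a in base.atoms()}
        for a in shifted.atoms():
            if a.strand == 1:
                assert a.position[0] == pytest.approx(
                    a0[a.site_id].position[0] + 2 * 3.5
                )

    def test_unknown_label_rejected(self):
        model = build_sheet_model("parallel", "none", n_strands=2)
        with pytest.raises(InvalidLabelError):
            model.label_atoms(["F4 XX"])
        with pytest.raises(InvalidLabelError):
            model.label_atoms(["A4 CO"])  # sequence has F at position 4


class TestExtractSpinSystem:
    def test_parallel_f4co_extraction(self):
        model = build_sheet_model("parallel", "none", n_strands=10)
        sys = extract_spin_system(model, ["F4 CO"], max_spins=8)
        assert len(sys) == 8
        assert set(sys.isotopes) == {"C13"}
        ys = np.sort(sys.positions[:, 1])
        np.testing.assert_allclose(np.diff(ys), 5.0)
        # collinear: x and z constant
        assert np.ptp(sys.positions[:, 0]) == pytest.approx(0.0)
        assert np.ptp(sys.positions[:, 2]) == pytest.approx(0.0)

    def test_clamps_to_available_matches(self):
        model = build_sheet_model("parallel", "none", n_strands=3)
        sys = extract_spin_system(model, ["F4 CO"], max_spins=8)
        assert len(sys) == 3

    def test_antiparallel_mixed_selection_alternates_isotopes(self):
        model = build_sheet_model("antiparallel", "none", n_strands=10)
        sys = extract_spin_system(model, ["F4 CO", "F8 N"], max_spins=8)
        assert len(sys) == 8
        # brute-force oracle: sort all matching lattice sites along the
        # hydrogen-bond axis; isotopes must alternate strand by strand
        atoms = model.label_atoms(["F4 CO", "F8 N"])
        central = sorted(sys.sites, key=lambda s: s.position[1])
        isotopes = [s.isotope for s in central]
        assert isotopes in (
            ["C13", "N15"] * 4,
            ["N15", "C13"] * 4,
        )
        # every selected site exists in the full enumeration
        all_ids = {a.site_id for a in atoms}
        assert all(s.site_id in all_ids for s in sys.sites)

    def test_empty_selection_raises(self):
        model = build_sheet_model("parallel", "none", n_strands=2)
        with pytest.raises(EmptySelectionError):
            extract_spin_system(model, [], max_spins=4)


class TestPredictContacts:
    def test_parallel_stacked_q2k3_but_not_k3e9(self):
        model = build_sheet_model(
            "parallel", "parallel", n_strands=5, n_sheets=2
        )
        pairs = {c.pair for c in predict_contacts(model, {"Q2", "K3", "E9"})}
        assert frozenset(("Q2", "K3")) in pairs
        assert frozenset(("K3", "E9")) not in pairs

    def test_antiparallel_k3e9_contact(self):
        model = build_sheet_model("antiparallel", "none", n_strands=4)
        pairs = {c.pair for c in predict_contacts(model, {"K3", "E9"})}
        assert frozenset(("K3", "E9")) in pairs

    def test_empty_labels_empty_contacts(self):
        model = build_sheet_model("parallel", "none", n_strands=4)
        assert predict_contacts(model, set()) == set()

    def test_agrees_with_brute_force_scan(self):
        model = build_sheet_model(
            "antiparallel", "antiparallel", n_strands=8, n_sheets=2,
            labels=SALT_BRIDGE_LABELS,
        )
        labels = {"Q2", "K3", "F6", "E9"}
        got = {c.pair for c in predict_contacts(model, labels, cutoff=6.0)}
        atoms = [a for a in model.atoms() if a.residue in labels]
        expected = set()
        for i, a in enumerate(atoms):
            for b in atoms[i + 1 :]:
                if a.residue == b.residue:
                    continue
                if np.linalg.norm(a.position - b.position) <= 6.0:
                    expected.add(frozenset((a.residue, b.residue)))
        assert got == expected


class TestPdbOutput:
    def test_two_strand_model_two_chains(self, tmp_path):
        import biotite.structure.io.pdb as pdb

        model = build_sheet_model("parallel", "none", n_strands=2)
        path = tmp_path / "model.pdb"
        write_model_pdb(model, str(path))
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        assert len(set(arr.chain_id)) == 2

    def test_coordinate_round_trip(self, tmp_path):
        import biotite.structure.io.pdb as pdb

        model = build_sheet_model(
            "antiparallel", "none", n_strands=3, labels=SALT_BRIDGE_LABELS
        )
        path = tmp_path / "model.pdb"
        write_model_pdb(model, str(path))
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        ours = np.array([a.position for a in model.atoms()])
        assert arr.array_length() == len(ours)
        # PDB stores 3 decimals
        assert np.abs(np.sort(arr.coord, axis=0) - np.sort(ours, axis=0)).max() < 1e-3

    def test_forty_chains(self, tmp_path):
        import biotite.structure.io.pdb as pdb

        model = build_sheet_model(
            "parallel", "parallel", n_strands=10, n_sheets=4
        )
        path = tmp_path / "model.pdb"
        write_model_pdb(model, str(path))
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        assert len(set(arr.chain_id)) == 40
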