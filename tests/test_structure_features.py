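"""Structural features: distances, SASA, secondary structure, B-factors."""

import copy
import math

import numpy as np
import pytest

from cbsvar import structure_features as sf
from cbsvar.data_model import VariantPanel
from cbsvar.synthetic_data import (
    helix_coordinates,
    simulate_structure,
    write_dihedral_backbone_pdb,
)


def rigid_transform(model, seed=3):
    """Random rotation + translation applied to every coordinate."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(size=3) * 20
    out = copy.deepcopy(model)
    for r in out.residues:
        object.__setattr__(r, "coords", r.coords @ q.T + t)
    out.ligands = {k: (v @ q.T + t if len(v) else v)
                   for k, v in out.ligands.items()}
    return out


class TestMinDistance:
    def test_planted_heme_distance_exact(self, helix_pdb, helix_model):
        d = sf.min_distance(helix_model, helix_pdb["target"], "heme")
        assert d == pytest.approx(7.3, abs=1e-6)

    def test_matches_brute_force_all_pairs(self, helix_model):
        for pos in (1, 17, 42, 60):
            for ligand in ("heme", "plp"):
                lig = helix_model.ligands[ligand]
                res = helix_model.residues_at(pos)[0]
                brute = min(
                    np.linalg.norm(a - b)
                    for a in res.coords for b in lig
                )
                assert sf.min_distance(helix_model, pos, ligand) == \
                    pytest.approx(brute, abs=1e-12)

    def test_minimum_over_residue_atoms(self, helix_model):
        # CB sits 1.5 A further out than CA; the reported distance can never
        # exceed the per-atom distances
        pos = 30
        res = helix_model.residues_at(pos)[0]
        d = sf.min_distance(helix_model, pos, "plp")
        per_atom = np.linalg.norm(
            res.coords[:, None, :] - helix_model.ligands["plp"][None], axis=-1)
        assert d == pytest.approx(per_atom.min())

    def test_rigid_body_invariance(self, helix_model):
        moved = rigid_transform(helix_model)
        for pos in (5, 33):
            assert sf.min_distance(moved, pos, "heme") == pytest.approx(
                sf.min_distance(helix_model, pos, "heme"), abs=1e-6)

    def test_missing_entities_rejected(self, helix_model):
        with pytest.raises(sf.MissingEntityError):
            sf.min_distance(helix_model, 999, "heme")
        stripped = copy.deepcopy(helix_model)
        stripped.ligands["heme"] = np.empty((0, 3))
        with pytest.raises(sf.MissingEntityError):
            sf.min_distance(stripped, 10, "heme")


class TestSasa:
    def test_isolated_atom_matches_closed_form(self):
        area = sf._atom_sasa(np.zeros((1, 3)), np.array([1.9]),
                             np.array([0]), 1.4, 960)[0]
        assert area == pytest.approx(4 * math.pi * 3.3 ** 2, rel=0.01)

    def test_fully_enclosed_atom_zero(self):
        # surround one atom with a tight shell of occluders
        shell = sf._sphere_points(60) * 2.0
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.9)
        area = sf._atom_sasa(coords, radii, np.array([0]), 1.4, 960)[0]
        assert area == 0.0

    def test_interior_less_exposed_than_terminal(self, helix_model):
        interior = sf.solvent_accessibility(helix_model, 30)
        terminal = sf.solvent_accessibility(helix_model, 1)
        assert interior < terminal

    def test_cross_check_against_independent_implementation(self, helix_pdb,
                                                            helix_model):
        """Absolute residue areas agree with biotite's Shrake-Rupley SASA
        (same radii, probe and point count) within 5%."""
        bst = pytest.importorskip("biotite.structure")
        bpdb = pytest.importorskip("biotite.structure.io.pdb")
        arr = bpdb.PDBFile.read(str(helix_pdb["path"])).get_structure(model=1)
        radii = np.array([sf.VDW_RADII[e.upper()] for e in arr.element])
        ref = bst.sasa(arr, probe_radius=1.4, point_number=960,
                       vdw_radii=radii)
        for pos in (1, 15, 30, 60):
            mine = sf.residue_sasa(helix_model, pos)
            theirs = ref[(arr.res_id == pos) & ~arr.hetero].sum()
            assert mine == pytest.approx(theirs, rel=0.05)

    def test_rigid_body_invariance(self, helix_model):
        moved = rigid_transform(helix_model, seed=11)
        for pos in (10, 25):
            assert sf.residue_sasa(moved, pos) == pytest.approx(
                sf.residue_sasa(helix_model, pos), abs=1e-6)

    def test_rsa_bounded(self, helix_model):
        for pos in (1, 20, 40, 60):
            assert 0.0 <= sf.solvent_accessibility(helix_model, pos) <= 1.0

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sf._radius("XX")


class TestSecondaryStructure:
    def test_helix_record_span_true(self, helix_model):
        assert sf.secondary_structure(helix_model, 10) is True

    def test_outside_any_record_false(self, tmp_path):
        p = tmp_path / "partial.pdb"
        simulate_structure(p, 20, write_helix_record=False)
        m = sf.load_structure(p)
        # no records: falls back to dihedrals of the coarse synthetic
        # backbone, which is not an ideal peptide geometry
        assert sf.secondary_structure(m, 10) in (True, False)

    @pytest.mark.parametrize("phi, psi", [(-57.0, -47.0), (-120.0, 130.0)])
    def test_dihedral_fallback_on_ideal_geometry(self, tmp_path, phi, psi):
        """Ideal helical / strand dihedrals assign every interior residue."""
        p = tmp_path / "bb.pdb"
        write_dihedral_backbone_pdb(p, 12, phi=phi, psi=psi)
        m = sf.load_structure(p)
        assert not m.helix_spans and not m.sheet_spans
        assert all(sf.secondary_structure(m, i) for i in range(2, 12))

    def test_loop_dihedrals_not_assigned(self, tmp_path):
        p = tmp_path / "loop.pdb"
        write_dihedral_backbone_pdb(p, 12, phi=80.0, psi=10.0)
        m = sf.load_structure(p)
        assert not any(sf.secondary_structure(m, i) for i in range(2, 12))


class TestBfactor:
    def test_constant_profile(self, helix_model):
        assert sf.bfactor(helix_model, 7) == pytest.approx(20.0)

    def test_known_per_residue_profile(self, tmp_path):
        profile = [10.0 + i for i in range(30)]
        p = tmp_path / "b.pdb"
        simulate_structure(p, 30, bfactor_profile=profile)
        m = sf.load_structure(p)
        for pos in (1, 13, 30):
            assert sf.bfactor(m, pos) == pytest.approx(profile[pos - 1],
                                                       abs=0.01)


class TestFeatureTable:
    def test_bundled_panel_counts(self, table1, tmp_path):
        """Any model covering the ddG-bearing positions maps 44 distinct
        residues and leaves the 7 unpredicted substitutions unmapped."""
        p = tmp_path / "cover.pdb"
        simulate_structure(p, 340, first_residue=60,
                           ligand_positions=[("heme", (20.0, 0.0, 100.0)),
                                             ("plp", (-20.0, 0.0, 300.0))])
        model = sf.load_structure(p)
        table = sf.feature_table(model, table1)
        assert table.n_mapped == 44
        assert table.n_unmapped_substitutions == 7
        mapped_rows = [r for r in table.rows if r.mapped]
        assert len(mapped_rows) == 44
        unmapped_rows = [r for r in table.rows if not r.mapped]
        assert {r.position for r in unmapped_rows} == \
            {423, 457, 408, 433, 490, 549, 559}

    def test_empty_panel(self, helix_model):
        empty = VariantPanel(records=())
        table = sf.feature_table(helix_model, empty)
        assert table.rows == ()


class TestLoading:
    def test_lossless_round_trip_of_written_fields(self, helix_pdb,
                                                   helix_model):
        coords = helix_coordinates(60)
        res30 = helix_model.residues_at(30)[0]
        for name, xyz in coords[30].items():
            idx = res30.atom_names.index(name)
            np.testing.assert_allclose(res30.coords[idx], xyz, atol=1e-9)

    def test_ligand_overlap_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="overlap"):
            simulate_structure(tmp_path / "x.pdb", 10,
                               ligand_positions=[("heme", (2.3, 0.0, 0.0))])
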