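import numpy as np
import pytest

import oracles
from foldswitch.contacts import (Atom, Coupling, Residue,
                                 Structure, backbone_hbond_geometry,
                                 classify_pair_geometry, optimize_threshold,
                                 pair_category_stats, parse_structure,
                                 true_contact)
from foldswitch.sspred import MSA


def _structure(residues):
    return Structure(id="test",
                     residues={("A", r.number): r for r in residues})


def _res(number, name, atoms):
    return Residue(chain="A", number=number, name=name,
                   atoms=[Atom(name=n, element=n[0], pos=p)
                          for n, p in atoms])


class TestParseStructure:
    def test_fixture_pdb_roundtrip(self, structure_fixtures, tmp_path):
        p = tmp_path / "helix.pdb"
        p.write_text(structure_fixtures.helix_pdb)
        st = parse_structure(p)
        assert len(st.residues) == 12
        res = st.get(1)
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O", "CB", "CG"}

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C\n"
            "END\n")
        p = tmp_path / "alt.pdb"
        p.write_text(pdb)
        st = parse_structure(p)
        ca = st.get(1).atom("CA")
        assert ca.pos[0] == pytest.approx(2.0)

    def test_hetatm_and_hydrogens_excluded(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  H   ALA A   1       0.500   0.500   0.000  1.00  0.00           H\n"
            "HETATM    3  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O\n"
            "END\n")
        p = tmp_path / "het.pdb"
        p.write_text(pdb)
        st = parse_structure(p)
        assert len(st.residues) == 1
        assert {a.name for a in st.get(1).atoms} == {"N"}

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError):
            parse_structure(p)


class TestTrueContact:
    def _pair_structure(self, distance):
        a = _res(10, "LEU", [("CA", (0.0, 0.0, 0.0)),
                             ("CB", (1.5, 0.0, 0.0))])
        b = _res(20, "ILE", [("CA", (1.5 + distance, 2.0, 0.0)),
                             ("CB", (1.5 + distance, 0.0, 0.0))])
        return _structure([a, b])

    def test_within_cutoff_with_sidechain(self):
        call = true_contact(Coupling(10, 20, 0.95),
                            [self._pair_structure(4.9)])
        assert call.is_true_positive and call.sidechain_involved
        assert call.min_heavy_distance == pytest.approx(4.9)

    def test_beyond_cutoff(self):
        call = true_contact(Coupling(10, 20, 0.95),
                            [self._pair_structure(5.1)])
        assert not call.is_true_positive

    def test_backbone_only_contact_not_true(self):
        a = _res(10, "GLY", [("CA", (0.0, 0.0, 0.0)), ("O", (1.0, 0.0, 0.0))])
        b = _res(20, "GLY", [("CA", (4.0, 0.0, 0.0)), ("N", (3.0, 0.0, 0.0))])
        call = true_contact(Coupling(10, 20, 0.9), [_structure([a, b])])
        assert not call.is_true_positive

    def test_exception_pair_true_at_5p2(self):
        a = _res(140, "ALA", [("CB", (0.0, 0.0, 0.0))])
        b = _res(151, "ALA", [("CB", (5.2, 0.0, 0.0))])
        call = true_contact(Coupling(140, 151, 0.9), [_structure([a, b])])
        assert call.is_true_positive and call.exception_applied

    def test_any_structure_suffices(self):
        call = true_contact(Coupling(10, 20, 0.9),
                            [self._pair_structure(8.0),
                             self._pair_structure(4.0)])
        assert call.is_true_positive

    def test_unresolved_flagged(self):
        call = true_contact(Coupling(1, 2, 0.9), [self._pair_structure(4.0)])
        assert call.matched_structure is None
        assert not call.is_true_positive

    def test_monotone_in_cutoff(self):
        st = self._pair_structure(4.9)
        for lo, hi in ((4.0, 5.0), (5.0, 6.0), (2.0, 8.0)):
            c_lo = true_contact(Coupling(10, 20, 0.9), [st], cutoff=lo)
            c_hi = true_contact(Coupling(10, 20, 0.9), [st], cutoff=hi)
            assert c_hi.is_true_positive or not c_lo.is_true_positive


class TestOptimizeThreshold:
    def test_all_true_returns_lowest(self):
        cps = [Coupling(1, 2, 0.5), Coupling(1, 3, 0.9)]
        truth = {c: True for c in cps}
        assert optimize_threshold(cps, truth) == 0.5

    def test_separating_threshold(self):
        cps = [Coupling(1, 5, 0.95), Coupling(2, 6, 0.9), Coupling(3, 7, 0.8)]
        truth = {cps[0]: True, cps[1]: True, cps[2]: False}
        assert optimize_threshold(cps, truth) == 0.9

    def test_no_true_positives_errors(self):
        cps = [Coupling(1, 5, 0.95)]
        with pytest.raises(ValueError):
            optimize_threshold(cps, {cps[0]: False})

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 50))
            probs = np.round(rng.uniform(0, 1, size=n), 3)
            truths = rng.random(n) < 0.5
            if not truths.any():
                truths[0] = True
            cps = [Coupling(i + 1, i + 2 + int(rng.integers(0, 5)),
                            float(p)) for i, p in enumerate(probs)]
            truth = {c: bool(t) for c, t in zip(cps, truths)}
            expected = oracles.scan_threshold([c.probability for c in cps],
                                              list(truths))
            assert optimize_threshold(cps, truth) == pytest.approx(expected)


class TestClassifyPairGeometry:
    def test_hydrophobic_pair(self):
        a = _res(1, "LEU", [("CA", (0, 0, 0)), ("CG", (1.5, 0, 0)),
                            ("CD1", (2.5, 0, 0))])
        b = _res(5, "ILE", [("CA", (9, 0, 0)), ("CG1", (7.5, 0, 0)),
                            ("CD1", (6.5, 0, 0))])
        cats = classify_pair_geometry(_structure([a, b]), 1, 5)
        assert cats == {"hydrophobic"}

    def test_salt_bridge(self):
        lys = _res(2, "LYS", [("CE", (-1.4, 0.5, 0.0)), ("NZ", (0, 0, 0))])
        glu = _res(8, "GLU", [("CD", (4.9, 0.5, 0.0)), ("OE1", (3.5, 0, 0))])
        cats = classify_pair_geometry(_structure([lys, glu]), 2, 8)
        assert "coulombic" in cats

    def test_salt_bridge_rejected_at_acute_angle(self):
        # antecedent carbon between the charges: angle < 90 at the oxygen
        lys = _res(2, "LYS", [("CE", (-1.4, 0.5, 0.0)), ("NZ", (0, 0, 0))])
        glu = _res(8, "GLU", [("CD", (2.3, 0.2, 0.0)), ("OE1", (3.5, 0, 0))])
        cats = classify_pair_geometry(_structure([lys, glu]), 2, 8)
        assert "coulombic" not in cats

    def test_serine_cap_geometry(self):
        # Ser OG 2.9 A from a backbone O, both angle tests obtuse
        ser = _res(9, "SER", [("CB", (0.0, 1.4, 0.0)), ("OG", (0, 0, 0))])
        cap = _res(5, "ALA", [("C", (4.0, 1.2, 0.0)), ("O", (2.9, 0, 0))])
        cats = classify_pair_geometry(_structure([ser, cap]), 5, 9)
        assert "helix_cap" in cats

    def test_like_charges_not_coulombic(self):
        lys = _res(2, "LYS", [("CE", (-1.4, 0.5, 0.0)), ("NZ", (0, 0, 0))])
        lys2 = _res(8, "LYS", [("CE", (4.9, 0.5, 0.0)), ("NZ", (3.5, 0, 0))])
        cats = classify_pair_geometry(_structure([lys, lys2]), 2, 8)
        assert "coulombic" not in cats


class TestGeometryFixtures:
    def test_helix_backbone_hbonds_every_interior_residue(self, structure_fixtures):
        st = structure_fixtures.helix_structure
        assert all(backbone_hbond_geometry(st, i) for i in range(5, 13))

    def test_helix_i_ip4_true_contacts(self, structure_fixtures):
        st = structure_fixtures.helix_structure
        for i in range(1, 9):
            call = true_contact(Coupling(i, i + 4, 1.0), [st], exceptions=())
            assert call.is_true_positive

    def test_strand_pair_cross_contacts_no_caps(self, structure_fixtures):
        fx = structure_fixtures
        assert fx.sheet_contacts, "expected cross-strand contacts"
        assert all(i <= 8 < j for i, j in fx.sheet_contacts)
        assert not any(j - i == 4 for i, j in fx.sheet_contacts)
        for i, j in fx.sheet_contacts:
            cats = classify_pair_geometry(fx.sheet_structure, i, j)
            assert "helix_cap" not in cats

    def test_ground_truth_matches_true_contact(self, structure_fixtures):
        fx = structure_fixtures
        n = len(fx.helix_structure.residues)
        recomputed = [
            (i, j) for i in range(1, n + 1) for j in range(i + 2, n + 1)
            if true_contact(Coupling(i, j, 1.0), [fx.helix_structure],
                            exceptions=()).is_true_positive]
        assert recomputed == fx.helix_contacts


class TestPairCategoryStats:
    def test_all_leucine_columns(self):
        msa = MSA(rows=[(f"r{i}", "LLLL") for i in range(5)])
        stats = pair_category_stats(msa, [Coupling(1, 3, 0.9)])
        assert stats[0].fraction_both_hydrophobic == 1.0
        assert stats[0].fraction_one_charged == 0.0

    def test_constructed_fractions(self):
        rows = [(f"r{i}", "LV") for i in range(8)] + \
               [(f"r{i+8}", "LD") for i in range(2)]
        stats = pair_category_stats(MSA(rows=rows), [Coupling(1, 2, 0.9)])
        assert stats[0].fraction_both_hydrophobic == pytest.approx(0.8)
        assert stats[0].fraction_one_charged == pytest.approx(0.2)

    def test_both_charged_does_not_count(self):
        msa = MSA(rows=[(f"r{i}", "KE") for i in range(4)])
        stats = pair_category_stats(msa, [Coupling(1, 2, 0.9)])
        assert stats[0].fraction_one_charged == 0.0
        assert stats[0].fraction_cap_capable == 1.0

    def test_row_permutation_invariant(self, rng):
        rows = [(f"r{i}", "".join(rng.choice(list("LKDE-SA"), size=4)))
                for i in range(12)]
        msa = MSA(rows=rows)
        c = Coupling(1, 4, 0.9)
        try:
            base = pair_category_stats(msa, [c])[0]
        except ValueError:
            pytest.skip("all-gap draw")
        perm = MSA(rows=[rows[i] for i in rng.permutation(12)])
        again = pair_category_stats(perm, [c])[0]
        assert again.fraction_both_hydrophobic == base.fraction_both_hydrophobic
        assert again.fraction_one_charged == base.fraction_one_charged
        assert again.fraction_cap_capable == base.fraction_cap_capable

    def test_all_gap_column_errors(self):
        msa = MSA(rows=[("a", "L-"), ("b", "L-")])
        with pytest.raises(ValueError):
            pair_category_stats(msa, [Coupling(1, 2, 0.9)])
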