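"""PSFM construction, accessibility, secondary structure, matrix assembly."""

import numpy as np
import pytest

from metalsites.features import (AA_ORDER, FEATURE_NAMES, N_FEATURES,
                                 ROLE_COLS, SS_COLS, SiteFeatureMatrix,
                                 assemble_features, parse_dssp, psfm_from_msa,
                                 read_alignment_a3m,
                                 secondary_structure_fallback,
                                 SecondaryStructureRecord)
from metalsites.sasa import (AccessibilityRecord, parse_rsa,
                             relative_from_absolute, sasa_shrake_rupley,
                             MAX_SASA_TIEN)


class TestPSFM:
    def test_identical_sequences_give_one_hots(self):
        psfm = psfm_from_msa(["ACD", "ACD", "ACD"])
        assert psfm.length == 3
        assert psfm.freqs[0, AA_ORDER.index("A")] == 1.0
        assert psfm.freqs[1, AA_ORDER.index("C")] == 1.0
        assert psfm.freqs.sum(axis=1) == pytest.approx([1, 1, 1])

    def test_column_frequencies(self):
        psfm = psfm_from_msa(["A", "A", "C"])
        assert psfm.freqs[0, AA_ORDER.index("A")] == pytest.approx(2 / 3)
        assert psfm.freqs[0, AA_ORDER.index("C")] == pytest.approx(1 / 3)

    def test_majority_gap_column_masked_with_query_one_hot(self):
        psfm = psfm_from_msa(["H", "-", "-"])
        assert psfm.masked[0]
        assert psfm.freqs[0, AA_ORDER.index("H")] == 1.0

    def test_query_gap_columns_dropped(self):
        psfm = psfm_from_msa(["A-C", "AGC", "AGC"])
        assert psfm.length == 2  # middle column dropped (query gapped)

    def test_nonstandard_residues_ignored(self):
        psfm = psfm_from_msa(["A", "X", "A"])
        assert psfm.freqs[0, AA_ORDER.index("A")] == 1.0

    def test_row_stochastic_property(self, rng):
        """Unmasked rows sum to 1; masked rows are valid one-hots."""
        alphabet = AA_ORDER + "-"
        for _ in range(20):
            n, w = int(rng.integers(2, 8)), int(rng.integers(1, 15))
            msa = ["".join(rng.choice(list(AA_ORDER), size=w))]
            msa += ["".join(rng.choice(list(alphabet), size=w))
                    for _ in range(n - 1)]
            psfm = psfm_from_msa(msa)
            sums = psfm.freqs.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)
            for p in np.flatnonzero(psfm.masked):
                assert sorted(psfm.freqs[p])[-1] == 1.0

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            psfm_from_msa(["AC", "A"])

    def test_query_index_out_of_range(self):
        with pytest.raises(IndexError):
            psfm_from_msa(["AC"], query_row=5)

    def test_a3m_lowercase_removed(self, tmp_path):
        p = tmp_path / "aln.a3m"
        p.write_text(">q\nACD\n>s\nAcCD\n")
        rows = read_alignment_a3m(p)
        assert rows == ["ACD", "ACD"]


def _lone_residue_model():
    from metalsites.structures import Atom, StructureModel

    # a single alanine-like residue, atoms ~1.5 Å apart
    coords = [(0, 0, 0), (1.5, 0, 0), (2.3, 1.2, 0), (1.6, -1.4, 0.4)]
    names = ["N", "CA", "C", "CB"]
    elements = ["N", "C", "C", "C"]
    atoms = [
        Atom(element=e, name=n, coords=c, residue_key=("A", 1, ""),
             residue_name="ALA", is_hetero=False)
        for e, n, c in zip(elements, names, coords)
    ]
    return StructureModel(atoms=atoms)


class TestSASA:
    def test_isolated_residue_matches_dense_mesh(self):
        """Default mesh agrees with a 10× denser recomputation within 5%."""
        model = _lone_residue_model()
        coarse = sasa_shrake_rupley(model, "A", points_per_atom=960)
        dense = sasa_shrake_rupley(model, "A", points_per_atom=9600)
        assert coarse[0].absolute == pytest.approx(dense[0].absolute, rel=0.05)

    def test_cross_check_against_reference_implementation(self):
        """Independent Shrake–Rupley (biotite) agrees within mesh error."""
        biotite_struct = pytest.importorskip("biotite.structure")
        model = _lone_residue_model()
        ours = sasa_shrake_rupley(model, "A", points_per_atom=2000)

        arr = biotite_struct.AtomArray(len(model.atoms))
        for i, a in enumerate(model.atoms):
            arr.coord[i] = a.coords
            arr.chain_id[i] = "A"
            arr.res_id[i] = 1
            arr.res_name[i] = "ALA"
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        ref = float(np.nansum(
            biotite_struct.sasa(arr, point_number=2000, vdw_radii="Single")
        ))
        assert ours[0].absolute == pytest.approx(ref, rel=0.05)

    def test_enclosed_residue_is_buried(self):
        from metalsites.structures import Atom, StructureModel

        atoms = [Atom(element="C", name="CA", coords=(0, 0, 0),
                      residue_key=("A", 1, ""), residue_name="GLY",
                      is_hetero=False)]
        # cage of atoms on a sphere of radius 3 Å
        golden = np.pi * (3 - 5 ** 0.5)
        for i in range(80):
            z = 1 - 2 * (i + 0.5) / 80
            r = np.sqrt(1 - z * z)
            th = golden * i
            atoms.append(Atom(
                element="C", name="CB", coords=(3 * r * np.cos(th),
                                                3 * r * np.sin(th), 3 * z),
                residue_key=("A", 2, ""), residue_name="GLY", is_hetero=False))
        model = StructureModel(atoms=atoms)
        rec = sasa_shrake_rupley(model, "A")
        assert rec[0].absolute < 1.0  # enclosed

    def test_distant_atom_is_irrelevant(self):
        from metalsites.structures import Atom, StructureModel

        model = _lone_residue_model()
        far = Atom(element="C", name="CA", coords=(50.0, 0, 0),
                   residue_key=("A", 2, ""), residue_name="GLY",
                   is_hetero=False)
        with_far = StructureModel(atoms=model.atoms + [far])
        a = sasa_shrake_rupley(model, "A")[0].absolute
        b = sasa_shrake_rupley(with_far, "A")[0].absolute
        assert a == pytest.approx(b, abs=1e-9)

    def test_missing_chain_errors(self):
        with pytest.raises(ValueError, match="no protein atoms"):
            sasa_shrake_rupley(_lone_residue_model(), "Z")


class TestRSA:
    def test_parse_naccess_style(self, tmp_path):
        p = tmp_path / "x.rsa"
        p.write_text(
            "REM  File of summed (Sum) and % (per.) accessibilities\n"
            "RES CYS A  10    51.2  38.9  40.1  35.0  11.1  60.2\n"
            "RES HIS A  14    20.0  10.9  18.1  11.0   1.9   8.2\n"
        )
        recs = parse_rsa(p)
        assert [r.position for r in recs] == [1, 2]
        assert recs[0].absolute == pytest.approx(51.2)
        assert recs[0].relative == pytest.approx(38.9)

    def test_parse_without_chain_column(self, tmp_path):
        p = tmp_path / "x.rsa"
        p.write_text("RES CYS   10    51.2  38.9  40.1  35.0  11.1  60.2\n")
        recs = parse_rsa(p)
        assert recs[0].absolute == pytest.approx(51.2)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.rsa"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert parse_rsa(p) == []

    def test_malformed_line_errors(self, tmp_path):
        p = tmp_path / "bad.rsa"
        p.write_text("RES CYS A ten nonsense\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_rsa(p)


class TestRelativeSASA:
    def test_endpoints(self):
        recs = [AccessibilityRecord(1, 0.0), AccessibilityRecord(2, 129.0)]
        out = relative_from_absolute(recs, ["ALA", "ALA"])
        assert out[0].relative == 0.0
        assert out[1].relative == pytest.approx(100.0)

    def test_above_reference_allowed(self):
        recs = [AccessibilityRecord(1, MAX_SASA_TIEN["GLY"] * 1.1)]
        out = relative_from_absolute(recs, ["GLY"])
        assert out[0].relative == pytest.approx(110.0)

    def test_nonstandard_flagged_zero(self):
        with pytest.warns(UserWarning, match="nonstandard"):
            out = relative_from_absolute(
                [AccessibilityRecord(1, 42.0)], ["LIG"])
        assert out[0].relative == 0.0


class TestSecondaryStructure:
    def test_dssp_state_mapping(self, tmp_path):
        header = "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
        #          pos 0....5....11 13  16
        rows = [
            "    1    1 A M  H  >  -",
            "    2    2 A K  B     -",
            "    3    3 A V  T     -",
            "    4    4 A L        -",
        ]
        p = tmp_path / "x.dssp"
        p.write_text(header + "\n".join(rows) + "\n")
        recs = parse_dssp(p, "A")
        assert [r.klass for r in recs] == ["helix", "sheet", "turn", "other"]

    def test_fallback_short_chain_is_other(self):
        recs = secondary_structure_fallback(np.zeros((2, 3)))
        assert [r.klass for r in recs] == ["other", "other"]

    def test_fallback_ideal_helix(self):
        # ideal alpha-helix trace: rise 1.5 Å, 100° per residue, r = 2.3 Å
        t = np.arange(12)
        coords = np.column_stack([
            2.3 * np.cos(np.deg2rad(100) * t),
            2.3 * np.sin(np.deg2rad(100) * t),
            1.5 * t,
        ])
        recs = secondary_structure_fallback(coords)
        assert sum(r.klass == "helix" for r in recs) >= 6


class TestAssemble:
    def _inputs(self, L=5):
        from metalsites.features import PSFM

        rng = np.random.default_rng(0)
        freqs = rng.dirichlet(np.ones(20), size=L)
        psfm = PSFM(freqs=freqs, masked=np.zeros(L, bool))
        roles = np.zeros(L, int)
        roles[0] = 2
        roles[1] = 1
        acc = [AccessibilityRecord(i + 1, 10.0 * i, 5.0 * i) for i in range(L)]
        ss = [SecondaryStructureRecord(i + 1, "helix") for i in range(L)]
        return "ACDEF"[:L], roles, psfm, acc, ss

    def test_shape_and_column_semantics(self):
        sfm = assemble_features(*self._inputs(), label="physiological",
                                site_id="s1")
        assert sfm.values.shape == (5, N_FEATURES)
        assert sfm.values[0, ROLE_COLS[0]] == 1.0  # ligand one-hot
        assert sfm.values[1, ROLE_COLS[1]] == 1.0
        assert sfm.values[2, ROLE_COLS[2]] == 1.0
        assert (sfm.values[:, list(ROLE_COLS)].sum(axis=1) == 1.0).all()
        assert (sfm.values[:, list(SS_COLS)].sum(axis=1) == 1.0).all()
        assert sfm.values[3, 20] == pytest.approx(30.0)
        assert sfm.values[3, 21] == pytest.approx(15.0)

    def test_permutation_safe(self):
        seq, roles, psfm, acc, ss = self._inputs()
        a = assemble_features(seq, roles, psfm, acc, ss)
        b = assemble_features(seq, roles, psfm, list(reversed(acc)),
                              list(reversed(ss)))
        assert np.array_equal(a.values, b.values)

    def test_length_mismatch_names_input(self):
        seq, roles, psfm, acc, ss = self._inputs()
        with pytest.raises(ValueError, match="accessibility"):
            assemble_features(seq, roles, psfm, acc[:-1], ss)

    def test_roundtrip_bitwise(self, tmp_path, small_dataset):
        sfm = small_dataset.sites[0]
        path = tmp_path / "site.tsv"
        sfm.write(path)
        back = SiteFeatureMatrix.read(path)
        assert np.array_equal(back.values, sfm.values)
        assert back.label == sfm.label
        assert back.site_id == sfm.site_id

    def test_feature_names_stable(self):
        assert len(FEATURE_NAMES) == N_FEATURES == 29
        assert FEATURE_NAMES[0] == "freq_A"
        assert FEATURE_NAMES[20] == "abs_sasa"
        assert FEATURE_NAMES[22] == "role_ligand"
        assert FEATURE_NAMES[28] == "ss_other"
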