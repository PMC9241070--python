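"""Structure parsing and geometric site extraction."""

import numpy as np
import pytest

from metalsites.structures import (MetalSite, StructureModel, binding_roles,
                                   build_sites, chain_residues, donor_atoms,
                                   filter_sites, find_metal_atoms,
                                   read_structure, Atom, StructureParseError)
from metalsites.synthetic import (ToyAtom, generate_toy_structure,
                                  random_structure_text)

from conftest import brute_force_sites


MINIMAL_PDB = """\
ATOM      1  SG  CYS A  10       0.000   0.000   2.300  1.00  0.00           S
HETATM    2 ZN    ZN A 900       0.000   0.000   0.000  1.00  0.00          ZN
END
"""


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert len(model.atoms) == 2
        assert model.chains == {"A"}
        zn = [a for a in model.atoms if a.element == "Zn"][0]
        assert zn.is_hetero

    def test_mmcif_parity(self, tmp_path, zinc_pdb_text):
        """The same coordinates parsed from PDB and mmCIF agree exactly."""
        import gemmi

        p = tmp_path / "site.pdb"
        p.write_text(zinc_pdb_text)
        st = gemmi.read_structure(str(p))
        st.setup_entities()
        cif = tmp_path / "site.cif"
        st.make_mmcif_document().write_file(str(cif))

        m_pdb = read_structure(p, format="pdb")
        m_cif = read_structure(cif, format="mmcif")
        assert len(m_pdb.atoms) == len(m_cif.atoms)
        c1 = sorted(map(tuple, m_pdb.coords_array().tolist()))
        c2 = sorted(map(tuple, m_cif.coords_array().tolist()))
        assert np.allclose(c1, c2, atol=1e-6)

    def test_first_model_only(self, tmp_path):
        text = (
            "MODEL        1\n" + MINIMAL_PDB.replace("END\n", "ENDMDL\n")
            + "MODEL        2\n"
            + "ATOM      3  SG  CYS A  11       9.000   0.000   2.300  1.00"
            + "  0.00           S\nENDMDL\nEND\n"
        )
        p = tmp_path / "two_models.pdb"
        p.write_text(text)
        model = read_structure(p)
        assert len(model.atoms) == 2  # second model discarded

    def test_altloc_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  SG ACYS A  10       0.000   0.000   2.300  0.40"
            "  0.00           S\n"
            "ATOM      2  SG BCYS A  10       1.000   0.000   2.300  0.60"
            "  0.00           S\nEND\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        model = read_structure(p)
        assert len(model.atoms) == 1
        assert model.atoms[0].altloc == "B"
        # tie → lowest altloc character
        text_tie = text.replace("0.40", "0.60")
        p.write_text(text_tie)
        model = read_structure(p)
        assert model.atoms[0].altloc == "A"

    def test_empty_structure_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(StructureParseError):
            read_structure(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")


class TestFindMetals:
    def _model(self, *elems):
        atoms = [
            Atom(element=e, name=e.upper(), coords=(float(i), 0, 0),
                 residue_key=("A", 900 + i, ""), residue_name=e.upper(),
                 is_hetero=True)
            for i, e in enumerate(elems)
        ]
        return StructureModel(atoms=atoms)

    def test_selects_by_element(self):
        model = self._model("Zn", "Fe")
        assert [a.element for a in find_metal_atoms(model, {"Zn"})] == ["Zn"]
        assert len(find_metal_atoms(model, {"Zn", "Fe"})) == 2

    def test_metal_free(self):
        model = self._model("Ca")
        assert find_metal_atoms(model, {"Zn"}) == []

    def test_empty_element_set_rejected(self):
        with pytest.raises(ValueError):
            find_metal_atoms(self._model("Zn"), set())


class TestDonorAtoms:
    def test_strict_cutoff_and_hydrogen_rule(self, tmp_path):
        text = generate_toy_structure([
            ToyAtom("S", "SG", "CYS", 10, 2.30, (1, 0, 0)),
            ToyAtom("O", "OD1", "ASP", 20, 3.00, (0, 1, 0)),  # exactly 3.0: out
            ToyAtom("H", "HG", "CYS", 10, 1.00, (0, 0, 1)),   # hydrogen: out
            ToyAtom("O", "O", "HOH", 500, 2.60, (0, -1, 0), hetero=True),
        ])
        p = tmp_path / "t.pdb"
        p.write_text(text)
        model = read_structure(p)
        zn = find_metal_atoms(model, {"Zn"})[0]
        donors = donor_atoms(model, zn)
        names = {(a.residue_name, a.name) for a in donors}
        assert ("CYS", "SG") in names
        assert ("HOH", "O") in names  # waters can be donors
        assert ("ASP", "OD1") not in names
        assert ("CYS", "HG") not in names

    def test_other_metals_never_donors(self, tmp_path):
        text = generate_toy_structure([
            ToyAtom("ZN", "ZN", "ZN", 901, 2.8, (1, 0, 0), hetero=True),
            ToyAtom("S", "SG", "CYS", 10, 2.3, (0, 1, 0)),
        ])
        p = tmp_path / "two_zn.pdb"
        p.write_text(text)
        model = read_structure(p)
        metals = find_metal_atoms(model, {"Zn"})
        assert len(metals) == 2
        for m in metals:
            assert all(a.element != "Zn" for a in donor_atoms(model, m))


class TestBuildSites:
    def test_classic_site_membership(self, zinc_model):
        sites = build_sites(zinc_model)
        assert len(sites) == 1
        s = sites[0]
        lig_names = {(k[1], n) for k, n in s.ligand_residues}
        assert lig_names == {(10, "CYS"), (13, "CYS"), (14, "HIS"), (30, "HIS")}
        env_names = {(k[1], n) for k, n in s.environment_residues}
        assert (40, "ASP") in env_names
        assert s.protein_ligand_count == 4
        assert s.protein_donor_count == 4
        assert s.chain_of_record == "A"

    def test_shared_ligand_merge(self, tmp_path):
        # second zinc placed so both bind the same Asp carboxylate
        text = generate_toy_structure([
            ToyAtom("O", "OD1", "ASP", 30, 2.0, (1, 0, 0)),
            ToyAtom("O", "OD2", "ASP", 30, 2.4, (1, 0.4, 0)),
            ToyAtom("ZN", "ZN", "ZN", 901, 4.0, (1, 0, 0), hetero=True),
        ])
        p = tmp_path / "dizinc.pdb"
        p.write_text(text)
        model = read_structure(p)
        sites = build_sites(model)
        assert len(sites) == 1
        assert len(sites[0].metal_atoms) == 2

    def test_merge_partitions_metals_and_is_idempotent(self, rng):
        for trial in range(5):
            text = random_structure_text(
                np.random.default_rng(500 + trial), n_metals=3, n_residues=25
            )
            model = _model_from_text(text)
            sites = build_sites(model)
            n_metals = sum(len(s.metal_atoms) for s in sites)
            assert n_metals == len(find_metal_atoms(model))
            again = build_sites(model)
            assert [s.ligand_residues for s in again] == \
                [s.ligand_residues for s in sites]

    def test_matches_brute_force_oracle(self):
        """Site membership equals an all-pairs distance recomputation."""
        for trial in range(25):
            rng = np.random.default_rng(1000 + trial)
            model = _model_from_text(random_structure_text(rng))
            expected = brute_force_sites(model)
            got = build_sites(model)
            exp = {(s["metals"], s["ligands"], s["environment"])
                   for s in expected}
            act = {
                (frozenset(tuple(a.coords) for a in s.metal_atoms),
                 frozenset(s.ligand_residues),
                 frozenset(s.environment_residues))
                for s in got
            }
            assert act == exp

    def test_cutoff_monotonicity(self):
        model = _model_from_text(
            random_structure_text(np.random.default_rng(7)))
        small = build_sites(model, donor_cutoff=2.5, env_cutoff=4.0)
        large = build_sites(model, donor_cutoff=3.0, env_cutoff=5.0)
        small_members = set().union(*(
            s.ligand_residues | s.environment_residues for s in small
        )) if small else set()
        large_members = set().union(*(
            s.ligand_residues | s.environment_residues for s in large
        )) if large else set()
        assert small_members <= large_members

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(42)
        model = _model_from_text(random_structure_text(rng))
        # random rotation (QR) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(scale=30.0, size=3)
        moved = StructureModel(atoms=[
            Atom(element=a.element, name=a.name,
                 coords=tuple(q @ a.xyz + t), residue_key=a.residue_key,
                 residue_name=a.residue_name, is_hetero=a.is_hetero,
                 occupancy=a.occupancy, altloc=a.altloc)
            for a in model.atoms
        ], source_id=model.source_id)
        orig = build_sites(model)
        trans = build_sites(moved)
        assert [(s.ligand_residues, s.environment_residues) for s in orig] \
            == [(s.ligand_residues, s.environment_residues) for s in trans]


class TestFilterSites:
    def test_water_only_site_removed(self, tmp_path):
        text = generate_toy_structure([
            ToyAtom("O", "O", "HOH", 501 + i, 2.1 + 0.1 * i, d, hetero=True)
            for i, d in enumerate([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)])
        ])
        p = tmp_path / "w.pdb"
        p.write_text(text)
        sites = build_sites(read_structure(p))
        assert len(sites) == 1  # produced by extraction
        assert filter_sites(sites) == []  # removed by the protein-donor rule

    def test_heme_exclusion(self, tmp_path):
        text = generate_toy_structure([
            ToyAtom("N", "NA", "HEM", 600, 2.0, (1, 0, 0), hetero=True),
            ToyAtom("N", "NE2", "HIS", 20, 2.1, (0, 0, 1)),
        ], metal_element="FE")
        p = tmp_path / "heme.pdb"
        p.write_text(text)
        sites = build_sites(read_structure(p))
        assert filter_sites(sites, exclude_heme=True) == []
        assert len(filter_sites(sites, exclude_heme=False)) == 1

    def test_protein_site_retained(self, zinc_model):
        sites = build_sites(zinc_model)
        assert len(filter_sites(sites)) == 1


class TestBindingRoles:
    def test_role_labels(self, zinc_model):
        site = build_sites(zinc_model)[0]
        roles = binding_roles(site, "A", zinc_model)
        residues = chain_residues(zinc_model, "A")
        by_num = {key[1]: i for (key, _name), i in
                  zip(residues, range(len(residues)))}
        assert roles[by_num[10]] == 2  # ligand Cys
        assert roles[by_num[40]] == 1  # environment Asp
        assert set(roles) <= {0, 1, 2}

    def test_chain_without_site_is_all_zero(self, tmp_path):
        text = generate_toy_structure([
            ToyAtom("S", "SG", "CYS", 10, 2.3, (1, 0, 0)),
            ToyAtom("C", "CA", "GLY", 5, 30.0, (0, 0, 1), chain="B"),
        ])
        p = tmp_path / "b.pdb"
        p.write_text(text)
        model = read_structure(p)
        site = build_sites(model)[0]
        assert (binding_roles(site, "B", model) == 0).all()

    def test_unmappable_residue_errors(self, zinc_model):
        site = build_sites(zinc_model)[0]
        bad = MetalSite(
            site_id="x", metal_atoms=site.metal_atoms,
            donor_atoms=site.donor_atoms,
            ligand_residues={(("A", 999, ""), "CYS")},
            environment_residues=set(), chain_of_record="A",
        )
        with pytest.raises(KeyError, match="999"):
            binding_roles(bad, "A", zinc_model)


def _model_from_text(text: str) -> StructureModel:
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as f:
        f.write(text)
        name = f.name
    try:
        return read_structure(name)
    finally:
        os.unlink(name)
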