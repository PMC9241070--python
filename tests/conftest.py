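import numpy as np
import pytest

from metalsites.structures import StructureModel, read_structure
from metalsites.synthetic import (SyntheticSpec, ToyAtom, generate_dataset,
                                  generate_toy_structure)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


CLASSIC_ZINC_SITE = [
    # Cys2His2-like zinc coordination plus a second-sphere Asp
    ToyAtom("S", "SG", "CYS", 10, 2.30, (1, 0, 0)),
    ToyAtom("S", "SG", "CYS", 13, 2.35, (-1, 0, 0)),
    ToyAtom("N", "NE2", "HIS", 14, 2.10, (0, 1, 0)),
    ToyAtom("N", "NE2", "HIS", 30, 2.15, (0, -1, 0)),
    ToyAtom("O", "OD1", "ASP", 40, 6.80, (1.2, 0.5, 0)),  # 4.5 Å from Cys10 SG
]


@pytest.fixture
def zinc_pdb_text() -> str:
    return generate_toy_structure(CLASSIC_ZINC_SITE)


@pytest.fixture
def zinc_model(tmp_path, zinc_pdb_text) -> StructureModel:
    p = tmp_path / "zinc_site.pdb"
    p.write_text(zinc_pdb_text)
    return read_structure(p)


@pytest.fixture(scope="session")
def small_dataset():
    """60-site default-spec synthetic dataset shared across tests."""
    return generate_dataset(30, 30, seed=3)


def brute_force_sites(model, donor_cutoff=3.0, env_cutoff=5.0,
                      elements=frozenset({"Zn", "Fe"})):
    """Independent O(n²) re-derivation of the site-extraction rules.

    Works directly from the atom list with explicit all-pairs distances and
    a hand-rolled merge loop; returns per-site frozensets of metal
    positions, ligand residues and environment residues.
    """
    atoms = model.atoms
    coords = np.array([a.coords for a in atoms])
    elements = {e.capitalize() for e in elements}
    metals = [i for i, a in enumerate(atoms)
              if a.is_hetero and a.element.capitalize() in elements]
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)

    def ref(i):
        return (atoms[i].residue_key, atoms[i].residue_name)

    per_metal = []
    for m in metals:
        donors = [
            j for j in range(len(atoms))
            if j != m
            and not atoms[j].is_hydrogen
            and atoms[j].element.capitalize() not in elements
            and dist[m, j] < donor_cutoff
        ]
        per_metal.append(donors)

    # merge metals sharing a ligand residue, to a fixed point
    groups = [{i} for i in range(len(metals))]
    changed = True
    while changed:
        changed = False
        for a_i in range(len(groups)):
            for b_i in range(a_i + 1, len(groups)):
                la = {ref(j) for i in groups[a_i] for j in per_metal[i]}
                lb = {ref(j) for i in groups[b_i] for j in per_metal[i]}
                if la & lb:
                    groups[a_i] |= groups[b_i]
                    del groups[b_i]
                    changed = True
                    break
            if changed:
                break

    heavy = [i for i, a in enumerate(atoms)
             if not a.is_hydrogen and i not in metals]
    sites = []
    for g in groups:
        ligands = {ref(j) for i in g for j in per_metal[i]}
        lig_atoms = [i for i in heavy if ref(i) in ligands]
        environment = set()
        for i in heavy:
            if ref(i) in ligands:
                continue
            if any(dist[i, j] < env_cutoff for j in lig_atoms):
                environment.add(ref(i))
        environment -= {ref(metals[i]) for i in g}
        sites.append({
            "metals": frozenset(tuple(atoms[metals[i]].coords) for i in g),
            "ligands": frozenset(ligands),
            "environment": frozenset(environment),
        })
    return sites
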