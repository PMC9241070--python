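"""Parse protein structures and extract metal-binding sites (MBSs).

A metal-binding site is defined geometrically, following the MetalPDB
convention: the *donor atoms* of a metal are the non-hydrogen atoms lying
strictly within 3.0 Å of it; the residues or small molecules contributing at
least one donor atom are the *metal ligands* (first coordination sphere); the
full site additionally contains every species with at least one heavy atom
strictly within 5.0 Å of any atom of a ligand (the *environment*, or second
coordination sphere).  Metals sharing a ligand residue are merged into a
single polynuclear site.

Only the asymmetric-unit content of the first model is used, with the
highest-occupancy alternate conformation retained per atom.  No symmetry
expansion is attempted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "StructureModel",
    "MetalSite",
    "StructureParseError",
    "read_structure",
    "find_metal_atoms",
    "donor_atoms",
    "build_sites",
    "filter_sites",
    "binding_roles",
    "chain_residues",
    "chain_sequence",
    "DEFAULT_METALS",
    "DEFAULT_DONOR_CUTOFF",
    "DEFAULT_ENV_CUTOFF",
    "HEME_CODES",
    "STANDARD_AA",
    "WATER_CODES",
]

DEFAULT_METALS = frozenset({"Zn", "Fe"})
DEFAULT_DONOR_CUTOFF = 3.0
DEFAULT_ENV_CUTOFF = 5.0
HEME_CODES = frozenset({"HEM", "HEA", "HEB", "HEC"})
WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """One atom of the retained model."""

    element: str
    name: str
    coords: tuple[float, float, float]
    residue_key: tuple[str, int, str]  # (chain id, residue number, insertion code)
    residue_name: str
    is_hetero: bool
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def chain(self) -> str:
        return self.residue_key[0]


@dataclass
class StructureModel:
    """Atoms of a single model of a structure."""

    atoms: list[Atom]
    source_id: str = ""
    model_number: int = 1

    @property
    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


# residue reference: (residue_key, residue_name)
ResidueRef = tuple[tuple[str, int, str], str]


def _is_protein(ref: ResidueRef) -> bool:
    return ref[1] in STANDARD_AA


def _is_water(ref: ResidueRef) -> bool:
    return ref[1] in WATER_CODES


@dataclass
class MetalSite:
    """A metal site: metals + first coordination sphere + environment."""

    site_id: str
    metal_atoms: list[Atom]
    donor_atoms: list[Atom]
    ligand_residues: set[ResidueRef]
    environment_residues: set[ResidueRef]
    chain_of_record: str

    @property
    def protein_ligands(self) -> set[ResidueRef]:
        return {r for r in self.ligand_residues if _is_protein(r)}

    @property
    def protein_environment(self) -> set[ResidueRef]:
        return {r for r in self.environment_residues if _is_protein(r)}

    @property
    def protein_donor_count(self) -> int:
        return sum(
            1 for a in self.donor_atoms
            if (a.residue_key, a.residue_name) in self.protein_ligands
        )

    @property
    def protein_ligand_count(self) -> int:
        return len(self.protein_ligands)

    @property
    def site_residue_count(self) -> int:
        return len(self.protein_ligands) + len(self.protein_environment)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "metals": [a.element for a in self.metal_atoms],
            "chain_of_record": self.chain_of_record,
            "donor_atoms": [
                {"name": a.name, "element": a.element,
                 "residue": list(a.residue_key), "residue_name": a.residue_name}
                for a in self.donor_atoms
            ],
            "ligand_residues": sorted([list(k) + [n] for k, n in self.ligand_residues]),
            "environment_residues": sorted(
                [list(k) + [n] for k, n in self.environment_residues]
            ),
            "protein_donor_count": self.protein_donor_count,
            "protein_ligand_count": self.protein_ligand_count,
            "site_residue_count": self.site_residue_count,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model's atoms are retained.  For alternate locations the
    highest-occupancy conformer wins (ties broken by lowest altloc character).
    Hydrogens are kept but flagged by element.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no models in structure")
    model = st[0]

    # keep best altloc per (residue key, atom name)
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            for at in res:
                alt = at.altloc if at.altloc not in ("", "\x00") else ""
                icode = res.seqid.icode.strip()
                atom = Atom(
                    element=at.element.name,
                    name=at.name,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    residue_key=(chain.name, res.seqid.num, icode),
                    residue_name=res.name,
                    is_hetero=(res.het_flag == "H"),
                    occupancy=float(at.occ),
                    altloc=alt,
                )
                key = (atom.residue_key, atom.residue_name, atom.name)
                prev = best.get(key)
                if prev is None:
                    best[key] = atom
                    order.append(key)
                elif (atom.occupancy, -ord(atom.altloc or "~")) > (
                    prev.occupancy, -ord(prev.altloc or "~")
                ):
                    best[key] = atom
    atoms = [best[k] for k in order]
    if not atoms:
        raise StructureParseError(f"{path}: structure contains no atoms")
    return StructureModel(atoms=atoms, source_id=path.stem, model_number=1)


def find_metal_atoms(
    model: StructureModel, elements: Iterable[str] = DEFAULT_METALS
) -> list[Atom]:
    """Hetero atoms whose element is in *elements*, in file order."""
    wanted = {e.capitalize() for e in elements}
    if not wanted:
        raise ValueError("element set must be non-empty")
    return [a for a in model.atoms if a.is_hetero and a.element.capitalize() in wanted]


def donor_atoms(
    model: StructureModel,
    metal: Atom,
    cutoff: float = DEFAULT_DONOR_CUTOFF,
    metal_elements: Iterable[str] = DEFAULT_METALS,
) -> list[Atom]:
    """Non-hydrogen atoms strictly within *cutoff* Å of *metal*.

    The metal itself and any other atom of the metal element set are never
    donors.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    excluded = {e.capitalize() for e in metal_elements}
    mpos = metal.xyz
    out = []
    for a in model.atoms:
        if a is metal or a.is_hydrogen or a.element.capitalize() in excluded:
            continue
        if np.linalg.norm(a.xyz - mpos) < cutoff:
            out.append(a)
    return out


def _residue_ref(atom: Atom) -> ResidueRef:
    return (atom.residue_key, atom.residue_name)


def build_sites(
    model: StructureModel,
    metals: Sequence[Atom] | None = None,
    donor_cutoff: float = DEFAULT_DONOR_CUTOFF,
    env_cutoff: float = DEFAULT_ENV_CUTOFF,
    metal_elements: Iterable[str] = DEFAULT_METALS,
) -> list[MetalSite]:
    """Extract one :class:`MetalSite` per metal, merging metals that share a
    ligand residue into polynuclear sites.

    Environment membership uses heavy atoms only, consistent with the donor
    rule; both cutoffs are strict inequalities.
    """
    if env_cutoff <= 0:
        raise ValueError("env_cutoff must be positive")
    if metals is None:
        metals = find_metal_atoms(model, metal_elements)
    metals = list(metals)
    if not metals:
        return []

    per_metal = [
        donor_atoms(model, m, donor_cutoff, metal_elements) for m in metals
    ]
    ligand_sets = [frozenset(_residue_ref(a) for a in donors) for donors in per_metal]

    # union-find merge of metals with intersecting ligand-residue sets
    parent = list(range(len(metals)))

    def root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(metals)):
        for j in range(i + 1, len(metals)):
            if ligand_sets[i] & ligand_sets[j]:
                parent[root(j)] = root(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(metals)):
        groups.setdefault(root(i), []).append(i)

    # heavy, non-metal atoms indexed by residue for environment search
    metal_ids = {id(m) for m in metals}
    heavy = [
        a for a in model.atoms
        if not a.is_hydrogen and id(a) not in metal_ids
    ]
    heavy_coords = (
        np.array([a.coords for a in heavy]) if heavy else np.zeros((0, 3))
    )
    tree = cKDTree(heavy_coords) if heavy else None

    sites = []
    for n, idxs in enumerate(sorted(groups.values(), key=lambda g: g[0])):
        site_metals = [metals[i] for i in idxs]
        donors: list[Atom] = []
        seen = set()
        for i in idxs:
            for a in per_metal[i]:
                k = (a.residue_key, a.name)
                if k not in seen:
                    seen.add(k)
                    donors.append(a)
        ligands = set().union(*(ligand_sets[i] for i in idxs))

        # environment: residues with >=1 heavy atom < env_cutoff from any
        # atom of any ligand residue, excluding the ligands themselves
        environment: set[ResidueRef] = set()
        if tree is not None and ligands:
            lig_atom_coords = np.array(
                [a.coords for a in heavy if _residue_ref(a) in ligands]
            )
            if len(lig_atom_coords):
                near = tree.query_ball_point(lig_atom_coords, env_cutoff)
                for hits in near:
                    for h in hits:
                        ref = _residue_ref(heavy[h])
                        if ref not in ligands:
                            environment.add(ref)
                # strict inequality: discard exact-boundary hits
                drop = set()
                for ref in environment:
                    pts = np.array(
                        [a.coords for a in heavy if _residue_ref(a) == ref]
                    )
                    d = np.linalg.norm(
                        pts[:, None, :] - lig_atom_coords[None, :, :], axis=-1
                    )
                    if not (d < env_cutoff).any():
                        drop.add(ref)
                environment -= drop

        # drop this site's own metals from environment bookkeeping
        environment -= {_residue_ref(m) for m in site_metals}

        donor_chain_counts: dict[str, int] = {}
        for a in donors:
            if _residue_ref(a) in ligands and _is_protein(_residue_ref(a)):
                donor_chain_counts[a.chain] = donor_chain_counts.get(a.chain, 0) + 1
        if donor_chain_counts:
            chain_of_record = min(
                donor_chain_counts, key=lambda c: (-donor_chain_counts[c], c)
            )
        else:
            chain_of_record = min(model.chains) if model.chains else ""

        elem = "".join(sorted({m.element.upper() for m in site_metals}))
        sites.append(
            MetalSite(
                site_id=f"{model.source_id or 'site'}_{elem}_{n + 1}",
                metal_atoms=site_metals,
                donor_atoms=donors,
                ligand_residues=ligands,
                environment_residues=environment,
                chain_of_record=chain_of_record,
            )
        )
    return sites


def filter_sites(
    sites: Iterable[MetalSite],
    exclude_heme: bool = True,
    heme_codes: Iterable[str] = HEME_CODES,
) -> list[MetalSite]:
    """Drop sites with no protein donor atoms and, optionally, heme sites."""
    heme = set(heme_codes)
    kept = []
    for s in sites:
        if s.protein_donor_count == 0:
            continue
        if exclude_heme and any(name in heme for _, name in s.ligand_residues):
            continue
        kept.append(s)
    return kept


def chain_residues(model: StructureModel, chain: str) -> list[ResidueRef]:
    """Protein residues of *chain* in coordinate-file order.

    Positions 1..L follow this order; gaps in author numbering do not create
    positional gaps.
    """
    seen = []
    have = set()
    for a in model.atoms:
        ref = _residue_ref(a)
        if a.chain == chain and _is_protein(ref) and ref not in have:
            have.add(ref)
            seen.append(ref)
    return seen


def chain_sequence(model: StructureModel, chain: str) -> str:
    """One-letter sequence of the observed protein residues of *chain*."""
    return "".join(
        _THREE_TO_ONE.get(name, "X") for _, name in chain_residues(model, chain)
    )


def binding_roles(
    site: MetalSite, chain: str, model: StructureModel
) -> np.ndarray:
    """Per-residue binding roles along the chain: 2 = metal ligand, 1 = other
    site residue (second sphere), 0 = rest of the protein."""
    residues = chain_residues(model, chain)
    index = {ref: i for i, ref in enumerate(residues)}
    roles = np.zeros(len(residues), dtype=int)
    for group, value in ((site.protein_environment, 1), (site.protein_ligands, 2)):
        for ref in group:
            if ref[0][0] != chain:
                continue
            if ref not in index:
                raise KeyError(
                    f"site residue {ref} not found among the observed residues "
                    f"of chain {chain!r}"
                )
            roles[index[ref]] = value
    return roles
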