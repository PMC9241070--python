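"""Solvent-accessible surface area (SASA).

Per-residue absolute SASA is computed with the Shrake–Rupley algorithm on the
isolated protein chain (metals, waters, other chains and het species removed,
so accessibility is measured without the metal ion present).  Relative SASA is
the absolute value as a percentage of a per-residue-type reference maximum
(theoretical maxima of Tien et al. 2013); values above 100 are allowed for
extended conformations.  NACCESS-style .rsa files are parsed when supplied and
take precedence over the internal computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structures import StructureModel, chain_residues, STANDARD_AA

__all__ = [
    "AccessibilityRecord",
    "sasa_shrake_rupley",
    "parse_rsa",
    "relative_from_absolute",
    "MAX_SASA_TIEN",
    "VDW_RADII",
]

# theoretical maximum accessible surface per residue type, Å² (Tien 2013)
MAX_SASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "MSE": 224.0,
}

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "D": 1.20,
}
_DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class AccessibilityRecord:
    """Solvent accessibility of one residue (1-based position)."""

    position: int
    absolute: float  # Å²
    relative: float | None = None  # percent of type maximum

    def __post_init__(self):
        if self.absolute < 0:
            raise ValueError("absolute SASA must be non-negative")
        if self.relative is not None and self.relative < 0:
            raise ValueError("relative SASA must be non-negative")


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa_shrake_rupley(
    model: StructureModel,
    chain: str,
    probe: float = 1.4,
    points_per_atom: int = 960,
) -> list[AccessibilityRecord]:
    """Per-residue absolute SASA of the isolated protein chain.

    Each heavy atom is surrounded by a mesh of ``points_per_atom`` test points
    at radius r_vdw + probe; points not buried inside any neighbouring
    atom's probe-expanded sphere count as exposed surface.
    """
    residues = chain_residues(model, chain)
    if not residues:
        raise ValueError(f"chain {chain!r} has no protein atoms")
    wanted = set(residues)
    atoms = [
        a for a in model.atoms
        if (a.residue_key, a.residue_name) in wanted and not a.is_hydrogen
    ]
    coords = np.array([a.coords for a in atoms])
    radii = np.array(
        [VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS) for a in atoms]
    )
    expanded = radii + probe
    mesh = _sphere_points(points_per_atom)
    tree = cKDTree(coords)
    max_r = expanded.max()

    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + expanded[i] * mesh
        neighbours = [
            j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
            if j != i
        ]
        if neighbours:
            d = np.linalg.norm(
                pts[:, None, :] - coords[neighbours][None, :, :], axis=-1
            )
            buried = (d < expanded[neighbours][None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed_frac

    index = {ref: p for p, ref in enumerate(residues)}
    per_res = np.zeros(len(residues))
    for a, area in zip(atoms, per_atom):
        per_res[index[(a.residue_key, a.residue_name)]] += area
    return [
        AccessibilityRecord(position=p + 1, absolute=float(v))
        for p, v in enumerate(per_res)
    ]


def parse_rsa(path: str | Path) -> list[AccessibilityRecord]:
    """Parse NACCESS-style .rsa output (``RES`` lines, all-atom ABS/REL).

    Handles both the dialect with a chain-id column and the one without.
    Residues are mapped to 1-based sequence positions in file order.
    """
    records = []
    position = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith("RES"):
            continue
        position += 1
        # RES <resname> [chain] <resnum> ABS REL ... ; chain column may be absent
        try:
            rest = line[4:]
            fields = rest.split()
            if len(fields) < 4:
                raise ValueError("too few fields")
            # fields[1] is either the chain id (len 1, non-numeric) or resnum
            if fields[1].lstrip("-").isdigit():
                abs_v, rel_v = float(fields[2]), float(fields[3])
            else:
                abs_v, rel_v = float(fields[3]), float(fields[4])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed RES line {lineno}: {line!r}") from exc
        records.append(
            AccessibilityRecord(position=position, absolute=abs_v, relative=rel_v)
        )
    if not records:
        warnings.warn(f"{path}: no RES lines found; empty accessibility")
    return records


def relative_from_absolute(
    records: list[AccessibilityRecord],
    residue_types: list[str],
    reference: dict[str, float] | None = None,
) -> list[AccessibilityRecord]:
    """Fill in relative SASA as 100 × absolute / reference[type].

    Nonstandard residue types get relative 0 (flagged with a warning); no
    clamping is applied, so values above 100 survive.
    """
    ref = MAX_SASA_TIEN if reference is None else reference
    missing = {t for t in residue_types if t not in ref and t in STANDARD_AA}
    if missing:
        raise ValueError(f"reference table lacks standard residues: {sorted(missing)}")
    if len(records) != len(residue_types):
        raise ValueError("records and residue_types length mismatch")
    out = []
    flagged = []
    for rec, rtype in zip(records, residue_types):
        if rtype in ref:
            rel = 100.0 * rec.absolute / ref[rtype]
        else:
            rel = 0.0
            flagged.append((rec.position, rtype))
        out.append(
            AccessibilityRecord(position=rec.position, absolute=rec.absolute,
                                relative=rel)
        )
    if flagged:
        warnings.warn(f"nonstandard residue types set to relative 0: {flagged}")
    return out
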