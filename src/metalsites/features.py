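"""Per-residue feature matrices (L × 29) describing a metal-binding site.

Each residue of the chain harbouring a site is encoded with 29 features:

* columns 0–19: sequence-conservation profile — the residue's row of the
  position-specific frequency matrix (PSFM) derived from an MSA, amino acids
  in the fixed order A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y;
* columns 20–21: absolute (Å²) and relative (%) solvent accessibility;
* columns 22–24: binding-role one-hot (metal ligand / second sphere / other);
* columns 25–28: secondary-structure one-hot (helix / sheet / turn / other).

The matrix is the classifier input; order and meaning of the columns are a
package convention (kept stable across the I/O round trip).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sasa import AccessibilityRecord

__all__ = [
    "AA_ORDER",
    "FEATURE_NAMES",
    "N_FEATURES",
    "COL_ABS_SASA",
    "COL_REL_SASA",
    "ROLE_COLS",
    "SS_COLS",
    "PSFM",
    "SecondaryStructureRecord",
    "SiteFeatureMatrix",
    "read_alignment_fasta",
    "read_alignment_a3m",
    "psfm_from_msa",
    "parse_dssp",
    "secondary_structure_fallback",
    "assemble_features",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

SS_CLASSES = ("helix", "sheet", "turn", "other")
ROLE_NAMES = ("role_ligand", "role_environment", "role_other")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"freq_{a}" for a in AA_ORDER]
    + ["abs_sasa", "rel_sasa"]
    + list(ROLE_NAMES)
    + [f"ss_{c}" for c in SS_CLASSES]
)
N_FEATURES = 29
COL_ABS_SASA = 20
COL_REL_SASA = 21
ROLE_COLS = (22, 23, 24)
SS_COLS = (25, 26, 27, 28)

_GAPS = {"-", "."}


@dataclass
class PSFM:
    """Position-specific frequency matrix projected onto the query sequence.

    ``freqs[p]`` holds the 20 amino-acid frequencies at query position p
    (AA_ORDER); positions whose alignment column is majority-gap are masked
    and carry the query's one-hot instead.
    """

    freqs: np.ndarray  # (L, 20)
    masked: np.ndarray  # (L,) bool

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


def read_alignment_fasta(path: str | Path) -> list[str]:
    """Aligned FASTA → list of equal-length rows."""
    from Bio import SeqIO

    rows = [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"{path}: no sequences")
    return rows


def read_alignment_a3m(path: str | Path) -> list[str]:
    """A3M → aligned rows; lowercase insertion states are removed."""
    from Bio import SeqIO

    rows = []
    for r in SeqIO.parse(str(path), "fasta"):
        rows.append("".join(c for c in str(r.seq) if not c.islower()))
    if not rows:
        raise ValueError(f"{path}: no sequences")
    return rows


def psfm_from_msa(
    msa: list[str], query_row: int = 0, gap_fraction: float = 0.5
) -> PSFM:
    """Build the PSFM for the query sequence of an alignment.

    Alignment columns where the query is gapped are dropped first (features
    are per query residue).  In each retained column the frequencies of the
    20 standard amino acids are counted over the sequences carrying a residue
    there; nonstandard residues are ignored.  Columns where strictly more
    than ``gap_fraction`` of the sequences are gapped are masked and receive
    the query one-hot, so every residue keeps a conservation row.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment: rows have different lengths")
    if not 0 <= query_row < len(msa):
        raise IndexError(f"query_row {query_row} out of range")

    query = msa[query_row]
    cols = [j for j, c in enumerate(query) if c not in _GAPS]
    n_seq = len(msa)
    L = len(cols)
    freqs = np.zeros((L, 20))
    masked = np.zeros(L, dtype=bool)
    for p, j in enumerate(cols):
        column = [row[j] for row in msa]
        n_gap = sum(1 for c in column if c in _GAPS)
        q = query[j].upper()
        if n_gap > gap_fraction * n_seq:
            masked[p] = True
            if q in _AA_INDEX:
                freqs[p, _AA_INDEX[q]] = 1.0
            continue
        counts = np.zeros(20)
        for c in column:
            idx = _AA_INDEX.get(c.upper())
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        if total == 0:  # column holds only nonstandard residues
            masked[p] = True
            if q in _AA_INDEX:
                freqs[p, _AA_INDEX[q]] = 1.0
        else:
            freqs[p] = counts / total
    return PSFM(freqs=freqs, masked=masked)


@dataclass(frozen=True)
class SecondaryStructureRecord:
    position: int
    klass: str = "other"

    def __post_init__(self):
        if self.klass not in SS_CLASSES:
            raise ValueError(f"unknown secondary-structure class {self.klass!r}")


_DSSP_MAP = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "sheet", "B": "sheet",
    "T": "turn",
}


def parse_dssp(path: str | Path, chain: str) -> list[SecondaryStructureRecord]:
    """Parse classic DSSP output; 8-state codes collapse to 4 classes
    (H,G,I → helix; E,B → sheet; T → turn; else other)."""
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError(f"{path}: no DSSP residue table found")
    records = []
    position = 0
    for line in lines[start:]:
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break marker
            continue
        if line[11].strip() != chain:
            continue
        position += 1
        records.append(
            SecondaryStructureRecord(
                position=position, klass=_DSSP_MAP.get(line[16].strip(), "other")
            )
        )
    return records


def secondary_structure_fallback(ca_coords: np.ndarray) -> list[SecondaryStructureRecord]:
    """Geometric secondary-structure assignment from Cα positions.

    Helix: d(i,i+3) ≈ 5.3 Å and d(i,i+4) ≈ 6.2 Å (tight turns of the helical
    wheel).  Sheet: extended backbone, d(i,i+3) ≳ 9.5 Å.  Turn: chain
    reversal, d(i,i+3) < 7 Å without the helical signature.  Everything
    else, and chains too short to measure, is "other".
    """
    n = len(ca_coords)
    classes = ["other"] * n
    if n >= 4:
        d3 = np.linalg.norm(ca_coords[3:] - ca_coords[:-3], axis=1)
        d4 = (
            np.linalg.norm(ca_coords[4:] - ca_coords[:-4], axis=1)
            if n >= 5 else np.array([])
        )
        for i in range(n - 3):
            helix = 4.5 <= d3[i] <= 6.0 and (i >= len(d4) or 5.0 <= d4[i] <= 6.8)
            if helix:
                classes[i] = "helix"
            elif d3[i] >= 9.5:
                classes[i] = "sheet"
            elif d3[i] < 7.0:
                classes[i] = "turn"
    return [
        SecondaryStructureRecord(position=i + 1, klass=c)
        for i, c in enumerate(classes)
    ]


@dataclass
class SiteFeatureMatrix:
    """The L × 29 classifier input for one site, with its label."""

    site_id: str
    values: np.ndarray  # (L, 29) float64
    label: str = "unknown"  # physiological | adventitious | unknown
    chain: str = ""
    positions: list[int] = field(default_factory=list)  # author residue numbers
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must be L×{N_FEATURES}, got {self.values.shape}"
            )
        if self.label not in ("physiological", "adventitious", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    # --- on-disk format: TSV of values + JSON sidecar -------------------
    def write(self, tsv_path: str | Path) -> None:
        tsv_path = Path(tsv_path)
        header = "\t".join(self.feature_names)
        np.savetxt(tsv_path, self.values, fmt="%.17g", delimiter="\t",
                   header=header, comments="")
        sidecar = {
            "site_id": self.site_id,
            "label": self.label,
            "chain": self.chain,
            "positions": list(map(int, self.positions)),
        }
        tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, tsv_path: str | Path) -> "SiteFeatureMatrix":
        tsv_path = Path(tsv_path)
        values = np.loadtxt(tsv_path, delimiter="\t", skiprows=1, ndmin=2)
        meta = json.loads(tsv_path.with_suffix(".json").read_text())
        return cls(
            site_id=meta["site_id"], values=values, label=meta["label"],
            chain=meta.get("chain", ""), positions=meta.get("positions", []),
        )


def assemble_features(
    sequence: str,
    roles: np.ndarray,
    psfm: PSFM,
    accessibility: list[AccessibilityRecord],
    secondary: list[SecondaryStructureRecord],
    label: str = "unknown",
    site_id: str = "",
    chain: str = "",
    positions: list[int] | None = None,
) -> SiteFeatureMatrix:
    """Combine per-residue inputs into the canonical L × 29 matrix.

    Binding roles are one-hot encoded (2 → ligand, 1 → environment,
    0 → other).  All inputs must cover positions 1..L; record order is
    irrelevant (records are keyed by position).
    """
    L = len(sequence)
    for name, n in (
        ("roles", len(roles)),
        ("psfm", psfm.length),
        ("accessibility", len(accessibility)),
        ("secondary structure", len(secondary)),
    ):
        if n != L:
            raise ValueError(
                f"{name} covers {n} positions but the sequence has {L}"
            )

    values = np.zeros((L, N_FEATURES))
    values[:, :20] = psfm.freqs
    for rec in accessibility:
        if rec.relative is None:
            raise ValueError(
                f"accessibility record at position {rec.position} lacks a "
                "relative value"
            )
        values[rec.position - 1, COL_ABS_SASA] = rec.absolute
        values[rec.position - 1, COL_REL_SASA] = rec.relative
    role_col = {2: ROLE_COLS[0], 1: ROLE_COLS[1], 0: ROLE_COLS[2]}
    for t, r in enumerate(np.asarray(roles, dtype=int)):
        values[t, role_col[int(r)]] = 1.0
    ss_col = {c: SS_COLS[i] for i, c in enumerate(SS_CLASSES)}
    for rec in secondary:
        values[rec.position - 1, ss_col[rec.klass]] = 1.0

    return SiteFeatureMatrix(
        site_id=site_id, values=values, label=label, chain=chain,
        positions=list(positions) if positions is not None else [],
    )
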