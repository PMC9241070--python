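"""Interpretable rule-of-thumb baseline for site classification.

Large, buried, highly coordinated sites are overwhelmingly physiological:
a site is called physiological when it involves at least 20 residues OR at
least 4 protein metal ligands (both thresholds inclusive), or — when a cutoff
is configured — when the mean absolute solvent accessibility of its ligands
falls below that cutoff.  No accessibility cutoff is set by default because
the accessibility distributions of the two classes overlap too much for a
reliable threshold.

Sites whose His ligands cluster near a chain terminus may reflect a poly-His
purification tag; this raises a warning but never changes the call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .classifier import NEGATIVE_CLASS, POSITIVE_CLASS
from .features import COL_ABS_SASA, ROLE_COLS, SiteFeatureMatrix
from .structures import MetalSite, chain_residues

__all__ = [
    "RuleConfig",
    "rule_classify",
    "site_summary",
    "summary_from_features",
    "RuleBaselineClassifier",
]


@dataclass(frozen=True)
class RuleConfig:
    min_site_residues: int = 20
    min_protein_ligands: int = 4
    ligand_sasa_cutoff: float | None = None  # Å², unset by default

    def __post_init__(self):
        if self.min_site_residues < 1 or self.min_protein_ligands < 1:
            raise ValueError("rule thresholds must be >= 1")
        if self.ligand_sasa_cutoff is not None and self.ligand_sasa_cutoff < 0:
            raise ValueError("ligand_sasa_cutoff must be non-negative")


def rule_classify(summary: dict, config: RuleConfig = RuleConfig()
                  ) -> tuple[str, list[str]]:
    """Classify a site summary; returns (class, fired-rule trace).

    The clauses combine with OR: each alone marks a site as extremely likely
    physiological.
    """
    if summary["site_residue_count"] < 0 or summary["protein_ligand_count"] < 0:
        raise ValueError("counts must be non-negative")
    fired = []
    if summary["site_residue_count"] >= config.min_site_residues:
        fired.append(
            f"site_residue_count >= {config.min_site_residues}"
        )
    if summary["protein_ligand_count"] >= config.min_protein_ligands:
        fired.append(
            f"protein_ligand_count >= {config.min_protein_ligands}"
        )
    if (config.ligand_sasa_cutoff is not None
            and summary.get("mean_ligand_sasa") is not None
            and summary["mean_ligand_sasa"] < config.ligand_sasa_cutoff):
        fired.append(f"mean_ligand_sasa < {config.ligand_sasa_cutoff}")
    if summary.get("n_terminal_his_ligands", 0) > 2:
        warnings.warn(
            f"site {summary.get('site_id', '?')}: >2 His ligands within a "
            "terminal 12-residue window — possible poly-His purification tag"
        )
    return (POSITIVE_CLASS if fired else NEGATIVE_CLASS), fired


def summary_from_features(sfm: SiteFeatureMatrix) -> dict:
    """Rule inputs read off a feature matrix alone (synthetic-friendly)."""
    v = sfm.values
    ligand_rows = v[:, ROLE_COLS[0]] == 1.0
    env_rows = v[:, ROLE_COLS[1]] == 1.0
    if not ligand_rows.any():
        raise ValueError(f"site {sfm.site_id}: no ligand rows in features")
    return {
        "site_id": sfm.site_id,
        "site_residue_count": int(ligand_rows.sum() + env_rows.sum()),
        "protein_ligand_count": int(ligand_rows.sum()),
        "mean_ligand_sasa": float(v[ligand_rows, COL_ABS_SASA].mean()),
        "second_sphere_mean_sasa": (
            float(v[env_rows, COL_ABS_SASA].mean()) if env_rows.any() else None
        ),
    }


def site_summary(site: MetalSite, features: SiteFeatureMatrix,
                 model=None) -> dict:
    """Rule inputs for an extracted site.

    Counts come from the :class:`MetalSite` (amino-acid ligands only; waters
    and het species never count); accessibility means come from the feature
    matrix's absolute-SASA column over the role rows.  When the structure
    model is given, His ligands within 12 residues of either chain terminus
    are counted for the poly-His-tag caveat.
    """
    fs = summary_from_features(features)
    out = {
        "site_id": site.site_id,
        "site_residue_count": site.site_residue_count,
        "protein_ligand_count": site.protein_ligand_count,
        "mean_ligand_sasa": fs["mean_ligand_sasa"],
        "second_sphere_mean_sasa": fs["second_sphere_mean_sasa"],
    }
    if model is not None:
        residues = chain_residues(model, site.chain_of_record)
        index = {ref: i for i, ref in enumerate(residues)}
        L = len(residues)
        n_his = 0
        for ref in site.protein_ligands:
            if ref[1] == "HIS" and ref in index:
                pos = index[ref]
                if pos < 12 or pos >= L - 12:
                    n_his += 1
        out["n_terminal_his_ligands"] = n_his
    return out


class RuleBaselineClassifier(BaseEstimator, ClassifierMixin):
    """Thin estimator wrapper over :func:`rule_classify` for pipelines.

    ``fit`` only records the classes (thresholds are never learned from
    data); ``X`` is a list of :class:`SiteFeatureMatrix` or summary dicts.
    """

    def __init__(self, min_site_residues: int = 20,
                 min_protein_ligands: int = 4,
                 ligand_sasa_cutoff: float | None = None):
        self.min_site_residues = min_site_residues
        self.min_protein_ligands = min_protein_ligands
        self.ligand_sasa_cutoff = ligand_sasa_cutoff

    def _config(self) -> RuleConfig:
        return RuleConfig(self.min_site_residues, self.min_protein_ligands,
                          self.ligand_sasa_cutoff)

    def fit(self, X=None, y=None):
        self.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS])
        return self

    def predict(self, X) -> np.ndarray:
        cfg = self._config()
        out = []
        for x in X:
            summary = x if isinstance(x, dict) else summary_from_features(x)
            out.append(rule_classify(summary, cfg)[0])
        return np.array(out)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
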