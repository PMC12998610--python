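"""Per-subject cell-cell communication inference.

The inference follows the Domino rule set: transcription factors with
differentially high activity in a cell type (one-sided Wilcoxon rank-sum
against all other cells), receptor genes correlated with TF activity
(Spearman), and three gates that turn these into binary linkages:

* intracellular linkage (cell type, TF, receptor): the TF is enriched in the
  type, every component gene of the receptor complex has Spearman rho with
  the TF at or above ``rec_tf_cor_threshold``, and every component is
  expressed by at least ``min_rec_percentage`` of the type's cells;
* ligand sender (cell type, ligand): every component gene of the ligand has
  mean scaled expression strictly greater than
  ``sender_mean_scaled_threshold`` in the type;
* intercellular linkage (recipient type, receptor, ligand, sender type): the
  recipient holds an active receptor, the database pairs the ligand with the
  receptor, and the sender passes the ligand gate.

A heteromeric complex passes a gate only if every component passes; the rho
of a complex is the minimum over its components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cell_data import CellDataset, CellTypeProfile, profile_cell_types
from .lr_database import LRDatabase
from .tf_activity import Regulon, TFActivityMatrix

log = logging.getLogger(__name__)


@dataclass
class CCCIConfig:
    """Inference thresholds; defaults follow the published parameterization."""

    min_tf_pval: float = 0.001
    rec_tf_cor_threshold: float = 0.15
    min_rec_percentage: float = 0.05
    sender_mean_scaled_threshold: float = 0.0  # strict >
    max_tfs_per_celltype: int | None = None
    max_recs_per_tf: int | None = None
    exclude_regulon_targets: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_tf_pval <= 1):
            raise ValueError("min_tf_pval must lie in (0, 1]")
        if not (-1 <= self.rec_tf_cor_threshold <= 1):
            raise ValueError("rec_tf_cor_threshold must lie in [-1, 1]")
        if not (0 <= self.min_rec_percentage <= 1):
            raise ValueError("min_rec_percentage must lie in [0, 1]")
        for cap in (self.max_tfs_per_celltype, self.max_recs_per_tf):
            if cap is not None and cap < 1:
                raise ValueError("caps must be positive when set")


@dataclass
class SubjectLinkages:
    """All active features and signaling linkages inferred for one subject."""

    subject: str
    cell_types: set = field(default_factory=set)
    tfs: set = field(default_factory=set)  # (cell_type, tf)
    rec: set = field(default_factory=set)  # (cell_type, receptor)
    incoming_lig: set = field(default_factory=set)  # (cell_type, ligand)
    tfs_rec: set = field(default_factory=set)  # (cell_type, tf, receptor)
    cl_rec_lig: set = field(default_factory=set)  # (recipient, receptor, ligand, sender)

    LINKAGE_CLASSES = ("tfs", "rec", "incoming_lig", "tfs_rec", "cl_rec_lig")

    def linkage_set(self, linkage_class: str) -> set:
        if linkage_class not in self.LINKAGE_CLASSES:
            raise ValueError(f"unknown linkage class {linkage_class!r}")
        return getattr(self, linkage_class)

    def validate(self) -> None:
        for ct, tf, rec in self.tfs_rec:
            if (ct, tf) not in self.tfs:
                raise AssertionError(f"tfs_rec entry without enriched TF: {(ct, tf, rec)}")
            if (ct, rec) not in self.rec:
                raise AssertionError(f"tfs_rec entry without active receptor: {(ct, tf, rec)}")
        for recipient, rec, lig, sender in self.cl_rec_lig:
            if (recipient, rec) not in self.rec:
                raise AssertionError(
                    f"cl_rec_lig entry without active receptor: {(recipient, rec, lig, sender)}"
                )
        derived = {(recipient, lig) for recipient, _, lig, _ in self.cl_rec_lig}
        if derived != self.incoming_lig:
            raise AssertionError("incoming_lig is not the projection of cl_rec_lig")

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "cell_types": sorted(self.cell_types),
            "tfs": sorted(self.tfs),
            "rec": sorted(self.rec),
            "incoming_lig": sorted(self.incoming_lig),
            "tfs_rec": sorted(self.tfs_rec),
            "cl_rec_lig": sorted(self.cl_rec_lig),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SubjectLinkages":
        return cls(
            subject=data["subject"],
            cell_types=set(data.get("cell_types", [])),
            tfs={tuple(x) for x in data.get("tfs", [])},
            rec={tuple(x) for x in data.get("rec", [])},
            incoming_lig={tuple(x) for x in data.get("incoming_lig", [])},
            tfs_rec={tuple(x) for x in data.get("tfs_rec", [])},
            cl_rec_lig={tuple(x) for x in data.get("cl_rec_lig", [])},
        )


# ---------------------------------------------------------------------------
# TF enrichment


def _ranksum_greater_asymptotic(scores: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized one-sided Wilcoxon rank-sum (normal approximation with tie
    correction and continuity correction) for each row of ``scores``."""
    n = scores.shape[1]
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = stats.rankdata(scores, axis=1)
    u = ranks[:, in_group].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per row
    tie_term = np.zeros(scores.shape[0])
    for i in range(scores.shape[0]):
        _, counts = np.unique(scores[i], return_counts=True)
        t = counts[counts > 1]
        tie_term[i] = (t**3 - t).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu - 0.5) / sigma
    p = stats.norm.sf(z)
    p[sigma == 0] = 1.0  # all values tied: no evidence
    return p


def tf_enrichment_pvalues(
    tf_scores: TFActivityMatrix, cell_type: np.ndarray, small_n: int = 50
) -> pd.DataFrame:
    """One-sided rank-sum p-values (type vs all other cells) per (type, TF).

    Exact enumeration of the rank-sum null when both groups are small
    (``<= small_n``) and the data are tie-free; otherwise the normal
    approximation with tie correction.  Types with fewer than 3 cells are
    skipped with a warning.
    """
    cell_type = np.asarray(cell_type, dtype=object)
    types = list(pd.unique(cell_type))
    if len(types) < 2:
        raise ValueError("TF enrichment needs at least 2 cell types")
    rows = {}
    for ct in types:
        in_group = cell_type == ct
        n1, n2 = int(in_group.sum()), int((~in_group).sum())
        if n1 < 3:
            log.warning("cell type %s has %d cells (<3); enrichment skipped", ct, n1)
            continue
        if max(n1, n2) <= small_n:
            pvals = np.empty(len(tf_scores.tfs))
            for i in range(len(tf_scores.tfs)):
                x = tf_scores.scores[i, in_group]
                y = tf_scores.scores[i, ~in_group]
                ties = len(np.unique(np.concatenate([x, y]))) < (n1 + n2)
                method = "asymptotic" if ties else "exact"
                pvals[i] = stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
        else:
            pvals = _ranksum_greater_asymptotic(tf_scores.scores, in_group)
        rows[ct] = pvals
    return pd.DataFrame(rows, index=tf_scores.tfs)


def enriched_tfs(
    tf_scores: TFActivityMatrix, cell_type: np.ndarray, cfg: CCCIConfig | None = None
) -> set[tuple[str, str]]:
    """TFs with differentially high activity per cell type (p < min_tf_pval)."""
    cfg = cfg or CCCIConfig()
    pvals = tf_enrichment_pvalues(tf_scores, cell_type)
    out: set[tuple[str, str]] = set()
    for ct in pvals.columns:
        hits = pvals.index[pvals[ct] < cfg.min_tf_pval]
        if cfg.max_tfs_per_celltype is not None and len(hits) > cfg.max_tfs_per_celltype:
            in_group = np.asarray(cell_type, dtype=object) == ct
            order = []
            for tf in hits:
                i = int(np.flatnonzero(tf_scores.tfs == tf)[0])
                med_diff = float(
                    np.median(tf_scores.scores[i, in_group])
                    - np.median(tf_scores.scores[i, ~in_group])
                )
                order.append((pvals.loc[tf, ct], -med_diff, tf))
            hits = [tf for _, _, tf in sorted(order)[: cfg.max_tfs_per_celltype]]
        out.update((ct, tf) for tf in hits)
    return out


# ---------------------------------------------------------------------------
# receptor-TF correlation


def receptor_tf_correlation(
    ds: CellDataset,
    tf_scores: TFActivityMatrix,
    db: LRDatabase,
    regulons: list[Regulon] | None = None,
    exclude_regulon_targets: bool = True,
) -> dict[tuple[str, str], float]:
    """Spearman rho of each receptor component gene with each TF's activity.

    Computed over all cells of ``ds`` (one subject's cells in per-subject
    mode).  Pairs with a constant receptor or constant TF vector are absent
    (undefined correlation).  When ``exclude_regulon_targets`` and regulons
    are given, pairs where the receptor gene is a target of the TF's regulon
    are removed.
    """
    tf_scores = tf_scores.aligned_to(ds)
    receptor_genes = sorted(
        {g for inter in db for g in inter.receptor.components if ds.gene_index(g) is not None}
    )
    missing = {g for inter in db for g in inter.receptor.components} - set(receptor_genes)
    if missing:
        log.info("receptor_tf_correlation: %d receptor gene(s) absent from dataset", len(missing))
    if not receptor_genes:
        return {}
    rec_idx = np.asarray([ds.gene_index(g) for g in receptor_genes])
    rec_ranks = stats.rankdata(ds.expr[rec_idx, :], axis=1)
    tf_ranks = stats.rankdata(tf_scores.scores, axis=1)

    def _center_norm(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((c**2).sum(axis=1))
        return c, norm

    rc, rnorm = _center_norm(rec_ranks)
    tc, tnorm = _center_norm(tf_ranks)
    denom = np.outer(rnorm, tnorm)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc @ tc.T) / denom

    regulon_targets: dict[str, frozenset[str]] = {}
    if regulons and exclude_regulon_targets:
        for reg in regulons:
            regulon_targets[reg.tf] = (
                regulon_targets.get(reg.tf, frozenset()) | reg.targets
            )

    out: dict[tuple[str, str], float] = {}
    for i, gene in enumerate(receptor_genes):
        for j, tf in enumerate(tf_scores.tfs):
            if denom[i, j] == 0:  # constant vector: undefined rho
                continue
            if gene in regulon_targets.get(tf, ()):  # regulon-target exclusion
                continue
            out[(gene, tf)] = float(rho[i, j])
    return out


# ---------------------------------------------------------------------------
# gates and assembly


def _complex_rho(
    components: tuple[str, ...], tf: str, correlations: dict[tuple[str, str], float]
) -> float | None:
    """Minimum rho over components; None if any component's rho is undefined."""
    rhos = []
    for g in components:
        if (g, tf) not in correlations:
            return None
        rhos.append(correlations[(g, tf)])
    return min(rhos)


def intracellular_linkages(
    profiles: list[CellTypeProfile],
    enriched: set[tuple[str, str]],
    correlations: dict[tuple[str, str], float],
    db: LRDatabase,
    cfg: CCCIConfig | None = None,
) -> tuple[set, set]:
    """Receptor-TF linkages per cell type, and the active-receptor projection."""
    cfg = cfg or CCCIConfig()
    receptors = db.receptor_complexes()
    tfs_rec: set[tuple[str, str, str]] = set()
    by_ct_tf: dict[tuple[str, str], list[tuple[float, str]]] = {}
    for prof in profiles:
        ct = prof.cell_type
        ct_tfs = {tf for (c, tf) in enriched if c == ct}
        for tf in ct_tfs:
            for rec_name, rec in receptors.items():
                if not all(prof.has_gene(g) for g in rec.components):
                    continue
                rho = _complex_rho(rec.components, tf, correlations)
                if rho is None or rho < cfg.rec_tf_cor_threshold:
                    continue
                if any(
                    prof.pct_expressing_of(g) < cfg.min_rec_percentage
                    for g in rec.components
                ):
                    continue
                by_ct_tf.setdefault((ct, tf), []).append((rho, rec_name))
    for (ct, tf), cands in by_ct_tf.items():
        if cfg.max_recs_per_tf is not None and len(cands) > cfg.max_recs_per_tf:
            cands = sorted(cands, key=lambda x: (-x[0], x[1]))[: cfg.max_recs_per_tf]
        tfs_rec.update((ct, tf, rec_name) for _, rec_name in cands)
    rec_set = {(ct, rec_name) for ct, _, rec_name in tfs_rec}
    return tfs_rec, rec_set


def ligand_senders(
    profiles: list[CellTypeProfile], db: LRDatabase, cfg: CCCIConfig | None = None
) -> set[tuple[str, str]]:
    """(cell type, ligand) pairs passing the mean-scaled-expression gate."""
    cfg = cfg or CCCIConfig()
    ligands = db.ligand_complexes()
    out: set[tuple[str, str]] = set()
    for prof in profiles:
        for lig_name, lig in ligands.items():
            if not all(prof.has_gene(g) for g in lig.components):
                continue
            if all(
                prof.mean_scaled_of(g) > cfg.sender_mean_scaled_threshold
                for g in lig.components
            ):
                out.add((prof.cell_type, lig_name))
    return out


def infer_subject(
    ds: CellDataset,
    tf_scores: TFActivityMatrix,
    db: LRDatabase,
    cfg: CCCIConfig | None = None,
    subject=None,
    regulons: list[Regulon] | None = None,
) -> SubjectLinkages:
    """Run the full inference for one subject and assemble its linkages."""
    cfg = cfg or CCCIConfig()
    if subject is None:
        subjects = ds.subjects
        if len(subjects) != 1:
            raise ValueError("dataset holds multiple subjects; pass `subject`")
        subject = subjects[0]
    else:
        ds = ds.for_subject(subject)
    tf_scores = tf_scores.aligned_to(ds)

    profiles = profile_cell_types(ds, subject)
    enriched = enriched_tfs(tf_scores, ds.cell_type, cfg)
    correlations = receptor_tf_correlation(
        ds, tf_scores, db, regulons=regulons,
        exclude_regulon_targets=cfg.exclude_regulon_targets,
    )
    tfs_rec, rec_set = intracellular_linkages(profiles, enriched, correlations, db, cfg)
    senders = ligand_senders(profiles, db, cfg)

    cl_rec_lig: set[tuple[str, str, str, str]] = set()
    for inter in db:
        for recipient, rec_name in rec_set:
            if rec_name != inter.receptor.name:
                continue
            for sender_ct, lig_name in senders:
                if lig_name == inter.ligand.name:
                    cl_rec_lig.add((recipient, rec_name, lig_name, sender_ct))
    incoming_lig = {(recipient, lig) for recipient, _, lig, _ in cl_rec_lig}

    linkages = SubjectLinkages(
        subject=str(subject),
        cell_types=set(ds.cell_types),
        tfs=enriched,
        rec=rec_set,
        incoming_lig=incoming_lig,
        tfs_rec=tfs_rec,
        cl_rec_lig=cl_rec_lig,
    )
    linkages.validate()
    return linkages
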