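"""Bootstrap pseudo-subjects for pooled or few-sample conditions.

Designs with pooled cells (or a single sample per condition) cannot feed the
DCST directly because the exact test needs subjects to count.  Resampling
cells with replacement within each cell-type stratum of a condition creates
pseudo-subjects that preserve the condition's cell-type composition; twenty
such pseudo-replicates per arm make the contingency tables testable without
manufacturing differential signals (resampling is exchangeable across arms
drawn from the same cells).

TF activity scores are per-cell quantities, so each pseudo-subject carries
over the scores of its sampled source cells; recomputation from regulons is
available for workflows where scores depend on the cell pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_data import CellDataset
from .ccci import CCCIConfig, infer_subject
from .linkage_summary import LinkageSummary, build_summary
from .lr_database import LRDatabase
from .tf_activity import Regulon, TFActivityMatrix, aucell_score

log = logging.getLogger(__name__)


@dataclass
class BootstrapPlan:
    condition: str
    n_boot: int = 20
    stratify_by_cell_type: bool = True
    sample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must lie in (0, 1]")


def _condition_mask(ds: CellDataset, condition: str, condition_var: str) -> np.ndarray:
    if condition_var == "condition":
        if ds.condition is None:
            raise ValueError("dataset has no condition labels")
        labels = ds.condition
    elif condition_var == "subject":
        labels = ds.subject
    else:
        raise ValueError(f"unknown condition variable {condition_var!r}")
    mask = labels == condition
    if not mask.any():
        raise ValueError(f"condition {condition!r} not present in dataset")
    return mask


def make_bootstraps(
    ds: CellDataset, plan: BootstrapPlan, condition_var: str = "condition"
) -> list[CellDataset]:
    """Draw ``plan.n_boot`` pseudo-subjects from one condition's cells.

    Cells are resampled with replacement within each cell-type stratum
    (or from the whole condition when unstratified); each stratum's output
    size is ``round(sample_fraction * stratum size)``.  Pseudo-subject ids
    are ``{condition}_boot{i}``; repeated draws of a cell get suffixed cell
    ids.  Each returned dataset carries ``source_index`` (positions into the
    source dataset's columns) for provenance and score carry-over.
    """
    mask = _condition_mask(ds, plan.condition, condition_var)
    src = np.flatnonzero(mask)
    cell_type = ds.cell_type[src]
    strata = (
        [src[cell_type == ct] for ct in pd.unique(cell_type)]
        if plan.stratify_by_cell_type
        else [src]
    )
    for stratum in strata:
        if len(stratum) < 2:
            ct = ds.cell_type[stratum[0]] if len(stratum) else "?"
            raise ValueError(
                f"cell type {ct!r} has fewer than 2 cells in condition {plan.condition!r}"
            )
    out = []
    for i in range(plan.n_boot):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=plan.seed, spawn_key=(i,)))
        chosen = np.concatenate(
            [
                rng.choice(stratum, size=max(1, round(plan.sample_fraction * len(stratum))),
                           replace=True)
                for stratum in strata
            ]
        )
        subject_id = f"{plan.condition}_boot{i}"
        counts: dict[str, int] = {}
        cell_ids = []
        for j in chosen:
            base = str(ds.cells[j])
            k = counts.get(base, 0)
            counts[base] = k + 1
            cell_ids.append(base if k == 0 else f"{base}.dup{k}")
        boot = CellDataset(
            expr=ds.expr[:, chosen],
            genes=ds.genes,
            cells=np.asarray(cell_ids, dtype=object),
            cell_type=ds.cell_type[chosen],
            subject=np.full(len(chosen), subject_id, dtype=object),
            condition=np.full(len(chosen), plan.condition, dtype=object),
        )
        boot.source_index = chosen  # provenance: positions in the source dataset
        out.append(boot)
    return out


def carry_over_scores(tf_scores: TFActivityMatrix, boot: CellDataset) -> TFActivityMatrix:
    """Reuse per-cell TF scores for a pseudo-subject's resampled cells."""
    idx = getattr(boot, "source_index", None)
    if idx is None:
        raise ValueError("dataset has no bootstrap provenance (source_index)")
    return TFActivityMatrix(
        tfs=tf_scores.tfs, cells=boot.cells, scores=tf_scores.scores[:, idx],
        method=tf_scores.method,
    )


def bootstrap_summary(
    ds: CellDataset,
    conditions: list[str],
    tf_scores: TFActivityMatrix,
    db: LRDatabase,
    cfg: CCCIConfig | None = None,
    n_boot: int = 20,
    stratify_by_cell_type: bool = True,
    sample_fraction: float = 1.0,
    seed: int = 0,
    condition_var: str = "condition",
    regulons: list[Regulon] | None = None,
    recompute_scores: bool = False,
    top_frac: float = 0.05,
) -> LinkageSummary:
    """Bootstrap every condition and run inference on each pseudo-subject.

    The resulting summary has one metadata variable, ``condition``, naming
    each pseudo-subject's source condition; it is ready for a (multilevel)
    DCST across the conditions.
    """
    if len(conditions) < 2:
        raise ValueError("DCST needs at least 2 conditions; got fewer")
    tf_scores = tf_scores.aligned_to(ds)
    entries = []
    meta_rows = []
    for c_idx, condition in enumerate(conditions):
        plan = BootstrapPlan(
            condition=condition, n_boot=n_boot,
            stratify_by_cell_type=stratify_by_cell_type,
            sample_fraction=sample_fraction,
            seed=int(np.random.SeedSequence(entropy=seed, spawn_key=(c_idx,)).generate_state(1)[0] % (2**31)),
        )
        for boot in make_bootstraps(ds, plan, condition_var=condition_var):
            if recompute_scores:
                if not regulons:
                    raise ValueError("recompute_scores requires regulons")
                scores = aucell_score(boot, regulons, top_frac=top_frac, seed=plan.seed)
            else:
                scores = carry_over_scores(tf_scores, boot)
            subject = str(boot.subject[0])
            entries.append((subject, infer_subject(boot, scores, db, cfg, regulons=regulons)))
            meta_rows.append({"subject": subject, "condition": condition})
    meta = pd.DataFrame(meta_rows)
    return build_summary(entries, meta)
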