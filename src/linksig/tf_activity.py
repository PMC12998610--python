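"""Transcription-factor activity scoring and accessibility-aware regulons.

TF activity per cell is the area under the recovery curve of a regulon's
target genes within the top-ranked genes of that cell (the AUCell
convention), normalized by the maximal achievable area so every regulon
spans [0, 1] regardless of size.  Ranking ties are broken by a seeded
per-cell permutation so runs are reproducible.

Targeted regulons prune each regulon's target set per cell type to the genes
called "accessible" in scATAC-derived gene activity (at least ``min_frac`` of
the type's cells with nonzero activity), before scoring.  The score of a TF
whose pruned regulon is empty in a type is 0 for that type's cells.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_data import CellDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.targets:
            raise ValueError(f"regulon {self.tf!r} has no targets")


@dataclass
class TFActivityMatrix:
    tfs: np.ndarray
    cells: np.ndarray
    scores: np.ndarray  # tfs x cells, in [0, 1]
    method: str = "external"

    def __post_init__(self) -> None:
        self.tfs = np.asarray(self.tfs, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.tfs), len(self.cells)):
            raise ValueError("score matrix shape does not match tf/cell labels")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("TF activity scores must lie in [0, 1]")

    def subset_cells(self, mask: np.ndarray) -> "TFActivityMatrix":
        return TFActivityMatrix(self.tfs, self.cells[mask], self.scores[:, mask], self.method)

    def aligned_to(self, ds: CellDataset) -> "TFActivityMatrix":
        """Reorder columns to ``ds.cells``; error on missing cells."""
        if len(self.cells) == len(ds.cells) and np.array_equal(self.cells, ds.cells):
            return self
        pos = {c: i for i, c in enumerate(self.cells)}
        try:
            order = [pos[c] for c in ds.cells]
        except KeyError as exc:
            raise ValueError(f"TF scores missing cell {exc.args[0]!r}") from None
        return TFActivityMatrix(self.tfs, ds.cells, self.scores[:, order], self.method)


@dataclass
class AccessibilityMask:
    """Per cell type, the set of genes accessible for transcription."""

    accessible: dict[str, frozenset[str]] = field(default_factory=dict)

    def __getitem__(self, cell_type: str) -> frozenset[str]:
        return self.accessible[cell_type]

    def __contains__(self, cell_type: str) -> bool:
        return cell_type in self.accessible

    @property
    def cell_types(self) -> list[str]:
        return list(self.accessible)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({ct: sorted(gs) for ct, gs in self.accessible.items()}, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "AccessibilityMask":
        data = json.loads(Path(path).read_text())
        return cls({ct: frozenset(gs) for ct, gs in data.items()})


# ---------------------------------------------------------------------------
# regulon input formats


def load_regulons_gmt(path: str | Path) -> list[Regulon]:
    """GMT: one regulon per line, ``tf<TAB>description<TAB>target...``."""
    regulons = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        regulons.append(Regulon(parts[0], frozenset(parts[2:])))
    return regulons


def load_regulons_table(path: str | Path) -> list[Regulon]:
    """Two-column delimited table (tf, target); one row per edge."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("regulon table needs two columns (tf, target)")
    tf_col, tg_col = df.columns[:2]
    return [
        Regulon(str(tf), frozenset(str(t) for t in grp[tg_col]))
        for tf, grp in df.groupby(tf_col, sort=True)
    ]


def load_tf_scores(path: str | Path, tfs_in: str = "rows") -> TFActivityMatrix:
    """Load an externally computed TF activity matrix (CSV/TSV).

    ``tfs_in`` is "rows" or "columns".  Values outside [0, 1] are clipped
    (the clip count is logged); non-numeric entries are a parse error naming
    the offending coordinates.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if tfs_in == "columns":
        df = df.T
    elif tfs_in != "rows":
        raise ValueError(f"tfs_in must be 'rows' or 'columns', got {tfs_in!r}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path.name}: non-numeric TF score at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    n_clipped = int(np.sum((values < 0) | (values > 1)))
    if n_clipped:
        log.info("load_tf_scores: clipped %d value(s) into [0, 1]", n_clipped)
        values = np.clip(values, 0.0, 1.0)
    return TFActivityMatrix(
        tfs=np.asarray(df.index, dtype=object),
        cells=np.asarray(df.columns, dtype=object),
        scores=values,
        method="external",
    )


# ---------------------------------------------------------------------------
# AUCell-style scoring


def _rank_matrix(ds: CellDataset, seed: int) -> np.ndarray:
    """1-based rank of each gene within each cell, by decreasing expression;
    ties broken by a per-cell random permutation drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    n_genes, n_cells = ds.expr.shape
    ranks = np.empty((n_genes, n_cells), dtype=np.int64)
    for j in range(n_cells):
        tie_break = rng.permutation(n_genes)
        order = np.lexsort((tie_break, -ds.expr[:, j]))
        ranks[order, j] = np.arange(1, n_genes + 1)
    return ranks


def _max_area(t: int, n_targets: int) -> int:
    """Sum over i = 1..t of min(i, n_targets): best achievable recovery area."""
    if n_targets >= t:
        return t * (t + 1) // 2
    return n_targets * (n_targets + 1) // 2 + (t - n_targets) * n_targets


def _present_regulons(ds: CellDataset, regulons: list[Regulon]) -> list[tuple[str, np.ndarray]]:
    if not regulons:
        raise ValueError("empty regulon list")
    gene_pos = {g: i for i, g in enumerate(ds.genes)}
    out = []
    for reg in regulons:
        idx = np.asarray([gene_pos[g] for g in sorted(reg.targets) if g in gene_pos], dtype=int)
        n_pruned = len(reg.targets) - len(idx)
        if n_pruned:
            log.debug("regulon %s: %d target(s) absent from dataset", reg.tf, n_pruned)
        if len(idx) == 0:
            log.warning("regulon %s dropped: no targets present in dataset", reg.tf)
            continue
        out.append((reg.tf, idx))
    if not out:
        raise ValueError("no regulon has any target present in the dataset")
    return out


def _score_block(ranks: np.ndarray, target_idx: np.ndarray, t: int) -> np.ndarray:
    """AUC of the recovery curve for one target set across cells (columns)."""
    tr = ranks[target_idx, :]
    within = tr <= t
    area = np.where(within, t - tr + 1, 0).sum(axis=0)
    return area / _max_area(t, len(target_idx))


def aucell_score(
    ds: CellDataset, regulons: list[Regulon], top_frac: float = 0.05, seed: int = 0
) -> TFActivityMatrix:
    """Score regulon activity per cell from the target-gene recovery curve.

    With ``t = ceil(top_frac * n_genes)`` and recovery curve
    ``R(i) = #targets among the top-i ranked genes``, the score is
    ``sum_i R(i) / sum_i min(i, n_targets)`` for ``i = 1..t``.
    """
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must lie in (0, 1]")
    present = _present_regulons(ds, regulons)
    ranks = _rank_matrix(ds, seed)
    t = math.ceil(top_frac * ds.n_genes)
    tfs = [tf for tf, _ in present]
    scores = np.vstack([_score_block(ranks, idx, t) for _, idx in present])
    return TFActivityMatrix(tfs=np.asarray(tfs, dtype=object), cells=ds.cells,
                            scores=scores, method="aucell")


# ---------------------------------------------------------------------------
# targeted regulons (scATAC pruning)


def compute_accessibility(
    gene_activity: np.ndarray | CellDataset,
    genes: np.ndarray | None = None,
    cell_type: np.ndarray | None = None,
    min_frac: float = 0.10,
) -> AccessibilityMask:
    """Call genes accessible per cell type from a gene-activity matrix.

    A gene is accessible in type ``k`` iff the fraction of type-``k`` cells
    with activity > 0 is at least ``min_frac`` (the boundary fraction
    qualifies).  Cell types with zero cells are excluded.
    """
    if isinstance(gene_activity, CellDataset):
        genes = gene_activity.genes
        cell_type = gene_activity.cell_type
        gene_activity = gene_activity.expr
    if not (0 <= min_frac <= 1):
        raise ValueError("min_frac must lie in [0, 1]")
    gene_activity = np.asarray(gene_activity)
    genes = np.asarray(genes, dtype=object)
    cell_type = np.asarray(cell_type, dtype=object)
    mask: dict[str, frozenset[str]] = {}
    for ct in pd.unique(cell_type):
        cols = cell_type == ct
        if not cols.any():
            continue
        frac = (gene_activity[:, cols] > 0).mean(axis=1)
        mask[ct] = frozenset(genes[frac >= min_frac])
    return AccessibilityMask(mask)


def prune_regulons(
    regulons: list[Regulon], mask: AccessibilityMask
) -> dict[str, list[Regulon]]:
    """Intersect each regulon's targets with each type's accessible set.

    Regulons left with no accessible target are dropped for that type.
    """
    if not mask.accessible:
        raise ValueError("accessibility mask is empty")
    out: dict[str, list[Regulon]] = {}
    for ct, accessible in mask.accessible.items():
        kept = []
        for reg in regulons:
            pruned = reg.targets & accessible
            if pruned:
                kept.append(Regulon(reg.tf, pruned))
            else:
                log.info("prune_regulons: %s dropped for cell type %s", reg.tf, ct)
        out[ct] = kept
    return out


def targeted_regulon_scores(
    ds: CellDataset,
    regulons: list[Regulon],
    mask: AccessibilityMask,
    top_frac: float = 0.05,
    seed: int = 0,
) -> TFActivityMatrix:
    """AUCell scores in which each cell uses the pruned regulon of its type.

    TFs whose pruned regulon is empty (or absent) for a type score 0 for that
    type's cells.
    """
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must lie in (0, 1]")
    if not regulons:
        raise ValueError("empty regulon list")
    pruned_by_type = prune_regulons(regulons, mask)
    ranks = _rank_matrix(ds, seed)
    t = math.ceil(top_frac * ds.n_genes)
    tfs = [reg.tf for reg in regulons]
    tf_pos = {tf: i for i, tf in enumerate(tfs)}
    gene_pos = {g: i for i, g in enumerate(ds.genes)}
    scores = np.zeros((len(tfs), ds.n_cells))
    for ct in pd.unique(ds.cell_type):
        cols = np.flatnonzero(ds.cell_type == ct)
        for reg in pruned_by_type.get(ct, []):
            idx = np.asarray(
                [gene_pos[g] for g in sorted(reg.targets) if g in gene_pos], dtype=int
            )
            if len(idx) == 0:
                continue
            scores[tf_pos[reg.tf], cols] = _score_block(ranks[:, cols], idx, t)
    return TFActivityMatrix(
        tfs=np.asarray(tfs, dtype=object), cells=ds.cells, scores=scores,
        method="targeted_regulons",
    )
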