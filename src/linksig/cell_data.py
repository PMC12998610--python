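"""Per-cell expression data with cell type / subject / condition annotations.

The central container is :class:`CellDataset`, a genes x cells matrix of
log-normalized expression with per-cell labels.  Inference consumes two
derived quantities:

* *scaled expression*: per-gene z-scores (population SD).  Scaling defaults
  to per-subject scope so that sender/recipient calls for one subject never
  depend on the cellular composition of other subjects.
* *cell-type profiles*: per cell type within one subject, the mean of scaled
  expression and the fraction of cells with nonzero raw expression per gene.

Zero-variance genes scale to all-zero rows, so a gene that is constant within
the scaling scope can never pass the "mean scaled expression > 0" sender rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_META_COLS = ("cell_id", "cell_type", "subject")


@dataclass
class CellDataset:
    expr: np.ndarray  # genes x cells, log-normalized (non-negative)
    genes: np.ndarray  # gene symbols, ordered
    cells: np.ndarray  # cell ids, ordered
    cell_type: np.ndarray  # per-cell label
    subject: np.ndarray  # per-cell subject id
    condition: np.ndarray | None = None
    _scaled: dict = field(default_factory=dict, repr=False, compare=False)
    _gene_idx: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.subject = np.asarray(self.subject, dtype=object)
        if self.condition is not None:
            self.condition = np.asarray(self.condition, dtype=object)
        n_genes, n_cells = self.expr.shape
        if len(self.genes) != n_genes:
            raise ValueError("gene labels do not match matrix rows")
        for name, vec in (
            ("cells", self.cells),
            ("cell_type", self.cell_type),
            ("subject", self.subject),
        ):
            if len(vec) != n_cells:
                raise ValueError(f"{name} labels do not match matrix columns")
        if pd.isna(self.cell_type).any():
            raise ValueError("every cell must have a cell_type")
        if pd.isna(self.subject).any():
            raise ValueError("every cell must have a subject")
        if np.any(self.expr < 0):
            raise ValueError("expression matrix has negative entries")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expr.shape[1]

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.subject))

    @property
    def cell_types(self) -> list:
        return list(pd.unique(self.cell_type))

    def gene_index(self, gene: str) -> int | None:
        if self._gene_idx is None:
            self._gene_idx = {g: i for i, g in enumerate(self.genes)}
        return self._gene_idx.get(gene)

    def subset_cells(self, mask: np.ndarray) -> "CellDataset":
        mask = np.asarray(mask)
        return CellDataset(
            expr=self.expr[:, mask],
            genes=self.genes,
            cells=self.cells[mask],
            cell_type=self.cell_type[mask],
            subject=self.subject[mask],
            condition=None if self.condition is None else self.condition[mask],
        )

    def for_subject(self, subject) -> "CellDataset":
        mask = self.subject == subject
        if not mask.any():
            raise KeyError(f"unknown subject {subject!r}")
        return self.subset_cells(mask)


@dataclass
class CellTypeProfile:
    """Per-gene summary of one cell type within one subject."""

    cell_type: str
    n_cells: int
    mean_scaled: np.ndarray  # aligned to `genes`
    pct_expressing: np.ndarray  # aligned to `genes`
    genes: np.ndarray

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("profile requires at least one cell")
        self._idx = {g: i for i, g in enumerate(self.genes)}

    def mean_scaled_of(self, gene: str) -> float:
        return float(self.mean_scaled[self._idx[gene]])

    def pct_expressing_of(self, gene: str) -> float:
        return float(self.pct_expressing[self._idx[gene]])

    def has_gene(self, gene: str) -> bool:
        return gene in self._idx


def _zscore(block: np.ndarray) -> np.ndarray:
    """Population z-score per row; zero-variance rows map to all zeros."""
    mean = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, keepdims=True)  # population SD (ddof=0)
    out = block - mean
    nonzero = sd[:, 0] > 0
    out[nonzero] /= sd[nonzero]
    out[~nonzero] = 0.0
    return out


def scale_expression(ds: CellDataset, scope: str = "per_subject") -> np.ndarray:
    """Z-score expression per gene within scope ("per_subject" or "global")."""
    if scope in ds._scaled:
        return ds._scaled[scope]
    if scope == "global":
        if ds.n_cells < 2:
            raise ValueError("global scaling requires at least 2 cells")
        scaled = _zscore(ds.expr.copy())
    elif scope == "per_subject":
        scaled = np.empty_like(ds.expr)
        for subj in ds.subjects:
            mask = ds.subject == subj
            if mask.sum() < 2:
                raise ValueError(
                    f"subject {subj!r} has a single cell; merge or drop it before scaling"
                )
            scaled[:, mask] = _zscore(ds.expr[:, mask].copy())
    else:
        raise ValueError(f"unknown scaling scope {scope!r}")
    ds._scaled[scope] = scaled
    return scaled


def profile_cell_types(ds: CellDataset, subject) -> list[CellTypeProfile]:
    """Cell-type profiles (mean scaled expression, pct expressing) for one subject.

    Scaling is computed within the subject's cells only, matching the
    per-subject inference scope.
    """
    sub = ds.for_subject(subject)
    scaled = scale_expression(sub, scope="global")  # sub holds one subject only
    profiles = []
    for ct in sub.cell_types:
        mask = sub.cell_type == ct
        profiles.append(
            CellTypeProfile(
                cell_type=ct,
                n_cells=int(mask.sum()),
                mean_scaled=scaled[:, mask].mean(axis=1),
                pct_expressing=(sub.expr[:, mask] > 0).mean(axis=1),
                genes=sub.genes,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# loading


def _read_meta(meta_path: Path) -> pd.DataFrame:
    sep = "\t" if meta_path.suffix.lower() in {".tsv", ".txt"} else ","
    meta = pd.read_csv(meta_path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_META_COLS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    return meta


def _read_sidecar(dir_path: Path, names: tuple[str, ...], symbol_col: bool) -> list[str]:
    """Read a features/barcodes sidecar; 10x features files carry the symbol
    in the second column, barcodes files a single column."""
    for name in names:
        for suffix in ("", ".gz"):
            p = dir_path / (name + suffix)
            if p.exists():
                df = pd.read_csv(p, sep="\t", header=None)
                col = 1 if symbol_col and df.shape[1] > 1 else 0
                return [str(v) for v in df.iloc[:, col]]
    raise FileNotFoundError(f"no sidecar file found among {names} in {dir_path}")


def _dedup_genes(expr: np.ndarray, genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    seen: set[str] = set()
    keep = []
    n_dropped = 0
    for i, g in enumerate(genes):
        if g in seen:
            n_dropped += 1
            continue
        seen.add(g)
        keep.append(i)
    if n_dropped:
        log.info("load_dataset: dropped %d duplicated gene symbol(s), first kept", n_dropped)
    return expr[keep, :], np.asarray([genes[i] for i in keep], dtype=object)


def load_dataset(
    expr_path: str | Path, meta_path: str | Path, fmt: str | None = None
) -> CellDataset:
    """Load an expression matrix plus cell metadata into a :class:`CellDataset`.

    ``fmt="mtx"``: ``expr_path`` is a MatrixMarket file whose directory also
    contains ``features.tsv``/``genes.tsv`` and ``barcodes.tsv`` (optionally
    gzipped).  ``fmt="csv"``: dense delimited matrix, genes as rows (first
    column gene symbols), cells as columns.  Cells are reordered to the
    metadata row order; metadata cell ids absent from the matrix are an error.
    """
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    if fmt is None:
        fmt = "mtx" if expr_path.suffix in {".mtx", ".gz"} else "csv"
    if fmt == "mtx":
        from scipy.io import mmread

        mat = mmread(str(expr_path)).tocsr()
        genes = _read_sidecar(expr_path.parent, ("features.tsv", "genes.tsv"), True)
        barcodes = _read_sidecar(expr_path.parent, ("barcodes.tsv",), False)
        expr = np.asarray(mat.todense(), dtype=float)
        if expr.shape != (len(genes), len(barcodes)):
            raise ValueError("matrix dimensions do not match features/barcodes sidecars")
    elif fmt == "csv":
        sep = "\t" if expr_path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(expr_path, sep=sep, index_col=0)
        genes = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
        expr = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    expr, gene_arr = _dedup_genes(expr, genes)
    meta = _read_meta(meta_path)
    pos = {b: i for i, b in enumerate(barcodes)}
    missing = [c for c in meta["cell_id"] if c not in pos]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} metadata cell id(s) missing from expression matrix: {shown}"
        )
    order = [pos[c] for c in meta["cell_id"]]
    return CellDataset(
        expr=expr[:, order],
        genes=gene_arr,
        cells=meta["cell_id"].to_numpy(dtype=object),
        cell_type=meta["cell_type"].to_numpy(dtype=object),
        subject=meta["subject"].to_numpy(dtype=object),
        condition=meta["condition"].to_numpy(dtype=object) if "condition" in meta else None,
    )
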