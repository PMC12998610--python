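import numpy as np
import pandas as pd
import pytest

from linksig import (
    CellDataset,
    GeneComplex,
    LRDatabase,
    LRInteraction,
    SubjectLinkages,
    TFActivityMatrix,
)


def write_cellphonedb_dir(
    path,
    interactions,
    complexes=None,
    genes=None,
):
    """Write a minimal CellPhoneDB-v4-style directory.

    ``interactions``: list of (id, partner_a, partner_b);
    ``complexes``: dict complex_name -> list of uniprot ids;
    ``genes``: list of (gene_name, uniprot).
    """
    complexes = complexes or {}
    genes = genes or []
    inter = pd.DataFrame(interactions, columns=["id_cp_interaction", "partner_a", "partner_b"])
    inter.to_csv(path / "interaction_input.csv", index=False)
    rows = []
    for name, members in complexes.items():
        row = {"complex_name": name}
        for i, m in enumerate(members, start=1):
            row[f"uniprot_{i}"] = m
        rows.append(row)
    cols = ["complex_name", "uniprot_1", "uniprot_2", "uniprot_3", "uniprot_4"]
    pd.DataFrame(rows, columns=cols).to_csv(path / "complex_input.csv", index=False)
    pd.DataFrame(
        [{"uniprot": up} for _, up in genes], columns=["uniprot"]
    ).to_csv(path / "protein_input.csv", index=False)
    pd.DataFrame(genes, columns=["gene_name", "uniprot"]).to_csv(
        path / "gene_input.csv", index=False
    )
    return path


@pytest.fixture
def cpdb_simple(tmp_path):
    """One simple pair: ligand L (uniprot UL), receptor R (uniprot UR)."""
    return write_cellphonedb_dir(
        tmp_path,
        interactions=[("CPI-1", "UL", "UR")],
        genes=[("L", "UL"), ("R", "UR")],
    )


def simple_db(pairs, source="test"):
    """LRDatabase of single-gene pairs from (ligand, receptor) tuples."""
    return LRDatabase(
        [
            LRInteraction(
                f"{l}_{r}", GeneComplex(l, (l,)), GeneComplex(r, (r,)), source
            )
            for l, r in pairs
        ]
    )


def make_dataset(expr, genes, cell_type, subject=None, cells=None, condition=None):
    expr = np.asarray(expr, dtype=float)
    n_cells = expr.shape[1]
    return CellDataset(
        expr=expr,
        genes=np.asarray(genes, dtype=object),
        cells=np.asarray(
            cells if cells is not None else [f"c{i}" for i in range(n_cells)], dtype=object
        ),
        cell_type=np.asarray(cell_type, dtype=object),
        subject=np.asarray(
            subject if subject is not None else ["s1"] * n_cells, dtype=object
        ),
        condition=None if condition is None else np.asarray(condition, dtype=object),
    )


def make_scores(tfs, cells, scores, method="external"):
    return TFActivityMatrix(
        tfs=np.asarray(tfs, dtype=object),
        cells=np.asarray(cells, dtype=object),
        scores=np.asarray(scores, dtype=float),
        method=method,
    )


def make_linkages(subject, cl_rec_lig=(), tfs=(), tfs_rec=(), cell_types=("A", "B")):
    cl = {tuple(x) for x in cl_rec_lig}
    tfs_rec = {tuple(x) for x in tfs_rec}
    tfs_set = {tuple(x) for x in tfs} | {(ct, tf) for ct, tf, _ in tfs_rec}
    rec = {(ct, r) for ct, r, _, _ in cl} | {(ct, r) for ct, _, r in tfs_rec}
    return SubjectLinkages(
        subject=subject,
        cell_types=set(cell_types),
        tfs=tfs_set,
        rec=rec,
        incoming_lig={(ct, l) for ct, _, l, _ in cl},
        tfs_rec=tfs_rec,
        cl_rec_lig=cl,
    )
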