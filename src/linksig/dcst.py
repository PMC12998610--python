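"""The Differential Cell Signaling Test (DCST).

Presence/absence of a binarized signaling linkage across subjects is tested
for dependence on a grouping variable with an exact conditional test: the
two-group case is Fisher's exact test on the 2x2 table of subjects with /
without the linkage; three or more groups use the Freeman-Halton
generalization on the r x 2 table.  The two-sided p-value follows the
probability-mass rule: the total null probability of all tables with the
observed margins whose probability does not exceed the observed table's
(within relative tolerance 1e-7).

Odds ratios for 2x2 tables are the conditional maximum-likelihood estimate
under the noncentral hypergeometric model (the convention of R's
``fisher.test``), with the naive cross-product ratio reported alongside.
Multiple testing is controlled per family -- all unique linkages of one
class incoming to one recipient cell type -- with Benjamini-Hochberg
step-up adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage_summary import LinkageSummary, count_linkage, unique_linkages

log = logging.getLogger(__name__)

_REL_TOL = 1e-7


@dataclass
class ContingencyTable:
    """r x 2 table of subject counts; columns are (with linkage, without)."""

    groups: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be an r x 2 matrix")
        if self.counts.shape[0] != len(self.groups):
            raise ValueError("group labels do not match rows")
        if self.counts.shape[0] < 2:
            raise ValueError("need at least 2 groups")
        if (self.counts < 0).any():
            raise ValueError("negative counts")


def fisher_exact_2x2(
    table: ContingencyTable | np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table (two-sided by default).

    Returns ``(odds_ratio, p_value)`` where the odds ratio is the conditional
    MLE (``inf``/``0`` at boundary tables, ``nan`` when a margin is zero, in
    which case p = 1).  The two-sided p follows the probability-mass rule;
    ``alternative`` may also be "greater" or "less" (one-sided tails on the
    first row's with-linkage count).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    if (counts < 0).any():
        raise ValueError("negative counts")
    a, b = counts[0]
    c, d = counts[1]
    n1, n2, m = a + b, c + d, a + c
    total = n1 + n2
    if n1 == 0 or n2 == 0 or m == 0 or (b + d) == 0:
        return math.nan, 1.0  # degenerate margin: no information
    dist = stats.hypergeom(total, n1, m)
    if alternative == "two-sided":
        support = np.arange(max(0, m - n2), min(n1, m) + 1)
        pmf = dist.pmf(support)
        p_obs = pmf[support == a][0]
        p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    elif alternative == "greater":
        p = float(dist.sf(a - 1))
    elif alternative == "less":
        p = float(dist.cdf(a))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    oddsr = stats.contingency.odds_ratio(counts, kind="conditional").statistic
    return float(oddsr), p


def sample_odds_ratio(counts: np.ndarray) -> float:
    """Naive cross-product odds ratio (a*d)/(b*c); inf/nan at zero cells."""
    counts = np.asarray(counts, dtype=float)
    a, b = counts[0]
    c, d = counts[1]
    if b * c == 0:
        return math.nan if a * d == 0 else math.inf
    return (a * d) / (b * c)


def _rx2_tables(row_sums: np.ndarray, col1: int):
    """Yield all first-column vectors consistent with the margins."""
    r = len(row_sums)
    suffix = np.concatenate([np.cumsum(row_sums[::-1])[::-1][1:], [0]])

    def rec(i: int, remaining: int, prefix: list[int]):
        if i == r - 1:
            if 0 <= remaining <= row_sums[i]:
                yield prefix + [remaining]
            return
        lo = max(0, remaining - suffix[i])
        hi = min(row_sums[i], remaining)
        for a in range(lo, hi + 1):
            yield from rec(i + 1, remaining - a, prefix + [a])

    yield from rec(0, col1, [])


def fisher_exact_rx2(table: ContingencyTable | np.ndarray, budget: int = 10**7) -> float:
    """Freeman-Halton exact test on an r x 2 table (two-sided p-value).

    Rows with zero subjects are dropped.  Enumerates all tables with the
    observed margins under the multivariate hypergeometric null; errors when
    the enumeration would exceed ``budget`` tables.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if (counts < 0).any():
        raise ValueError("negative counts")
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2:
        return 1.0
    row_sums = counts.sum(axis=1)
    col1 = int(counts[:, 0].sum())
    total = int(row_sums.sum())
    if col1 == 0 or col1 == total:
        return 1.0
    est = 1.0
    for n_i in row_sums:
        est *= min(int(n_i), col1) + 1
        if est > budget:
            raise ValueError(
                "enumeration budget exceeded; consider collapsing groups"
            )
    lweights = [
        sum(math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
            for n, x in zip(row_sums, vec))
        for vec in _rx2_tables(row_sums, col1)
    ]
    lweights = np.asarray(lweights)
    lw_obs = sum(
        math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
        for n, x in zip(row_sums, counts[:, 0])
    )
    lnorm = math.lgamma(total + 1) - math.lgamma(col1 + 1) - math.lgamma(total - col1 + 1)
    probs = np.exp(lweights - lnorm)
    p_obs = math.exp(lw_obs - lnorm)
    p = float(probs[probs <= p_obs * (1 + _REL_TOL)].sum())
    return min(p, 1.0)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def test_differential_linkages(
    s: LinkageSummary,
    group_var: str,
    linkage_class: str = "cl_rec_lig",
    cell_type: str | None = None,
    reference_group: str | None = None,
    subjects: list[str] | None = None,
    global_adjust: bool = False,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Run the DCST for every unique linkage of a class incoming to a cell type.

    Linkages absent from every included subject are not tested.  With two
    group levels the table rows are ordered (reference, alternative) and the
    conditional-MLE odds ratio is reported; with three or more levels the
    Freeman-Halton test is used and the odds ratio is undefined.  BH
    adjustment is applied within this family (or across all recipient cell
    types of the class when ``global_adjust``).

    Returns a table sorted by p-value then linkage, with per-group
    with/without counts, ``odds_ratio`` (conditional MLE),
    ``odds_ratio_sample`` (cross-product), ``p_value`` and ``p_adj``.
    """
    if group_var not in s.meta.columns:
        raise ValueError(f"unknown grouping variable {group_var!r}")
    included = s.subjects if subjects is None else [x for x in s.subjects if x in set(subjects)]
    levels = list(pd.unique(s.meta.loc[included, group_var]))
    if len(levels) < 2:
        raise ValueError("grouping variable has fewer than 2 levels among included subjects")
    if reference_group is not None:
        if reference_group not in levels:
            raise ValueError(f"reference group {reference_group!r} not a level of {group_var!r}")
        levels = [reference_group] + [g for g in levels if g != reference_group]

    if cell_type is None and not global_adjust:
        raise ValueError("cell_type is required unless global_adjust=True")
    if global_adjust and cell_type is None:
        cell_types = sorted(
            {lk[0] for subj in included for lk in s.linkages[subj].linkage_set(linkage_class)}
        )
    else:
        cell_types = [cell_type]

    rows = []
    for ct in cell_types:
        for linkage in unique_linkages(s, linkage_class, ct):
            grouped = count_linkage(s, linkage_class, linkage, group_var, subjects=included)
            counts = np.asarray(
                [grouped.get(g, (0, 0)) for g in levels], dtype=np.int64
            )
            keep = counts.sum(axis=1) > 0
            tab = ContingencyTable(
                [g for g, k in zip(levels, keep) if k], counts[keep]
            )
            if tab.counts[:, 0].sum() == 0:
                continue  # linkage absent from every included subject
            if len(tab.groups) == 2:
                oddsr, p = fisher_exact_2x2(tab, alternative=alternative)
                or_sample = sample_odds_ratio(tab.counts)
            else:
                if alternative != "two-sided":
                    raise ValueError("one-sided alternatives need exactly 2 groups")
                p = fisher_exact_rx2(tab)
                oddsr, or_sample = math.nan, math.nan
            row = {
                "linkage": linkage,
                "linkage_class": linkage_class,
                "cell_type": ct,
                "odds_ratio": oddsr,
                "odds_ratio_sample": or_sample,
                "p_value": p,
            }
            for g in levels:
                n_with, n_without = grouped.get(g, (0, 0))
                row[f"{g}_with"] = n_with
                row[f"{g}_without"] = n_without
            rows.append(row)

    base_cols = ["linkage", "linkage_class", "cell_type", "odds_ratio",
                 "odds_ratio_sample", "p_value"]
    count_cols = [f"{g}_{suffix}" for g in levels for suffix in ("with", "without")]
    result = pd.DataFrame(rows, columns=base_cols + count_cols if not rows else None)
    if len(result):
        result["p_adj"] = bh_adjust(result["p_value"].to_numpy())
        result = result.sort_values(
            by=["p_value", "linkage"], key=lambda col: col.map(str) if col.name == "linkage" else col
        ).reset_index(drop=True)
    else:
        result["p_adj"] = []
    return result


def render_results(res: pd.DataFrame, path) -> None:
    """Write a DCST result table as TSV (inf -> "Inf", undefined -> "NA")."""
    out = res.copy()
    if "linkage" in out.columns:
        out["linkage"] = out["linkage"].map(lambda t: "|".join(map(str, t)))
    out = out.replace([np.inf], "Inf").replace([-np.inf], "-Inf")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    """Read back a table written by :func:`render_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "linkage" in df.columns:
        df["linkage"] = df["linkage"].map(lambda x: tuple(str(x).split("|")))
    for col in ("odds_ratio", "odds_ratio_sample"):
        if col in df.columns:
            df[col] = df[col].replace({"Inf": np.inf, "-Inf": -np.inf}).astype(float)
    return df
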