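"""Two-condition signaling simulation and the sensitivity/specificity benchmark.

The generator emulates a cohort of single-cell samples measuring two cell
types, A and B, which can interact through two ligand-receptor pairs
(L1 - R1 and L2 - R2).  Per cell, each gene is expressed as a Bernoulli draw
whose probability depends on (condition, cell type, gene); expressed entries
get a lognormal magnitude, mimicking log-normalized counts.  Receptors are
expressed by B; L1 is sent by A in condition C1 and by B in condition C2
(the autocrine arrangement), while L2 from A is equally likely in both
conditions.  The ground truth therefore contains two truly
condition-dependent intercellular linkages -- paracrine [B]: R1 <- L1: [A]
(C1) and autocrine [B]: R1 <- L1: [B] (C2) -- and one condition-independent
linkage, [B]: R2 <- L2: [A].

TF activity is simulated directly (TFj coupled to the scaled expression of
Rj plus Gaussian noise, clipped to [0, 1]) so the benchmark isolates the
linkage-calling and DCST stack from regulon scoring.

``run_benchmark`` sweeps sample number or B-cell count; per initialization
the non-background expression probabilities are re-drawn uniformly within
+/- ``jitter_width`` of their defaults (independently per condition entry),
producing cohorts whose exact effect sizes vary across initializations the
way biological replication varies across studies.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cell_data import CellDataset
from .ccci import CCCIConfig, infer_subject
from .dcst import test_differential_linkages
from .linkage_summary import build_summary
from .lr_database import GeneComplex, LRDatabase, LRInteraction
from .tf_activity import TFActivityMatrix

log = logging.getLogger(__name__)

SIGNAL_GENES = ("L1", "L2", "R1", "R2")


def default_expr_prob() -> dict:
    """Condition-dependent Bernoulli expression probabilities.

    Only non-background entries are listed; any (cell type, gene) pair not
    named here falls back to ``SimulationConfig.lr_background_prob``.  The
    condition-dependent pair (L1-R1) operates near the inference margin;
    the condition-independent pair (L2-R2) is modeled as a decisively
    expressed constitutive signal, so its linkage is present in essentially
    every sample of both conditions.
    """
    return {
        "C1": {"A": {"L1": 0.6, "L2": 0.5}, "B": {"L1": 0.1, "R1": 0.5, "R2": 0.7}},
        "C2": {"A": {"L1": 0.1, "L2": 0.5}, "B": {"L1": 0.6, "R1": 0.5, "R2": 0.7}},
    }


@dataclass
class SimulationConfig:
    n_samples_per_condition: int = 12
    n_cells: dict = field(default_factory=lambda: {"A": 600, "B": 400})
    expr_prob: dict = field(default_factory=default_expr_prob)
    expr_level: tuple[float, float] = (0.0, 0.5)  # lognormal (mu, sigma)
    tf_coupling: float = 0.146
    tf_noise_sd: float = 0.5
    n_background_genes: int = 50
    background_expr_prob: float = 0.3
    lr_background_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for cond in self.expr_prob.values():
            for genes in cond.values():
                for p in genes.values():
                    if not (0 <= p <= 1):
                        raise ValueError("expression probabilities must lie in [0, 1]")
        for ct, n in self.n_cells.items():
            if n < 10:
                raise ValueError(f"cell count for {ct} must be at least 10")
        if self.tf_noise_sd <= 0:
            raise ValueError("tf_noise_sd must be positive")

    def prob(self, condition: str, cell_type: str, gene: str) -> float:
        return self.expr_prob[condition].get(cell_type, {}).get(gene, self.lr_background_prob)


@dataclass
class GroundTruth:
    differential: frozenset
    null_linkages: frozenset

    def __post_init__(self) -> None:
        self.differential = frozenset(self.differential)
        self.null_linkages = frozenset(self.null_linkages)
        if self.differential & self.null_linkages:
            raise ValueError("differential and null linkage sets overlap")


def default_truth() -> GroundTruth:
    """Ground truth of the default two-cell-type network."""
    return GroundTruth(
        differential={("B", "R1", "L1", "A"), ("B", "R1", "L1", "B")},
        null_linkages={("B", "R2", "L2", "A")},
    )

# display labels for the three truth linkages, used in benchmark tables
LINKAGE_LABELS = {
    ("B", "R1", "L1", "A"): "paracrine",
    ("B", "R1", "L1", "B"): "autocrine",
    ("B", "R2", "L2", "A"): "null",
}


def benchmark_database() -> LRDatabase:
    """The two-pair ligand-receptor database of the simulated network."""
    return LRDatabase(
        [
            LRInteraction("L1_R1", GeneComplex("L1", ("L1",)), GeneComplex("R1", ("R1",)), "sim"),
            LRInteraction("L2_R2", GeneComplex("L2", ("L2",)), GeneComplex("R2", ("R2",)), "sim"),
        ]
    )


# ---------------------------------------------------------------------------
# cohort generation


def _sample_seed(seed: int, condition: str, index: int) -> np.random.Generator:
    cond_idx = {"C1": 0, "C2": 1}[condition]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cond_idx, index))
    )


def simulate_sample(
    cfg: SimulationConfig, condition: str, index: int
) -> tuple[CellDataset, TFActivityMatrix]:
    """Simulate one sample (subject) of the given condition.

    Deterministic in (cfg.seed, condition, index).
    """
    rng = _sample_seed(cfg.seed, condition, index)
    genes = list(SIGNAL_GENES) + [f"BG{i}" for i in range(cfg.n_background_genes)]
    types = sorted(cfg.n_cells)
    cell_type = np.concatenate([np.full(cfg.n_cells[ct], ct, dtype=object) for ct in types])
    n_cells = len(cell_type)
    n_genes = len(genes)

    probs = np.empty((n_genes, n_cells))
    for gi, gene in enumerate(genes):
        if gene in SIGNAL_GENES:
            col = np.empty(n_cells)
            for ct in types:
                col[cell_type == ct] = cfg.prob(condition, ct, gene)
            probs[gi] = col
        else:
            probs[gi] = cfg.background_expr_prob

    mu, sigma = cfg.expr_level
    expressed = rng.random((n_genes, n_cells)) < probs
    levels = rng.lognormal(mean=mu, sigma=sigma, size=(n_genes, n_cells))
    expr = np.where(expressed, levels, 0.0)

    subject = f"{condition}.s{index}"
    ds = CellDataset(
        expr=expr,
        genes=np.asarray(genes, dtype=object),
        cells=np.asarray([f"{subject}.c{j}" for j in range(n_cells)], dtype=object),
        cell_type=cell_type,
        subject=np.full(n_cells, subject, dtype=object),
        condition=np.full(n_cells, condition, dtype=object),
    )

    tf_scores = np.empty((2, n_cells))
    for j, rec in enumerate(("R1", "R2")):
        r = expr[genes.index(rec)]
        sd = r.std()
        z = (r - r.mean()) / sd if sd > 0 else np.zeros_like(r)
        act = cfg.tf_coupling * z + rng.normal(0.0, cfg.tf_noise_sd, size=n_cells)
        tf_scores[j] = np.clip(act, 0.0, 1.0)
    tfs = TFActivityMatrix(
        tfs=np.asarray(["TF1", "TF2"], dtype=object), cells=ds.cells,
        scores=tf_scores, method="external",
    )
    return ds, tfs


def simulate_cohort(
    cfg: SimulationConfig, condition: str
) -> list[tuple[CellDataset, TFActivityMatrix]]:
    """One sample per subject for a condition (n_samples_per_condition total)."""
    if condition not in cfg.expr_prob:
        raise ValueError(f"unknown condition {condition!r}")
    return [
        simulate_sample(cfg, condition, i) for i in range(cfg.n_samples_per_condition)
    ]


def run_cohort_pair(
    cfg: SimulationConfig,
    ccci_cfg: CCCIConfig | None = None,
    recipient: str = "B",
    reference: str = "C1",
) -> pd.DataFrame:
    """Simulate both conditions, infer per sample, and run the DCST."""
    ccci_cfg = ccci_cfg or CCCIConfig()
    db = benchmark_database()
    entries = []
    meta_rows = []
    for condition in ("C1", "C2"):
        for ds, tfs in simulate_cohort(cfg, condition):
            subject = str(ds.subject[0])
            entries.append((subject, infer_subject(ds, tfs, db, ccci_cfg)))
            meta_rows.append({"subject": subject, "condition": condition})
    summary = build_summary(entries, pd.DataFrame(meta_rows))
    return test_differential_linkages(
        summary, group_var="condition", linkage_class="cl_rec_lig",
        cell_type=recipient, reference_group=reference,
    )


def detected_linkages(results: pd.DataFrame, alpha: float = 0.05) -> frozenset:
    """Linkages called significantly differential at BH-adjusted p < alpha."""
    if len(results) == 0:
        return frozenset()
    hits = results.loc[results["p_adj"] < alpha, "linkage"]
    return frozenset(tuple(x) for x in hits)


def evaluate_run(
    results: pd.DataFrame, truth: GroundTruth, alpha: float = 0.05
) -> tuple[float, float]:
    """(sensitivity, specificity) of one cohort pair's DCST result.

    A truth-differential linkage counts as detected iff it appears in the
    result table with adjusted p below alpha; linkages never inferred in any
    subject are simply not detected.
    """
    detected = detected_linkages(results, alpha)
    sens = (
        len(detected & truth.differential) / len(truth.differential)
        if truth.differential
        else float("nan")
    )
    spec = (
        1.0 - len(detected & truth.null_linkages) / len(truth.null_linkages)
        if truth.null_linkages
        else float("nan")
    )
    return sens, spec


# ---------------------------------------------------------------------------
# benchmark sweep


def jitter_config(cfg: SimulationConfig, rng: np.random.Generator,
                  width: float = 0.1) -> SimulationConfig:
    """Re-draw every non-background expression probability within +/- width.

    Draws are clipped to [0.01, 0.95]; background probabilities are left
    alone.  A (cell type, gene) entry whose default is identical in every
    condition receives one shared draw applied to all conditions, so that
    condition-independent genes stay condition-independent and the simulated
    ground-truth null is preserved under every initialization; entries whose
    defaults differ between conditions are drawn independently per condition.
    """
    prob = copy.deepcopy(cfg.expr_prob)
    conds = sorted(prob)
    entries = sorted({(ct, g) for cond in conds for ct in prob[cond] for g in prob[cond][ct]})
    for ct, gene in entries:
        present = [c for c in conds if gene in prob[c].get(ct, {})]
        values = {prob[c][ct][gene] for c in present}
        if len(values) == 1 and len(present) == len(conds):
            p0 = values.pop()
            drawn = float(np.clip(rng.uniform(p0 - width, p0 + width), 0.01, 0.95))
            for c in present:
                prob[c][ct][gene] = drawn
        else:
            for c in present:
                p0 = prob[c][ct][gene]
                prob[c][ct][gene] = float(
                    np.clip(rng.uniform(p0 - width, p0 + width), 0.01, 0.95)
                )
    return replace(cfg, expr_prob=prob)


@dataclass
class BenchmarkResult:
    """Per-grid-point operating characteristics, aggregated over initializations."""

    vary: str
    table: pd.DataFrame
    n_init: int
    n_rep_per_init: int
    alpha: float

    def at(self, value) -> pd.Series:
        row = self.table[self.table[self.vary] == value]
        if len(row) != 1:
            raise KeyError(f"grid value {value!r} not in benchmark result")
        return row.iloc[0]


def _apply_grid(cfg: SimulationConfig, vary: str, value: int) -> SimulationConfig:
    if vary == "n_samples":
        return replace(cfg, n_samples_per_condition=int(value))
    if vary == "n_cells":
        n_cells = dict(cfg.n_cells)
        n_cells["B"] = int(value)
        return replace(cfg, n_cells=n_cells)
    raise ValueError(f"unknown sweep variable {vary!r}")


def run_benchmark(
    base_cfg: SimulationConfig | None = None,
    vary: str = "n_samples",
    grid: list[int] = (5, 15, 25, 35, 45, 55),
    n_init: int = 10,
    n_rep_per_init: int = 25,
    seed: int = 0,
    alpha: float = 0.05,
    jitter_width: float = 0.1,
    truth: GroundTruth | None = None,
) -> BenchmarkResult:
    """Sweep sample number or B-cell count and measure DCST detection rates.

    Per initialization, expression probabilities are jittered around the
    base configuration; per grid point, ``n_rep_per_init`` cohort pairs are
    simulated and each run through per-sample inference plus DCST.  Means
    and standard deviations over initializations are reported, together with
    per-linkage detection rates (columns ``paracrine``/``autocrine``/``null``
    for the default truth structure).
    """
    if not len(grid):
        raise ValueError("empty grid")
    base_cfg = base_cfg or SimulationConfig()
    truth = truth or default_truth()
    tracked = sorted(truth.differential | truth.null_linkages)
    labels = [LINKAGE_LABELS.get(lk, "|".join(lk)) for lk in tracked]

    rows = []
    for g_idx, value in enumerate(grid):
        sens_by_init = np.empty(n_init)
        spec_by_init = np.empty(n_init)
        det_by_init = np.empty((n_init, len(tracked)))
        spec_min = 1.0
        for i_init in range(n_init):
            init_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(1, i_init))
            )
            cfg_i = jitter_config(base_cfg, init_rng, width=jitter_width)
            cfg_i = _apply_grid(cfg_i, vary, value)
            sens_reps = np.empty(n_rep_per_init)
            spec_reps = np.empty(n_rep_per_init)
            det_reps = np.zeros((n_rep_per_init, len(tracked)))
            for rep in range(n_rep_per_init):
                rep_seed = int(
                    np.random.SeedSequence(
                        entropy=seed, spawn_key=(2, i_init, g_idx, rep)
                    ).generate_state(1)[0]
                    % (2**31)
                )
                cfg_rep = replace(cfg_i, seed=rep_seed)
                results = run_cohort_pair(cfg_rep)
                sens_reps[rep], spec_reps[rep] = evaluate_run(results, truth, alpha)
                detected = detected_linkages(results, alpha)
                det_reps[rep] = [lk in detected for lk in tracked]
            sens_by_init[i_init] = np.nanmean(sens_reps)
            spec_by_init[i_init] = np.nanmean(spec_reps)
            det_by_init[i_init] = det_reps.mean(axis=0)
            spec_min = min(spec_min, float(np.nanmin(spec_reps)))
        row = {
            vary: value,
            "sensitivity_mean": float(np.mean(sens_by_init)),
            "sensitivity_sd": float(np.std(sens_by_init, ddof=1)) if n_init > 1 else 0.0,
            "specificity_mean": float(np.mean(spec_by_init)),
            "specificity_sd": float(np.std(spec_by_init, ddof=1)) if n_init > 1 else 0.0,
            "specificity_min": spec_min,
        }
        for k, label in enumerate(labels):
            row[f"{label}_mean"] = float(det_by_init[:, k].mean())
            row[f"{label}_sd"] = (
                float(det_by_init[:, k].std(ddof=1)) if n_init > 1 else 0.0
            )
        rows.append(row)
        log.info("benchmark %s=%s: %s", vary, value, rows[-1])
    return BenchmarkResult(
        vary=vary, table=pd.DataFrame(rows), n_init=n_init,
        n_rep_per_init=n_rep_per_init, alpha=alpha,
    )
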