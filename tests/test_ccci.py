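import numpy as np
import pytest
from scipy import stats

from linksig import (
    CCCIConfig,
    CellTypeProfile,
    enriched_tfs,
    infer_subject,
    intracellular_linkages,
    ligand_senders,
    receptor_tf_correlation,
    tf_enrichment_pvalues,
)
from linksig.tf_activity import Regulon
from conftest import make_dataset, make_scores, simple_db


def profile(cell_type, genes, mean_scaled, pct, n_cells=20):
    return CellTypeProfile(
        cell_type=cell_type,
        n_cells=n_cells,
        mean_scaled=np.asarray(mean_scaled, dtype=float),
        pct_expressing=np.asarray(pct, dtype=float),
        genes=np.asarray(genes, dtype=object),
    )


class TestEnrichment:
    def test_complete_separation_is_enriched(self):
        scores = np.concatenate([np.linspace(0.6, 0.9, 30), np.linspace(0.1, 0.4, 30)])
        m = make_scores(["TF"], [f"c{i}" for i in range(60)], scores[None, :])
        hits = enriched_tfs(m, np.asarray(["k"] * 30 + ["o"] * 30, dtype=object))
        assert ("k", "TF") in hits and ("o", "TF") not in hits

    def test_identical_distribution_not_enriched(self):
        rng = np.random.default_rng(0)
        scores = rng.random(60)[None, :]
        m = make_scores(["TF"], [f"c{i}" for i in range(60)], scores)
        assert enriched_tfs(m, np.asarray(["k"] * 30 + ["o"] * 30, dtype=object)) == set()

    def test_exact_small_sample_pvalue(self):
        # type k = {0.9, 0.8, 0.7} vs others {0.1, 0.2}: one-sided p = 1/C(5,3)
        m = make_scores(["TF"], list("abcde"), [[0.9, 0.8, 0.7, 0.1, 0.2]])
        labels = np.asarray(["k", "k", "k", "o", "o"], dtype=object)
        p = tf_enrichment_pvalues(m, labels)
        assert p.loc["TF", "k"] == pytest.approx(0.1)
        assert enriched_tfs(m, labels) == set()  # 0.1 is not below 0.001

    def test_single_cell_type_is_error(self):
        m = make_scores(["TF"], list("abc"), [[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError):
            tf_enrichment_pvalues(m, np.asarray(["k", "k", "k"], dtype=object))

    def test_asymptotic_matches_scipy_on_large_groups(self):
        rng = np.random.default_rng(1)
        scores = rng.random(160)[None, :]
        labels = np.asarray(["k"] * 60 + ["o"] * 100, dtype=object)
        m = make_scores(["TF"], [f"c{i}" for i in range(160)], scores)
        p = tf_enrichment_pvalues(m, labels).loc["TF", "k"]
        ref = stats.mannwhitneyu(
            scores[0, :60], scores[0, 60:], alternative="greater", method="asymptotic"
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-10)

    def test_max_tfs_cap_keeps_lowest_p(self):
        rng = np.random.default_rng(2)
        base = rng.random(40)
        strong = np.concatenate([base[:20] + 2.0, base[20:]]) / 3.0
        weak = np.concatenate([base[:20] + 0.8, base[20:]]) / 3.0
        m = make_scores(["TFS", "TFW"], [f"c{i}" for i in range(40)],
                        np.vstack([strong, weak]))
        labels = np.asarray(["k"] * 20 + ["o"] * 20, dtype=object)
        cfg = CCCIConfig(max_tfs_per_celltype=1)
        assert enriched_tfs(m, labels, cfg) == {("k", "TFS")}


class TestReceptorTfCorrelation:
    def _db(self):
        return simple_db([("L1", "R1")])

    def test_perfect_monotone_gives_rho_one(self):
        expr = np.vstack([np.arange(8), np.zeros(8), np.ones(8)])
        ds = make_dataset(expr, ["R1", "L1", "F"], ["A"] * 4 + ["B"] * 4)
        tf = make_scores(["TF"], ds.cells, [np.arange(8) ** 2 / 49.0])
        rho = receptor_tf_correlation(ds, tf, self._db())
        assert rho[("R1", "TF")] == pytest.approx(1.0)

    def test_constant_receptor_absent(self):
        expr = np.vstack([np.ones(6), np.zeros(6)])
        ds = make_dataset(expr, ["R1", "L1"], ["A"] * 3 + ["B"] * 3)
        tf = make_scores(["TF"], ds.cells, [np.linspace(0, 1, 6)])
        assert receptor_tf_correlation(ds, tf, self._db()) == {}

    def test_regulon_target_excluded(self):
        expr = np.vstack([np.arange(6), np.zeros(6)])
        ds = make_dataset(expr, ["R1", "L1"], ["A"] * 3 + ["B"] * 3)
        tf = make_scores(["TF"], ds.cells, [np.linspace(0, 1, 6)])
        regs = [Regulon("TF", {"R1"})]
        assert receptor_tf_correlation(ds, tf, self._db(), regulons=regs) == {}
        kept = receptor_tf_correlation(
            ds, tf, self._db(), regulons=regs, exclude_regulon_targets=False
        )
        assert ("R1", "TF") in kept

    def test_receptor_gene_absent_from_dataset(self):
        ds = make_dataset([[1, 2, 3, 4]], ["OTHER"], ["A"] * 2 + ["B"] * 2)
        tf = make_scores(["TF"], ds.cells, [np.linspace(0, 1, 4)])
        assert receptor_tf_correlation(ds, tf, self._db()) == {}

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(3)
        expr = rng.poisson(2, size=(2, 25)).astype(float)
        ds = make_dataset(expr, ["R1", "L1"], ["A"] * 12 + ["B"] * 13)
        tf_vals = rng.random(25)
        tf = make_scores(["TF"], ds.cells, [tf_vals])
        rho = receptor_tf_correlation(ds, tf, self._db())
        ref = stats.spearmanr(expr[0], tf_vals).statistic
        assert rho[("R1", "TF")] == pytest.approx(ref, abs=1e-12)


class TestGates:
    GENES = ["R1", "L1"]

    def test_intracellular_all_gates_pass_at_defaults(self):
        prof = profile("B", self.GENES, [0.0, 0.0], [0.10, 0.0])
        tfs_rec, rec = intracellular_linkages(
            [prof], {("B", "TF")}, {("R1", "TF"): 0.2}, simple_db([("L1", "R1")])
        )
        assert tfs_rec == {("B", "TF", "R1")} and rec == {("B", "R1")}

    @pytest.mark.parametrize(
        "rho,pct,expected",
        [
            (0.15, 0.05, True),   # both thresholds inclusive at the boundary
            (0.1499, 0.05, False),
            (0.15, 0.0499, False),
            (0.14, 0.10, False),
        ],
    )
    def test_gate_boundaries(self, rho, pct, expected):
        prof = profile("B", self.GENES, [0.0, 0.0], [pct, 0.0])
        tfs_rec, _ = intracellular_linkages(
            [prof], {("B", "TF")}, {("R1", "TF"): rho}, simple_db([("L1", "R1")])
        )
        assert (("B", "TF", "R1") in tfs_rec) is expected

    def test_unenriched_tf_gives_no_linkage(self):
        prof = profile("B", self.GENES, [0.0, 0.0], [0.5, 0.0])
        tfs_rec, _ = intracellular_linkages(
            [prof], set(), {("R1", "TF"): 0.9}, simple_db([("L1", "R1")])
        )
        assert tfs_rec == set()

    def test_two_component_receptor_requires_all_components(self):
        from linksig import GeneComplex, LRDatabase, LRInteraction

        db = LRDatabase(
            [
                LRInteraction(
                    "i", GeneComplex("L1", ("L1",)), GeneComplex("RC", ("Ra", "Rb"))
                )
            ]
        )
        genes = ["Ra", "Rb", "L1"]
        cors = {("Ra", "TF"): 0.5, ("Rb", "TF"): 0.5}
        ok = profile("B", genes, [0] * 3, [0.06, 0.05, 0])
        bad = profile("B", genes, [0] * 3, [0.06, 0.04, 0])
        assert intracellular_linkages([ok], {("B", "TF")}, cors, db)[0] == {("B", "TF", "RC")}
        assert intracellular_linkages([bad], {("B", "TF")}, cors, db)[0] == set()

    def test_complex_rho_is_minimum_over_components(self):
        from linksig import GeneComplex, LRDatabase, LRInteraction

        db = LRDatabase(
            [
                LRInteraction(
                    "i", GeneComplex("L1", ("L1",)), GeneComplex("RC", ("Ra", "Rb"))
                )
            ]
        )
        prof = profile("B", ["Ra", "Rb", "L1"], [0] * 3, [0.5, 0.5, 0])
        cors = {("Ra", "TF"): 0.5, ("Rb", "TF"): 0.14}
        assert intracellular_linkages([prof], {("B", "TF")}, cors, db)[0] == set()

    def test_max_recs_per_tf_keeps_highest_rho(self):
        db = simple_db([("L1", "R1"), ("L2", "R2")])
        prof = profile("B", ["R1", "R2", "L1", "L2"], [0] * 4, [0.5] * 4)
        cors = {("R1", "TF"): 0.9, ("R2", "TF"): 0.5}
        cfg = CCCIConfig(max_recs_per_tf=1)
        tfs_rec, _ = intracellular_linkages([prof], {("B", "TF")}, cors, db, cfg)
        assert tfs_rec == {("B", "TF", "R1")}

    @pytest.mark.parametrize(
        "mean_scaled,expected",
        [(0.5, True), (0.0, False), (-0.1, False)],
    )
    def test_sender_gate_is_strict(self, mean_scaled, expected):
        prof = profile("A", self.GENES, [0.0, mean_scaled], [0.0, 0.5])
        senders = ligand_senders([prof], simple_db([("L1", "R1")]))
        assert (("A", "L1") in senders) is expected

    def test_multi_component_ligand_requires_all(self):
        from linksig import GeneComplex, LRDatabase, LRInteraction

        db = LRDatabase(
            [
                LRInteraction(
                    "i", GeneComplex("LC", ("La", "Lb")), GeneComplex("R1", ("R1",))
                )
            ]
        )
        prof = profile("A", ["La", "Lb", "R1"], [0.3, -0.1, 0.0], [0.5] * 3)
        assert ligand_senders([prof], db) == set()


def _fixture(seed=0, n_per_type=12):
    """Seeded 2-type fixture with receptors, ligands and one filler gene."""
    rng = np.random.default_rng(seed)
    genes = ["R1", "R2", "L1", "L2", "F1"]
    n = 2 * n_per_type
    expr = rng.poisson(1.0, size=(len(genes), n)).astype(float)
    ds = make_dataset(expr, genes, ["A"] * n_per_type + ["B"] * n_per_type)
    tf = make_scores(
        ["TF1", "TF2"], ds.cells, np.clip(rng.normal(0.5, 0.2, size=(2, n)), 0, 1)
    )
    return ds, tf, simple_db([("L1", "R1"), ("L2", "R2")])


def _rule_oracle(ds, tf, db, cfg):
    """Independent, direct evaluation of the published inference rules."""
    expr = ds.expr
    scaled = (expr - expr.mean(axis=1, keepdims=True))
    sd = expr.std(axis=1, keepdims=True)
    scaled = np.divide(scaled, sd, out=np.zeros_like(scaled), where=sd > 0)
    types = ["A", "B"]
    gidx = {g: i for i, g in enumerate(ds.genes)}

    enriched = set()
    for ct in types:
        mask = ds.cell_type == ct
        for ti, tf_name in enumerate(tf.tfs):
            x, y = tf.scores[ti, mask], tf.scores[ti, ~mask]
            tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
            p = stats.mannwhitneyu(
                x, y, alternative="greater",
                method="exact" if tie_free else "asymptotic",
            ).pvalue
            if p < cfg.min_tf_pval:
                enriched.add((ct, tf_name))

    tfs_rec = set()
    for ct in types:
        mask = ds.cell_type == ct
        for ti, tf_name in enumerate(tf.tfs):
            if (ct, tf_name) not in enriched:
                continue
            for rec in ("R1", "R2"):
                r = expr[gidx[rec]]
                if r.std() == 0 or tf.scores[ti].std() == 0:
                    continue
                rho = stats.spearmanr(r, tf.scores[ti]).statistic
                pct = (r[mask] > 0).mean()
                if rho >= cfg.rec_tf_cor_threshold and pct >= cfg.min_rec_percentage:
                    tfs_rec.add((ct, tf_name, rec))
    rec_set = {(ct, r) for ct, _, r in tfs_rec}

    senders = set()
    for ct in types:
        mask = ds.cell_type == ct
        for lig in ("L1", "L2"):
            if scaled[gidx[lig], mask].mean() > cfg.sender_mean_scaled_threshold:
                senders.add((ct, lig))

    pairs = {"R1": "L1", "R2": "L2"}
    cl = {
        (ct, r, pairs[r], s_ct)
        for ct, r in rec_set
        for s_ct, lig in senders
        if lig == pairs[r]
    }
    return enriched, tfs_rec, rec_set, senders, cl


class TestInferSubject:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_matches_rule_evaluation_oracle(self, seed):
        cfg = CCCIConfig(min_tf_pval=0.2, rec_tf_cor_threshold=0.15,
                         min_rec_percentage=0.05)
        ds, tf, db = _fixture(seed)
        out = infer_subject(ds, tf, db, cfg)
        enriched, tfs_rec, rec_set, senders, cl = _rule_oracle(ds, tf, db, cfg)
        assert out.tfs == enriched
        assert out.tfs_rec == tfs_rec
        assert out.rec == rec_set
        assert out.cl_rec_lig == cl
        assert out.incoming_lig == {(ct, l) for ct, _, l, _ in cl}
        out.validate()

    def test_autocrine_assembly(self):
        # B both sends L1 (high in B, low in A) and receives via R1
        n = 30
        rng = np.random.default_rng(10)
        expr = np.zeros((3, 2 * n))
        expr[0, n:] = rng.lognormal(0, 0.2, n)  # R1 in B
        expr[1, n:] = rng.lognormal(0, 0.2, n)  # L1 high in B only
        expr[2, :] = rng.lognormal(0, 0.2, 2 * n)  # filler
        ds = make_dataset(expr, ["R1", "L1", "F"], ["A"] * n + ["B"] * n)
        tf_vals = np.clip(0.5 * (expr[0] > 0) + rng.normal(0.2, 0.05, 2 * n), 0, 1)
        tf = make_scores(["TF1"], ds.cells, [tf_vals])
        out = infer_subject(ds, tf, simple_db([("L1", "R1")]))
        assert ("B", "R1", "L1", "B") in out.cl_rec_lig
        assert ("B", "R1", "L1", "A") not in out.cl_rec_lig

    def test_receptor_without_sender_stays_active_without_linkage(self):
        n = 30
        rng = np.random.default_rng(11)
        expr = np.zeros((3, 2 * n))
        expr[0, n:] = rng.lognormal(0, 0.2, n)  # R1 in B; L1 never expressed
        expr[2, :] = rng.lognormal(0, 0.2, 2 * n)
        ds = make_dataset(expr, ["R1", "L1", "F"], ["A"] * n + ["B"] * n)
        tf_vals = np.clip(0.5 * (expr[0] > 0) + rng.normal(0.2, 0.05, 2 * n), 0, 1)
        tf = make_scores(["TF1"], ds.cells, [tf_vals])
        out = infer_subject(ds, tf, simple_db([("L1", "R1")]))
        assert ("B", "R1") in out.rec
        assert out.cl_rec_lig == set()
        assert out.incoming_lig == set()

    def test_deterministic(self):
        ds, tf, db = _fixture(3)
        cfg = CCCIConfig(min_tf_pval=0.2)
        a = infer_subject(ds, tf, db, cfg)
        b = infer_subject(ds, tf, db, cfg)
        assert a.to_dict() == b.to_dict()

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_threshold_monotonicity(self, seed):
        """Raising rho or pct thresholds never adds a linkage."""
        ds, tf, db = _fixture(seed)
        grids = [
            CCCIConfig(min_tf_pval=0.3, rec_tf_cor_threshold=r, min_rec_percentage=p)
            for r in (-1.0, 0.0, 0.15, 0.5)
            for p in (0.0, 0.05, 0.25)
        ]
        results = {
            (c.rec_tf_cor_threshold, c.min_rec_percentage): infer_subject(ds, tf, db, c)
            for c in grids
        }
        for (r1, p1), out1 in results.items():
            for (r2, p2), out2 in results.items():
                if r2 >= r1 and p2 >= p1:
                    assert out2.tfs_rec <= out1.tfs_rec
                    assert out2.cl_rec_lig <= out1.cl_rec_lig

    def test_multi_subject_requires_subject_argument(self):
        ds, tf, db = _fixture(0)
        ds.subject[:5] = "s2"
        with pytest.raises(ValueError):
            infer_subject(ds, tf, db)
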