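"""Clustering of gene-body 5hmC, expression summaries and dynamics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hmcscan as h


def _matrix(values, cell_types=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    cell_types = cell_types or [f"ct{j}" for j in range(values.shape[1])]
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return h.GeneBodyMatrix(pd.DataFrame(values, index=gene_ids, columns=cell_types))


def _oracle_complete_linkage(points, k):
    """O(n^3) agglomerative complete linkage; returns a partition of indices."""
    clusters = [frozenset([i]) for i in range(len(points))]
    d = lambda a, b: np.linalg.norm(points[a] - points[b])
    while len(clusters) > k:
        best = None
        for ci, cj in itertools.combinations(clusters, 2):
            dist = max(d(a, b) for a in ci for b in cj)
            if best is None or dist < best[0]:
                best = (dist, ci, cj)
        _, ci, cj = best
        clusters = [c for c in clusters if c not in (ci, cj)] + [ci | cj]
    return {frozenset(c) for c in clusters}


def _partition_of(assign):
    return {frozenset(assign.members(c).tolist()) for c in assign.labels.unique()}


class TestClusterGenes:
    def test_planted_groups_recovered_at_k2(self, rng):
        high = rng.normal(100, 3, size=(30, 4))
        low = rng.normal(2, 0.5, size=(30, 4))
        m = _matrix(np.vstack([high, low]))
        assign = h.cluster_genes(m, k=2)
        labels = assign.labels
        assert labels.iloc[:30].nunique() == 1 and labels.iloc[30:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_row_permutation_invariant_partition(self, rng):
        vals = rng.gamma(2, 10, size=(40, 3))
        m1 = _matrix(vals)
        perm = rng.permutation(40)
        m2 = h.GeneBodyMatrix(m1.values.iloc[perm])
        p1 = {frozenset(s) for s in map(tuple, map(sorted, map(list, _partition_of(h.cluster_genes(m1, 5)))))}
        p2 = {frozenset(s) for s in map(tuple, map(sorted, map(list, _partition_of(h.cluster_genes(m2, 5)))))}
        assert p1 == p2

    @pytest.mark.parametrize("n,k", [(12, 2), (20, 4), (50, 6)])
    def test_matches_brute_force_complete_linkage(self, rng, n, k):
        vals = rng.gamma(2.0, 5.0, size=(n, 3))
        m = _matrix(vals)
        got = {frozenset(int(g[1:]) for g in c) for c in _partition_of(h.cluster_genes(m, k))}
        # the oracle must see the same transformed coordinates the method uses
        pts = m.log2().values.to_numpy()
        expected = _oracle_complete_linkage(pts, k)
        assert got == expected

    def test_k_exceeding_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            h.cluster_genes(_matrix(rng.random((5, 2))), k=6)

    def test_missing_levels_imputed_zero_before_log(self):
        df = pd.DataFrame({"a": [np.nan, 3.0], "b": [1.0, 1.0]}, index=["g0", "g1"])
        m = h.GeneBodyMatrix(df).log2()
        assert m.values.loc["g0", "a"] == 0.0
        assert m.values.loc["g1", "a"] == pytest.approx(2.0)

    def test_two_stage_selects_planted_high_cluster(self, rng):
        high = rng.normal(80, 5, size=(40, 4))
        low = rng.normal(3, 1, size=(120, 4))
        m = _matrix(np.vstack([high, low]))
        first = h.cluster_genes(m, k=3)
        hc = h.select_high_cluster(m, first)
        members = set(first.members(hc))
        planted = {f"g{i}" for i in range(40)}
        jaccard = len(members & planted) / len(members | planted)
        assert jaccard >= 0.95


class TestClusterExpressionSummary:
    def _assign(self, labels):
        s = pd.Series(labels, index=[f"g{i}" for i in range(len(labels))], name="cluster")
        return h.ClusterAssignment(s, k=len(set(labels)))

    def test_constant_fpkm_mean_and_zero_ci(self):
        assign = self._assign([1, 1, 1, 1])
        expr = {"ct": pd.DataFrame({"gene_id": [f"g{i}" for i in range(4)], "fpkm": 4.0})}
        out = h.cluster_expression_summary(assign, expr)
        row = out.iloc[0]
        assert row["mean_log2_fpkm"] == pytest.approx(2.0)
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0)

    def test_fpkm_exactly_one_excluded(self):
        assign = self._assign([1, 1, 1])
        expr = {"ct": pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "fpkm": [1.0, 1.0, 8.0]})}
        out = h.cluster_expression_summary(assign, expr)
        assert out.iloc[0]["n_genes"] == 1
        assert out.iloc[0]["mean_log2_fpkm"] == pytest.approx(3.0)

    def test_empty_cluster_cell_pair_is_missing_not_zero(self):
        assign = self._assign([1, 2])
        expr = {"ct": pd.DataFrame({"gene_id": ["g0", "g1"], "fpkm": [4.0, 0.5]})}
        out = h.cluster_expression_summary(assign, expr).set_index("cluster")
        assert np.isnan(out.loc[2, "mean_log2_fpkm"])

    def test_planted_cluster_specific_expression(self, rng):
        labels = [1] * 20 + [2] * 20
        assign = self._assign(labels)
        ids = [f"g{i}" for i in range(40)]
        expr = {
            "A": pd.DataFrame({"gene_id": ids, "fpkm": [50.0] * 20 + [2.0] * 20}),
            "B": pd.DataFrame({"gene_id": ids, "fpkm": [2.0] * 20 + [50.0] * 20}),
        }
        out = h.cluster_expression_summary(assign, expr).set_index(["cell_type", "cluster"])
        assert out.loc[("A", 1), "mean_log2_fpkm"] > out.loc[("A", 2), "mean_log2_fpkm"]
        assert out.loc[("B", 2), "mean_log2_fpkm"] > out.loc[("B", 1), "mean_log2_fpkm"]


class TestDeltaAnalysis:
    def _tables(self, fpkm_p, fpkm_m, hmc_p, hmc_m):
        ids = [f"g{i}" for i in range(len(fpkm_p))]
        mk_e = lambda v: pd.DataFrame({"gene_id": ids, "fpkm": v})
        mk_h = lambda v: pd.DataFrame({"gene_id": ids, "level": v})
        return mk_e(fpkm_p), mk_e(fpkm_m), mk_h(hmc_p), mk_h(hmc_m)

    def test_lfc_arithmetic_and_categories(self):
        t = self._tables([2.0, 8.0, 4.0], [16.0, 2.0, 5.0], [5.0] * 3, [5.0] * 3)
        df, _ = h.delta_analysis(*t)
        rec = df.set_index("gene_id")
        assert rec.loc["g0", "lfc"] == pytest.approx(3.0)
        assert rec.loc["g0", "category"] == "increase"
        assert rec.loc["g1", "category"] == "loss"
        assert rec.loc["g2", "category"] == "unchanged"

    def test_antisymmetric_under_cell_type_swap(self, rng):
        fp = rng.lognormal(2, 1, 50) + 1.5
        fm = rng.lognormal(2, 1, 50) + 1.5
        hp = rng.lognormal(1.5, 0.5, 50) + 1.5
        hm = rng.lognormal(1.5, 0.5, 50) + 1.5
        d1, _ = h.delta_analysis(*self._tables(fp, fm, hp, hm))
        d2, _ = h.delta_analysis(*self._tables(fm, fp, hm, hp))
        m = d1.set_index("gene_id").join(d2.set_index("gene_id"), rsuffix="_swap")
        assert np.allclose(m["lfc"], -m["lfc_swap"])
        swapped = {"increase": "loss", "loss": "increase", "unchanged": "unchanged"}
        assert (m["category"].map(swapped) == m["category_swap"]).all()

    def test_identical_cell_types_all_unchanged_rho_flagged(self):
        t = self._tables([4.0, 8.0, 2.0], [4.0, 8.0, 2.0], [5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        df, rho = h.delta_analysis(*t)
        assert (df["category"] == "unchanged").all()
        assert rho is None  # constant LFC vector: correlation undefined

    def test_filter_at_least_one_side_above_one(self):
        # g0 passes (mature side), g1 fails everywhere, strict mode drops g0 too
        t = self._tables([0.5, 0.5], [4.0, 0.9], [0.2, 0.1], [3.0, 0.3])
        df, _ = h.delta_analysis(*t)
        assert df["gene_id"].tolist() == ["g0"]
        with pytest.raises(ValueError):
            h.delta_analysis(*t, strict_both=True)

    def test_planted_coupling_recovers_positive_rho(self, bundle_small):
        genes = bundle_small["genome"].genes
        hmc = {ct: h.gene_body_levels(genes, bundle_small["rrhp"][(ct, 1)])
               for ct in ("hESC", "CD34")}
        expr = bundle_small["expression"]
        df, rho = h.delta_analysis(expr["hESC"], expr["CD34"], hmc["hESC"], hmc["CD34"],
                                   n_perm=500, seed=9)
        assert rho is not None and rho.rho > 0.3 and rho.p < 0.01


class TestBivalentState:
    @pytest.mark.parametrize("meth,hmc,fpkm,expected", [
        (80.0, 9.0, 0.2, "primed"),
        (5.0, 9.0, 30.0, "expressed"),
        (80.0, 1.0, 0.1, "repressed"),
    ])
    def test_rule_application(self, meth, hmc, fpkm, expected):
        res = h.bivalent_state(meth, hmc, fpkm, hmc_high=5.0)
        assert res.state == expected
        assert res.thresholds == (50.0, 5.0, 1.0)

    def test_missing_measurement_unknown(self):
        assert h.bivalent_state(None, 9.0, 1.0, hmc_high=5.0).state == "unknown"
        assert h.bivalent_state(50.0, 9.0, 1.0, hmc_high=None).state == "unknown"

    def test_invalid_percentage_rejected(self):
        with pytest.raises(ValueError):
            h.bivalent_state(120.0, 9.0, 1.0, hmc_high=5.0)
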