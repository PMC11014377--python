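import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agingtx import (
    ModuleConfig,
    SimConfig,
    detect_modules,
    generate_transcript_catalog,
    module_overlap,
    run_wgcna_like,
    signed_adjacency,
    simulate_count_matrices,
    topological_overlap,
)

from conftest import make_matrix


def _log_matrix(m):
    return m.with_values(np.log2(m.values + 1.0))


class TestSignedAdjacency:
    def test_correlation_boundaries(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_matrix(np.vstack([x, 2 * x, -x + 10]), n_young=2, n_aged=2)
        adj = signed_adjacency(m, beta=18).to_numpy()
        assert adj[0, 1] == pytest.approx(1.0)          # rho = +1
        assert adj[0, 2] == pytest.approx(0.0, abs=1e-12)  # rho = -1

    def test_zero_correlation_value(self):
        x = np.array([2.0, 0.0, 2.0, 0.0])
        y = np.array([2.0, 2.0, 0.0, 0.0])
        m = make_matrix(np.vstack([x, y]), n_young=2, n_aged=2)
        adj = signed_adjacency(m, beta=18).to_numpy()
        assert adj[0, 1] == pytest.approx(0.5 ** 18)

    def test_zero_variance_gene_is_named(self):
        m = make_matrix([[1, 1, 1, 1], [1, 2, 3, 4]], n_young=2, n_aged=2)
        with pytest.raises(ValueError, match="f0"):
            signed_adjacency(m, beta=6)


class TestTopologicalOverlap:
    def test_identical_binary_neighborhoods_with_full_edge(self):
        # nodes a and b fully linked and sharing their whole neighborhood
        a = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        adj = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
        tom = topological_overlap(adj).to_numpy()
        assert tom[0, 1] == pytest.approx(1.0)

    def test_three_node_formula_arithmetic(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
        tom = topological_overlap(adj).to_numpy()
        # shared = 0.5*0.5; k = 0.5+0.5 = 1 -> (0.25 + 0.5)/(1 + 1 - 0.5)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        n = 20
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        tom = topological_overlap(adj).to_numpy()
        k = a.sum(axis=1) - 1
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            topological_overlap(pd.DataFrame(a, index=list("ab"), columns=list("ab")))


def _block_design(seed, module_effect=0.0):
    cfg = SimConfig(n_genes=200, isoforms_per_gene=(1, 1), n_modules=5,
                    module_size=40, module_effect=module_effect,
                    switch_fraction=0.0, seed=seed)
    catalog, _ = generate_transcript_catalog(cfg)
    gene_m, _, gene_truth, _ = simulate_count_matrices(catalog, cfg)
    return gene_m, gene_truth


class TestModuleDetection:
    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        gene_m, truth = _block_design(seed=9)
        asg = run_wgcna_like(_log_matrix(gene_m), ModuleConfig.desk_scale())
        ari = adjusted_rand_score(truth.loc[asg.labels.index, "module"], asg.labels)
        assert ari >= 0.9

    def test_planted_age_shift_detected_with_sign(self):
        gene_m, truth = _block_design(seed=12, module_effect=0.5)
        asg = run_wgcna_like(_log_matrix(gene_m), ModuleConfig.desk_scale())
        # map detected modules onto planted blocks via majority label
        joined = truth.loc[asg.labels.index].assign(found=asg.labels)
        for planted, sub in joined.groupby("module"):
            detected = sub["found"].mode()[0]
            if detected == "M0":
                continue
            row = asg.direction.loc[detected]
            want = "up" if sub["age_lfc"].iloc[0] > 0 else "down"
            assert row["padj"] <= 0.05
            assert row["direction"] == want

    def test_iid_noise_goes_unassigned(self):
        cfg = SimConfig(n_genes=200, isoforms_per_gene=(1, 1), n_modules=1,
                        module_size=1, module_effect=0.0, switch_fraction=0.0,
                        de_fraction=0.0, seed=10)
        catalog, _ = generate_transcript_catalog(cfg)
        gene_m, _, _, _ = simulate_count_matrices(catalog, cfg)
        asg = run_wgcna_like(_log_matrix(gene_m), ModuleConfig.desk_scale())
        assert (asg.labels == "M0").mean() >= 0.95

    def test_gene_order_invariance(self):
        gene_m, _ = _block_design(seed=9)
        logged = _log_matrix(gene_m)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(logged.feature_ids))
        shuffled = logged.with_values(logged.values.iloc[perm])
        a = run_wgcna_like(logged, ModuleConfig.desk_scale()).labels
        b = run_wgcna_like(shuffled, ModuleConfig.desk_scale()).labels
        # same partition of gene ids, compared order-independently
        grp_a = {g: sorted(a.index[a == a[g]]) for g in a.index}
        grp_b = {g: sorted(b.index[b == b[g]]) for g in b.index}
        assert grp_a == grp_b

    def test_eigengene_dominates_single_members(self):
        gene_m, _ = _block_design(seed=9)
        logged = _log_matrix(gene_m)
        asg = run_wgcna_like(logged, ModuleConfig.desk_scale())
        for module in asg.module_names():
            members = asg.members(module)
            z = logged.values.loc[members].to_numpy()
            z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
            eg = asg.eigengenes.loc[module].to_numpy()
            var_eg = np.mean((z @ eg / np.linalg.norm(eg)) ** 2)
            for row in z:
                v = row / np.linalg.norm(row)
                assert var_eg >= np.mean((z @ v) ** 2) - 1e-9

    def test_fewer_genes_than_min_size_all_unassigned(self):
        gene_m, _ = _block_design(seed=9)
        small = gene_m.with_values(_log_matrix(gene_m).values.iloc[:10])
        adj = signed_adjacency(small, beta=6)
        tom = topological_overlap(adj)
        with pytest.warns(UserWarning):
            asg = detect_modules(tom, ModuleConfig.desk_scale(), small)
        assert (asg.labels == "M0").all()


class TestModuleOverlap:
    def _assignment(self):
        gene_m, _ = _block_design(seed=9)
        return run_wgcna_like(_log_matrix(gene_m), ModuleConfig.desk_scale())

    def test_identical_list_has_ratio_one(self):
        asg = self._assignment()
        universe = list(asg.labels.index)
        m1 = asg.members("M1")
        res = module_overlap(asg, {"exact": m1}, universe)
        row = res[(res["module"] == "M1") & (res["list"] == "exact")].iloc[0]
        assert row["ratio"] == pytest.approx(1.0)
        assert row["p"] < 1e-10

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        asg = self._assignment()
        universe = list(asg.labels.index)
        rng = np.random.default_rng(5)
        lst = list(rng.choice(universe, size=20, replace=False))
        res = module_overlap(asg, {"random": lst}, universe)
        for _, row in res[res["list"] == "random"].iterrows():
            mod = set(asg.members(row["module"]))
            k = len(mod & set(lst))
            p = stats.hypergeom.sf(k - 1, len(universe), len(mod), len(lst))
            assert row["p"] == pytest.approx(p, abs=1e-10)

    def test_disjoint_list_reported_missing(self):
        asg = self._assignment()
        universe = list(asg.labels.index)
        res = module_overlap(asg, {"alien": ["zz1", "zz2"]}, universe)
        assert res[res["list"] == "alien"]["ratio"].isna().all()
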