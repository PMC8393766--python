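"""Network construction, TOM, module detection and eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from betameth.coexpression import (
    CoexpressionNetwork,
    adjacency,
    assign_eigengenes,
    choose_soft_power,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    scale_free_fit,
    tom,
)
from betameth.expression import filter_counts, normalize_transform

from oracles import tom_oracle


class TestTom:
    def test_two_fully_connected_genes(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        t = tom(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_three_node_hand_computation(self):
        a = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        t = tom(a)
        # genes 2,3: shared neighbour 1 contributes 0.25, direct link 0
        assert t[1, 2] == pytest.approx(0.25 / (0.5 + 1.0), rel=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (50, 50))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom(a), tom_oracle(a), atol=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (20, 20))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom(a)
        assert np.allclose(t, t.T, atol=1e-14)
        assert t.min() >= 0 and t.max() <= 1 + 1e-12
        assert np.allclose(np.diag(t), 1.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            tom(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestSoftPower:
    def test_fit_matches_independent_loglog_regression(self):
        rng = np.random.default_rng(2)
        k = rng.pareto(2.0, 500) + 0.5  # heavy-tailed connectivity
        r2, slope = scale_free_fit(k, n_bins=8)
        edges = np.linspace(k.min(), k.max() + 1e-12, 9)
        which = np.clip(np.digitize(k, edges) - 1, 0, 7)
        lk, lf = [], []
        for b in range(8):
            sel = which == b
            if sel.sum():
                lk.append(np.log10(k[sel].mean()))
                lf.append(np.log10(sel.mean()))
        r_ref = np.corrcoef(lk, lf)[0, 1]
        assert r2 == pytest.approx(r_ref**2, rel=1e-10)
        assert slope == pytest.approx(np.polyfit(lk, lf, 1)[0], rel=1e-10)

    def test_selection_deterministic(self, small_bundle):
        log_expr = normalize_transform(filter_counts(small_bundle.counts))
        p1, _ = choose_soft_power(log_expr)
        p2, _ = choose_soft_power(log_expr)
        assert p1 == p2

    def test_pure_noise_takes_warning_path(self, caplog):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(40, 30)))
        with caplog.at_level("WARNING"):
            power, diag = choose_soft_power(expr, powers=[1, 2, 3], fit_target=0.99)
        assert power in (1, 2, 3)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            adjacency(pd.DataFrame(np.ones((2, 5))), power=6)


def _block_network(sizes=(30, 30), within=0.8, between=0.02):
    n = sum(sizes)
    a = np.full((n, n), between)
    start = 0
    for s in sizes:
        a[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(a, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return CoexpressionNetwork(genes, 6, "unsigned", tom(a), a.sum(0) - 1)


class TestDetectModules:
    def test_two_separated_blocks_recovered_exactly(self):
        net = _block_network()
        modules = detect_modules(net, min_size=10)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, modules.labels) == pytest.approx(1.0)
        named = modules.sizes.drop("grey", errors="ignore")
        assert len(named) == 2

    def test_largest_module_is_turquoise(self):
        net = _block_network(sizes=(40, 25))
        modules = detect_modules(net, min_size=10)
        assert modules.sizes.index[0] == "turquoise"
        assert modules.sizes.iloc[0] == 40

    def test_small_clusters_relabelled_grey(self):
        net = _block_network(sizes=(30, 8))
        modules = detect_modules(net, min_size=15)
        assert (modules.labels.iloc[30:] == "grey").all()

    def test_deterministic(self, small_bundle):
        log_expr = normalize_transform(filter_counts(small_bundle.counts))
        adj = adjacency(log_expr, 6)
        net = CoexpressionNetwork(log_expr.index.tolist(), 6, "unsigned",
                                  tom(adj), adj.sum(0) - 1)
        m1 = detect_modules(net, min_size=15)
        m2 = detect_modules(net, min_size=15)
        assert m1.labels.equals(m2.labels)

    def test_min_size_larger_than_gene_count_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(_block_network(), min_size=10_000)

    def test_planted_modules_recovered(self, small_bundle):
        log_expr = normalize_transform(filter_counts(small_bundle.counts))
        power, _ = choose_soft_power(log_expr)
        adj = adjacency(log_expr, power)
        net = CoexpressionNetwork(log_expr.index.tolist(), power, "unsigned",
                                  tom(adj), adj.sum(0) - 1)
        modules = detect_modules(net, min_size=15)
        truth = small_bundle.truth["module_labels"].reindex(modules.labels.index)
        assert adjusted_rand_score(truth, modules.labels) > 0.7


class TestEigengene:
    def test_shared_profile_reproduced(self):
        profile = np.array([1.0, -0.5, 0.3, 2.0, -1.2, 0.1])
        expr = pd.DataFrame(
            np.vstack([2 * profile + 1, -0.5 * (-profile) + 3, profile]),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(6)],
        )
        eig, var = module_eigengene(expr, ["a", "b", "c"])
        z = (profile - profile.mean()) / profile.std()
        assert var == pytest.approx(1.0, abs=1e-12)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert np.corrcoef(eig, z)[0, 1] > 0  # oriented with the mean profile

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(4, 6)),
                            index=list("abcd"), columns=[f"s{i}" for i in range(6)])
        eig, var = module_eigengene(expr, list("abcd"))
        x = expr.to_numpy()
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        _, s, vt = np.linalg.svd(xs, full_matrices=False)
        ref = vt[0]
        assert (np.allclose(eig, ref, atol=1e-10) or np.allclose(eig, -ref, atol=1e-10))
        assert var == pytest.approx(s[0] ** 2 / (s**2).sum(), rel=1e-12)

    def test_gene_order_invariance_and_sign_flip(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(5, 8)), index=list("abcde"))
        e1, _ = module_eigengene(expr, list("abcde"))
        e2, _ = module_eigengene(expr.loc[list("edcba")], list("edcba"))
        assert np.allclose(e1, e2, atol=1e-10)
        e3, _ = module_eigengene(-expr, list("abcde"))
        assert np.allclose(e3, -e1, atol=1e-10)

    def test_missing_member_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(6).normal(size=(3, 5)),
                            index=list("abc"))
        with pytest.raises(KeyError, match="absent"):
            module_eigengene(expr, ["a", "zzz"])

    def test_planted_factor_recovered(self, small_bundle):
        log_expr = normalize_transform(filter_counts(small_bundle.counts))
        labels = small_bundle.truth["module_labels"]
        members = [g for g in labels.index[labels == "M1"] if g in log_expr.index]
        eig, _ = module_eigengene(log_expr, members)
        f1 = small_bundle.truth["factors"]["M1"]
        assert abs(np.corrcoef(eig, f1)[0, 1]) > 0.95


class TestModuleTraitCorrelation:
    def test_self_correlation_is_one(self):
        v = np.random.default_rng(7).normal(size=30)
        res = module_trait_correlation(v, v)
        assert res["r"] == pytest.approx(1.0, abs=1e-12)

    def test_eigengene_methylation_link_recovered(self, small_bundle):
        log_expr = normalize_transform(filter_counts(small_bundle.counts))
        labels = small_bundle.truth["module_labels"]
        members = [g for g in labels.index[labels == "M1"] if g in log_expr.index]
        eig, _ = module_eigengene(log_expr, members)
        res = module_trait_correlation(eig, small_bundle.expr_phenotypes["focal_cpg_beta"])
        assert res["r"] < 0
        assert res["r"] == pytest.approx(-0.33, abs=0.18)  # n=120 here


def test_assign_eigengenes_covers_every_named_module(small_bundle):
    log_expr = normalize_transform(filter_counts(small_bundle.counts))
    adj = adjacency(log_expr, 6)
    net = CoexpressionNetwork(log_expr.index.tolist(), 6, "unsigned",
                              tom(adj), adj.sum(0) - 1)
    modules = assign_eigengenes(log_expr, detect_modules(net, min_size=15))
    named = [m for m in modules.sizes.index if m != "grey"]
    assert set(modules.eigengenes.columns) == set(named)
    for m in named:
        assert 0 < modules.variance_explained[m] <= 1
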