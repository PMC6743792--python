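import numpy as np
import pandas as pd
import pytest

from boolpath import (
    Contrast,
    Rule,
    RuleSet,
    SignedDiGraph,
    SimulationConfig,
    export_annotated_network,
    fold_difference,
    generate_random_network,
    hold_rule,
    impact_score,
    impact_scores,
    modulation_score,
    pathway_pvalue,
    random_ruleset,
    read_graph,
    run_pathway_analysis,
)
from boolpath.inference import initial_probabilities
from boolpath.pathway import analyze_pathway, fold_differences
from boolpath.propagation import exact_state_distribution


def const_probs(graph, n_samples=3, value=0.5):
    nodes = sorted(graph.nodes)
    return pd.DataFrame(value, index=nodes,
                        columns=[f"s{i}" for i in range(n_samples)])


class TestImpactScore:
    def test_isolated_node_equals_sample_count(self):
        g = SignedDiGraph()
        g.add_nodes_from("AB")
        g.add_signed_edge("A", "B", 1)
        rs = RuleSet(graph=g, rules={"A": hold_rule("A"),
                                     "B": Rule("B", ("A",), (1,), 1)})
        d = 4
        cfg = SimulationConfig(runs=100, steps=10, tail=3, seed=0)
        # B has no out-edges: clamping it changes only its own column
        assert impact_score(rs, const_probs(g, d), cfg, "B") == pytest.approx(d)

    def test_chain_source_impact_two_d(self):
        g = SignedDiGraph()
        g.add_nodes_from("AB")
        g.add_signed_edge("A", "B", 1)
        rs = RuleSet(graph=g, rules={"A": hold_rule("A"),
                                     "B": Rule("B", ("A",), (1,), 1)})
        d = 3
        cfg = SimulationConfig(runs=400, steps=15, tail=3, seed=1)
        # verify against the exact oracle: B copies A, so I_A = d (A) + d (B)
        ko = exact_state_distribution(rs, {"A": 0.5, "B": 0.5}, cfg, clamps={"A": 0})
        ki = exact_state_distribution(rs, {"A": 0.5, "B": 0.5}, cfg, clamps={"A": 1})
        assert float(((ko - ki) ** 2).sum()) * d == pytest.approx(2 * d)
        assert impact_score(rs, const_probs(g, d), cfg, "A") == pytest.approx(2 * d)

    @pytest.mark.parametrize("seed", range(10))
    def test_agreement_with_exact_oracle(self, seed):
        g = generate_random_network(6, seed=seed)
        rs = random_ruleset(g, seed=seed + 500)
        gene = sorted(g.nodes)[seed % 6]
        cfg = SimulationConfig(runs=2000, steps=15, tail=3, seed=seed)
        d = 2
        probs = const_probs(g, d)
        exact = 0.0
        for col in probs:
            ko = exact_state_distribution(rs, probs[col], cfg, clamps={gene: 0})
            ki = exact_state_distribution(rs, probs[col], cfg, clamps={gene: 1})
            exact += float(((ko - ki) ** 2).sum())
        mc = impact_score(rs, probs, cfg, gene, rng=np.random.default_rng(seed))
        # squared-difference sums over 6 nodes x 2 samples; loose MC bound
        assert abs(mc - exact) < 0.5

    def test_unknown_gene(self):
        g = generate_random_network(5, seed=1)
        rs = random_ruleset(g, seed=2)
        with pytest.raises(ValueError):
            impact_score(rs, const_probs(g), SimulationConfig(runs=10, steps=5, tail=2), "nope")

    def test_invariant_under_relabeling_of_others(self):
        import networkx as nx

        g = generate_random_network(7, seed=3)
        rs = random_ruleset(g, seed=4)
        gene = sorted(g.nodes)[0]
        cfg = SimulationConfig(runs=500, steps=10, tail=3, seed=5)
        i1 = impact_score(rs, const_probs(g), cfg, gene, rng=np.random.default_rng(9))
        mapping = {n: (n if n == gene else f"z_{n}") for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        h.__class__ = SignedDiGraph
        rules2 = {}
        for n, r in rs.rules.items():
            rules2[mapping[n]] = Rule(mapping[n],
                                      tuple(mapping[x] for x in r.regulators),
                                      r.signs, r.term_mask)
        rs2 = RuleSet(graph=h, rules=rules2)
        probs2 = const_probs(h)
        i2 = impact_score(rs2, probs2, cfg, gene, rng=np.random.default_rng(9))
        assert i1 == pytest.approx(i2)


class TestFoldDifference:
    expr = pd.DataFrame(
        {"s1": [8.0, 5.0], "s2": [8.0, 5.0], "t1": [2.0, 5.0], "t2": [2.0, 5.0]},
        index=["g1", "g2"],
    )
    contrast = Contrast(("s1", "s2"), ("t1", "t2"))

    def test_equal_means_q_one(self):
        assert fold_difference(self.expr, "g2", self.contrast) == pytest.approx(1.0)

    def test_pseudocount_arithmetic(self):
        assert fold_difference(self.expr, "g1", self.contrast) == pytest.approx(3.0)

    def test_swap_symmetry(self):
        swapped = Contrast(self.contrast.group2, self.contrast.group1)
        q = fold_difference(self.expr, "g1", self.contrast)
        q_swapped = fold_difference(self.expr, "g1", swapped)
        assert q_swapped == pytest.approx(1 / q)
        assert abs(np.log2(q)) == pytest.approx(abs(np.log2(q_swapped)))

    def test_unknown_gene(self):
        with pytest.raises(ValueError):
            fold_difference(self.expr, "nope", self.contrast)

    def test_vectorized_matches_scalar(self):
        qs = fold_differences(self.expr, self.contrast)
        for g in self.expr.index:
            assert qs[g] == pytest.approx(fold_difference(self.expr, g, self.contrast))


class TestModulationScore:
    def test_all_q_one_gives_zero(self):
        assert modulation_score([3.0, 1.0], [1.0, 1.0], [0.5, 0.5]) == 0.0

    def test_single_gene_arithmetic(self):
        # log2(1+1) * |log2 2| * 0.5 = 0.5
        assert modulation_score([1.0], [2.0], [0.5]) == pytest.approx(0.5)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(0)
        I, q, s = rng.random(6) * 5, rng.random(6) + 0.5, rng.random(6)
        perm = rng.permutation(6)
        assert modulation_score(I, q, s) == pytest.approx(
            modulation_score(I[perm], q[perm], s[perm])
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            modulation_score([1.0], [2.0, 3.0], [0.5, 0.5])


class TestPathwayPvalue:
    def test_add_one_estimator_floor(self):
        impacts = pd.Series([5.0, 5.0], index=["a", "b"])
        # pool of tiny folds: permuted scores all << observed
        pool = pd.DataFrame({"fold": np.full(50, 1.0001), "std": np.full(50, 0.01)})
        p = pathway_pvalue(100.0, impacts, pool, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_degenerate_null_all_q_one(self):
        impacts = pd.Series([5.0, 5.0], index=["a", "b"])
        pool = pd.DataFrame({"fold": np.ones(50), "std": np.full(50, 0.3)})
        p = pathway_pvalue(0.0, impacts, pool, n_perm=99, seed=1)
        assert p == 1.0

    def test_never_zero(self):
        impacts = pd.Series([1.0], index=["a"])
        pool = pd.DataFrame({"fold": np.full(10, 1.5), "std": np.full(10, 0.5)})
        for seed in range(5):
            p = pathway_pvalue(1e9, impacts, pool, n_perm=50, seed=seed)
            assert 0 < p <= 1

    def test_reproducible(self):
        rng = np.random.default_rng(2)
        impacts = pd.Series(rng.random(4), index=list("abcd"))
        pool = pd.DataFrame({"fold": rng.random(30) + 0.5, "std": rng.random(30)})
        p1 = pathway_pvalue(0.5, impacts, pool, n_perm=200, seed=7)
        p2 = pathway_pvalue(0.5, impacts, pool, n_perm=200, seed=7)
        assert p1 == p2

    def test_uniform_under_null(self):
        # network and background genes generated identically, labels carry no
        # signal, impacts fixed: p should be ~ Uniform(0,1) (KS at alpha=0.01)
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        impacts = pd.Series(rng.gamma(2.0, 2.0, size=8),
                            index=[f"g{i}" for i in range(8)])
        pvals = []
        for _ in range(200):
            counts = rng.negative_binomial(5, 0.05, size=(100, 10)).astype(float)
            expr = pd.DataFrame(counts, index=[f"g{i}" for i in range(100)],
                                columns=[f"s{i}" for i in range(10)])
            contrast = Contrast(tuple(expr.columns[:5]), tuple(expr.columns[5:]))
            q = fold_differences(expr, contrast)
            scaled = expr / expr.max(axis=1).to_numpy()[:, None]
            s = scaled.std(axis=1, ddof=0)
            m_obs = modulation_score(impacts, q.iloc[:8], s.iloc[:8])
            pool = pd.DataFrame({"fold": q, "std": s})
            pvals.append(pathway_pvalue(m_obs, impacts, pool, n_perm=200,
                                        seed=int(rng.integers(2**32))))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestRunPathwayAnalysis:
    def _dataset(self, graph, seed=0, n=40, d=6):
        rng = np.random.default_rng(seed)
        genes = sorted(graph.nodes) + [f"bg{i}" for i in range(n - len(graph))]
        expr = pd.DataFrame(rng.poisson(50, size=(len(genes), d)).astype(float),
                            index=genes, columns=[f"s{i}" for i in range(d)])
        return expr

    def test_null_contrast_duplicated_samples(self):
        g = generate_random_network(6, seed=0)
        expr = self._dataset(g, seed=1, d=2)
        # duplicate the two samples so both groups are identical
        expr = pd.concat([expr, expr.add_suffix("_d", axis=1)], axis=1)
        contrast = Contrast(tuple(expr.columns[:2]), tuple(expr.columns[2:]))
        rs = random_ruleset(g, seed=2)
        res = analyze_pathway(g, expr, contrast,
                              sim_cfg=SimulationConfig(runs=100, steps=10, tail=3),
                              n_perm=99, seed=3, ruleset=rs)
        assert res.modulation_score == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_min_gene_filter(self):
        g = generate_random_network(6, seed=4)
        expr = pd.DataFrame(np.ones((3, 4)),
                            index=sorted(g.nodes)[:3],
                            columns=[f"s{i}" for i in range(4)])
        contrast = Contrast(("s0", "s1"), ("s2", "s3"))
        assert analyze_pathway(g, expr, contrast, n_perm=10, seed=0,
                               ruleset=random_ruleset(g, seed=1)) is None
        table = run_pathway_analysis([g], expr, contrast, n_perm=10, seed=0,
                                     rulesets=[random_ruleset(g, seed=1)])
        assert table.empty

    def test_deterministic(self):
        g = generate_random_network(7, seed=5)
        expr = self._dataset(g, seed=6)
        contrast = Contrast(tuple(expr.columns[:3]), tuple(expr.columns[3:]))
        rs = random_ruleset(g, seed=7)
        kwargs = dict(sim_cfg=SimulationConfig(runs=100, steps=10, tail=3),
                      n_perm=50, seed=11, rulesets=[rs])
        t1 = run_pathway_analysis([g], expr, contrast, **kwargs)
        t2 = run_pathway_analysis([g], expr, contrast, **kwargs)
        pd.testing.assert_frame_equal(t1, t2)

    def test_modulated_pathway_ranks_first(self):
        # planted signal in one network's genes; the other network's genes are
        # left at the null -> modulated pathway should win the p-value race
        from boolpath.benchmark import attenuate_and_propagate, simulate_counts

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            g_mod = generate_random_network(8, seed=int(rng.integers(2**32)))
            g_null = generate_random_network(8, seed=int(rng.integers(2**32)))
            import networkx as nx

            g_null = nx.relabel_nodes(g_null, {n: f"u{n}" for n in g_null.nodes})
            g_null.__class__ = SignedDiGraph
            g_mod.graph["name"] = "modulated"
            g_null.graph["name"] = "unmodulated"
            genes = sorted(g_mod.nodes) + sorted(g_null.nodes) + \
                [f"bg{i}" for i in range(30)]
            expr = pd.DataFrame(
                rng.poisson(60, size=(len(genes), 10)).astype(float),
                index=genes, columns=[f"s{i}" for i in range(10)])
            sim = SimulationConfig(runs=150, steps=12, tail=3)
            g1, g2 = list(expr.columns[:5]), list(expr.columns[5:])
            planted = random_ruleset(g_mod, seed=int(rng.integers(2**32)))
            ctrl, _ = attenuate_and_propagate(g_mod, expr[g1], 0.0, seed=rng,
                                              ruleset=planted, sim_cfg=sim)
            trt, _ = attenuate_and_propagate(g_mod, expr[g2], 2.0, seed=rng,
                                             ruleset=planted, sim_cfg=sim)
            data = pd.concat([ctrl, trt], axis=1)
            contrast = Contrast(tuple(g1), tuple(g2))
            table = run_pathway_analysis(
                [g_mod, g_null], data, contrast, sim_cfg=sim, n_perm=200,
                seed=int(rng.integers(2**32)),
                rulesets=[planted, random_ruleset(g_null, seed=1)])
            by_path = table.set_index("pathway")["p_value"]
            wins += int(by_path["modulated"] < by_path["unmodulated"])
        assert wins >= 8, f"modulated pathway won only {wins}/{n_seeds}"


class TestExport:
    def test_and_connector_convention(self, tmp_path):
        g = SignedDiGraph()
        g.add_nodes_from("ABCD")
        for u in "ABD":
            g.add_signed_edge(u, "C", 1)
        rules = {
            "A": hold_rule("A"), "B": hold_rule("B"), "D": hold_rule("D"),
            # C = A or (B and D)
            "C": Rule("C", ("A", "B", "D"), (1, 1, 1), term_mask=(1 << 0) | (1 << 5)),
        }
        rs = RuleSet(graph=g, rules=rules)
        impacts = pd.Series({"A": 2.0, "B": 1.0, "C": 4.0, "D": 0.5})
        folds = pd.Series({"A": 1.2, "B": 0.8, "C": 1.0, "D": 1.0})
        out = tmp_path / "annotated.graphml"
        export_annotated_network(g, rs, impacts, folds, out)
        back = read_graph(out)
        aux = [n for n, d in back.nodes(data=True) if d.get("kind") == "and"]
        assert len(aux) == 1
        assert set(back.predecessors(aux[0])) == {"B", "D"}
        assert ("A", "C") in back.edges
        assert (aux[0], "C") in back.edges
        impacts_back = [d["impact"] for _, d in back.nodes(data=True)
                        if d.get("kind") == "gene"]
        assert max(impacts_back) == pytest.approx(1.0)
        assert back.nodes["C"]["rule"] == rules["C"].to_text()
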