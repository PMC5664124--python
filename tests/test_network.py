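"""ceRNA network: correlation screens, score, hypergeometric test,
assembly invariants, term enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from cernet.expression import ExpressionMatrix
from cernet.network import (
    build_network,
    cerna_score,
    coexpressed_pairs,
    mirna_anticorrelated,
    pearson,
    shared_mirna_hypergeom,
    term_enrichment,
    CoexpressionPair,
)
from cernet.targeting import MRESite, TargetMap
from oracles import oracle_hypergeom_upper


def matrix(values_by_id, n=6):
    cols = [f"embryo_9DAP_rep{k}" for k in range(1, n + 1)]
    samples = pd.DataFrame(
        {"tissue": ["embryo"] * n, "stage": [9] * n, "replicate": range(1, n + 1)},
        index=cols,
    )
    return ExpressionMatrix(
        pd.DataFrame([values_by_id[i] for i in values_by_id],
                     index=list(values_by_id), columns=cols),
        samples,
    )


class TestPearson:
    def test_perfect_linearity(self):
        r, p = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        r, _ = pearson([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value_and_t_transform_p(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        r, p = pearson(x, y)
        assert r == pytest.approx(10 / math.sqrt(148))  # sum of deviation products
        # p from first principles: t = r sqrt((m-2)/(1-r^2)), m-2 df
        from scipy import stats

        t = r * math.sqrt(3 / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestScreens:
    def test_coexpression_thresholds_are_strict(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 6) + np.linspace(0, 3, 6)
        y = x + rng.normal(0, 0.3, 6)
        lnc = matrix({"L": 2.0 ** x})
        mrna = matrix({"M": 2.0 ** y})
        pairs = coexpressed_pairs(lnc, mrna)
        assert [(p.id_a, p.id_b) for p in pairs] == [("L", "M")]
        r = pairs[0].pcc
        # raising min_pcc to the observed r excludes the pair: strict '>'
        assert coexpressed_pairs(lnc, mrna, min_pcc=r) == []
        # an impossible alpha excludes it too
        assert coexpressed_pairs(lnc, mrna, alpha=1e-12) == []

    def test_anticorrelation_requires_negative_sign(self):
        up = np.linspace(1, 3, 6)
        mirna = matrix({"m": 2.0 ** up})
        partners = matrix({"anti": 2.0 ** (-1.5 * up + 5), "co": 2.0 ** (up + 0.1)})
        got = mirna_anticorrelated(mirna, partners)
        assert [(p.id_a, p.id_b) for p in got] == [("m", "anti")]
        assert all(p.pcc < -0.5 for p in got)

    def test_mismatched_samples_rejected(self):
        a = matrix({"x": [1, 2, 3, 4, 5, 6]})
        b = matrix({"y": [1, 2, 3, 4]}, n=4)
        with pytest.raises(ValueError, match="sample columns"):
            coexpressed_pairs(a, b)


def toy_target_map():
    """lncRNA 'L' carries MREs miR-a x2, miR-b x1, miR-c x1; mRNA 'M' is
    targeted by miR-a and miR-b; mRNA 'M2' by miR-c only."""
    sites = [
        MRESite("miR-a", "L", 10, 0.0, 21),
        MRESite("miR-a", "L", 100, 0.0, 21),
        MRESite("miR-b", "L", 200, 0.0, 21),
        MRESite("miR-c", "L", 300, 0.0, 21),
        MRESite("miR-a", "M", 10, 0.0, 21),
        MRESite("miR-b", "M", 60, 0.0, 21),
        MRESite("miR-c", "M2", 10, 0.0, 21),
    ]
    return TargetMap(sites)


class TestCeRNAScore:
    def test_worked_ratio(self):
        score, shared = cerna_score("L", "M", toy_target_map())
        assert shared == {"miR-a", "miR-b"}
        assert score == pytest.approx(3 / 4)

    def test_all_shared_gives_one_and_count_mode(self):
        tm = TargetMap(
            [
                MRESite("miR-a", "L", 10, 0.0, 21),
                MRESite("miR-a", "M", 10, 0.0, 21),
            ]
        )
        score, _ = cerna_score("L", "M", tm)
        assert score == 1.0
        count, _ = cerna_score("L", "M", tm, mode="count")
        assert count == 1.0

    def test_partial_and_empty_shared_sets(self):
        score, shared = cerna_score("L", "M2", toy_target_map())
        assert shared == {"miR-c"} and score == pytest.approx(1 / 4)
        # a partner with no common miRNA at all scores zero
        score, shared = cerna_score("L", "unrelated", toy_target_map())
        assert score == 0.0 and shared == frozenset()

    def test_anticorrelation_screen_restricts_shared(self):
        screen = {("miR-a", "L"), ("miR-a", "M")}  # miR-b failed for M
        score, shared = cerna_score("L", "M", toy_target_map(), screen)
        assert shared == {"miR-a"} and score == pytest.approx(2 / 4)

    def test_untargeted_lncrna_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            cerna_score("ghost", "M", toy_target_map())

    def test_monotone_in_shared_set(self):
        """Adding a miRNA to the shared set never lowers the ratio."""
        tm = toy_target_map()
        s1, _ = cerna_score("L", "M", tm, anticorrelated={("miR-a", "L"), ("miR-a", "M")})
        s2, _ = cerna_score(
            "L", "M", tm,
            anticorrelated={("miR-a", "L"), ("miR-a", "M"), ("miR-b", "L"), ("miR-b", "M")},
        )
        assert 0.0 <= s1 <= s2 <= 1.0


class TestHypergeometric:
    def test_worked_combinatorial_values(self):
        assert shared_mirna_hypergeom(20, 5, 4, 4) == pytest.approx(5 / 4845, rel=1e-12)
        assert shared_mirna_hypergeom(20, 5, 4, 2) == pytest.approx(1205 / 4845, rel=1e-12)

    def test_k_zero_is_certain(self):
        assert shared_mirna_hypergeom(20, 5, 4, 0) == 1.0

    @pytest.mark.parametrize("N,K,n,k", [(5, 6, 2, 1), (5, 3, 2, 3), (5, 3, 6, 1)])
    def test_invalid_counts_rejected(self, N, K, n, k):
        with pytest.raises(ValueError):
            shared_mirna_hypergeom(N, K, n, k)

    def test_spot_check_against_enumeration(self):
        for N, K, n, k in [(12, 4, 6, 2), (9, 9, 3, 3), (15, 7, 7, 5)]:
            assert shared_mirna_hypergeom(N, K, n, k) == pytest.approx(
                float(oracle_hypergeom_upper(N, K, n, k)), abs=1e-14
            )


class TestBuildNetwork:
    def test_fixture_triplets_recovered_and_edges_connected(
        self, default_bundle, default_target_map
    ):
        b = default_bundle
        lnc = b.lnc_expr.subset(sorted(b.truth.true_lncrna_ids))
        co = coexpressed_pairs(lnc, b.mrna_expr)
        anti_l = mirna_anticorrelated(b.mirna_expr, lnc)
        anti_m = mirna_anticorrelated(b.mirna_expr, b.mrna_expr)
        net = build_network(co, anti_l, anti_m, default_target_map,
                            n_mirna_universe=len(b.mirnas))
        planted = {(t.lncrna_id, t.mrna_id) for t in b.truth.planted_triplets}
        edges = {(p.lncrna_id, p.mrna_id) for p in net.retained_pairs}
        assert planted <= edges
        # invariant: each lncRNA-mRNA edge is bridged by >= 1 shared miRNA node
        g = net.graph
        for u, v, d in g.edges(data=True):
            if d["kind"] != "cerna":
                continue
            bridge = set(g.neighbors(u)) & set(g.neighbors(v))
            assert any(g.nodes[m]["kind"] == "miRNA" for m in bridge)
        # min_score = 1.0 => every targeting miRNA of the lncRNA is shared
        for p in net.retained_pairs:
            assert p.shared_mirnas == default_target_map.mirnas_targeting(p.lncrna_id)

    def test_thresholds_are_monotone(self, default_bundle, default_target_map):
        b = default_bundle
        lnc = b.lnc_expr.subset(sorted(b.truth.true_lncrna_ids))
        co = coexpressed_pairs(lnc, b.mrna_expr)
        anti_l = mirna_anticorrelated(b.mirna_expr, lnc)
        anti_m = mirna_anticorrelated(b.mirna_expr, b.mrna_expr)

        def edges(min_score, alpha):
            net = build_network(co, anti_l, anti_m, default_target_map,
                                n_mirna_universe=len(b.mirnas),
                                min_score=min_score, alpha=alpha)
            return {(p.lncrna_id, p.mrna_id) for p in net.retained_pairs}

        permissive = edges(0.0, 0.05)
        assert edges(1.0, 0.05) <= permissive  # raising min_score
        assert edges(0.0, 0.001) <= permissive  # lowering alpha

    def test_empty_coexpression_gives_empty_network(self, default_target_map):
        net = build_network([], [], [], default_target_map, n_mirna_universe=158)
        assert net.graph.number_of_nodes() == 0 and net.pairs == []

    def test_pair_without_lncrna_targeting_is_skipped(self, default_target_map):
        co = [CoexpressionPair("no_such_lnc", "MRNA0001", 0.9, 1e-5)]
        net = build_network(co, [], [], default_target_map, n_mirna_universe=158)
        assert net.pairs == [] and net.graph.number_of_edges() == 0


class TestTermEnrichment:
    def annotation(self):
        # universe of 100; term T annotates 5 features, 3 inside a 10-set
        universe = [f"f{i}" for i in range(100)]
        ann = {f: {"T"} for f in ["f1", "f2", "f3", "f50", "f60"]}
        ann["f99"] = {"whole"}
        for f in universe:
            ann.setdefault(f, set()).add("universal")
        return universe, ann

    def test_fold_enrichment_and_retention(self):
        universe, ann = self.annotation()
        fset = [f"f{i}" for i in range(10)]  # contains f1,f2,f3
        results = term_enrichment(fset, ann, universe, return_all=True)
        by_term = {r.term_id: r for r in results}
        assert by_term["T"].fold_enrichment == pytest.approx(6.0)
        assert by_term["T"].p_value == pytest.approx(
            float(oracle_hypergeom_upper(100, 5, 10, 3)), abs=1e-14
        )
        retained = term_enrichment(fset, ann, universe)
        assert [r.term_id for r in retained] == ["T"]

    def test_universal_term_never_retained(self):
        universe, ann = self.annotation()
        retained = term_enrichment([f"f{i}" for i in range(10)], ann, universe)
        assert all(r.term_id != "universal" for r in retained)  # FE = 1

    def test_absent_term_has_zero_fe(self):
        universe, ann = self.annotation()
        results = term_enrichment(["f10", "f11"], ann, universe, return_all=True)
        t = next(r for r in results if r.term_id == "T")
        assert t.k == 0 and t.fold_enrichment == 0.0

    def test_empty_universe_and_non_subset_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            term_enrichment(["a"], {}, [])
        with pytest.raises(ValueError, match="subset"):
            term_enrichment(["alien"], {}, ["a", "b"])

    def test_dataframe_annotation_accepted(self):
        df = pd.DataFrame(
            {"feature_id": ["a", "b", "b"], "term_id": ["T", "T", "S"]}
        )
        results = term_enrichment(["a"], df, ["a", "b", "c"], return_all=True)
        assert {r.term_id for r in results} == {"T", "S"}
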