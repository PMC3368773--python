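import numpy as np
import pytest

from mitocomp.gene_order import (
    GeneOrder,
    GeneOrderError,
    breakpoint_distance,
    common_intervals,
    distance_matrix,
    format_gene_orders,
    hp_distance,
    order_from_annotation,
    parse_gene_orders,
    restrict_to_shared,
    reversal_distance,
)
from mitocomp.annotation import GeneFeature, MitogenomeAnnotation
from mitocomp.synthetic import scramble_gene_order

from oracles import all_signed_permutations, bfs_reversal_distances


def random_order(n, rng, gid="r"):
    names = [f"g{i}" for i in range(n)]
    rng.shuffle(names)
    toks = tuple(("-" + x if rng.random() < 0.5 else x) for x in names)
    return GeneOrder(gid, toks)


class TestOrderFromAnnotation:
    def test_non_trna_order_of_mirabilis(self, mirabilis):
        o = order_from_annotation(mirabilis, "non_tRNA")
        assert o.genes == (
            "nad6", "cob", "nad4L", "nad4", "nad5", "cox3", "nad3", "cox1",
            "nad2", "cox2", "atp8", "atp6", "rrnS", "rrnL", "nad1",
        )

    def test_all_genes_order_has_37_signed_tokens(self, mirabilis):
        o = order_from_annotation(mirabilis)
        assert len(o) == 37
        assert o.genes[:3] == ("trnY", "-trnP", "nad6")
        assert "-trnT" in o.genes

    def test_noncoding_only_annotation_rejected(self):
        ann = MitogenomeAnnotation(
            "nc", 100, [GeneFeature("AT-rich", "noncoding", "H", 1, 100)]
        )
        with pytest.raises(GeneOrderError, match="no genes"):
            order_from_annotation(ann)


class TestRestrictToShared:
    def test_partial_genome_restriction(self, mir_order):
        partial = GeneOrder("partial", mir_order.genes[1:])  # 36 genes
        a, b = restrict_to_shared(mir_order, partial)
        assert len(a) == len(b) == 36

    def test_identical_sets_unchanged(self, mir_order, rub_order):
        a, b = restrict_to_shared(mir_order, rub_order)
        assert a.genes == mir_order.genes and b.genes == rub_order.genes

    def test_disjoint_sets_rejected(self):
        o1 = GeneOrder("a", ("x1", "x2", "x3"))
        o2 = GeneOrder("b", ("y1", "y2", "y3"))
        with pytest.raises(GeneOrderError, match="shared"):
            restrict_to_shared(o1, o2)

    def test_filtering_is_positional(self, mir_order):
        rng = np.random.default_rng(0)
        keep = set(rng.choice(mir_order.names(), size=20, replace=False))
        sub = GeneOrder("sub", tuple(t for t in mir_order.genes if t.lstrip("-") in keep))
        a, b = restrict_to_shared(mir_order, sub)
        assert a.genes == sub.genes == b.genes


class TestCommonIntervals:
    def test_published_all_genes_value(self, mir_order, rub_order):
        assert common_intervals(mir_order, rub_order) == 1124

    def test_published_non_trna_value(self, mirabilis, rubens):
        a = order_from_annotation(mirabilis, "non_tRNA")
        b = order_from_annotation(rubens, "non_tRNA")
        assert common_intervals(a, b) == 178

    def test_self_comparison_diagonals(self, mir_order, rubens):
        assert common_intervals(mir_order, mir_order) == 1326  # n = 37
        b = order_from_annotation(rubens, "non_tRNA")
        assert common_intervals(b, b) == 204  # n = 15

    def test_ground_pattern_comparisons_match_published_matrix(
        self, mir_order, rub_order, ground_pattern
    ):
        assert common_intervals(mir_order, ground_pattern) == 20
        assert common_intervals(rub_order, ground_pattern) == 20
        gp_nt = GeneOrder(
            "gp", tuple(t for t in ground_pattern.genes if not t.lstrip("-").startswith("trn")),
            "non_tRNA",
        )
        mir_nt = GeneOrder(
            "m", tuple(t for t in mir_order.genes if not t.lstrip("-").startswith("trn")),
            "non_tRNA",
        )
        rub_nt = GeneOrder(
            "r", tuple(t for t in rub_order.genes if not t.lstrip("-").startswith("trn")),
            "non_tRNA",
        )
        assert common_intervals(mir_nt, gp_nt) == 44
        assert common_intervals(rub_nt, gp_nt) == 52

    @pytest.mark.parametrize("n", range(8, 41))
    def test_identity_calibration_law(self, n):
        rng = np.random.default_rng(n)
        o = random_order(n, rng)
        assert common_intervals(o, o, anchor=o.names()[0]) == n * (n - 1) - 6

    def test_rotation_invariance(self, mir_order, rub_order):
        for k in (1, 9, 20):
            assert (
                common_intervals(mir_order.rotated(k), rub_order.rotated(2 * k))
                == common_intervals(mir_order, rub_order)
            )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        o1, o2 = random_order(12, rng, "a"), None
        o2 = GeneOrder("b", tuple(reversed(o1.genes[:6])) + o1.genes[6:])
        mapping = {f"g{i}": f"h{i}" for i in range(12)}

        def relab(o, gid):
            return GeneOrder(
                gid,
                tuple(
                    ("-" + mapping[t[1:]]) if t.startswith("-") else mapping[t]
                    for t in o.genes
                ),
            )

        v1 = common_intervals(o1, o2, anchor=o1.names()[0])
        v2 = common_intervals(relab(o1, "a2"), relab(o2, "b2"), anchor=mapping[o1.names()[0]])
        assert v1 == v2

    def test_gene_set_mismatch_rejected(self, mir_order):
        other = GeneOrder("x", mir_order.genes[:30])
        with pytest.raises(GeneOrderError, match="differ"):
            common_intervals(mir_order, other)


def brute_breakpoints(o1, o2):
    """Independent adjacency-set comparison."""
    def adj(o):
        g = o.genes
        return {(g[i], g[(i + 1) % len(g)]) for i in range(len(g))}

    def neg(t):
        return t[1:] if t.startswith("-") else "-" + t

    a2 = adj(o2)
    return sum((a, b) not in a2 and (neg(b), neg(a)) not in a2 for (a, b) in adj(o1))


class TestBreakpoints:
    def test_identical_orders_have_zero(self, mir_order):
        assert breakpoint_distance(mir_order, mir_order.rotated(5)) == 0

    def test_published_value_against_ground_pattern(
        self, mir_order, rub_order, ground_pattern
    ):
        a, b = restrict_to_shared(mir_order, ground_pattern)
        assert breakpoint_distance(a, b) == 31
        a, b = restrict_to_shared(rub_order, ground_pattern)
        assert breakpoint_distance(a, b) == 31

    def test_toy_circular_case_matches_adjacency_enumeration(self):
        o1 = GeneOrder("a", ("g1", "g2", "g3", "g4"))
        o2 = GeneOrder("b", ("g1", "g3", "g2", "g4"))
        assert breakpoint_distance(o1, o2) == brute_breakpoints(o1, o2)

    def test_random_pairs_match_brute_force_and_are_symmetric(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(4, 15))
            o1, o2 = random_order(n, rng, "a"), random_order(n, rng, "b")
            o2 = GeneOrder("b", tuple(sorted(o2.genes, key=lambda t: rng.random())))
            d = breakpoint_distance(o1, o2)
            assert d == brute_breakpoints(o1, o2)
            assert d == breakpoint_distance(o2, o1)


class TestReversalDistance:
    def test_identity_and_single_negation(self, mir_order):
        assert reversal_distance(mir_order, mir_order.rotated(11)) == 0
        toks = list(mir_order.genes)
        toks[5] = "-" + toks[5] if not toks[5].startswith("-") else toks[5][1:]
        assert reversal_distance(mir_order, GeneOrder("neg", tuple(toks))) == 1

    def test_published_value_against_ground_pattern(self, mir_order, ground_pattern):
        a, b = restrict_to_shared(mir_order, ground_pattern)
        assert reversal_distance(a, b) == 28

    def test_hp_matches_bfs_exhaustively_small(self):
        for m in range(1, 5):
            truth = bfs_reversal_distances(m)
            for p in all_signed_permutations(m):
                assert hp_distance(p) == truth[p], p

    def test_hp_matches_bfs_exhaustively_m5(self):
        truth = bfs_reversal_distances(5)
        for p in all_signed_permutations(5):
            assert hp_distance(p) == truth[p], p

    def test_anchor_choice_does_not_change_distance(self, mir_order, ground_pattern):
        a, b = restrict_to_shared(mir_order, ground_pattern)
        vals = {reversal_distance(a, b, anchor=g) for g in ("cox1", "trnM", "nad5", "rrnL")}
        assert vals == {28}

    def test_zero_iff_same_circle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            o = random_order(n, rng)
            refl = o.reflected().rotated(int(rng.integers(0, n)))
            assert reversal_distance(o, refl) == 0
            scrambled, _ = scramble_gene_order(o, 2, seed=int(rng.integers(1e6)))
            d = reversal_distance(o, scrambled)
            assert (d == 0) == o.same_circle(scrambled)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(5, 12))
            a, b, c = (random_order(n, rng, g) for g in "abc")
            b = GeneOrder("b", tuple(sorted(b.genes, key=lambda t: rng.random())))
            dab = reversal_distance(a, b)
            assert dab == reversal_distance(b, a)
            assert dab <= reversal_distance(a, c) + reversal_distance(c, b)

    def test_reversal_at_least_half_breakpoints(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(4, 14))
            a, b = random_order(n, rng, "a"), random_order(n, rng, "b")
            b = GeneOrder("b", tuple(sorted(b.genes, key=lambda t: rng.random())))
            assert reversal_distance(a, b) >= breakpoint_distance(a, b) / 2

    def test_scramble_upper_bound(self, mir_order):
        for seed in range(25):
            scrambled, ops = scramble_gene_order(mir_order, 5, seed=seed)
            assert len(ops) == 5
            assert reversal_distance(mir_order, scrambled) <= 5

    def test_single_reversal_distance_exactly_one(self):
        rng = np.random.default_rng(6)
        o = random_order(10, rng)
        scrambled, _ = scramble_gene_order(o, 1, seed=17)
        assert reversal_distance(o, scrambled) == 1


class TestDistanceMatrix:
    def test_published_pair_cells(self, mir_order, rub_order):
        mat = distance_matrix([mir_order, rub_order], "common_intervals")
        assert mat.cell("Nectonemertes_cf_mirabilis", "Zygeupolia_rubens") == 1124
        assert mat.cell("Nectonemertes_cf_mirabilis", "Nectonemertes_cf_mirabilis") == 1326

    def test_duplicated_order_gives_self_values(self, mir_order):
        from dataclasses import replace

        twin = replace(mir_order, genome_id="twin")
        mat = distance_matrix([mir_order, twin], "reversals")
        assert all(v == 0 for row in mat.values for v in row)

    def test_matrix_equals_pairwise_recomputation(self):
        rng = np.random.default_rng(30)
        orders = [random_order(9, rng, f"o{i}") for i in range(3)]
        orders = [GeneOrder(o.genome_id, tuple(sorted(o.genes, key=lambda t: rng.random()))) for o in orders]
        mat = distance_matrix(orders, "breakpoints")
        for i, a in enumerate(orders):
            for j, b in enumerate(orders):
                assert mat.values[i][j] == breakpoint_distance(*restrict_to_shared(a, b))

    def test_unknown_measure_and_too_few_orders(self, mir_order):
        with pytest.raises(GeneOrderError):
            distance_matrix([mir_order, mir_order], "hamming")
        with pytest.raises(GeneOrderError):
            distance_matrix([mir_order], "reversals")


class TestGeneOrderIO:
    def test_round_trip(self, mir_order, rub_order):
        text = format_gene_orders([mir_order, rub_order])
        back = parse_gene_orders(text)
        assert back[0].genes == mir_order.genes
        assert back[1].genome_id == "Zygeupolia_rubens"

    def test_duplicate_tokens_rejected(self):
        with pytest.raises(GeneOrderError, match="duplicated"):
            GeneOrder("bad", ("a", "b", "-a"))
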