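import pytest

from quartetpp import TaxonIndex, parse_newick, unroot
from quartetpp.quartet_core import (
    Quadripartition,
    Tripartition,
    brute_force_quartet_counts,
    count_matching_quartets,
    gene_tree_quartet_counts,
    quadripartition_of_edge,
    quartet_support,
)
from quartetpp.trees import internal_bipartitions

from conftest import random_instances, trees_from


def _mask(taxa, names):
    return taxa.mask_of(names)


@pytest.fixture
def taxa6():
    t = TaxonIndex()
    for n in "123456":
        t.add(n)
    return t


class TestCountMatching:
    def test_quartet_resolved_at_cherry_node(self, taxa6):
        q = Quadripartition(*(_mask(taxa6, [c]) for c in "1234"))
        r = Tripartition(
            _mask(taxa6, ["1"]), _mask(taxa6, ["2"]), _mask(taxa6, ["3", "4"])
        )
        assert count_matching_quartets(q, r) == 1

    def test_alternative_topology_gets_zero(self, taxa6):
        q13 = Quadripartition(
            _mask(taxa6, ["1"]), _mask(taxa6, ["3"]),
            _mask(taxa6, ["2"]), _mask(taxa6, ["4"]),
        )
        r = Tripartition(
            _mask(taxa6, ["1"]), _mask(taxa6, ["2"]), _mask(taxa6, ["3", "4"])
        )
        assert count_matching_quartets(q13, r) == 0

    def test_multi_leaf_clusters_match_brute_force(self):
        # Q = ({1,2},{3},{4,5},{6}) vs gene tree with R = ({1,3},{2},{4,5,6})
        gts, taxa = trees_from(["((1,3),(2,(4,(5,6))));"])
        q = Quadripartition(
            _mask(taxa, ["1", "2"]), _mask(taxa, ["3"]),
            _mask(taxa, ["4", "5"]), _mask(taxa, ["6"]),
        )
        q2, q3 = q.alternatives()
        r = Tripartition(
            _mask(taxa, ["1", "3"]), _mask(taxa, ["2"]),
            _mask(taxa, ["4", "5", "6"]),
        )
        # node-level count must agree with classifying each of the 4 quartets
        per_node = count_matching_quartets(q, r)
        assert 0 <= per_node <= q.m_total
        eff = gene_tree_quartet_counts(q, (q2, q3), gts[0])
        assert eff == brute_force_quartet_counts(q, (q2, q3), gts[0])

    def test_disjointness_enforced(self, taxa6):
        with pytest.raises(ValueError):
            Quadripartition(
                _mask(taxa6, ["1"]), _mask(taxa6, ["1"]),
                _mask(taxa6, ["3"]), _mask(taxa6, ["4"]),
            )


class TestQuadripartitionOfEdge:
    def test_four_taxon_edge(self):
        (sp,), taxa = trees_from(["((1,2),(3,4));"])
        edge, _ = internal_bipartitions(sp)[0]
        q, q2, q3 = quadripartition_of_edge(sp, edge)
        assert set(q.clusters) == {taxa.bit(c) for c in "1234"}
        assert q.m_total == 1
        # alternatives pair cluster A with C and with D respectively
        assert {q2.clusters[:2], q3.clusters[:2]} == {
            (taxa.bit("1"), taxa.bit("3")),
            (taxa.bit("1"), taxa.bit("4")),
        }

    def test_six_taxon_deep_edge_cluster_sizes(self):
        (sp,), taxa = trees_from(["((1,2),((3,4),(5,6)));"])
        by_sizes = {}
        for edge, _ in internal_bipartitions(sp):
            q, _, _ = quadripartition_of_edge(sp, edge)
            sizes = tuple(sorted(bin(c).count("1") for c in q.clusters))
            by_sizes.setdefault(sizes, []).append(q)
        # the edge separating {1,2} from {3,4}+{5,6} has clusters 1,1,2,2
        assert (1, 1, 2, 2) in by_sizes
        assert by_sizes[(1, 1, 2, 2)][0].m_total == 4

    def test_five_taxon_caterpillar(self):
        (sp,), taxa = trees_from(["((((1,2),3),4),5);"])
        bips = internal_bipartitions(sp)
        assert len(bips) == 2
        for edge, _ in bips:
            q, _, _ = quadripartition_of_edge(sp, edge)
            import math
            assert q.m_total == math.prod(
                bin(c).count("1") for c in q.clusters
            )

    def test_polytomy_edge_is_unscorable(self):
        (sp,), _ = trees_from(["(((1,2,3),4),5,6);"])
        for edge, mask in internal_bipartitions(sp):
            if bin(mask).count("1") == 3:
                with pytest.raises(ValueError, match="polytomy"):
                    quadripartition_of_edge(sp, edge)


class TestGeneTreeCounts:
    @pytest.fixture
    def q_balanced(self):
        (sp,), taxa = trees_from(["((1,2),(3,4));"])
        edge, _ = internal_bipartitions(sp)[0]
        return quadripartition_of_edge(sp, edge), taxa

    def test_identical_topology(self, q_balanced):
        (q, q2, q3), taxa = q_balanced
        (g,), _ = trees_from(["((1,2),(3,4));"], taxa)
        assert gene_tree_quartet_counts(q, (q2, q3), g) == (1, 0, 0, 1)

    def test_first_alternative(self, q_balanced):
        (q, q2, q3), taxa = q_balanced
        (g,), _ = trees_from(["((1,3),(2,4));"], taxa)
        c1, c2, c3, mg = gene_tree_quartet_counts(q, (q2, q3), g)
        assert (c1, mg) == (0, 1) and {c2, c3} == {0, 1}
        # the alternative that scored is the one pairing 1 with 3
        hit = q2 if c2 else q3
        assert hit.clusters[:2] in (
            (taxa.bit("1"), taxa.bit("3")), (taxa.bit("3"), taxa.bit("1"))
        )

    def test_star_gene_tree_resolves_nothing(self, q_balanced):
        (q, q2, q3), taxa = q_balanced
        (g,), _ = trees_from(["(1,2,3,4);"], taxa)
        assert gene_tree_quartet_counts(q, (q2, q3), g) == (0, 0, 0, 1)

    def test_missing_taxon_restricts_quartets(self):
        (sp,), taxa = trees_from(["((1,2),((3,5),4));"])
        q = Quadripartition(
            taxa.bit("1"), taxa.bit("2"),
            taxa.mask_of(["3", "5"]), taxa.bit("4"),
        )
        (g,), _ = trees_from(["((1,2),(3,4));"], taxa)  # taxon 5 absent
        assert gene_tree_quartet_counts(q, q.alternatives(), g) == (1, 0, 0, 1)

    def test_tiny_gene_tree_contributes_nothing(self, q_balanced):
        (q, q2, q3), taxa = q_balanced
        (g,), _ = trees_from(["(1,2,3);"], taxa)
        assert gene_tree_quartet_counts(q, (q2, q3), g) == (0, 0, 0, 0)


class TestOracleEquivalence:
    def test_randomized_instances_agree_exactly(self):
        checked = 0
        for sp, gts in random_instances(seed=1729, n_reps=12):
            spu = unroot(sp.clone())
            for edge, _ in internal_bipartitions(spu):
                q, q2, q3 = quadripartition_of_edge(spu, edge)
                for g in gts:
                    eff = gene_tree_quartet_counts(q, (q2, q3), g)
                    assert eff == brute_force_quartet_counts(q, (q2, q3), g)
                    c1, c2, c3, mg = eff
                    assert c1 + c2 + c3 <= mg
                    checked += 1
        assert checked >= 300

    def test_symmetry_under_alternative_permutation(self):
        for sp, gts in random_instances(seed=4, n_reps=2):
            spu = unroot(sp.clone())
            edge, _ = internal_bipartitions(spu)[0]
            q, q2, q3 = quadripartition_of_edge(spu, edge)
            for g in gts[:4]:
                c1, c2, c3, mg = gene_tree_quartet_counts(q, (q2, q3), g)
                # present the branch from Q2's point of view
                d1, d2, d3, mg2 = gene_tree_quartet_counts(q2, (q, q3), g)
                assert (d1, d2, d3, mg2) == (c2, c1, c3, mg)

    def test_conservation_for_complete_binary_gene_trees(self):
        from quartetpp import SimConfig, simulate_msc_gene_trees, simulate_yule_tree

        sp = simulate_yule_tree(SimConfig(n_leaves=8, seed=11))
        gts = simulate_msc_gene_trees(sp, 20, seed=12)
        spu = unroot(sp.clone())
        for edge, _ in internal_bipartitions(spu):
            q, q2, q3 = quadripartition_of_edge(spu, edge)
            for g in gts:
                c1, c2, c3, mg = gene_tree_quartet_counts(q, (q2, q3), g)
                assert c1 + c2 + c3 == mg == q.m_total


class TestQuartetSupport:
    def test_unanimous_gene_trees(self):
        (sp,), taxa = trees_from(["((1,2),(3,4));"])
        gts, _ = trees_from(["((1,2),(3,4));"] * 10, taxa)
        edge, _ = internal_bipartitions(sp)[0]
        q, q2, q3 = quadripartition_of_edge(sp, edge)
        rec = quartet_support(q, (q2, q3), gts)
        assert rec.z == (10.0, 0.0, 0.0)
        assert rec.n_eff == 10.0
        assert rec.m_bar == 1.0
        assert rec.frequencies == (1.0, 0.0, 0.0)

    def test_mixed_gene_trees_sum_counts(self):
        (sp,), taxa = trees_from(["((1,2),(3,4));"])
        gts, _ = trees_from(
            ["((1,2),(3,4));"] * 2 + ["((1,3),(2,4));", "((1,4),(2,3));"],
            taxa,
        )
        edge, _ = internal_bipartitions(sp)[0]
        q, q2, q3 = quadripartition_of_edge(sp, edge)
        rec = quartet_support(q, (q2, q3), gts)
        assert rec.z == (2.0, 1.0, 1.0)
        assert rec.n_eff == 4.0
        assert rec.n_genes_eff == 4

    def test_gene_missing_whole_cluster_is_excluded(self):
        (sp,), taxa = trees_from(["((1,2),((3,4),5));"])
        # cluster {5} is one side of the deepest quadripartition
        gts, _ = trees_from(
            ["((1,2),((3,4),5));", "((1,2),(3,4));"], taxa
        )
        for edge, mask in internal_bipartitions(sp):
            q, q2, q3 = quadripartition_of_edge(sp, edge)
            rec = quartet_support(q, (q2, q3), gts)
            if any(c == taxa.bit("5") for c in q.clusters):
                assert rec.n_genes_eff == 1  # the complete gene only
            else:
                assert rec.n_genes_eff == 2

    def test_strict_mode_counts_genes_with_unresolved_quartets(self):
        (sp,), taxa = trees_from(["((1,2),(3,4));"])
        gts, _ = trees_from(["((1,2),(3,4));", "(1,2,3,4);"], taxa)
        edge, _ = internal_bipartitions(sp)[0]
        q, q2, q3 = quadripartition_of_edge(sp, edge)
        default = quartet_support(q, (q2, q3), gts)
        strict = quartet_support(q, (q2, q3), gts, strict_n=True)
        assert default.n_eff == 1.0  # only the resolved outcome is a trial
        assert strict.n_eff == 2.0  # literal effective-gene count
        assert default.z == strict.z

    def test_no_signal_record_is_flagged(self):
        (sp,), taxa = trees_from(["((1,2),((3,4),5));"])
        gts, _ = trees_from(["((1,2),(3,4));"], taxa)
        for edge, _ in internal_bipartitions(sp):
            q, q2, q3 = quadripartition_of_edge(sp, edge)
            rec = quartet_support(q, (q2, q3), gts)
            if any(c == taxa.bit("5") for c in q.clusters):
                assert not rec.has_signal and rec.n_eff == 0
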