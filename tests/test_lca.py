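"""Filtered-LCA classifier: boundary behaviour, oracle equivalence,
invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metatrx import (
    Hit,
    LCAParams,
    TaxonomyTree,
    assign_contig,
    filter_hits,
    lca,
    two_pass_assign,
)


def mk_hit(bitscore, length=150, evalue=1e-10, taxid=8, query="c1", subject=None):
    return Hit(query, subject or f"s{bitscore}_{taxid}", bitscore, length,
               evalue, 95.0, taxid)


# -- independent brute-force oracle --------------------------------------


def oracle_assign(hits, parent, params=LCAParams()):
    """Exhaustive filter + deepest-common-ancestor via full path
    intersection, written independently of the implementation."""
    keep = [
        h for h in hits
        if h.evalue <= params.max_evalue
        and h.bitscore > params.min_bitscore
        and h.length > params.min_len
    ]
    if keep:
        best = max(h.bitscore for h in keep)
        keep = [h for h in keep if h.bitscore >= (1 - params.top_fraction) * best]
    taxa = {h.taxid for h in keep if h.taxid in parent}
    if not taxa:
        return None
    paths = []
    for t in taxa:
        p = [t]
        while parent[p[-1]] != p[-1]:
            p.append(parent[p[-1]])
        paths.append(p[::-1])
    anc = None
    for nodes in zip(*paths):
        if len(set(nodes)) == 1:
            anc = nodes[0]
        else:
            break
    return anc


def random_tree(rng, max_nodes=50):
    n = int(rng.integers(2, max_nodes + 1))
    t = TaxonomyTree()
    t.add_node(0, 0, "no rank", "root")
    for i in range(1, n):
        t.add_node(i, int(rng.integers(0, i)), "no rank", f"n{i}")
    return t


class TestFilterHits:
    def test_bitscore_exactly_50_removed(self):
        assert filter_hits([mk_hit(50.0)]) == []

    def test_bitscore_just_above_50_kept(self):
        assert len(filter_hits([mk_hit(50.1)])) == 1

    def test_length_exactly_100_removed(self):
        assert filter_hits([mk_hit(200, length=100)]) == []

    def test_length_101_kept(self):
        assert len(filter_hits([mk_hit(200, length=101)])) == 1

    def test_evalue_ceiling(self):
        assert filter_hits([mk_hit(200, evalue=1e-3)]) == []
        assert len(filter_hits([mk_hit(200, evalue=1e-4)])) == 1

    def test_top_fraction_rule(self):
        hits = [mk_hit(200.0), mk_hit(185.0), mk_hit(170.0)]
        kept = filter_hits(hits)
        assert [h.bitscore for h in kept] == [200.0, 185.0]

    def test_bitscore_exactly_90pct_of_best_included(self):
        kept = filter_hits([mk_hit(200.0), mk_hit(180.0)])
        assert [h.bitscore for h in kept] == [200.0, 180.0]

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_mixed_queries_raise(self):
        with pytest.raises(ValueError):
            filter_hits([mk_hit(200, query="a"), mk_hit(200, query="b")])

    def test_length_top_metric_switch(self):
        hits = [mk_hit(100.0, length=400), mk_hit(300.0, length=200)]
        kept = filter_hits(hits, LCAParams(top_metric="length"))
        assert [h.length for h in kept] == [400]


class TestAssignContig:
    def test_all_hits_below_threshold_unassigned(self, small_tree):
        res = assign_contig([mk_hit(40), mk_hit(30)], small_tree)
        assert not res.assigned and res.pass_label == "none" and res.n_hits == 0

    def test_single_surviving_hit_assigns_species(self, small_tree):
        res = assign_contig([mk_hit(200, taxid=8)], small_tree)
        assert res.taxid == 8 and res.n_hits == 1

    def test_sister_species_assign_genus_and_weak_hit_is_irrelevant(
        self, small_tree
    ):
        hits = [mk_hit(200, taxid=8), mk_hit(190, taxid=9)]
        assert assign_contig(hits, small_tree).taxid == 7
        hits.append(mk_hit(20, taxid=17))  # sub-threshold, other phylum
        assert assign_contig(hits, small_tree).taxid == 7

    def test_unknown_taxid_dropped_not_fatal(self, small_tree):
        hits = [mk_hit(200, taxid=8), mk_hit(195, taxid=4242)]
        res = assign_contig(hits, small_tree)
        assert res.taxid == 8 and res.n_hits == 1

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            tree = random_tree(rng)
            nodes = list(tree.parent)
            hits = [
                Hit(
                    "c", f"s{j}",
                    float(np.round(rng.uniform(0, 300), 1)),
                    int(rng.integers(0, 300)),
                    float(10.0 ** -rng.integers(0, 12)),
                    95.0,
                    int(rng.choice(nodes)),
                )
                for j in range(int(rng.integers(0, 20)))
            ]
            expected = oracle_assign(hits, tree.parent)
            got = assign_contig(hits, tree)
            assert got.taxid == expected

    @given(st.data())
    def test_permutation_invariance(self, data):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, max_nodes=20)
        nodes = list(tree.parent)
        hits = [
            mk_hit(float(b), length=l, taxid=int(t))
            for b, l, t in zip(
                data.draw(st.lists(st.integers(0, 300), min_size=1, max_size=10)),
                data.draw(st.lists(st.integers(50, 300), min_size=10, max_size=10)),
                data.draw(
                    st.lists(st.sampled_from(nodes), min_size=10, max_size=10)
                ),
            )
        ]
        perm = data.draw(st.permutations(hits))
        assert assign_contig(hits, tree).taxid == assign_contig(perm, tree).taxid


class TestLCAProperties:
    def test_idempotence_and_associativity(self, small_tree):
        nodes = list(small_tree.parent)
        for t in nodes:
            assert lca({t}, small_tree) == t
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = set(rng.choice(nodes, size=int(rng.integers(1, 4))).tolist())
            b = set(rng.choice(nodes, size=int(rng.integers(1, 4))).tolist())
            union = lca(a | b, small_tree)
            nested = lca({lca(a, small_tree), lca(b, small_tree)}, small_tree)
            assert union == nested


class TestTwoPass:
    def test_pass1_assignment_wins(self, small_tree):
        p1 = {"c1": [mk_hit(200, taxid=8)]}
        p2 = {"c1": [mk_hit(200, taxid=17)]}
        (res,) = two_pass_assign(p1, p2, small_tree)
        assert res.taxid == 8 and res.pass_label == "first"

    def test_fallback_to_pass2(self, small_tree):
        p1 = {"c1": [mk_hit(40, taxid=8)]}  # all filtered out
        p2 = {"c1": [mk_hit(200, taxid=11)]}
        (res,) = two_pass_assign(p1, p2, small_tree)
        assert res.taxid == 11 and res.pass_label == "second"

    def test_contig_absent_from_both_tables(self, small_tree):
        (res,) = two_pass_assign({}, {}, small_tree, contigs=["ghost"])
        assert not res.assigned and res.pass_label == "none"
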