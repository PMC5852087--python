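"""Synthetic consortium generator: determinism, truth-label consistency,
and the statistical properties downstream recovery tests rely on."""

import filecmp
import math

import numpy as np
import pytest

from metatrx import (
    assign_contig,
    generate_community,
    generate_taxonomy,
    simulate_hit_table,
    simulate_reads,
    write_community,
)

_COMP = str.maketrans("ACGT", "TGCA")


class TestGenerateTaxonomy:
    def test_single_lineage_tree(self):
        tree = generate_taxonomy(1, 1, seed=0)
        (sp,) = tree.species()
        assert tree.lca({sp}) == sp
        assert len(tree.lineage(sp)) == 8  # root + 7 ranks

    def test_determinism(self):
        a = generate_taxonomy(3, 2, seed=7)
        b = generate_taxonomy(3, 2, seed=7)
        assert (a.parent, a.rank, a.name) == (b.parent, b.rank, b.name)

    def test_every_species_has_family_ancestor_by_parent_walk(self):
        tree = generate_taxonomy(3, 2, seed=7)
        for sp in tree.species():
            node, found = sp, False
            while tree.parent[node] != node:
                node = tree.parent[node]
                if tree.rank[node] == "family":
                    found = True
            assert found

    def test_nonpositive_counts_raise(self):
        with pytest.raises(ValueError):
            generate_taxonomy(0, 1, seed=0)


class TestGenerateCommunity:
    def test_dominance_passthrough_and_sum(self):
        tree = generate_taxonomy(5, 1, seed=3)
        truth = generate_community(tree, 5, dominance=0.30, seed=3)
        assert truth.abundance[truth.dominant_taxon] == pytest.approx(0.30)
        assert sum(truth.abundance.values()) == pytest.approx(1.0, abs=1e-9)

    def test_sigma_zero_gives_identical_expression_within_plain_taxon(self):
        tree = generate_taxonomy(3, 1, seed=3)
        truth = generate_community(tree, 3, expression_sigma=0.0, seed=3)
        for taxid in truth.abundance:
            if taxid == truth.dominant_taxon:
                continue  # carries the fixed high-expression cluster levels
            exprs = {g.expression for g in truth.genes if g.taxid == taxid}
            assert exprs == {1.0}

    def test_determinism(self):
        tree = generate_taxonomy(4, 2, seed=9)
        a = generate_community(tree, 4, seed=9)
        b = generate_community(tree, 4, seed=9)
        assert a.abundance == b.abundance
        assert a.genes == b.genes
        assert a.contigs == b.contigs

    def test_each_gene_belongs_to_one_taxon_and_cluster_colocalized(self):
        tree = generate_taxonomy(4, 2, seed=9)
        truth = generate_community(tree, 4, seed=9)
        tags = [g.locus_tag for g in truth.genes]
        assert len(tags) == len(set(tags))
        cluster = truth.operons[truth.dominant_taxon]
        assert len(cluster) >= 2
        by_tag = truth.gene_by_tag()
        assert len({by_tag[t].contig for t in cluster}) == 1

    def test_dominance_out_of_range_raises(self):
        tree = generate_taxonomy(3, 1, seed=0)
        with pytest.raises(ValueError):
            generate_community(tree, 3, dominance=1.5)


@pytest.fixture(scope="module")
def community():
    tree = generate_taxonomy(4, 2, seed=5)
    return tree, generate_community(tree, 4, seed=5)


class TestSimulateReads:
    def test_error_free_reads_are_exact_transcript_substrings(self, community):
        _, truth = community
        rs = simulate_reads(truth, 500, error_rate=0.0, seed=5)
        by_tag = truth.gene_by_tag()
        for read, rt in zip(rs.reads, rs.truth):
            g = by_tag[rt.locus_tag]
            transcript = truth.contigs[g.contig][g.start - 1 : g.end]
            if g.strand == "-":
                transcript = transcript.translate(_COMP)[::-1]
            assert read.sequence in transcript

    def test_quality_strings_match_length_and_conservation(self, community):
        _, truth = community
        rs = simulate_reads(truth, 1000, error_rate=0.02, rrna_fraction=0.1, seed=5)
        assert all(len(r.sequence) == len(r.qualities) for r in rs.reads)
        n_rrna = sum(t.is_rrna for t in rs.truth)
        n_mrna = sum(t.locus_tag is not None for t in rs.truth)
        assert n_rrna + n_mrna == 1000

    def test_rrna_flag_count_within_binomial_3_sigma(self, community):
        _, truth = community
        n, p = 10000, 0.05
        rs = simulate_reads(truth, n, rrna_fraction=p, seed=5)
        flagged = sum(t.is_rrna for t in rs.truth)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(flagged - n * p) <= 3 * sigma

    def test_3_to_1_expression_ratio_recovered_in_read_counts(self, community):
        # abcA and abcD have equal lengths and a fixed 3:1 expression ratio
        _, truth = community
        rs = simulate_reads(truth, 50000, error_rate=0.0, seed=5)
        by_symbol = {g.symbol: g.locus_tag for g in truth.genes}
        counts = {"abcA": 0, "abcD": 0}
        for rt in rs.truth:
            for sym, tag in by_symbol.items():
                if rt.locus_tag == tag and sym in counts:
                    counts[sym] += 1
        n_pair = counts["abcA"] + counts["abcD"]
        p_hat = counts["abcA"] / n_pair
        sigma = math.sqrt(0.75 * 0.25 / n_pair)
        assert abs(p_hat - 0.75) <= 3 * sigma

    def test_zero_reads_gives_empty_set(self, community):
        _, truth = community
        rs = simulate_reads(truth, 0, seed=5)
        assert rs.reads == [] and rs.truth == []

    def test_error_rate_out_of_range_raises(self, community):
        _, truth = community
        with pytest.raises(ValueError):
            simulate_reads(truth, 10, error_rate=1.0)


class TestSimulateHitTable:
    def test_no_decoys_lca_lies_on_true_lineage(self, demo_community):
        tree, truth = demo_community
        hits = simulate_hit_table(truth.contig_taxon, tree, decoy_rate=0.0, seed=11)
        by_contig = {}
        for h in hits:
            by_contig.setdefault(h.query, []).append(h)
        for contig, contig_hits in by_contig.items():
            res = assign_contig(contig_hits, tree)
            assert res.assigned
            assert res.taxid in tree.lineage(truth.contig_taxon[contig])

    def test_decoys_never_change_assignment_off_true_lineage(self, demo_community):
        tree, truth = demo_community
        hits = simulate_hit_table(truth.contig_taxon, tree, decoy_rate=1.0, seed=11)
        by_contig = {}
        for h in hits:
            by_contig.setdefault(h.query, []).append(h)
        for contig, contig_hits in by_contig.items():
            res = assign_contig(contig_hits, tree)
            assert res.taxid in tree.lineage(truth.contig_taxon[contig])

    def test_single_hit_contig_is_true_taxon(self):
        tree = generate_taxonomy(2, 1, seed=1)
        sp = tree.species()
        contig_taxon = {"c0": sp[0]}
        hits = simulate_hit_table(contig_taxon, tree, seed=1, n_sisters=0)
        assert len(hits) == 1 and hits[0].taxid == sp[0]


class TestFileEmission:
    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        dirs = []
        for sub in ("a", "b"):
            tree = generate_taxonomy(3, 2, seed=21)
            truth = generate_community(tree, 3, seed=21)
            rs = simulate_reads(truth, 300, error_rate=0.01, rrna_fraction=0.05,
                                seed=21)
            hits = simulate_hit_table(truth.contig_taxon, tree, decoy_rate=0.3,
                                      seed=21)
            d = tmp_path / sub
            write_community(truth, rs, hits, d)
            dirs.append(d)
        names = sorted(p.name for p in dirs[0].iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            dirs[0], dirs[1], names, shallow=False
        )
        assert mismatch == [] and errors == []
        assert "reads.fastq" in match and "hits.tsv" in match
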