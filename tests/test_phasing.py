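"""Phasing: site selection, linkage graph, bipartition quality, blocks, I/O."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import (
    brute_force_min_conflict,
    make_fragment,
    make_sites,
    random_phasing_instance,
)
from haplopgx import phasing as ph
from haplopgx import simulate as sim
from haplopgx.simulate import TruthVariant


def _variant(pos, genotype, contig="chr1", ref="C", alt="T", vtype="SNV", hap=None):
    return TruthVariant(contig, pos, ref, alt, vtype, genotype, hap)


class TestSelectHetSites:
    def test_all_homozygous_yields_empty(self):
        variants = [_variant(p, ("T", "T")) for p in range(0, 100, 10)]
        assert ph.select_het_sites(variants) == []

    def test_cyp2c19_like_mixture(self):
        # 52 small variants of which 33 homozygous -> 19 phaseable sites
        variants = [_variant(10 * i, ("T", "T")) for i in range(33)]
        variants += [_variant(1000 + 10 * i, ("C", "T"), hap=1) for i in range(19)]
        sites = ph.select_het_sites(variants)
        assert len(sites) == 19

    def test_matches_brute_force_filter_and_sorts(self):
        rng = np.random.default_rng(4)
        variants = []
        for i in range(60):
            pos = int(rng.integers(0, 10_000))
            het = rng.random() < 0.5
            variants.append(_variant(pos, ("C", "T") if het else ("T", "T"), hap=1 if het else None))
        sites = ph.select_het_sites(variants)
        expected = sorted(
            {(v.contig, v.pos) for v in variants if v.genotype == ("C", "T")},
            key=lambda t: t[1],
        )
        assert [(s.contig, s.position) for s in sites] == expected

    def test_svs_and_missing_genotypes_skipped(self):
        class NoGt:
            contig, pos, ref, alt, vtype, genotype = "chr1", 5, "C", "T", "SNV", None

        variants = [_variant(10, ("C", "T"), vtype="SV", hap=1), NoGt()]
        assert ph.select_het_sites(variants) == []


class TestLinkageGraph:
    def test_no_spanning_fragment_means_no_edges(self):
        sites = make_sites([100, 200, 300])
        frags = [make_fragment(f"r{i}", [s], [1]) for i, s in enumerate(sites)]
        graph = ph.build_linkage_graph(frags, sites)
        assert graph.graph.number_of_nodes() == 3
        assert graph.graph.number_of_edges() == 0

    def test_chained_fragments_form_one_component(self):
        s1, s2, s3 = make_sites([100, 200, 300])
        frags = [
            make_fragment("r1", [s1, s2], [1, 1]),
            make_fragment("r2", [s2, s3], [1, 1]),
        ]
        graph = ph.build_linkage_graph(frags, [s1, s2, s3])
        assert set(map(frozenset, graph.graph.edges)) == {
            frozenset({s1, s2}),
            frozenset({s2, s3}),
        }
        assert graph.edge_support(s1, s2) == (1, 0)

    def test_missing_middle_linkage_breaks_into_two_components(self):
        import networkx as nx

        sites = make_sites(list(range(100, 1100, 100)))
        frags = []
        # link within the first five and last five sites only
        for i in range(4):
            frags.append(make_fragment(f"a{i}", sites[i : i + 2], [1, 1]))
            frags.append(make_fragment(f"b{i}", sites[5 + i : 7 + i], [1, 1]))
        graph = ph.build_linkage_graph(frags, sites)
        comps = [c for c in nx.connected_components(graph.graph) if len(c) > 1]
        assert len(comps) == 2

    def test_edges_match_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(8)
        sites, frags, _ = random_phasing_instance(rng, n_sites=7, n_fragments=10)
        graph = ph.build_linkage_graph(frags, sites)
        by_pos = {s.position: s for s in sites}
        expected = set()
        for f in frags:
            obs = [by_pos[p] for p, _ in f.observations]
            for i in range(len(obs)):
                for j in range(i + 1, len(obs)):
                    expected.add(frozenset({obs[i], obs[j]}))
        assert set(map(frozenset, graph.graph.edges)) == expected

    def test_unknown_site_observation_ignored(self):
        sites = make_sites([100, 200])
        frag = make_fragment("r1", make_sites([100, 200, 999]), [1, 1, 1])
        graph = ph.build_linkage_graph([frag], sites)
        assert graph.graph.number_of_nodes() == 2
        assert graph.graph.has_edge(sites[0], sites[1])


class TestPhaseComponents:
    def test_unanimous_cis_evidence_puts_alts_together(self):
        s1, s2 = make_sites([10, 20])
        frags = [make_fragment(f"r{i}", [s1, s2], [1, 1]) for i in range(3)]
        graph = ph.build_linkage_graph(frags, [s1, s2])
        assignment = ph.phase_components(graph)
        assert assignment[s1] == assignment[s2]

    def test_trans_evidence_separates_alts(self):
        s1, s2 = make_sites([10, 20])
        frags = [make_fragment(f"r{i}", [s1, s2], [1, 0]) for i in range(3)]
        graph = ph.build_linkage_graph(frags, [s1, s2])
        assignment = ph.phase_components(graph)
        assert assignment[s1] != assignment[s2]

    def test_triangle_with_one_conflicting_edge_keeps_majority(self):
        s1, s2, s3 = make_sites([10, 20, 30])
        frags = [make_fragment(f"a{i}", [s1, s2], [1, 1]) for i in range(5)]
        frags += [make_fragment(f"b{i}", [s2, s3], [1, 1]) for i in range(5)]
        frags.append(make_fragment("c", [s1, s3], [1, 0]))  # lone conflicting trans
        graph = ph.build_linkage_graph(frags, [s1, s2, s3])
        assignment = ph.phase_components(graph)
        assert assignment[s1] == assignment[s2] == assignment[s3]
        assert ph.conflict_cost(graph, assignment) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_minimum_conflict_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        sites, frags, _ = random_phasing_instance(
            rng, n_sites=n, n_fragments=2 * n, error=0.15
        )
        graph = ph.build_linkage_graph(frags, sites)
        assignment = ph.phase_components(graph)
        assert ph.conflict_cost(graph, assignment) == brute_force_min_conflict(graph)

    def test_spanning_tree_heuristic_recovers_clean_data(self):
        # force the heuristic path with a component above the exact limit
        rng = np.random.default_rng(3)
        sites, frags, truth = random_phasing_instance(
            rng, n_sites=30, n_fragments=120, error=0.0, span=(2, 5)
        )
        graph = ph.build_linkage_graph(frags, sites)
        assignment = ph.phase_components(graph, exact_limit=4)
        assert ph.conflict_cost(graph, assignment) == 0

    def test_tie_edge_is_dropped_splitting_the_pair(self):
        s1, s2 = make_sites([10, 20])
        frags = [
            make_fragment("r1", [s1, s2], [1, 1]),
            make_fragment("r2", [s1, s2], [1, 0]),
        ]
        graph = ph.build_linkage_graph(frags, [s1, s2])
        assert ph.phase_components(graph) == {}
        assert ph.construct_haploblocks(graph, {}) == []


class TestHaploblocks:
    def test_zero_het_sites_zero_blocks(self):
        graph = ph.build_linkage_graph([], [])
        assert ph.construct_haploblocks(graph, {}) == []

    def test_two_linked_sites_form_one_block_with_variant_span(self):
        s1, s2 = make_sites([100, 200])
        frags = [make_fragment("r1", [s1, s2], [1, 1])] * 2
        graph = ph.build_linkage_graph(frags, [s1, s2])
        assignment = ph.phase_components(graph)
        blocks = ph.construct_haploblocks(graph, assignment)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (100, 201)

    def test_homozygous_desert_fragments_blocks(self, tmp_path):
        cfg = sim.SyntheticConfig(
            seed=6, error_rate=0.0, homozygous_desert_intervals=((25_000, 75_000),)
        )
        truth = sim.simulate_truth(cfg)
        frags = sim.simulate_fragments(truth, cfg)
        sites = ph.select_het_sites(truth.variants)
        result = ph.HaplotypePhaser(frags, sites, region_length=cfg.region_length).fit()
        assert result.n_blocks >= 2
        for b in result.blocks:
            assert not (b.start < 50_000 < b.end)  # no block spans the desert centre

    def test_coverage_gap_splits_a_component(self):
        # one long fragment links distant sites, but depth is zero between
        # them once the fragment is excluded from the depth profile
        sites = make_sites([100, 5000])
        frag = make_fragment("r1", sites, [1, 1])
        graph = ph.build_linkage_graph([frag], sites)
        assignment = ph.phase_components(graph)
        empty_coverage = ph.CoverageProfile("chr1", np.zeros(6000, dtype=int))
        assert ph.construct_haploblocks(graph, assignment, coverage=empty_coverage) == []
        real_coverage = ph.CoverageProfile.from_fragments([frag], 6000)
        blocks = ph.construct_haploblocks(graph, assignment, coverage=real_coverage)
        assert len(blocks) == 1

    def test_adding_consistent_read_never_splits_blocks(self):
        rng = np.random.default_rng(12)
        sites, frags, truth = random_phasing_instance(
            rng, n_sites=8, n_fragments=10, error=0.0
        )
        graph = ph.build_linkage_graph(frags, sites)
        before = ph.construct_haploblocks(graph, ph.phase_components(graph))
        extra = make_fragment(
            "extra", sites[2:5], [1 if truth[s] == 1 else 0 for s in sites[2:5]]
        )
        graph2 = ph.build_linkage_graph(frags + [extra], sites)
        after = ph.construct_haploblocks(graph2, ph.phase_components(graph2))
        for b in before:
            members = set(b.sites)
            assert any(members <= set(nb.sites) for nb in after)

    def test_block_label_flip_is_a_symmetry(self):
        from haplopgx.resolution import Feature, phased_fraction

        s1, s2 = make_sites([100, 200])
        frags = [make_fragment("r1", [s1, s2], [1, 1])] * 2
        graph = ph.build_linkage_graph(frags, [s1, s2])
        blocks = ph.construct_haploblocks(graph, ph.phase_components(graph))
        feature = Feature("f", "chr1", 50, 250)
        a = phased_fraction(feature, blocks)
        b = phased_fraction(feature, [blk.flipped() for blk in blocks])
        assert a == b


class TestVcfAndBedIO:
    def test_phased_vcf_round_trip_matches_fragment_blocks(self, tmp_path):
        cfg = sim.SyntheticConfig(seed=17, error_rate=0.0)
        truth = sim.simulate_truth(cfg)
        frags = sim.simulate_fragments(truth, cfg)
        sites = ph.select_het_sites(truth.variants)
        result = ph.HaplotypePhaser(frags, sites, region_length=cfg.region_length).fit()
        path = tmp_path / "phased.vcf"
        ph.write_phased_vcf(
            truth.variants, result.blocks, path, {truth.contig: cfg.region_length}
        )
        _, _, imported = ph.import_phased_vcf(path)
        assert len(imported) == len(result.blocks)
        for orig, imp in zip(result.blocks, imported):
            assert (imp.contig, imp.start, imp.end) == (orig.contig, orig.start, orig.end)
            assert set(imp.sites) == set(orig.sites)
            same = all(imp.assignment[s] == orig.assignment[s] for s in orig.sites)
            flipped = all(imp.assignment[s] != orig.assignment[s] for s in orig.sites)
            assert same or flipped

    def test_import_one_phase_set_of_three_variants(self, tmp_path):
        path = tmp_path / "in.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=10000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
            '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="PS">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS",
            "chr1\t101\t.\tC\tT\t.\tPASS\t.\tGT:PS\t1|0:101",
            "chr1\t201\t.\tG\tA\t.\tPASS\t.\tGT:PS\t0|1:101",
            "chr1\t301\t.\tC\tG\t.\tPASS\t.\tGT:PS\t1|0:101",
        ]
        path.write_text("\n".join(lines) + "\n")
        het_sites, assignment, blocks = ph.import_phased_vcf(path)
        assert len(het_sites) == 3
        assert len(blocks) == 1 and len(blocks[0].sites) == 3
        assert [assignment[s] for s in blocks[0].sites] == [1, 2, 1]

    def test_import_two_phase_sets_gives_two_blocks(self, tmp_path):
        path = tmp_path / "two.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=10000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
            '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="PS">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS",
            "chr1\t101\t.\tC\tT\t.\tPASS\t.\tGT:PS\t1|0:101",
            "chr1\t201\t.\tG\tA\t.\tPASS\t.\tGT:PS\t0|1:101",
            "chr1\t1101\t.\tC\tG\t.\tPASS\t.\tGT:PS\t1|0:1101",
            "chr1\t1201\t.\tA\tG\t.\tPASS\t.\tGT:PS\t1|0:1101",
            "chr1\t2001\t.\tA\tC\t.\tPASS\t.\tGT\t0/1",  # unphased singleton
        ]
        path.write_text("\n".join(lines) + "\n")
        het_sites, _, blocks = ph.import_phased_vcf(path)
        assert len(het_sites) == 5
        assert len(blocks) == 2

    def test_blocks_to_bed_coordinates_and_round_trip(self, tmp_path):
        s1, s2 = make_sites([99, 199])  # 1-based sites 100 and 200
        block = ph.Haploblock("chr1", 99, 200, (s1, s2), {s1: 1, s2: 2}, "b1")
        path = tmp_path / "blocks.bed"
        ph.blocks_to_bed([block], path)
        records = ph.read_blocks_bed(path)
        assert records == [("chr1", 99, 200, "b1")]
        empty = tmp_path / "empty.bed"
        ph.blocks_to_bed([], empty)
        assert ph.read_blocks_bed(empty) == []
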