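"""Star-allele matching, diplotype assignment, phenotypes, guideline coverage."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from haplopgx import pgx
from haplopgx.phasing import Haploblock, HetSite
from haplopgx.resolution import FULLY_PHASED, PARTIALLY_PHASED


@dataclass
class Obs:
    contig: str
    pos: int
    ref: str
    alt: str
    genotype: tuple


CYP2D6_V1 = ("chr22", 42128944, "C", "T")  # rs3892097, 1-based 42128945
CYP2D6_V2 = ("chr22", 42130691, "G", "A")  # rs1065852, 1-based 42130692


def het(key):
    c, p, r, a = key
    return Obs(c, p, r, a, (r, a))


def hom(key):
    c, p, r, a = key
    return Obs(c, p, r, a, (a, a))


def cyp2d6_block(hap1, hap2):
    s1 = HetSite(*CYP2D6_V1)
    s2 = HetSite(*CYP2D6_V2)
    return Haploblock(
        "chr22", s1.position, s2.position + 1, (s1, s2), {s1: hap1, s2: hap2}, "b"
    )


@pytest.fixture(scope="module")
def defs():
    return pgx.load_demo_definitions()


@pytest.fixture(scope="module")
def trans_table():
    return pgx.load_demo_translation()


class TestDefinitions:
    def test_demo_table_contents(self, defs):
        assert set(defs) == {"CYP2D6", "CYP3A5", "VKORC1"}
        star4 = next(d for d in defs["CYP2D6"] if d.allele == "*4")
        assert star4.defining_variants == frozenset({CYP2D6_V1, CYP2D6_V2})
        star3 = next(d for d in defs["CYP3A5"] if d.allele == "*3")
        assert star3.defining_variants == frozenset({("chr7", 99672915, "C", "T")})

    def test_empty_table_is_valid(self, tmp_path):
        p = tmp_path / "defs.tsv"
        p.write_text("gene\tallele\tvariants\n")
        assert pgx.load_allele_definitions(p) == {}

    def test_default_allele_with_variants_rejected(self):
        with pytest.raises(ValueError, match="empty defining set"):
            pgx.AlleleDefinition("G", "*1", frozenset({("chr1", 0, "A", "T")}))

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "defs.tsv"
        p.write_text(
            "gene\tallele\tvariants\nG\t*2\tchr1:10:A>T\nG\t*2\tchr1:20:A>T\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            pgx.load_allele_definitions(p)


class TestAlleleMatch:
    def test_empty_haplotype_is_default(self, defs):
        assert pgx.haplotype_allele_match("CYP2D6", set(), defs).allele == "*1"

    def test_cyp2d6_star4_from_both_variants(self, defs):
        m = pgx.haplotype_allele_match("CYP2D6", {CYP2D6_V1, CYP2D6_V2}, defs)
        assert m.allele == "*4" and not m.ambiguous

    def test_partial_defining_set_reported_not_called(self, defs):
        m = pgx.haplotype_allele_match("CYP2D6", {CYP2D6_V1}, defs)
        assert m.allele == "*1"
        assert m.partial == ("*4",)

    def test_incomparable_equal_priority_matches_are_ambiguous(self):
        v = [("chr1", i, "A", "T") for i in range(4)]
        defs = {
            "G": [
                pgx.AlleleDefinition("G", "*1", frozenset()),
                pgx.AlleleDefinition("G", "*2", frozenset(v[:2])),
                pgx.AlleleDefinition("G", "*3", frozenset(v[2:])),
            ]
        }
        m = pgx.haplotype_allele_match("G", set(v), defs)
        assert m.ambiguous and m.candidates == ("*2", "*3")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_containment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pool = [("chr1", int(p), "A", "T") for p in range(20)]
        defs_list = [pgx.AlleleDefinition("G", "*1", frozenset())]
        for i in range(int(rng.integers(2, 7))):
            size = int(rng.integers(1, 5))
            variants = frozenset(
                pool[j] for j in rng.choice(len(pool), size=size, replace=False)
            )
            try:
                defs_list.append(pgx.AlleleDefinition("G", f"*{i + 2}", variants))
            except ValueError:
                continue
        carried = {pool[j] for j in rng.choice(len(pool), size=6, replace=False)}
        defs = {"G": defs_list}
        m = pgx.haplotype_allele_match("G", carried, defs)
        contained = [
            d for d in defs_list if d.allele != "*1" and d.defining_variants <= carried
        ]
        if not contained:
            assert m.allele == "*1"
        else:
            top = max(len(d.defining_variants) for d in contained)
            best = sorted(
                d.allele for d in contained if len(d.defining_variants) == top
            )
            if len(best) > 1:
                assert m.ambiguous and list(m.candidates) == best
            else:
                assert m.allele == best[0]


class TestDiplotypes:
    def test_cyp2d6_cis_gives_star1_star4_phased(self, defs, trans_table):
        call = pgx.assign_diplotype(
            "CYP2D6", [het(CYP2D6_V1), het(CYP2D6_V2)], [cyp2d6_block(1, 1)], defs
        )
        assert call.diplotype == "*1/*4" and call.phased
        phenotype = pgx.translate_phenotype(call, trans_table)
        assert phenotype.phenotype == "IM" and phenotype.actionable

    def test_cyp2d6_trans_matches_neither_full_set(self, defs):
        call = pgx.assign_diplotype(
            "CYP2D6", [het(CYP2D6_V1), het(CYP2D6_V2)], [cyp2d6_block(1, 2)], defs
        )
        assert call.diplotype == "*1/*1" and call.phased
        assert "partial" in call.note  # neither haplotype completes *4

    def test_cyp3a5_homozygous_pm_not_actionable(self, defs, trans_table):
        call = pgx.assign_diplotype(
            "CYP3A5", [hom(("chr7", 99672915, "C", "T"))], [], defs
        )
        assert call.diplotype == "*3/*3"
        phenotype = pgx.translate_phenotype(call, trans_table)
        assert phenotype.phenotype == "PM" and not phenotype.actionable

    def test_vkorc1_homozygous_decreased_activity(self, defs, trans_table):
        call = pgx.assign_diplotype(
            "VKORC1", [hom(("chr16", 31093556, "G", "A"))], [], defs
        )
        phenotype = pgx.translate_phenotype(call, trans_table)
        assert phenotype.diplotype == "1173T/1173T"
        assert phenotype.phenotype == "1173TT, decreased activity"

    def test_unphased_fallback_places_variants_to_maximize_matches(self, defs):
        # het variants not covered by any block: the fallback puts both *4
        # variants on one haplotype because that maximises matched alleles
        call = pgx.assign_diplotype(
            "CYP2D6", [het(CYP2D6_V1), het(CYP2D6_V2)], [], defs
        )
        assert not call.phased
        assert call.diplotype == "*1/*4"
        assert "fallback" in call.note

    def test_diplotype_order_invariance(self, defs):
        a = pgx.assign_diplotype(
            "CYP2D6", [het(CYP2D6_V1), het(CYP2D6_V2)], [cyp2d6_block(1, 1)], defs
        )
        b = pgx.assign_diplotype(
            "CYP2D6", [het(CYP2D6_V1), het(CYP2D6_V2)], [cyp2d6_block(2, 2)], defs
        )
        assert a.diplotype == b.diplotype

    def test_homozygous_only_input_ignores_phasing(self, defs):
        obs = [hom(("chr7", 99672915, "C", "T"))]
        with_blocks = pgx.assign_diplotype("CYP3A5", obs, [cyp2d6_block(1, 1)], defs)
        without = pgx.assign_diplotype("CYP3A5", obs, [], defs)
        assert with_blocks.diplotype == without.diplotype == "*3/*3"

    def test_single_het_variant_agrees_with_and_without_phase(self, defs):
        obs = [het(("chr7", 99672915, "C", "T"))]
        s = HetSite("chr7", 99672915, "C", "T")
        s2 = HetSite("chr7", 99680000, "G", "A")
        block = Haploblock("chr7", s.position, s2.position + 1, (s, s2), {s: 2, s2: 1}, "b")
        phased = pgx.assign_diplotype("CYP3A5", obs, [block], defs)
        unphased = pgx.assign_diplotype("CYP3A5", obs, [], defs)
        assert phased.diplotype == unphased.diplotype == "*1/*3"
        assert phased.phased and not unphased.phased

    def test_unknown_gene_is_a_reasoned_no_call(self, defs):
        call = pgx.assign_diplotype("CYP9Z9", [], [], defs)
        assert call.allele_1 is None and "absent" in call.note

    def test_missing_translation_yields_indeterminate(self, defs, trans_table):
        call = pgx.DiplotypeCall("CYP2D6", "*9", "*9", True, ())
        p = pgx.translate_phenotype(call, trans_table)
        assert p.phenotype == "indeterminate" and not p.actionable


class TestGuidelineCoverage:
    def test_all_genes_fully_phased_full_coverage(self):
        table = pd.DataFrame(
            {"gene": ["A", "B"], "drug": ["d1", "d2"], "source": ["DPWG", "DPWG"]}
        )
        report = pgx.guideline_coverage({"A": FULLY_PHASED, "B": FULLY_PHASED}, table)
        assert report["per_source"]["DPWG"]["fraction_covered"] == 1.0

    def test_toy_four_interactions_three_covered(self):
        table = pd.DataFrame(
            {
                "gene": ["A", "A", "A", "B"],
                "drug": ["d1", "d2", "d3", "d4"],
                "source": ["CPIC"] * 4,
            }
        )
        report = pgx.guideline_coverage(
            {"A": FULLY_PHASED, "B": PARTIALLY_PHASED}, table
        )
        src = report["per_source"]["CPIC"]
        assert (src["covered_interactions"], src["total_interactions"]) == (3, 4)
        assert src["covered_interactions"] + src["uncovered_interactions"] == 4

    def test_ten_of_fifteen_genes_resolved(self):
        genes = [f"G{i}" for i in range(15)]
        rows = [
            {"gene": g, "drug": f"d{i}", "source": "DPWG" if i % 2 else "CPIC"}
            for i, g in enumerate(genes)
        ]
        table = pd.DataFrame(rows)
        categories = {
            g: FULLY_PHASED if i < 10 else PARTIALLY_PHASED for i, g in enumerate(genes)
        }
        report = pgx.guideline_coverage(categories, table)
        assert report["genes_fully_phased"] == 10
        assert report["gene_fraction_fully_phased"] == pytest.approx(10 / 15)

    def test_missing_gene_counts_as_unresolved(self):
        table = pd.DataFrame({"gene": ["A"], "drug": ["d"], "source": ["DPWG"]})
        report = pgx.guideline_coverage({}, table)
        assert report["per_source"]["DPWG"]["covered_interactions"] == 0
        assert report["per_gene"]["A"]["category"] == "missing"
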