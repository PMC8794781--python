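"""Phasing-aware star-allele diplotype and phenotype calling.

A *star allele* is a named pharmacogene haplotype defined by a set of
variants; ``*1`` is the default (reference) allele with an empty defining
set. Given the observed variants at a gene plus phasing information, the
caller:

1. restricts attention to variants appearing in the gene's allele
   definitions (panel variants);
2. if every definition-relevant heterozygous variant lies in a single
   haploblock, splits the variants by haplotype using the block's
   assignment (homozygous variants contribute to both haplotypes) and
   matches each haplotype against the definitions — a *phased* call;
3. otherwise falls back to the conventional non-phased assignment used in
   clinical practice: heterozygous panel variants are distributed over
   the two haplotypes so as to maximise the number of matched non-default
   alleles (distinct allele-defining variants placed in trans).

Matching is exact set containment, most specific (largest defining set)
first; two incomparable equal-priority matches are reported as ambiguous
rather than silently resolved. Diplotypes translate to phenotypes (PM /
IM / NM or an activity descriptor) through a user-supplied table, and a
guideline table (gene, drug, source) supports coverage reporting: how
many gene-drug interactions concern genes that were fully resolved in
phased haploblocks, where *actionable* means an interaction requiring a
drug switch, dose adjustment or intensive monitoring.

Bundled demo tables cover three worked genes (CYP2D6, CYP3A5, VKORC1);
full panels (e.g. the U-PGx 38-variant panel) are user-supplied data in
the same schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .resolution import FULLY_PHASED, FeatureResolution

logger = logging.getLogger(__name__)

DEFAULT_ALLELE = "*1"

VariantKey = tuple[str, int, str, str]  # contig, 0-based pos, ref, alt


@dataclass(frozen=True)
class AlleleDefinition:
    gene: str
    allele: str
    defining_variants: frozenset[VariantKey]

    @property
    def priority(self) -> int:
        """Most specific allele wins: priority = defining-set size."""
        return len(self.defining_variants)

    def __post_init__(self) -> None:
        if self.allele == DEFAULT_ALLELE and self.defining_variants:
            raise ValueError(f"{self.gene} {DEFAULT_ALLELE} must have an empty defining set")
        if self.allele != DEFAULT_ALLELE and not self.defining_variants:
            raise ValueError(f"{self.gene} {self.allele} has an empty defining set")


@dataclass(frozen=True)
class AlleleMatch:
    allele: str | None
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()
    # alleles whose defining set is only partly carried by the haplotype;
    # the haplotype still matches a smaller (possibly default) allele, but
    # the partial hit is surfaced rather than guessed at
    partial: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiplotypeCall:
    gene: str
    allele_1: str | None
    allele_2: str | None
    phased: bool
    supporting_variants: tuple[VariantKey, ...]
    ambiguous: bool = False
    note: str = ""

    @property
    def diplotype(self) -> str:
        a1, a2 = sorted(str(a) for a in (self.allele_1, self.allele_2))
        return f"{a1}/{a2}"


@dataclass(frozen=True)
class PhenotypeCall:
    gene: str
    diplotype: str
    phenotype: str
    actionable: bool


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------


def _parse_variant_token(token: str) -> VariantKey:
    """Parse ``contig:pos:ref>alt`` with a 1-based position (as printed in
    VCF/HGVS-style tables) into the internal 0-based key."""
    contig, pos, change = token.strip().split(":")
    ref, alt = change.split(">")
    return (contig, int(pos) - 1, ref, alt)


def load_allele_definitions(path) -> dict[str, list[AlleleDefinition]]:
    """Load a TSV with columns ``gene``, ``allele``, ``variants``.

    ``variants`` is a semicolon-separated list of ``contig:pos:ref>alt``
    tokens (1-based positions) and is empty for the default allele.
    Duplicate (gene, allele) rows fail the load.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene", "allele", "variants"}
    if not required <= set(table.columns):
        raise ValueError(f"allele definition table must have columns {sorted(required)}")
    dups = table.duplicated(subset=["gene", "allele"])
    if dups.any():
        row = table[dups].iloc[0]
        raise ValueError(f"duplicate allele definition: {row['gene']} {row['allele']}")
    defs: dict[str, list[AlleleDefinition]] = {}
    for _, row in table.iterrows():
        variants = frozenset(
            _parse_variant_token(tok) for tok in row["variants"].split(";") if tok.strip()
        )
        defs.setdefault(row["gene"], []).append(
            AlleleDefinition(row["gene"], row["allele"], variants)
        )
    for gene, alleles in defs.items():
        if not any(a.allele == DEFAULT_ALLELE for a in alleles):
            defs[gene] = alleles + [AlleleDefinition(gene, DEFAULT_ALLELE, frozenset())]
    return defs


def load_translation_table(path) -> dict[tuple[str, str], tuple[str, bool]]:
    """TSV columns: gene, diplotype (canonical sorted ``a/b``), phenotype, actionable."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[tuple[str, str], tuple[str, bool]] = {}
    for _, row in table.iterrows():
        a1, a2 = row["diplotype"].split("/")
        key = (row["gene"], "/".join(sorted((a1, a2))))
        out[key] = (row["phenotype"], str(row["actionable"]).lower() in ("true", "1", "yes"))
    return out


def load_guidelines(path) -> pd.DataFrame:
    """TSV columns: gene, drug, source (DPWG or CPIC); rows must be unique."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "drug", "source"}
    if not required <= set(table.columns):
        raise ValueError(f"guideline table must have columns {sorted(required)}")
    if table.duplicated(subset=["gene", "drug", "source"]).any():
        raise ValueError("duplicate (gene, drug, source) rows in guideline table")
    return table


def _demo_path(name: str):
    return resources.files("haplopgx").joinpath("data").joinpath(name)


def load_demo_definitions() -> dict[str, list[AlleleDefinition]]:
    with resources.as_file(_demo_path("demo_allele_definitions.tsv")) as p:
        return load_allele_definitions(p)


def load_demo_translation() -> dict[tuple[str, str], tuple[str, bool]]:
    with resources.as_file(_demo_path("demo_phenotype_translation.tsv")) as p:
        return load_translation_table(p)


def load_demo_guidelines() -> pd.DataFrame:
    with resources.as_file(_demo_path("demo_guidelines.tsv")) as p:
        return load_guidelines(p)


# ---------------------------------------------------------------------------
# Allele matching and diplotype assignment
# ---------------------------------------------------------------------------


def haplotype_allele_match(
    gene: str,
    haplotype_variants: Iterable[VariantKey],
    definitions: Mapping[str, Sequence[AlleleDefinition]],
) -> AlleleMatch:
    """The most specific allele whose defining set the haplotype contains.

    Falls back to the default allele when nothing matches. When two
    distinct alleles of equal priority match and neither defining set
    contains the other, the call is ambiguous.
    """
    if gene not in definitions:
        raise KeyError(f"gene {gene} absent from allele definitions")
    carried = set(haplotype_variants)
    matches = [
        d for d in definitions[gene]
        if d.allele != DEFAULT_ALLELE and d.defining_variants <= carried
    ]
    partial = tuple(
        sorted(
            d.allele
            for d in definitions[gene]
            if d.allele != DEFAULT_ALLELE
            and d.defining_variants & carried
            and not d.defining_variants <= carried
        )
    )
    if not matches:
        return AlleleMatch(DEFAULT_ALLELE, partial=partial)
    top = max(d.priority for d in matches)
    best = sorted((d for d in matches if d.priority == top), key=lambda d: d.allele)
    if len(best) > 1:
        logger.warning(
            "%s: ambiguous allele match among %s", gene, [d.allele for d in best]
        )
        return AlleleMatch(
            None, ambiguous=True, candidates=tuple(d.allele for d in best), partial=partial
        )
    return AlleleMatch(best[0].allele, partial=partial)


def _non_default_matches(*alleles: str | None) -> int:
    return sum(a is not None and a != DEFAULT_ALLELE for a in alleles)


def assign_diplotype(
    gene: str,
    variants: Sequence,
    blocks: Sequence,
    definitions: Mapping[str, Sequence[AlleleDefinition]],
) -> DiplotypeCall:
    """Diplotype for one gene from observed variants plus phasing.

    ``variants`` are observed records with ``contig``, ``pos``, ``ref``,
    ``alt`` and ``genotype`` attributes (genotype an allele tuple; two
    equal entries = homozygous). ``blocks`` are haploblocks whose
    ``assignment`` maps het sites to the haplotype carrying the alternate
    allele.
    """
    if gene not in definitions:
        return DiplotypeCall(gene, None, None, False, (), note="gene absent from definitions")
    panel: set[VariantKey] = set()
    for d in definitions[gene]:
        panel |= d.defining_variants

    relevant = []
    for v in variants:
        key = (v.contig, v.pos, v.ref, v.alt)
        if key in panel:
            relevant.append((key, v))
    hom_keys = [k for k, v in relevant if len(set(v.genotype)) == 1]
    het = [(k, v) for k, v in relevant if len(set(v.genotype)) > 1]

    # locate each het variant's block
    site_to_block = {}
    for b in blocks:
        for s in b.sites:
            site_to_block[(s.contig, s.position, s.ref_allele, s.alt_allele)] = b
    het_blocks = [site_to_block.get(k) for k, _ in het]

    phased = len(het) == 0 or (
        all(b is not None for b in het_blocks) and len({id(b) for b in het_blocks}) == 1
    )

    supporting = tuple(sorted(k for k, _ in relevant))

    if phased and het:
        block = het_blocks[0]
        hap_vars: dict[int, set[VariantKey]] = {1: set(hom_keys), 2: set(hom_keys)}
        for (key, _v) in het:
            site = next(
                s for s in block.sites
                if (s.contig, s.position, s.ref_allele, s.alt_allele) == key
            )
            hap_vars[block.assignment[site]].add(key)
        m1 = haplotype_allele_match(gene, hap_vars[1], definitions)
        m2 = haplotype_allele_match(gene, hap_vars[2], definitions)
        partial = tuple(sorted(set(m1.partial) | set(m2.partial)))
        return DiplotypeCall(
            gene, m1.allele, m2.allele, True, supporting,
            ambiguous=m1.ambiguous or m2.ambiguous,
            note=f"partial allele match: {', '.join(partial)}" if partial else "",
        )
    if phased:  # homozygous-only: phase cannot matter
        m = haplotype_allele_match(gene, set(hom_keys), definitions)
        return DiplotypeCall(gene, m.allele, m.allele, True, supporting, ambiguous=m.ambiguous)

    # unphased fallback: place het panel variants to maximise matched
    # non-default alleles (trans placement of distinct allele-defining
    # variants, the conventional clinical assumption)
    best: tuple[int, str, AlleleMatch, AlleleMatch] | None = None
    scored: list[tuple[int, str]] = []
    for sides in product((1, 2), repeat=len(het)):
        hap_vars = {1: set(hom_keys), 2: set(hom_keys)}
        for (key, _v), side in zip(het, sides):
            hap_vars[side].add(key)
        m1 = haplotype_allele_match(gene, hap_vars[1], definitions)
        m2 = haplotype_allele_match(gene, hap_vars[2], definitions)
        a1, a2 = sorted(str(m.allele) for m in (m1, m2))
        score = _non_default_matches(m1.allele, m2.allele)
        diplotype = f"{a1}/{a2}"
        scored.append((score, diplotype))
        # deterministic tie-break within a diplotype: lexicographically
        # smallest diplotype string wins
        if best is None or score > best[0] or (score == best[0] and diplotype < best[1]):
            best = (score, diplotype, m1, m2)
    assert best is not None
    top = best[0]
    diplotypes_at_top = {d for s, d in scored if s == top}
    _, _, m1, m2 = best
    return DiplotypeCall(
        gene, m1.allele, m2.allele, False, supporting,
        ambiguous=m1.ambiguous or m2.ambiguous or len(diplotypes_at_top) > 1,
        note="unphased fallback" + (": multiple optimal placements" if len(diplotypes_at_top) > 1 else ""),
    )


def translate_phenotype(
    call: DiplotypeCall,
    translation: Mapping[tuple[str, str], tuple[str, bool]],
) -> PhenotypeCall:
    """Look up the phenotype label and actionability for a diplotype.

    Missing mappings yield an "indeterminate" phenotype with a warning.
    """
    key = (call.gene, call.diplotype)
    if call.allele_1 is None or call.allele_2 is None or key not in translation:
        logger.warning("no phenotype mapping for %s %s", call.gene, call.diplotype)
        return PhenotypeCall(call.gene, call.diplotype, "indeterminate", False)
    phenotype, actionable = translation[key]
    return PhenotypeCall(call.gene, call.diplotype, phenotype, actionable)


# ---------------------------------------------------------------------------
# Guideline coverage
# ---------------------------------------------------------------------------


def guideline_coverage(
    resolutions: Mapping[str, FeatureResolution | str],
    guideline_table: pd.DataFrame,
) -> dict:
    """Coverage of guideline gene-drug interactions by fully phased genes.

    ``resolutions`` maps gene name to its :class:`FeatureResolution` (or
    directly to a category string). Guideline genes without a resolution
    record count as unresolved, with a warning. Returns per-source totals
    plus per-gene interaction counts; covered + uncovered = total per
    source.
    """

    def category(gene: str) -> str:
        r = resolutions.get(gene)
        if r is None:
            logger.warning("guideline gene %s has no resolution record", gene)
            return "missing"
        return r if isinstance(r, str) else r.category

    per_source = {}
    for source, sub in guideline_table.groupby("source"):
        total = len(sub)
        covered = int(sum(category(g) == FULLY_PHASED for g in sub["gene"]))
        per_source[source] = {
            "total_interactions": total,
            "covered_interactions": covered,
            "uncovered_interactions": total - covered,
            "fraction_covered": covered / total if total else 0.0,
        }
    genes = sorted(set(guideline_table["gene"]))
    per_gene = {
        g: {
            "interactions": int((guideline_table["gene"] == g).sum()),
            "category": category(g),
        }
        for g in genes
    }
    n_full = sum(1 for g in genes if category(g) == FULLY_PHASED)
    return {
        "per_source": per_source,
        "per_gene": per_gene,
        "genes_total": len(genes),
        "genes_fully_phased": n_full,
        "gene_fraction_fully_phased": n_full / len(genes) if genes else 0.0,
    }


def calls_to_json(diplotypes: Sequence[DiplotypeCall], phenotypes: Sequence[PhenotypeCall], path) -> None:
    payload = {
        "diplotypes": [
            {
                "gene": d.gene,
                "diplotype": d.diplotype,
                "phased": d.phased,
                "ambiguous": d.ambiguous,
                "supporting_variants": [
                    f"{c}:{p + 1}:{r}>{a}" for c, p, r, a in d.supporting_variants
                ],
                "note": d.note,
            }
            for d in diplotypes
        ],
        "phenotypes": [
            {
                "gene": p.gene,
                "diplotype": p.diplotype,
                "phenotype": p.phenotype,
                "actionable": p.actionable,
            }
            for p in phenotypes
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
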