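"""Genotype-aware variant benchmarking against a truth set.

Small variants (SNVs and indels) are normalised — multi-allelic records
split, indels left-aligned and trimmed — and then compared by exact
identity of contig, position, alleles and (unordered) genotype inside a
set of confident regions. A query-only record is a false positive, a
truth-only record a false negative, and a genotype mismatch at a matching
site counts as both. Precision, recall and F1 are reported in percent,
separately per variant type and, optionally, per stratification track.

Structural variants (>= 50 bp by default) are matched one-to-one by a
greedy nearest-breakpoint rule subject to a maximum breakpoint distance,
a minimum size similarity (min length / max length) and, optionally, SV
type identity — the conventional SV-comparison admissibility criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._intervals import Interval, contains_point, merge_intervals

logger = logging.getLogger(__name__)

SV_MIN_SIZE = 50

SNV = "SNV"
INDEL = "INDEL"
SV = "SV"


@dataclass(frozen=True)
class NormalizedVariant:
    """A left-aligned, trimmed, biallelic variant with an unordered genotype.

    ``genotype`` is a sorted tuple of allele codes (0 = ref, 1 = alt);
    a single-element tuple denotes a hemizygous call. ``sv_length`` is the
    absolute length difference for SVs, 0 otherwise.
    """

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    vtype: str
    genotype: tuple[int, ...]
    sv_length: int = 0
    svtype: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class RawVariant:
    """An unnormalised (possibly multi-allelic) input record."""

    contig: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    gt: tuple[int, ...]  # allele indices into (ref, *alts)


@dataclass(frozen=True)
class SvMatchParams:
    sv_min_size: int = SV_MIN_SIZE
    max_breakpoint_distance: int = 500
    min_size_similarity: float = 0.7
    type_match_required: bool = True

    def __post_init__(self) -> None:
        if self.sv_min_size < 0:
            raise ValueError("sv_min_size must be non-negative")
        if not 0.0 < self.min_size_similarity <= 1.0:
            raise ValueError("min_size_similarity must lie in (0, 1]")


@dataclass(frozen=True)
class BenchmarkResult:
    variant_type: str
    stratum: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)

    @property
    def degenerate(self) -> bool:
        """True when any denominator vanished and a metric defaulted to 0."""
        return self.tp + self.fp == 0 or self.tp + self.fn == 0

    def to_row(self) -> dict:
        return {
            "variant_type": self.variant_type,
            "stratum": self.stratum,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision_pct": round(self.precision, 2),
            "recall_pct": round(self.recall, 2),
            "f1_pct": self.f1,
            "degenerate": self.degenerate,
        }


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent), to two decimals.

    Returns 0.0 when both inputs are zero.
    """
    if not (0.0 <= precision <= 100.0 and 0.0 <= recall <= 100.0):
        raise ValueError("precision and recall must lie in [0, 100]")
    if precision + recall == 0:
        return 0.0
    return round(2.0 * precision * recall / (precision + recall), 2)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def left_align(reference: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Shift an allele pair to its leftmost equivalent placement and trim.

    Standard normalisation: repeatedly truncate a shared terminal base
    (borrowing the preceding reference base when an allele would empty),
    then trim shared leading bases.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 0:
                    raise ValueError("cannot extend allele past the contig start")
                pos -= 1
                base = reference[pos]
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_variant(ref: str, alt: str, sv_min_size: int = SV_MIN_SIZE) -> tuple[str, int, str | None]:
    diff = abs(len(alt) - len(ref))
    if diff == 0 and len(ref) == 1:
        return SNV, 0, None
    if diff >= sv_min_size:
        return SV, diff, "INS" if len(alt) > len(ref) else "DEL"
    return INDEL, 0, None


def normalize_variants(
    variants: Iterable[RawVariant],
    reference: Mapping[str, str] | str,
    sv_min_size: int = SV_MIN_SIZE,
) -> list[NormalizedVariant]:
    """Split multi-allelic records, left-align indels, classify by type.

    Records whose REF disagrees with the reference sequence are excluded
    from comparison with a logged warning. ``reference`` may be a single
    sequence (applied to every contig) or a contig -> sequence mapping.
    """
    out: list[NormalizedVariant] = []
    for v in variants:
        seq = reference if isinstance(reference, str) else reference.get(v.contig)
        if seq is None or seq[v.pos : v.pos + len(v.ref)].upper() != v.ref.upper():
            logger.warning(
                "variant %s:%d %s allele inconsistent with reference; excluded",
                v.contig, v.pos + 1, v.ref,
            )
            continue
        for i, alt in enumerate(v.alts, start=1):
            gt = tuple(sorted(1 if a == i else 0 for a in v.gt))
            if 1 not in gt:
                continue  # this alt allele is not carried
            pos, ref, alt_n = left_align(seq, v.pos, v.ref, alt)
            vtype, sv_len, svtype = classify_variant(ref, alt_n, sv_min_size)
            out.append(
                NormalizedVariant(v.contig, pos, ref, alt_n, vtype, gt, sv_len, svtype)
            )
    out.sort(key=lambda n: (n.contig, n.pos, n.ref, n.alt))
    return out


def read_vcf_variants(path, reference: Mapping[str, str] | str, sv_min_size: int = SV_MIN_SIZE) -> list[NormalizedVariant]:
    """Read a single-sample VCF and normalise its records."""
    import pysam

    raw: list[RawVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gt = rec.samples[0]["GT"]
            if gt is None or all(a is None for a in gt):
                logger.warning("record %s:%d has no genotype; skipped", rec.contig, rec.pos)
                continue
            raw.append(
                RawVariant(
                    rec.contig, rec.pos - 1, rec.ref, tuple(rec.alts or ()),
                    tuple(a for a in gt if a is not None),
                )
            )
    return normalize_variants(raw, reference, sv_min_size)


# ---------------------------------------------------------------------------
# Small-variant comparison
# ---------------------------------------------------------------------------


def _restrict(variants: Iterable[NormalizedVariant], merged: Sequence[Interval] | None):
    if merged is None:
        return [v for v in variants]
    return [v for v in variants if contains_point(merged, v.pos)]


def compare_small_variants(
    truth: Sequence[NormalizedVariant],
    query: Sequence[NormalizedVariant],
    confident_regions: Iterable[Interval] | None = None,
    stratum: str = "all",
) -> dict[str, BenchmarkResult]:
    """Exact genotype-aware comparison, reported per variant type.

    Matching requires identical contig/position/ref/alt *and* genotype; a
    site present in both sets with a different genotype counts as one FP
    plus one FN. Overlapping confident intervals are unioned. SV records
    are ignored here (see :func:`match_svs`).
    """
    merged = merge_intervals(confident_regions) if confident_regions is not None else None
    t = {v.key: v for v in _restrict(truth, merged) if v.vtype != SV}
    q = {v.key: v for v in _restrict(query, merged) if v.vtype != SV}
    counts = {vt: {"tp": 0, "fp": 0, "fn": 0} for vt in (SNV, INDEL)}
    for key, tv in t.items():
        qv = q.get(key)
        if qv is None:
            counts[tv.vtype]["fn"] += 1
        elif qv.genotype == tv.genotype:
            counts[tv.vtype]["tp"] += 1
        else:
            counts[tv.vtype]["fn"] += 1
            counts[tv.vtype]["fp"] += 1
    for key, qv in q.items():
        if key not in t:
            counts[qv.vtype]["fp"] += 1
    return {
        vt: BenchmarkResult(vt, stratum, c["tp"], c["fp"], c["fn"])
        for vt, c in counts.items()
    }


def stratify_results(
    truth: Sequence[NormalizedVariant],
    query: Sequence[NormalizedVariant],
    strata: Mapping[str, Iterable[Interval]],
) -> dict[str, dict[str, BenchmarkResult]]:
    """Per-stratum comparison; a variant may fall in several strata."""
    return {
        label: compare_small_variants(truth, query, intervals, stratum=label)
        for label, intervals in strata.items()
    }


def results_table(results: Iterable[BenchmarkResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


# ---------------------------------------------------------------------------
# Structural-variant matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SvMatchResult:
    tp_pairs: tuple[tuple[NormalizedVariant, NormalizedVariant], ...]
    fp: tuple[NormalizedVariant, ...]
    fn: tuple[NormalizedVariant, ...]
    params: SvMatchParams

    @property
    def metrics(self) -> BenchmarkResult:
        return sv_metrics(len(self.tp_pairs), len(self.fp), len(self.fn))


def sv_metrics(tp: int, fp: int, fn: int) -> BenchmarkResult:
    return BenchmarkResult(SV, "all", tp, fp, fn)


def _admissible(t: NormalizedVariant, q: NormalizedVariant, p: SvMatchParams) -> bool:
    if t.contig != q.contig:
        return False
    if abs(t.pos - q.pos) > p.max_breakpoint_distance:
        return False
    lo, hi = sorted((t.sv_length, q.sv_length))
    if hi == 0 or lo / hi < p.min_size_similarity:
        return False
    if p.type_match_required and t.svtype != q.svtype:
        return False
    return True


def match_svs(
    truth_svs: Sequence[NormalizedVariant],
    query_svs: Sequence[NormalizedVariant],
    params: SvMatchParams = SvMatchParams(),
) -> SvMatchResult:
    """Greedy one-to-one SV matching by ascending breakpoint distance.

    Candidate pairs must satisfy the admissibility criteria in ``params``;
    ties are broken by truth position, then query position, for
    determinism. Variants below ``sv_min_size`` are filtered out first.
    """
    truth = [v for v in truth_svs if v.sv_length >= params.sv_min_size]
    query = [v for v in query_svs if v.sv_length >= params.sv_min_size]
    candidates = sorted(
        (
            (abs(t.pos - q.pos), t.pos, q.pos, ti, qi)
            for ti, t in enumerate(truth)
            for qi, q in enumerate(query)
            if _admissible(t, q, params)
        ),
    )
    matched_t: set[int] = set()
    matched_q: set[int] = set()
    pairs: list[tuple[NormalizedVariant, NormalizedVariant]] = []
    for _, _, _, ti, qi in candidates:
        if ti in matched_t or qi in matched_q:
            continue
        matched_t.add(ti)
        matched_q.add(qi)
        pairs.append((truth[ti], query[qi]))
    fn = tuple(v for i, v in enumerate(truth) if i not in matched_t)
    fp = tuple(v for i, v in enumerate(query) if i not in matched_q)
    return SvMatchResult(tuple(pairs), fp, fn, params)
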