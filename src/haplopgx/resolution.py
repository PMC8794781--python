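"""Per-feature phasing resolution and genomic-complexity annotation.

A *feature* is any annotated locus (protein-coding gene, pharmacogene,
pseudogene, intergenic stretch). For each feature two fractions are
computed:

* **phased fraction** — bases of the feature covered by the union of
  haploblock intervals, divided by feature length. Features are then
  classified as fully phased (fraction at or above an upper threshold,
  default 0.90), unphased (at or below a lower threshold, default 0,
  i.e. no haploblock overlap at all) or partially phased.
* **complex fraction** — bases overlapping the union of segmental
  duplication / repeat tracks, divided by feature length. A feature with
  complex fraction 1.0 is "100% complex".

The module also derives simple sequence-context strata (homopolymers,
GC-rich windows, tandem repeats) from a reference sequence so that
benchmarking can be stratified on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import Interval, intersect_size, merge_intervals

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("protein_coding", "pseudogene", "pharmacogene", "intergenic", "other")

FULLY_PHASED = "fully_phased"
PARTIALLY_PHASED = "partially_phased"
UNPHASED = "unphased"


@dataclass(frozen=True)
class Feature:
    """An annotated genomic interval (0-based, half-open)."""

    feature_id: str
    contig: str
    start: int
    end: int
    feature_class: str = "other"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id}: empty interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class Stratum:
    """A labelled interval belonging to a stratification track (SD, repeat, ...)."""

    contig: str
    start: int
    end: int
    name: str = "SD"


@dataclass(frozen=True)
class ResolutionThresholds:
    """Classification cut-offs on the phased fraction.

    ``full`` — minimum fraction for "fully phased" (inclusive).
    ``unphased`` — maximum fraction for "unphased" (inclusive); the
    default 0.0 means only features with no haploblock overlap at all
    are unphased, but a laxer cut-off (e.g. 0.10) is supported.
    """

    full: float = 0.90
    unphased: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.unphased <= 1.0 and 0.0 <= self.full <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.unphased > self.full:
            raise ValueError(
                f"lower threshold {self.unphased} exceeds upper threshold {self.full}"
            )


@dataclass(frozen=True)
class FeatureResolution:
    feature_id: str
    length: int
    phased_bp: int
    phased_fraction: float
    category: str


@dataclass(frozen=True)
class ComplexityAnnotation:
    feature_id: str
    length: int
    complex_bp: int
    complex_fraction: float


def classify_resolution(
    fraction: float, thresholds: ResolutionThresholds = ResolutionThresholds()
) -> str:
    """Map a phased fraction onto {fully, partially, un}phased.

    The classification is exhaustive and mutually exclusive on [0, 1]:
    fully phased wins at the upper boundary.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction >= thresholds.full:
        return FULLY_PHASED
    if fraction <= thresholds.unphased:
        return UNPHASED
    return PARTIALLY_PHASED


def phased_fraction(
    feature: Feature,
    blocks: Iterable,
    thresholds: ResolutionThresholds = ResolutionThresholds(),
) -> FeatureResolution:
    """Fraction of a feature covered by the union of haploblock intervals.

    ``blocks`` is any iterable of objects with ``contig``, ``start`` and
    ``end`` attributes (such as :class:`haplopgx.phasing.Haploblock`).
    """
    merged = merge_intervals(
        (b.start, b.end) for b in blocks if b.contig == feature.contig
    )
    phased_bp = intersect_size(feature.interval, merged)
    fraction = phased_bp / feature.length
    return FeatureResolution(
        feature_id=feature.feature_id,
        length=feature.length,
        phased_bp=phased_bp,
        phased_fraction=fraction,
        category=classify_resolution(fraction, thresholds),
    )


def complexity_fraction(feature: Feature, strata: Iterable[Stratum]) -> ComplexityAnnotation:
    """Fraction of a feature overlapping the union of SD/repeat intervals.

    Overlapping strata are unioned first, so a base inside two repeat
    intervals is counted once.
    """
    merged = merge_intervals(
        (s.start, s.end) for s in strata if s.contig == feature.contig
    )
    complex_bp = intersect_size(feature.interval, merged)
    return ComplexityAnnotation(
        feature_id=feature.feature_id,
        length=feature.length,
        complex_bp=complex_bp,
        complex_fraction=complex_bp / feature.length,
    )


def summarize_by_class(
    resolutions: Sequence[FeatureResolution],
    features: Sequence[Feature],
    blocks: Iterable,
) -> pd.DataFrame:
    """Per-feature-class summary: counts, category tallies, median block length.

    The median block length within a class considers every haploblock that
    overlaps at least one feature of that class (a block may count toward
    several classes).
    """
    by_id = {f.feature_id: f for f in features}
    unknown = [r.feature_id for r in resolutions if r.feature_id not in by_id]
    if unknown:
        raise KeyError(f"resolutions reference unknown features: {unknown}")
    blocks = list(blocks)
    rows = []
    classes = sorted({f.feature_class for f in features})
    for cls in classes:
        cls_features = [f for f in features if f.feature_class == cls]
        cls_res = [r for r in resolutions if by_id[r.feature_id].feature_class == cls]
        lengths = [
            b.end - b.start
            for b in blocks
            if any(
                b.contig == f.contig and b.start < f.end and f.start < b.end
                for f in cls_features
            )
        ]
        rows.append(
            {
                "feature_class": cls,
                "n_features": len(cls_res),
                "fully_phased": sum(r.category == FULLY_PHASED for r in cls_res),
                "partially_phased": sum(r.category == PARTIALLY_PHASED for r in cls_res),
                "unphased": sum(r.category == UNPHASED for r in cls_res),
                "n_blocks": len(lengths),
                "median_block_length": float(np.median(lengths)) if lengths else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) and table["n_features"].sum() != len(resolutions):
        raise AssertionError("per-class counts do not conserve the input count")
    return table


def resolution_table(
    features: Sequence[Feature],
    resolutions: Sequence[FeatureResolution],
    complexities: Sequence[ComplexityAnnotation] | None = None,
) -> pd.DataFrame:
    """Tidy per-feature table (one row per feature) for TSV export."""
    cx: Mapping[str, ComplexityAnnotation] = (
        {c.feature_id: c for c in complexities} if complexities else {}
    )
    res = {r.feature_id: r for r in resolutions}
    rows = []
    for f in features:
        r = res[f.feature_id]
        rows.append(
            {
                "feature_id": f.feature_id,
                "feature_class": f.feature_class,
                "contig": f.contig,
                "start": f.start,
                "end": f.end,
                "length": f.length,
                "phased_bp": r.phased_bp,
                "phased_fraction": round(r.phased_fraction, 6),
                "category": r.category,
                "complex_fraction": round(cx[f.feature_id].complex_fraction, 6)
                if f.feature_id in cx
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence-context strata
# ---------------------------------------------------------------------------


def derive_sequence_strata(
    reference: str,
    contig: str = "chr1",
    min_homopolymer_run: int = 7,
    gc_window: int = 100,
    gc_threshold: float = 0.8,
    min_tandem_copies: int = 3,
    motif_sizes: Iterable[int] = (2, 3, 4, 5, 6),
) -> list[Stratum]:
    """Derive homopolymer, GC-rich and tandem-repeat strata from a sequence.

    Definitions:

    * homopolymer — a run of one base of length >= ``min_homopolymer_run``;
    * GC-rich — non-overlapping tiling windows of ``gc_window`` bp whose
      G+C fraction is >= ``gc_threshold``; adjacent qualifying windows are
      merged (the trailing partial window is ignored);
    * tandem repeat — >= ``min_tandem_copies`` adjacent copies of a 2-6 bp
      motif; motifs made of a single repeated base are left to the
      homopolymer track.

    Intervals within each track are merged before emission.
    """
    seq = reference.upper()
    n = len(seq)
    strata: list[Stratum] = []

    # homopolymers: run-length encode
    homos: list[Interval] = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_homopolymer_run:
            homos.append((i, j))
        i = j
    strata.extend(Stratum(contig, s, e, "homopolymer") for s, e in merge_intervals(homos))

    # GC-rich tiling windows
    gc: list[Interval] = []
    if n >= gc_window:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        for start in range(0, n - gc_window + 1, gc_window):
            if is_gc[start : start + gc_window].mean() >= gc_threshold:
                gc.append((start, start + gc_window))
    strata.extend(Stratum(contig, s, e, "gc_rich") for s, e in merge_intervals(gc))

    # tandem repeats
    tandems: list[Interval] = []
    for k in motif_sizes:
        i = 0
        while i + k * min_tandem_copies <= n:
            motif = seq[i : i + k]
            if len(set(motif)) == 1:
                i += 1
                continue
            copies = 1
            while seq[i + copies * k : i + (copies + 1) * k] == motif:
                copies += 1
            if copies >= min_tandem_copies:
                tandems.append((i, i + copies * k))
                i += copies * k
            else:
                i += 1
    strata.extend(Stratum(contig, s, e, "tandem_repeat") for s, e in merge_intervals(tandems))
    return strata


def strata_to_bed(strata: Iterable[Stratum], path) -> None:
    with open(path, "w") as fh:
        for s in strata:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.name}\n")


def read_strata_bed(path) -> list[Stratum]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[3] if len(fields) > 3 else "SD"
            out.append(Stratum(fields[0], int(fields[1]), int(fields[2]), name))
    return out
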