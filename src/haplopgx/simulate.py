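"""Synthetic diploid truth sets, long-read fragments and annotation tracks.

The generator emulates the statistical structure of a long-read
(CCS/HiFi-like) whole-genome experiment on a single diploid individual:

* a random reference contig;
* heterozygous and homozygous small variants placed as Poisson processes
  (counts Poisson in the interval length, positions uniform), with
  configurable *homozygous deserts* — intervals forced to contain no
  heterozygous variant, the mechanism that fragments haploblocks;
* an optional hemizygous (X-like) mode in which no heterozygous variant
  exists at all, so nothing can be phased;
* read *fragments* — per-read allele observations at heterozygous sites,
  drawn from one parental haplotype, with log-normal read lengths
  (default median 13,400 bp) at a target fold-coverage (default 28x)
  and an independent per-observation allele-flip error;
* feature and segmental-duplication/repeat tracks with exact, requested
  overlap fractions from 0% to 100%.

Everything is reproducible from ``SyntheticConfig.seed``; the simulator
never consumes global random state.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from ._intervals import Interval, merge_intervals
from .resolution import Feature, Stratum

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DIPLOID = "diploid"
HEMIZYGOUS = "hemizygous"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic experiment.

    Defaults reflect a HiFi-like profile: 13.4 kb median read length at
    28-fold coverage, ~1 het variant per kb (a human-like heterozygosity),
    half that rate of homozygous variants, 10% of small variants being
    indels, and a 0.2% residual per-observation allele error.
    """

    region_length: int = 100_000
    contig: str = "chr1"
    het_rate: float = 1e-3
    hom_rate: float = 5e-4
    homozygous_desert_intervals: tuple[Interval, ...] = ()
    ploidy_mode: str = DIPLOID
    read_length_median: int = 13_400
    read_length_dispersion: float = 0.35
    coverage: float = 28.0
    indel_fraction: float = 0.1
    error_rate: float = 0.002
    sv_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        if self.het_rate < 0 or self.hom_rate < 0 or self.error_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must lie in [0, 1]")
        if self.ploidy_mode not in (DIPLOID, HEMIZYGOUS):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.sv_count < 0:
            raise ValueError("sv_count must be non-negative")
        ivs = sorted(self.homozygous_desert_intervals)
        for s, e in ivs:
            if s < 0 or e > self.region_length or e <= s:
                raise ValueError(
                    f"homozygous desert [{s}, {e}) falls outside the "
                    f"region [0, {self.region_length}) or is empty"
                )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"homozygous deserts [{s1}, {e1}) and [{s2}, {e2}) overlap"
                )


@dataclass(frozen=True)
class TruthVariant:
    """One truth variant. ``pos`` is 0-based; genotype is an unordered allele tuple.

    ``haplotype`` names the parental haplotype (1 or 2) carrying the
    alternate allele of a heterozygous variant; it is None for homozygous
    and hemizygous variants.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vtype: str  # SNV | INDEL | SV
    genotype: tuple[str, ...]
    haplotype: int | None = None

    @property
    def is_het(self) -> bool:
        return len(self.genotype) == 2 and self.genotype[0] != self.genotype[1]

    @property
    def sv_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass(frozen=True)
class SyntheticTruth:
    contig: str
    reference: str
    variants: tuple[TruthVariant, ...]
    config: SyntheticConfig

    def __post_init__(self) -> None:
        positions = [v.pos for v in self.variants]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("variant positions must be strictly increasing")
        if self.config.ploidy_mode == HEMIZYGOUS and any(v.is_het for v in self.variants):
            raise ValueError("hemizygous truth cannot contain heterozygous variants")
        for v in self.variants:
            if v.is_het and v.haplotype not in (1, 2):
                raise ValueError(f"het variant at {v.pos} lacks a haplotype assignment")

    @property
    def het_variants(self) -> list[TruthVariant]:
        return [v for v in self.variants if v.is_het]


@dataclass(frozen=True)
class ReadFragment:
    """A read's allele observations at heterozygous variant sites."""

    read_id: str
    contig: str
    start: int
    end: int
    observations: tuple[tuple[int, str], ...]  # (0-based site position, observed allele)
    source_haplotype: int
    error_flips: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for pos, _ in self.observations:
            if not self.start <= pos < self.end:
                raise ValueError(f"observation at {pos} outside span [{self.start}, {self.end})")
            if pos in seen:
                raise ValueError(f"site {pos} observed twice in {self.read_id}")
            seen.add(pos)


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

_MIN_SMALL_GAP = 8  # bp kept free around small variants so alleles never collide
_MIN_SV_GAP = 700


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    region_length: int,
    forbidden: Sequence[Interval],
    occupied: list[int],
    min_gap: int,
) -> list[int]:
    """Uniform positions avoiding forbidden intervals and a gap around occupied ones."""
    merged = merge_intervals(forbidden)
    out: list[int] = []
    taken = sorted(occupied)
    attempts = 0
    while len(out) < n and attempts < 50 * n + 1000:
        attempts += 1
        p = int(rng.integers(0, region_length))
        if any(s <= p < e for s, e in merged):
            continue
        if any(abs(p - q) < min_gap for q in taken):
            continue
        out.append(p)
        taken.append(p)
    if len(out) < n:
        logger.warning("placed only %d of %d requested variants", len(out), n)
    return out


def simulate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw a reference sequence and a phased diploid truth set.

    Variant counts are Poisson in the configured rates; het positions are
    uniform outside the homozygous deserts; each het variant's alternate
    allele is assigned to haplotype 1 or 2 with equal probability. In
    hemizygous mode no het variant is produced regardless of ``het_rate``.
    """
    rng = np.random.default_rng([config.seed, 0])
    reference = _random_sequence(rng, config.region_length)

    desert_bp = sum(e - s for s, e in config.homozygous_desert_intervals)
    eligible = config.region_length - desert_bp

    hemizygous = config.ploidy_mode == HEMIZYGOUS
    n_het = 0 if hemizygous else int(rng.poisson(config.het_rate * eligible))
    n_hom = int(rng.poisson(config.hom_rate * config.region_length))

    occupied: list[int] = []
    het_pos = _draw_positions(
        rng, n_het, config.region_length, config.homozygous_desert_intervals,
        occupied, _MIN_SMALL_GAP,
    )
    occupied.extend(het_pos)
    hom_pos = _draw_positions(rng, n_hom, config.region_length, (), occupied, _MIN_SMALL_GAP)
    occupied.extend(hom_pos)

    variants: list[TruthVariant] = []

    def small_alleles(pos: int) -> tuple[str, str, str]:
        ref_base = reference[pos]
        if rng.random() < config.indel_fraction and pos + 7 < config.region_length:
            length = int(rng.integers(1, 7))
            if rng.random() < 0.5:  # deletion
                ref = reference[pos : pos + length + 1]
                return ref, ref[0], "INDEL"
            ins = _random_sequence(rng, length)
            return ref_base, ref_base + ins, "INDEL"
        alt = ref_base
        while alt == ref_base:
            alt = "ACGT"[int(rng.integers(0, 4))]
        return ref_base, alt, "SNV"

    for pos in sorted(het_pos):
        ref, alt, vtype = small_alleles(pos)
        variants.append(
            TruthVariant(
                config.contig, pos, ref, alt, vtype,
                genotype=(ref, alt), haplotype=int(rng.integers(1, 3)),
            )
        )
    for pos in sorted(hom_pos):
        ref, alt, vtype = small_alleles(pos)
        gt = (alt,) if hemizygous else (alt, alt)
        variants.append(TruthVariant(config.contig, pos, ref, alt, vtype, genotype=gt))

    sv_pos = _draw_positions(
        rng, config.sv_count, max(config.region_length - 1200, 1),
        config.homozygous_desert_intervals, occupied, _MIN_SV_GAP,
    )
    for pos in sorted(sv_pos):
        length = int(rng.integers(50, 501))
        if rng.random() < 0.5 and pos + length + 1 < config.region_length:
            ref = reference[pos : pos + length + 1]
            alt = ref[0]
        else:
            ref = reference[pos]
            alt = ref + _random_sequence(rng, length)
        if hemizygous:
            gt: tuple[str, ...] = (alt,)
            hap = None
        else:
            het = bool(rng.random() < 0.7)
            gt = (ref, alt) if het else (alt, alt)
            hap = int(rng.integers(1, 3)) if het else None
        variants.append(TruthVariant(config.contig, pos, ref, alt, "SV", genotype=gt, haplotype=hap))

    variants.sort(key=lambda v: v.pos)
    return SyntheticTruth(config.contig, reference, tuple(variants), config)


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------


def simulate_fragments(truth: SyntheticTruth, config: SyntheticConfig) -> list[ReadFragment]:
    """Draw per-read allele observations at the truth's heterozygous sites.

    Read lengths are log-normal with the configured median and dispersion
    (sigma of log length); the read count targets ``coverage`` fold so the
    summed read length over the region length matches the configured
    coverage. Each read originates from one haplotype and observes, at
    each het site it spans, that haplotype's allele — flipped to the other
    allele independently with probability ``error_rate``.
    """
    rng = np.random.default_rng([config.seed, 1])
    L = config.region_length
    mu = math.log(config.read_length_median)
    sigma = config.read_length_dispersion
    mean_len = math.exp(mu + sigma**2 / 2)
    n_reads = int(round(config.coverage * L / mean_len))
    if n_reads == 0:
        return []

    lengths = np.maximum(np.exp(rng.normal(mu, sigma, size=n_reads)).astype(int), 100)
    lengths = np.minimum(lengths, L)
    starts = np.array([int(rng.integers(0, L - l + 1)) for l in lengths])
    haps = (
        np.ones(n_reads, dtype=int)
        if config.ploidy_mode == HEMIZYGOUS
        else rng.integers(1, 3, size=n_reads)
    )

    het = truth.het_variants
    het_pos = np.array([v.pos for v in het], dtype=int)

    fragments: list[ReadFragment] = []
    for i in range(n_reads):
        start, end, hap = int(starts[i]), int(starts[i] + lengths[i]), int(haps[i])
        lo, hi = np.searchsorted(het_pos, [start, end])
        obs: list[tuple[int, str]] = []
        flips = 0
        for v in het[lo:hi]:
            allele = v.alt if v.haplotype == hap else v.ref
            if config.error_rate > 0 and rng.random() < config.error_rate:
                allele = v.ref if allele == v.alt else v.alt
                flips += 1
            obs.append((v.pos, allele))
        fragments.append(
            ReadFragment(
                read_id=f"r{i:06d}", contig=truth.contig, start=start, end=end,
                observations=tuple(obs), source_haplotype=hap, error_flips=flips,
            )
        )
    fragments.sort(key=lambda f: (f.start, f.read_id))
    return fragments


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------


def generate_tracks(
    config: SyntheticConfig,
    n_features: int,
    complexity_profile: Sequence[float],
    feature_length: int = 10_000,
    feature_class: str = "pharmacogene",
) -> tuple[list[Feature], list[Stratum]]:
    """Evenly spaced features plus SD strata overlapping each by a target fraction.

    ``complexity_profile`` is cycled across features; each requested
    fraction f yields a stratum overlapping exactly ``round(f * length)``
    bases of its feature (f = 1 places the feature strictly inside a
    stratum; f = 0 places no stratum).
    """
    if n_features == 0:
        return [], []
    if any(not 0.0 <= f <= 1.0 for f in complexity_profile):
        raise ValueError("overlap fractions must lie in [0, 1]")
    if not complexity_profile:
        raise ValueError("complexity_profile must not be empty")

    L = config.region_length
    margin = min(max(feature_length // 2, L // 20), max(L // 4, 1))
    usable = L - 2 * margin
    if usable < n_features * feature_length:
        raise ValueError(
            f"{n_features} features of {feature_length} bp do not fit in "
            f"region of {L} bp (usable {usable} bp)"
        )
    slot = usable // n_features
    features: list[Feature] = []
    strata: list[Stratum] = []
    for i in range(n_features):
        start = margin + i * slot + (slot - feature_length) // 2
        end = start + feature_length
        features.append(Feature(f"gene{i:03d}", config.contig, start, end, feature_class))
        f = complexity_profile[i % len(complexity_profile)]
        if f == 0.0:
            continue
        if f == 1.0:
            pad = 100
            strata.append(
                Stratum(config.contig, max(0, start - pad), min(L, end + pad), "SD")
            )
        else:
            ov = int(round(f * feature_length))
            strata.append(Stratum(config.contig, start, start + ov, "SD"))
    return features, strata


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------

_TRUTH_PS = 1  # the simulated truth is globally phased: one phase set


def write_reference_fasta(contig: str, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


def read_reference_fasta(path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_truth_vcf(truth: SyntheticTruth, path) -> None:
    """Write the truth as a phased VCF 4.2 (GT with '|', one PS per contig)."""
    hemizygous = truth.config.ploidy_mode == HEMIZYGOUS
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={truth.contig},length={truth.config.region_length}>\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for v in truth.variants:
            info = f"VT={v.vtype}"
            if v.vtype == "SV":
                svlen = len(v.alt) - len(v.ref)
                info += f";SVLEN={svlen}"
            if hemizygous:
                gt, fmt = "1", "GT"
                sample = gt
            else:
                if v.is_het:
                    gt = "1|0" if v.haplotype == 1 else "0|1"
                else:
                    gt = "1|1"
                fmt = "GT:PS"
                sample = f"{gt}:{_TRUTH_PS}"
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t{fmt}\t{sample}\n"
            )


def read_truth_vcf(path) -> list[TruthVariant]:
    """Read a (possibly phased) single-sample VCF back into truth variants."""
    out: list[TruthVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0]
            gt = sample["GT"]
            alleles = rec.alleles
            vtype = rec.info.get("VT")
            if vtype is None:
                ref, alt = rec.ref, rec.alts[0]
                diff = abs(len(alt) - len(ref))
                vtype = "SNV" if diff == 0 and len(ref) == 1 else ("SV" if diff >= 50 else "INDEL")
            alt = rec.alts[0]
            if len(gt) == 1:  # hemizygous
                out.append(
                    TruthVariant(rec.contig, rec.pos - 1, rec.ref, alt, vtype, (alt,))
                )
                continue
            a1, a2 = gt
            genotype = tuple(alleles[i] for i in (a1, a2))
            hap = None
            if a1 != a2:
                genotype = (rec.ref, alt)
                hap = 1 if a1 == 1 else 2
                if not sample.phased:
                    hap = None
            out.append(
                TruthVariant(rec.contig, rec.pos - 1, rec.ref, alt, vtype, genotype, hap)
            )
    return out


def write_fragments_tsv(fragments: Iterable[ReadFragment], path) -> None:
    """Fragment TSV: read_id, contig, start, end, haplotype, flips, obs.

    ``obs`` is a semicolon-separated list of ``pos:allele`` pairs with
    0-based positions; the column is empty for reads observing no site.
    """
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstart\tend\thaplotype\tflips\tobs\n")
        for f in fragments:
            obs = ";".join(f"{p}:{a}" for p, a in f.observations)
            fh.write(
                f"{f.read_id}\t{f.contig}\t{f.start}\t{f.end}\t"
                f"{f.source_haplotype}\t{f.error_flips}\t{obs}\n"
            )


def read_fragments_tsv(path) -> list[ReadFragment]:
    out: list[ReadFragment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["read_id", "contig", "start", "end"]:
            raise ValueError(f"unexpected fragment TSV header in {path}")
        for line in fh:
            rid, contig, start, end, hap, flips, obs = line.rstrip("\n").split("\t")
            observations = tuple(
                (int(p), a)
                for p, a in (pair.split(":") for pair in obs.split(";") if pair)
            )
            out.append(
                ReadFragment(rid, contig, int(start), int(end), observations, int(hap), int(flips))
            )
    return out


def write_features_bed(features: Iterable[Feature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t+\t{f.feature_class}\n")


def read_features_bed(path) -> list[Feature]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            cls = fields[6] if len(fields) > 6 else "other"
            name = fields[3] if len(fields) > 3 else f"{fields[0]}:{fields[1]}"
            out.append(Feature(name, fields[0], int(fields[1]), int(fields[2]), cls))
    return out


def write_features_gtf(features: Iterable[Feature], path) -> None:
    """GTF mirror of the feature BED (1-based, inclusive coordinates)."""
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.feature_id}"; gene_type "{f.feature_class}";'
            fh.write(
                f"{f.contig}\thaplopgx\tgene\t{f.start + 1}\t{f.end}\t.\t+\t.\t{attrs}\n"
            )


def read_features_gtf(path) -> list[Feature]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in fields[8].rstrip(";").split(";")
                if kv.strip()
            )
            out.append(
                Feature(
                    attrs.get("gene_id", f"{fields[0]}:{fields[3]}"),
                    fields[0],
                    int(fields[3]) - 1,
                    int(fields[4]),
                    attrs.get("gene_type", "other"),
                )
            )
    return out


def write_fixture_bundle(
    truth: SyntheticTruth,
    fragments: Sequence[ReadFragment],
    features: Sequence[Feature],
    strata: Sequence[Stratum],
    output_dir,
) -> dict[str, str]:
    """Write the full synthetic bundle and return a name -> path manifest."""
    from .resolution import strata_to_bed

    os.makedirs(output_dir, exist_ok=True)
    if not os.access(output_dir, os.W_OK):
        raise OSError(f"output directory not writable: {output_dir}")
    paths = {
        "reference": os.path.join(output_dir, "reference.fasta"),
        "truth_vcf": os.path.join(output_dir, "truth.vcf"),
        "fragments": os.path.join(output_dir, "fragments.tsv"),
        "features_bed": os.path.join(output_dir, "features.bed"),
        "features_gtf": os.path.join(output_dir, "features.gtf"),
        "strata_bed": os.path.join(output_dir, "strata.bed"),
    }
    write_reference_fasta(truth.contig, truth.reference, paths["reference"])
    write_truth_vcf(truth, paths["truth_vcf"])
    write_fragments_tsv(fragments, paths["fragments"])
    write_features_bed(features, paths["features_bed"])
    write_features_gtf(features, paths["features_gtf"])
    strata_to_bed(strata, paths["strata_bed"])
    manifest_path = os.path.join(output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(paths, fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
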