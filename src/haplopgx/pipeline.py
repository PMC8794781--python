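"""Pipeline orchestration: simulate -> phase -> resolve -> benchmark -> pgx-call.

A :class:`PipelineConfig` (constructible from a YAML file) names the
stages to run, the synthetic-data parameters, the thresholds, and any
externally supplied inputs. :func:`run_pipeline` executes the stages in
order, writes every artifact under ``out_dir`` and returns a
:class:`RunReport` with per-stage record counts, warnings, an output
manifest and a stable hash of the configuration. Identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
import yaml

from . import __version__
from . import benchmark as bm
from . import pgx, phasing, resolution, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phase", "resolve", "benchmark", "pgx-call")


class PipelineDependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "haplopgx_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # synthetic-data parameters (used by the simulate stage)
    region_length: int = 100_000
    contig: str = "chr1"
    het_rate: float = 1e-3
    hom_rate: float = 5e-4
    homozygous_desert_intervals: tuple[tuple[int, int], ...] = ()
    ploidy_mode: str = simulate.DIPLOID
    read_length_median: int = 13_400
    read_length_dispersion: float = 0.35
    coverage: float = 28.0
    indel_fraction: float = 0.1
    error_rate: float = 0.002
    sv_count: int = 0
    n_features: int = 4
    complexity_profile: tuple[float, ...] = (0.0, 0.5, 1.0)
    feature_length: int = 10_000
    # thresholds
    fully_phased_threshold: float = 0.90
    unphased_threshold: float = 0.0
    sv_max_breakpoint_distance: int = 500
    sv_min_size_similarity: float = 0.7
    # external inputs (override the simulate stage's outputs)
    truth_vcf: str | None = None
    query_vcf: str | None = None
    fragments_tsv: str | None = None
    features_bed: str | None = None
    strata_bed: str | None = None
    reference_fasta: str | None = None
    allele_definitions: str | None = None
    phenotype_translation: str | None = None
    guidelines: str | None = None

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.homozygous_desert_intervals = tuple(
            tuple(iv) for iv in self.homozygous_desert_intervals
        )
        self.complexity_profile = tuple(self.complexity_profile)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown configuration keys: {sorted(extra)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def synthetic_config(self) -> simulate.SyntheticConfig:
        return simulate.SyntheticConfig(
            region_length=self.region_length,
            contig=self.contig,
            het_rate=self.het_rate,
            hom_rate=self.hom_rate,
            homozygous_desert_intervals=self.homozygous_desert_intervals,
            ploidy_mode=self.ploidy_mode,
            read_length_median=self.read_length_median,
            read_length_dispersion=self.read_length_dispersion,
            coverage=self.coverage,
            indel_fraction=self.indel_fraction,
            error_rate=self.error_rate,
            sv_count=self.sv_count,
            seed=self.seed,
        )


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str
    path: str | None = None
    line: int | None = None


@dataclass
class RunReport:
    version: str
    config_hash: str
    parameters: dict
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def validate_inputs(config: PipelineConfig) -> list[Finding]:
    """Parse-check the configured input files and audit contig consistency.

    Findings are returned, never raised: errors are defects that would
    break a run (unreadable file, inverted BED interval), warnings are
    suspicious but tolerable (features on a contig the VCF never mentions).
    """
    findings: list[Finding] = []
    vcf_contigs: set[str] = set()

    def check_bed(path: str, label: str) -> set[str]:
        contigs: set[str] = set()
        try:
            with open(path) as fh:
                for ln, line in enumerate(fh, 1):
                    if not line.strip() or line.startswith(("#", "track", "browser")):
                        continue
                    fields = line.rstrip("\n").split("\t")
                    if len(fields) < 3:
                        findings.append(Finding("error", f"{label}: fewer than 3 columns", path, ln))
                        continue
                    try:
                        start, end = int(fields[1]), int(fields[2])
                    except ValueError:
                        findings.append(Finding("error", f"{label}: non-integer coordinates", path, ln))
                        continue
                    if end < start:
                        findings.append(
                            Finding("error", f"{label}: interval end {end} < start {start}", path, ln)
                        )
                    if start < 0:
                        findings.append(Finding("error", f"{label}: negative start", path, ln))
                    contigs.add(fields[0])
        except OSError as exc:
            findings.append(Finding("error", f"{label}: cannot read ({exc})", path))
        return contigs

    for attr, label in (("truth_vcf", "truth VCF"), ("query_vcf", "query VCF")):
        path = getattr(config, attr)
        if path is None:
            continue
        try:
            import pysam

            with pysam.VariantFile(path) as vcf:
                for rec in vcf:
                    vcf_contigs.add(rec.contig)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            findings.append(Finding("error", f"{label}: unparseable ({exc})", path))

    bed_contigs: set[str] = set()
    for attr, label in (("features_bed", "feature BED"), ("strata_bed", "strata BED")):
        path = getattr(config, attr)
        if path is not None:
            bed_contigs |= check_bed(path, label)

    if vcf_contigs and bed_contigs - vcf_contigs:
        findings.append(
            Finding(
                "warning",
                f"features on contigs absent from the VCF: {sorted(bed_contigs - vcf_contigs)}",
            )
        )
    return findings


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise PipelineDependencyError(message)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; see module docstring.

    Stage dependencies are validated before anything is written: running
    ``resolve`` without blocks (no ``phase`` stage and no phased input) or
    ``phase`` without fragments fails up front.
    """
    stages = config.stages
    _require(
        "simulate" in stages
        or config.truth_vcf is not None
        or not ({"phase", "resolve", "benchmark", "pgx-call"} & set(stages)),
        "downstream stages need either the simulate stage or a truth_vcf input",
    )
    _require(
        "resolve" not in stages or "phase" in stages or config.truth_vcf is not None,
        "resolve requires haploblocks: enable the phase stage or supply a phased VCF",
    )
    _require(
        "pgx-call" not in stages or "phase" in stages or config.truth_vcf is not None,
        "pgx-call requires phased variants",
    )

    os.makedirs(config.out_dir, exist_ok=True)
    report = RunReport(
        version=__version__, config_hash=config.config_hash(), parameters=config.to_dict()
    )
    manifest = report.manifest

    truth = fragments = features = strata = None
    blocks: list[phasing.Haploblock] = []
    het_sites: list[phasing.HetSite] = []
    reference: dict[str, str] | None = None
    resolutions: list[resolution.FeatureResolution] = []

    syn = config.synthetic_config()

    if "simulate" in stages:
        truth = simulate.simulate_truth(syn)
        fragments = simulate.simulate_fragments(truth, syn)
        features, strata = simulate.generate_tracks(
            syn, config.n_features, config.complexity_profile, config.feature_length
        )
        bundle = simulate.write_fixture_bundle(
            truth, fragments, features, strata, config.out_dir
        )
        manifest.update(bundle)
        report.counts["simulate"] = {
            "variants": len(truth.variants),
            "het_variants": len(truth.het_variants),
            "fragments": len(fragments),
            "features": len(features),
            "strata": len(strata),
        }
        reference = {truth.contig: truth.reference}

    # resolve external inputs where the simulate stage did not provide them
    truth_vcf = manifest.get("truth_vcf", config.truth_vcf)
    if reference is None and config.reference_fasta:
        reference = simulate.read_reference_fasta(config.reference_fasta)
    if features is None and config.features_bed:
        features = simulate.read_features_bed(config.features_bed)
    if strata is None and config.strata_bed:
        strata = resolution.read_strata_bed(config.strata_bed)

    if "phase" in stages:
        if fragments is None and config.fragments_tsv:
            fragments = simulate.read_fragments_tsv(config.fragments_tsv)
        variants = (
            list(truth.variants) if truth is not None else simulate.read_truth_vcf(truth_vcf)
        )
        het_sites = phasing.select_het_sites(variants)
        if fragments is not None:
            model = phasing.HaplotypePhaser(
                fragments, het_sites, region_length=config.region_length
            )
            result = model.fit()
            blocks = result.blocks
            report.counts["phase"] = {
                "het_sites": len(het_sites),
                "blocks": result.n_blocks,
                "phased_sites": result.phased_sites,
                "conflict_cost": result.conflict_cost,
            }
        else:
            het_sites, _assign, blocks = phasing.import_phased_vcf(truth_vcf)
            report.counts["phase"] = {"het_sites": len(het_sites), "blocks": len(blocks)}
        bed = os.path.join(config.out_dir, "haploblocks.bed")
        gtf = os.path.join(config.out_dir, "haploblocks.gtf")
        phasing.blocks_to_bed(blocks, bed)
        phasing.blocks_to_gtf(blocks, gtf)
        phased_vcf = os.path.join(config.out_dir, "phased.vcf")
        phasing.write_phased_vcf(
            variants, blocks, phased_vcf,
            contig_lengths={config.contig: config.region_length} if truth is not None else None,
        )
        manifest.update(
            {"haploblocks_bed": bed, "haploblocks_gtf": gtf, "phased_vcf": phased_vcf}
        )

    if "resolve" in stages:
        _require(features is not None, "resolve requires features (simulate stage or features_bed)")
        thresholds = resolution.ResolutionThresholds(
            full=config.fully_phased_threshold, unphased=config.unphased_threshold
        )
        resolutions = [resolution.phased_fraction(f, blocks, thresholds) for f in features]
        complexities = [
            resolution.complexity_fraction(f, strata or []) for f in features
        ]
        table = resolution.resolution_table(features, resolutions, complexities)
        path = os.path.join(config.out_dir, "resolution.tsv")
        table.to_csv(path, sep="\t", index=False)
        manifest["resolution_tsv"] = path
        summary = resolution.summarize_by_class(resolutions, list(features), blocks)
        spath = os.path.join(config.out_dir, "resolution_by_class.tsv")
        summary.to_csv(spath, sep="\t", index=False)
        manifest["resolution_by_class_tsv"] = spath
        report.counts["resolve"] = {
            "features": len(resolutions),
            "fully_phased": sum(r.category == resolution.FULLY_PHASED for r in resolutions),
            "partially_phased": sum(
                r.category == resolution.PARTIALLY_PHASED for r in resolutions
            ),
            "unphased": sum(r.category == resolution.UNPHASED for r in resolutions),
        }

    if "benchmark" in stages:
        _require(reference is not None, "benchmark requires a reference sequence")
        truth_norm = bm.read_vcf_variants(truth_vcf, reference)
        query_path = config.query_vcf or manifest.get("phased_vcf", truth_vcf)
        query_norm = bm.read_vcf_variants(query_path, reference)
        small = bm.compare_small_variants(truth_norm, query_norm)
        rows = [r.to_row() for r in small.values()]
        params = bm.SvMatchParams(
            max_breakpoint_distance=config.sv_max_breakpoint_distance,
            min_size_similarity=config.sv_min_size_similarity,
        )
        truth_svs = [v for v in truth_norm if v.vtype == bm.SV]
        query_svs = [v for v in query_norm if v.vtype == bm.SV]
        if truth_svs or query_svs:
            rows.append(bm.match_svs(truth_svs, query_svs, params).metrics.to_row())
        import pandas as pd

        path = os.path.join(config.out_dir, "benchmark.tsv")
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["benchmark_tsv"] = path
        report.counts["benchmark"] = {
            row["variant_type"]: {k: row[k] for k in ("tp", "fp", "fn")} for row in rows
        }

    if "pgx-call" in stages:
        definitions = (
            pgx.load_allele_definitions(config.allele_definitions)
            if config.allele_definitions
            else pgx.load_demo_definitions()
        )
        translation = (
            pgx.load_translation_table(config.phenotype_translation)
            if config.phenotype_translation
            else pgx.load_demo_translation()
        )
        guidelines = (
            pgx.load_guidelines(config.guidelines)
            if config.guidelines
            else pgx.load_demo_guidelines()
        )
        variants = (
            list(truth.variants) if truth is not None else simulate.read_truth_vcf(truth_vcf)
        )
        diplotypes = [
            pgx.assign_diplotype(gene, variants, blocks, definitions)
            for gene in sorted(definitions)
        ]
        phenotypes = [pgx.translate_phenotype(d, translation) for d in diplotypes]
        calls_path = os.path.join(config.out_dir, "pgx_calls.json")
        pgx.calls_to_json(diplotypes, phenotypes, calls_path)
        manifest["pgx_calls_json"] = calls_path
        res_by_gene = {
            f.feature_id: r for f, r in zip(features or [], resolutions)
        }
        coverage = pgx.guideline_coverage(res_by_gene, guidelines)
        cov_path = os.path.join(config.out_dir, "guideline_coverage.json")
        with open(cov_path, "w") as fh:
            json.dump(coverage, fh, indent=2, sort_keys=True)
        manifest["guideline_coverage_json"] = cov_path
        report.counts["pgx-call"] = {
            "diplotypes": len(diplotypes),
            "actionable_phenotypes": sum(p.actionable for p in phenotypes),
        }

    report_path = os.path.join(config.out_dir, "report.json")
    report.write(report_path)
    manifest["report"] = report_path
    return report
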