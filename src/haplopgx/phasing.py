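"""Read-backed haploblock phasing.

Heterozygous sites are linked whenever a read fragment observes both;
each linkage edge counts *cis* support (fragments seeing ref-ref or
alt-alt) against *trans* support (ref-alt / alt-ref). A haploblock is one
maximal stretch of consistently phased sequence: a connected component of
the informative linkage graph, additionally split wherever read coverage
drops out between consecutive sites. A block ends where

* no read carries a variant linking onward,
* cis and trans evidence tie, so the two alleles are indistinguishable, or
* the region lacks coverage.

Phasing within a component minimises disagreement with the pairwise
evidence: small components are solved exactly (enumeration over
bipartitions, vectorised), large ones by orienting a maximum spanning
tree weighted by |cis - trans|. Flipping the haplotype labels of a whole
block is an accepted symmetry — all downstream quantities are invariant
under it.

The central objects follow the model/results idiom:
:class:`HaplotypePhaser` holds the data (fragments + het sites), and
``fit()`` returns a :class:`PhasingResult` carrying blocks, per-site
assignments, the conflict (MEC-style) score and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

EXACT_COMPONENT_LIMIT = 16  # exhaustive bipartition search up to this many sites


@dataclass(frozen=True, order=True)
class HetSite:
    """A heterozygous small-variant site (0-based position)."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"site {self.contig}:{self.position} has ref == alt")


class LinkageGraph:
    """Het sites as nodes; edges carry cis/trans fragment support."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_site(self, site: HetSite) -> None:
        self.graph.add_node(site)

    def add_observation_pair(self, a: HetSite, b: HetSite, allele_a: int, allele_b: int) -> None:
        """Record one fragment's joint observation (allele codes 0=ref, 1=alt)."""
        if not self.graph.has_edge(a, b):
            self.graph.add_edge(a, b, cis=0, trans=0)
        key = "cis" if allele_a == allele_b else "trans"
        self.graph.edges[a, b][key] += 1

    @property
    def sites(self) -> list[HetSite]:
        return sorted(self.graph.nodes)

    def edge_support(self, a: HetSite, b: HetSite) -> tuple[int, int]:
        d = self.graph.edges[a, b]
        return d["cis"], d["trans"]

    def informative_subgraph(self) -> nx.Graph:
        """Drop tie edges (cis == trans): they carry no phase information.

        This realises the "no longer a difference between the two alleles"
        stopping condition — a block is split rather than phased through a
        tie.
        """
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for a, b, d in self.graph.edges(data=True):
            if d["cis"] != d["trans"]:
                g.add_edge(a, b, **d)
        return g


@dataclass(frozen=True)
class Haploblock:
    """One maximal phased stretch; ``assignment`` maps each site to the
    haplotype (1 or 2) carrying its alternate allele."""

    contig: str
    start: int  # position of the first site (0-based)
    end: int  # position after the last site (half-open)
    sites: tuple[HetSite, ...]
    assignment: Mapping[HetSite, int]
    block_id: str

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("a haploblock needs at least two het sites")
        if self.start != self.sites[0].position or self.end != self.sites[-1].position + 1:
            raise ValueError("block extent must span first to last site")
        if set(self.sites) != set(self.assignment):
            raise ValueError("assignment must cover exactly the block's sites")
        if not set(self.assignment.values()) <= {1, 2}:
            raise ValueError("haplotype labels must be 1 or 2")

    @property
    def length(self) -> int:
        return self.end - self.start

    def flipped(self) -> "Haploblock":
        """The same block with haplotype labels swapped (a phase symmetry)."""
        return Haploblock(
            self.contig, self.start, self.end, self.sites,
            {s: 3 - h for s, h in self.assignment.items()}, self.block_id,
        )


class CoverageProfile:
    """Per-base read depth over one contig, for coverage-gap block splitting."""

    def __init__(self, contig: str, depth: np.ndarray):
        if (depth < 0).any():
            raise ValueError("depth must be non-negative")
        self.contig = contig
        self.depth = depth

    @classmethod
    def from_fragments(cls, fragments: Iterable, region_length: int, contig: str | None = None):
        delta = np.zeros(region_length + 1, dtype=np.int32)
        for f in fragments:
            if contig is None:
                contig = f.contig
            if f.contig != contig:
                continue
            delta[max(f.start, 0)] += 1
            delta[min(f.end, region_length)] -= 1
        return cls(contig or "chr1", np.cumsum(delta[:-1]))

    def min_depth(self, start: int, end: int) -> int:
        start = max(start, 0)
        end = min(end, len(self.depth))
        if end <= start:
            return 0
        return int(self.depth[start:end].min())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def select_het_sites(variants: Iterable) -> list[HetSite]:
    """The phaseable sites: heterozygous small variants, sorted by position.

    ``variants`` is any iterable of objects with ``contig``, ``pos``,
    ``ref``, ``alt``, ``genotype`` and ``vtype`` attributes (e.g.
    :class:`haplopgx.simulate.TruthVariant`). Variants without a genotype
    are skipped with a warning; structural variants are not phaseable here.
    """
    sites = []
    for v in variants:
        gt = getattr(v, "genotype", None)
        if gt is None:
            logger.warning("variant %s:%s has no genotype; skipped", v.contig, v.pos)
            continue
        if getattr(v, "vtype", "SNV") == "SV":
            continue
        if len(gt) == 2 and gt[0] != gt[1]:
            sites.append(HetSite(v.contig, v.pos, v.ref, v.alt))
    return sorted(sites)


def build_linkage_graph(fragments: Iterable, het_sites: Sequence[HetSite]) -> LinkageGraph:
    """Connect every pair of het sites co-observed by a fragment.

    Observations at unknown sites, or with alleles matching neither ref
    nor alt, are ignored (logged once per fragment).
    """
    by_key = {(s.contig, s.position): s for s in het_sites}
    graph = LinkageGraph()
    for s in het_sites:
        graph.add_site(s)
    for frag in fragments:
        coded: list[tuple[HetSite, int]] = []
        for pos, allele in frag.observations:
            site = by_key.get((frag.contig, pos))
            if site is None:
                logger.debug("fragment %s observes unknown site %s:%d", frag.read_id, frag.contig, pos)
                continue
            if allele == site.ref_allele:
                coded.append((site, 0))
            elif allele == site.alt_allele:
                coded.append((site, 1))
            else:
                logger.debug(
                    "fragment %s observes foreign allele %r at %s:%d",
                    frag.read_id, allele, frag.contig, pos,
                )
        coded.sort(key=lambda t: t[0].position)
        for (sa, aa), (sb, ab) in combinations(coded, 2):
            graph.add_observation_pair(sa, sb, aa, ab)
    return graph


def _phase_exact(sub: nx.Graph, sites: list[HetSite]) -> dict[HetSite, int]:
    """Exhaustive minimum-conflict bipartition (first site pinned to hap 1)."""
    k = len(sites)
    idx = {s: i for i, s in enumerate(sites)}
    edges = np.array([[idx[a], idx[b]] for a, b in sub.edges], dtype=int)
    cis = np.array([sub.edges[a, b]["cis"] for a, b in sub.edges], dtype=np.int64)
    trans = np.array([sub.edges[a, b]["trans"] for a, b in sub.edges], dtype=np.int64)
    n_assign = 1 << (k - 1)
    codes = np.arange(n_assign, dtype=np.uint32)
    # bit matrix: site 0 fixed at 0, remaining k-1 sites free
    bits = np.zeros((n_assign, k), dtype=np.uint8)
    for j in range(1, k):
        bits[:, j] = (codes >> (j - 1)) & 1
    same = bits[:, edges[:, 0]] == bits[:, edges[:, 1]]
    # a cis-supporting fragment conflicts when the sites sit on different
    # haplotypes, and vice versa
    cost = np.where(same, trans, cis).sum(axis=1)
    best = bits[int(cost.argmin())]
    return {s: 1 + int(best[idx[s]]) for s in sites}


def _phase_spanning_tree(sub: nx.Graph, sites: list[HetSite]) -> dict[HetSite, int]:
    """Orient a maximum spanning tree on |cis - trans| and propagate."""
    weighted = nx.Graph()
    weighted.add_nodes_from(sub.nodes)
    for a, b, d in sub.edges(data=True):
        weighted.add_edge(a, b, weight=abs(d["cis"] - d["trans"]), cis=d["cis"], trans=d["trans"])
    tree = nx.maximum_spanning_tree(weighted, weight="weight")
    assignment: dict[HetSite, int] = {}
    root = sites[0]
    assignment[root] = 1
    for parent, child in nx.bfs_edges(tree, root):
        d = tree.edges[parent, child]
        same = d["cis"] > d["trans"]
        assignment[child] = assignment[parent] if same else 3 - assignment[parent]
    return assignment


def phase_components(
    graph: LinkageGraph, exact_limit: int = EXACT_COMPONENT_LIMIT
) -> dict[HetSite, int]:
    """Per-site haplotype assignment within each informative component.

    Components with up to ``exact_limit`` sites are solved exactly by
    enumerating bipartitions and minimising the summed support for the
    violated orientation of every edge; larger components fall back to the
    maximum-spanning-tree heuristic. Singleton components (including sites
    isolated by tie edges) receive no assignment. The global flip of each
    component is an accepted symmetry; hap 1 is pinned to the component's
    first site.
    """
    informative = graph.informative_subgraph()
    assignment: dict[HetSite, int] = {}
    for comp in nx.connected_components(informative):
        sites = sorted(comp)
        if len(sites) < 2:
            continue
        sub = informative.subgraph(sites)
        if len(sites) <= exact_limit:
            assignment.update(_phase_exact(sub, sites))
        else:
            assignment.update(_phase_spanning_tree(sub, sites))
    return assignment


def conflict_cost(graph: LinkageGraph, assignment: Mapping[HetSite, int]) -> int:
    """Summed support for the orientation each edge was phased against."""
    cost = 0
    for a, b, d in graph.informative_subgraph().edges(data=True):
        if a not in assignment or b not in assignment:
            continue
        same = assignment[a] == assignment[b]
        cost += d["trans"] if same else d["cis"]
    return cost


def construct_haploblocks(
    graph: LinkageGraph,
    assignment: Mapping[HetSite, int],
    coverage: CoverageProfile | None = None,
    min_depth: int = 1,
) -> list[Haploblock]:
    """One block per informative connected component with >= 2 sites.

    The block interval runs from the first to the last site. If a coverage
    profile is given, a component is additionally split wherever the depth
    between two consecutive sites falls below ``min_depth`` (default:
    any zero-coverage base breaks the block).
    """
    informative = graph.informative_subgraph()
    blocks: list[Haploblock] = []
    for comp in nx.connected_components(informative):
        sites = sorted(comp)
        if len(sites) < 2:
            continue
        runs: list[list[HetSite]] = [[sites[0]]]
        for prev, cur in zip(sites, sites[1:]):
            split = False
            if coverage is not None and coverage.contig == cur.contig:
                if coverage.min_depth(prev.position + 1, cur.position) < min_depth:
                    split = True
            if split:
                runs.append([cur])
            else:
                runs[-1].append(cur)
        for run in runs:
            if len(run) < 2:
                continue
            blocks.append(
                Haploblock(
                    contig=run[0].contig,
                    start=run[0].position,
                    end=run[-1].position + 1,
                    sites=tuple(run),
                    assignment={s: assignment[s] for s in run},
                    block_id=f"{run[0].contig}:{run[0].position + 1}",
                )
            )
    blocks.sort(key=lambda b: (b.contig, b.start))
    return blocks


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------


class HaplotypePhaser:
    """Phasing model over read fragments and heterozygous sites.

    Parameters
    ----------
    fragments
        Iterable of :class:`haplopgx.simulate.ReadFragment`-like objects.
    het_sites
        The phaseable sites; see :func:`select_het_sites`.
    coverage
        Optional :class:`CoverageProfile` enabling the coverage-gap block
        break; by default it is derived from the fragments themselves when
        ``region_length`` is given.
    """

    def __init__(
        self,
        fragments: Sequence,
        het_sites: Sequence[HetSite],
        coverage: CoverageProfile | None = None,
        region_length: int | None = None,
        exact_limit: int = EXACT_COMPONENT_LIMIT,
        min_depth: int = 1,
    ):
        self.fragments = sorted(fragments, key=lambda f: (f.start, f.read_id))
        self.het_sites = sorted(het_sites)
        if coverage is None and region_length is not None and self.fragments:
            coverage = CoverageProfile.from_fragments(self.fragments, region_length)
        self.coverage = coverage
        self.exact_limit = exact_limit
        self.min_depth = min_depth

    def fit(self) -> "PhasingResult":
        graph = build_linkage_graph(self.fragments, self.het_sites)
        assignment = phase_components(graph, exact_limit=self.exact_limit)
        blocks = construct_haploblocks(
            graph, assignment, coverage=self.coverage, min_depth=self.min_depth
        )
        return PhasingResult(model=self, graph=graph, assignment=assignment, blocks=blocks)


@dataclass
class PhasingResult:
    """Fitted phasing: blocks, per-site assignments and diagnostics."""

    model: HaplotypePhaser
    graph: LinkageGraph
    assignment: dict[HetSite, int]
    blocks: list[Haploblock]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def conflict_cost(self) -> int:
        return conflict_cost(self.graph, self.assignment)

    @property
    def block_lengths(self) -> np.ndarray:
        return np.array([b.length for b in self.blocks], dtype=int)

    @property
    def phased_sites(self) -> int:
        return sum(len(b.sites) for b in self.blocks)

    def summary(self) -> str:
        lengths = self.block_lengths
        tie_edges = self.graph.graph.number_of_edges() - self.graph.informative_subgraph().number_of_edges()
        lines = [
            "Haplotype phasing summary",
            "=" * 32,
            f"het sites            {len(self.model.het_sites):>10d}",
            f"fragments            {len(self.model.fragments):>10d}",
            f"linkage edges        {self.graph.graph.number_of_edges():>10d}",
            f"tie edges dropped    {tie_edges:>10d}",
            f"haploblocks          {self.n_blocks:>10d}",
            f"phased sites         {self.phased_sites:>10d}",
            f"conflict cost (MEC)  {self.conflict_cost:>10d}",
        ]
        if len(lengths):
            lines += [
                f"median block length  {int(np.median(lengths)):>10d} bp",
                f"max block length     {int(lengths.max()):>10d} bp",
            ]
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        blocks_to_bed(self.blocks, path)

    def to_gtf(self, path) -> None:
        blocks_to_gtf(self.blocks, path)

    def plot_block_lengths(self, ax=None):
        """Histogram of haploblock lengths (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.block_lengths, bins=30)
        ax.set_xlabel("haploblock length (bp)")
        ax.set_ylabel("count")
        return ax


# ---------------------------------------------------------------------------
# VCF / BED interoperability
# ---------------------------------------------------------------------------


def import_phased_vcf(path) -> tuple[list[HetSite], dict[HetSite, int], list[Haploblock]]:
    """Reconstruct haploblocks from a phased single-sample VCF.

    Phase sets (PS) group phased heterozygous genotypes; each PS with at
    least two sites becomes one block. Unphased het genotypes are treated
    as singleton, unblocked sites. Downstream behaviour is identical to
    fragment-derived blocks.
    """
    import pysam

    het_sites: list[HetSite] = []
    assignment: dict[HetSite, int] = {}
    groups: dict[tuple[str, int], list[HetSite]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0]
            gt = sample["GT"]
            if len(gt) != 2 or gt[0] is None or gt[0] == gt[1]:
                continue
            alt = rec.alts[0]
            site = HetSite(rec.contig, rec.pos - 1, rec.ref, alt)
            het_sites.append(site)
            ps = sample.get("PS")
            if not sample.phased or ps is None:
                continue
            assignment[site] = 1 if gt[0] == 1 else 2
            groups.setdefault((rec.contig, int(ps)), []).append(site)
    blocks = []
    for (contig, ps), sites in sorted(groups.items()):
        sites = sorted(sites)
        if len(sites) < 2:
            continue
        blocks.append(
            Haploblock(
                contig=contig,
                start=sites[0].position,
                end=sites[-1].position + 1,
                sites=tuple(sites),
                assignment={s: assignment[s] for s in sites},
                block_id=f"{contig}:{sites[0].position + 1}",
            )
        )
    return sorted(het_sites), assignment, blocks


def write_phased_vcf(variants: Sequence, blocks: Sequence[Haploblock], path,
                     contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write variants with phased GT ('|') and PS = 1-based block start.

    Het sites inside a block get a phased genotype oriented by the block's
    assignment; blocked-out het sites stay unphased ('0/1'); homozygous
    variants are written '1/1' (or '1' for a single-allele genotype).
    """
    site_block: dict[tuple[str, int], Haploblock] = {}
    for b in blocks:
        for s in b.sites:
            site_block[(s.contig, s.position)] = b
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            contigs = sorted({v.contig for v in variants})
            for name in contigs:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
            gt = v.genotype
            if len(gt) == 1:
                fmt, sample = "GT", "1"
            elif gt[0] == gt[1]:
                fmt, sample = "GT", "1/1"
            else:
                block = site_block.get((v.contig, v.pos))
                if block is None:
                    fmt, sample = "GT", "0/1"
                else:
                    site = HetSite(v.contig, v.pos, v.ref, v.alt)
                    hap = block.assignment[site]
                    gt_str = "1|0" if hap == 1 else "0|1"
                    fmt, sample = "GT:PS", f"{gt_str}:{block.start + 1}"
            fh.write(f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t{fmt}\t{sample}\n")


def blocks_to_bed(blocks: Iterable[Haploblock], path) -> None:
    """BED (0-based, half-open) of block intervals, name = block id."""
    with open(path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.contig, b.start)):
            fh.write(f"{b.contig}\t{b.start}\t{b.end}\t{b.block_id}\n")


def blocks_to_gtf(blocks: Iterable[Haploblock], path) -> None:
    with open(path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.contig, b.start)):
            fh.write(
                f"{b.contig}\thaplopgx\thaploblock\t{b.start + 1}\t{b.end}\t.\t+\t.\t"
                f'block_id "{b.block_id}";\n'
            )


def read_blocks_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return out
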