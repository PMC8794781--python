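"""Shared fixtures: tiny synthetic scenarios built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from haplopgx.phasing import HetSite, LinkageGraph
from haplopgx.simulate import ReadFragment, SyntheticConfig, simulate_fragments, simulate_truth


@pytest.fixture
def default_config():
    return SyntheticConfig(seed=11)


@pytest.fixture
def noiseless_config():
    return SyntheticConfig(seed=11, error_rate=0.0)


@pytest.fixture
def small_truth(noiseless_config):
    return simulate_truth(noiseless_config)


@pytest.fixture
def small_fragments(small_truth, noiseless_config):
    return simulate_fragments(small_truth, noiseless_config)


def make_sites(positions, contig="chr1"):
    """Het sites with C>T alleles at the given 0-based positions."""
    return [HetSite(contig, p, "C", "T") for p in positions]


def make_fragment(read_id, sites, alleles, contig="chr1", haplotype=1):
    """Fragment observing each site with allele code 0 (ref) or 1 (alt)."""
    obs = tuple(
        (s.position, s.alt_allele if a else s.ref_allele) for s, a in zip(sites, alleles)
    )
    start = min(s.position for s in sites)
    end = max(s.position for s in sites) + 1
    return ReadFragment(read_id, contig, start, end, obs, haplotype)


def random_phasing_instance(rng, n_sites=8, n_fragments=12, error=0.05, span=(2, 4)):
    """A random small phasing instance with a known true bipartition.

    Returns (sites, fragments, truth) where truth maps each site to the
    haplotype carrying its alternate allele.
    """
    positions = sorted(rng.choice(np.arange(10, 10_000, 10), size=n_sites, replace=False))
    sites = make_sites([int(p) for p in positions])
    truth = {s: int(rng.integers(1, 3)) for s in sites}
    fragments = []
    for i in range(n_fragments):
        k = int(rng.integers(span[0], span[1] + 1))
        k = min(k, n_sites)
        start = int(rng.integers(0, n_sites - k + 1))
        hap = int(rng.integers(1, 3))
        covered = sites[start : start + k]
        alleles = []
        for s in covered:
            a = 1 if truth[s] == hap else 0
            if rng.random() < error:
                a = 1 - a
            alleles.append(a)
        fragments.append(make_fragment(f"r{i}", covered, alleles, haplotype=hap))
    return sites, fragments, truth


def brute_force_min_conflict(graph: LinkageGraph) -> int:
    """Exhaustive minimum-conflict oracle over all 2^k bipartitions.

    Independent of the phaser: plain Python loops over every assignment of
    every site, summing the support against each informative edge's
    orientation. Tie edges (cis == trans) carry no information and are
    excluded, mirroring the block-splitting stopping rule.
    """
    from itertools import product

    sites = graph.sites
    edges = [
        (a, b, d["cis"], d["trans"])
        for a, b, d in graph.graph.edges(data=True)
        if d["cis"] != d["trans"]
    ]
    best = None
    for bits in product((0, 1), repeat=len(sites)):
        side = dict(zip(sites, bits))
        cost = 0
        for a, b, cis, trans in edges:
            cost += trans if side[a] == side[b] else cis
        best = cost if best is None else min(best, cost)
    return best or 0
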