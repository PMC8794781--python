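# Methods

## Phasing model

The phaser works on *fragments*: per-read allele observations at
heterozygous small-variant sites. Every pair of sites co-observed by a
fragment contributes one unit of evidence to a linkage edge — *cis* when
the read sees ref–ref or alt–alt, *trans* otherwise. The phasing objective
is minimum error correction (MEC) restricted to pairwise evidence: choose
a bipartition of the sites (which haplotype carries each alternate allele)
minimising the summed support for the orientation each edge is phased
against. Components of up to 16 sites are solved exactly by vectorised
enumeration over the 2^(k−1) bipartitions (the first site is pinned, since
the global flip of a component is a symmetry of the problem); larger
components are oriented along a maximum spanning tree weighted by
|cis − trans|. The exact bound of 16 keeps the enumeration below ~10⁶
candidate rows per component; on error-free data both paths recover the
simulated truth exactly because every edge is unanimous.

A haploblock is a connected component of the *informative* graph with at
least two sites. Three stopping conditions end a block:

* **no linking read** — the sites fall in different components;
* **evidence tie** — an edge with cis = trans carries no phase
  information and is removed before components are formed. This is
  deliberately conservative: rather than asserting an unsupported phase,
  the block is split. A corner-case consequence is that adding a read can,
  in principle, split a block by turning a 1–0 edge into a 1–1 tie;
  monotonicity ("more reads never split blocks") therefore holds for
  consistent, error-free reads, which is how the property is tested.
* **coverage gap** — if a depth profile is supplied, a component is split
  wherever depth between consecutive sites falls below a threshold
  (default 1, i.e. any zero-coverage base breaks the block). With
  fragment-derived profiles this rarely fires, because a linking fragment
  itself covers the gap; it matters for blocks imported from a phased VCF
  or externally supplied profiles.

Block extent is the variant span, [first site, last site]; read overhang
beyond the outermost sites is not counted. Singleton sites carry no phase
information and form no block. Phased VCFs (GT with `|`, PS phase-set
tags) import to the same block structure, and the writer emits PS = the
1-based position of the block's first site.

## Resolution and complexity

Phased fraction of a feature = |feature ∩ ∪ block intervals| / length on
half-open intervals; complex fraction is the same arithmetic against the
union of segmental-duplication/repeat tracks, so bases under two repeat
intervals count once. Classification: fully phased at ≥ 0.90, unphased at
≤ the lower threshold, otherwise partial. The lower threshold defaults to
0 (only features with no block overlap at all are unphased); a laxer
variant (e.g. ≤ 0.10 phased) is configurable because both conventions are
in use. Sequence-context strata are derived directly from the reference:
homopolymer runs ≥ 7 bp, non-overlapping 100 bp windows with GC ≥ 0.8
(adjacent qualifying windows merged, trailing partial window ignored), and
≥ 3 adjacent copies of a 2–6 bp motif (single-base motifs are left to the
homopolymer track).

## Benchmarking

Small variants are normalised before comparison: multi-allelic records are
split into biallelic ones, alleles are left-aligned against the reference
by the standard truncate-and-extend loop, and shared leading bases are
trimmed. A match requires identical contig, position, alleles and
unordered genotype; a genotype mismatch at a matching site counts one FP
plus one FN. This exact-representation comparison is sufficient here
because the synthetic truth controls representation; it does not attempt
the haplotype-aware complex-allele matching of dedicated benchmarking
engines. Metrics are percent; when a denominator vanishes the metric is 0
and the row is flagged `degenerate`.

Structural variants (default minimum size 50 bp) are matched greedily,
nearest breakpoint first, one-to-one, with admissibility: breakpoint
distance ≤ 500 bp, size similarity min(len)/max(len) ≥ 0.7, and equal type
(insertion/deletion) — conventional SV-comparison defaults. Ties are
broken by position for determinism. On the dispersed instances used in
testing the greedy matching attains maximum-cardinality matching;
adversarially clustered SVs could make greedy sub-optimal, which is
accepted as inherent to the nearest-first rule.

## Star-allele calling

Allele definitions are exact variant sets; matching is set containment
with priority = defining-set size, so the most specific allele wins and
`*1` (empty set) is the fallback. Two incomparable equal-priority matches
are reported as ambiguous, never resolved silently; a haplotype carrying a
strict subset of some allele's defining set is flagged as a partial match.
If every definition-relevant heterozygous variant lies in one haploblock,
variants are split by haplotype (homozygous variants feed both sides) and
each side is matched — a phased call. Otherwise the unphased fallback
enumerates placements of the het panel variants over the two haplotypes
and keeps the one maximising the number of matched non-default alleles,
the trans-placement assumption of conventional non-phased genotyping;
multiple optimal placements with different diplotypes are flagged
ambiguous. Copy-number and hybrid alleles are out of scope: SV calls pass
through the pipeline but are not translated into star alleles.

The bundled demo tables cover three worked genes — CYP2D6 `*4`
(rs3892097 g.42128945 C>T with rs1065852 g.42130692 G>A), CYP3A5 `*3`
(rs776746 g.99672916 C>T), and the VKORC1 1173 variant (g.31093557 G>A,
reported as the `1173T` allele with a decreased-activity phenotype when
homozygous) — plus a small DPWG/CPIC-style gene–drug table. Full panels
are user-supplied TSVs in the documented schema (positions 1-based, as
printed in VCF coordinates; converted internally to 0-based).

## Synthetic data

The generator emulates a single-sample long-read experiment:

* **Reference**: uniform random sequence, default 100 kb on one contig.
* **Variants**: counts Poisson in rate × length, positions uniform with a
  small exclusion gap (8 bp) so allele representations never collide.
  Defaults: het rate 1e−3/bp (human-like heterozygosity), hom rate
  5e−4/bp, 10% of small variants indels (1–6 bp). *Homozygous deserts*
  are intervals forced free of het variants — the mechanism behind
  fragmented haploblocks in variant-poor genes. *Hemizygous* mode
  produces no het variant at all, so nothing can be phased (the X-like
  case). Optional SVs are 50–500 bp insertions/deletions.
* **Fragments**: read lengths log-normal, parameterised by the median
  (default 13,400 bp) and a dispersion sigma (default 0.35 — the profile
  reports only the median, so the spread is a free knob); read count set
  so summed length / region length equals the configured coverage
  (default 28×). Each read draws one parental haplotype and observes that
  haplotype's allele at each het site it spans, flipped independently at
  the error rate (default 0.2%, a stand-in for residual CCS error; no
  published error model is being reproduced). Fragments carry allele
  observations only — no base-level sequences or alignments are
  simulated, since the pipeline consumes observations, not reads.
* **Tracks**: evenly spaced features with SD strata overlapping each by an
  exact requested fraction from 0 to 1 (a fraction of 1 places the
  feature strictly inside a stratum).

Everything derives from `numpy.random.default_rng([seed, stream])`; the
same seed and config give byte-identical output files.

What the simulator does *not* emulate: mapping ambiguity in segmental
duplications (observations are always correctly located), coverage biases,
read-length/error correlation, indel-rich error modes, population linkage
structure, and CNVs. Passing tests therefore demonstrate correctness of
the analysis logic under the stated generative assumptions, not
performance on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run 100 kb regions at 28× (~200 reads,
~100 het sites), 20 seeds for recovery, 100 random instances for the
exhaustive-MEC and interval oracles, and 50 for the benchmarking
properties — sizes chosen so the full suite completes in seconds while
every property is exercised well above its noise floor. The
desert-fragmentation scenario uses a 50 kb desert, comfortably above the
read-length distribution's practical maximum, so blocks cannot bridge it.
Fractions are exact rational arithmetic on integer base counts; F1 is
reported to two decimals; precision/recall/F1 default to 0 with a
`degenerate` flag when denominators vanish; fragment processing order is
position- then read-id-sorted for determinism.

## Known limitations

* Exact MEC is exponential and hence capped at 16-site components; the
  spanning-tree heuristic above that size is not guaranteed optimal under
  conflicting evidence.
* Small-variant comparison is representation-exact; equivalent complex
  representations that normalisation cannot reconcile would be
  mis-scored.
* The guideline tables bundled here are minimal demonstrations, not
  clinical content.
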