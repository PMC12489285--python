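# Methods

This note documents the models, conventions, and numerical choices behind
`ribovar`, and what the synthetic-data tests do and do not demonstrate about
real data.

## The biological model

The package targets genomes in which the nuclear rDNA operon
(SSU–ITS1–5.8S–ITS2–LSU) exists as a small number of *divergent* copies —
on the order of 6–11 per strain, distributed over several chromosomes —
rather than as a concerted tandem array. Within one genome the loci differ
sharply in copy-to-copy divergence: the SSU is nearly invariant, 5.8S and
LSU are intermediate, and the two ITS spacers are the most variable. The
companion protein-coding markers (glomalin, RPB1, H⁺-ATPase) are single
copy and show low intraspecific variability, which is what makes them
candidates for barcode thresholds where rDNA fails.

## Synthetic community generator

`CommunitySpec` encodes a three-level star hierarchy: one random root →
species ancestors (uniform substitution probability `species_divergence`,
default 0.04) → strain ancestors (`strain_divergence`, default 0.003) →
copies. Copies are independent descendants of the strain ancestor
(star-shaped, no within-strain tree), which is the simplest model
consistent with copy variation that does not cluster by strain or
chromosome. Each copy mutates each locus at its own rate
(`per_locus_copy_divergence`, defaults SSU 0.001, 5.8S 0.01, LSU 0.02,
ITS1 = ITS2 = 0.05 per site) plus 1-bp indels at `indel_prob` (default
5·10⁻⁴ per site). Expected pairwise copy distance per locus is therefore
roughly twice the per-copy rate, which forces the qualitative ordering
SSU < 5.8S < LSU < ITS that the locus-divergence tests assert.

Default locus lengths are SSU 1700, ITS1 250, 5.8S 160, ITS2 250, LSU 800 bp
(a ~3.2-kb operon fragment, matching the scale of long-amplicon rDNA
sequencing). Chromosome assignment of copies is a label only (uniform over
4–6 chromosomes per strain). True per-copy abundances are lognormal with
σ = 0.5 and unit mean — the abundance skew of real multi-copy amplification
is not well characterised, so this is a free modelling choice, flagged
here. An optional "L-variant" mode inserts one 100–300-bp block into a
random copy's ITS to emulate the long length polymorphism seen in some
lineages; it is off by default.

Gene defaults (length, interspecific, intraspecific substitution
probability): glomalin 900 bp 0.040/0.004, RPB1 1100 bp 0.050/0.005,
H⁺-ATPase 1000 bp 0.050/0.008. The intraspecific rates were chosen to put
conspecific pairwise distances in the ~1–2% range where indicative barcode
thresholds live; interspecific rates are ≥ 3× higher, so simulated genes
show clean barcode gaps — this is a *property of the generator*, not a
claim about real data, where gaps are frequently absent.

Reads (`ReadSimSpec`) are HiFi-like: per-copy counts Poisson(depth ×
relative abundance), substitution error 0.002/bp and indel error 0.0005/bp,
constant Phred 40, plus PCR chimeras (5% of total reads; two abundance-
weighted parents from the same strain, crossover uniform along the
template) and contaminants (2%; reads from a pool of random sequences of
matched length). Amplification primers flank every read; the default
primers are synthetic ACGT-only placeholders (real AMF primers carry IUPAC
degeneracies that the package's strict ACGTN alphabet deliberately
rejects), and real primer sequences can be supplied in config. All
randomness flows through `numpy` generators seeded from a single master
seed via `SeedSequence.spawn`, so every artefact is bit-reproducible.

What the generator does **not** emulate: realistic PacBio error profiles as
a function of pass number, quality-score variation along reads, primer-site
mutations, length heterogeneity between lineages, multi-spore abundance
structure beyond the lognormal, or cross-strain chimeras. Tests passing on
this generator show that the algorithms are correct under the stated model,
not that the pipeline parameters are optimal for any particular instrument.

## Distances

`eachgap_distance` implements the each-gap convention: with
`count_ends=False` the compared span runs from the later first non-gap
position to the earlier last non-gap position; inside the span, columns
gapped in both sequences are skipped, columns containing N in either
sequence are excluded from numerator and denominator (the conservative
treatment of ambiguity, recorded in `DistanceMatrix.convention`), and every
remaining column with a base mismatch or a single gap counts as one
difference. Pairs with zero comparable columns return distance 0 with a
warning flag instead of raising, so matrix construction never aborts;
flagged pairs are listed on the matrix object. The distance is symmetric
and zero on identical rows but deliberately *not* claimed to satisfy the
triangle inequality.

Percent rendering rounds half-away-from-zero to one decimal on the decimal
representation of the value (so a printed 4.55 becomes 4.6 regardless of
binary floating-point representation); raw fractions are always retained
alongside.

`align_pair` is a standard affine-gap global aligner (Biopython's
`PairwiseAligner`); ties between optimal paths are broken by the aligner's
canonical first path, which is deterministic across platforms. Empty
sequences align against all gaps. `pairwise_distance_matrix` composes it
with the each-gap distance for unaligned inputs as the built-in alternative
to an external MSA.

## Loci

Locus windows live in an annotated reference's ungapped coordinates
(0-based half-open, BED-like on disk) and are projected through the
reference row's gap structure onto alignment columns — a deterministic
replacement for HMM-based locus detection, sufficient because both the
generator and curated references carry annotations. `extract_locus` slices
columns and drops columns gapped in every record. The Krüger barcode
window is `[SSU.end − 280, LSU.start + 800)` clipped to the locus bounds;
the SSU tail is configurable because the ~280-bp figure is approximate.
Reference-anchored boundaries can differ from motif-based boundaries by a
few bp; distance statistics at the reported precision are insensitive to
this, but that equivalence has not been verified against an HMM locus
detector.

## Threshold clustering

`cluster_at_threshold` is plain agglomeration: repeatedly merge the pair of
clusters with the smallest linkage distance (nearest = min, average =
unweighted mean over cross pairs, furthest = max) while that distance is
≤ the threshold. Merge order is fully deterministic — lowest distance
first, ties by the lexicographically smallest pair of smallest member ids —
which is why the loop is written out instead of delegated to a library
whose tie behaviour is unspecified; scipy's hierarchy serves as an
independent oracle in the tests instead. The default sweep grid is 0–0.25
in steps of 0.01 (percent-integer thresholds); all three linkages are
computed and reported because no single linkage criterion can be assumed
when comparing against published OTU counts, and the linkage that produced
any given published figure is generally unstated.

## Copy recovery

Stage order: primer trim → length/N filter → dereplicate → chimera screen →
swarm cluster → reference filter → abundance gate → representative. Read
counts are conserved at every stage and reported. Two defaults differ from
the values habitual in short-read amplicon work, for quantified reasons:

* **Swarm `d` (default 16).** At HiFi-like error rates (0.0025/bp total)
  a 2.8-kb read carries ~7 errors in expectation, so two reads of the same
  copy are ~14 edits apart and Swarm's classic d = 1 links nothing —
  every amplicon would be its own cluster. d = 16 is roughly the mean plus
  3 SD of the same-copy read-pair edit distance, while distinct copies
  under the generator's divergence rates sit ≥ ~50 edits apart at read
  level, so the agglomeration neither shatters copies nor bridges them.
  Swarm's fastidious grafting phase is not implemented (desk-scale data
  does not need it); `d` remains configurable with a hard cap of 16.
* **Representative (default consensus).** For the same reason (~e⁻⁷
  probability of an error-free read) the highest-abundance amplicon of a
  cluster is itself an error-bearing read, so the cluster seed is polished:
  every member is globally aligned to the seed and each seed position (and
  each insertion site) is decided by abundance-weighted majority vote, ties
  preferring the seed's own state. This recovers the true copy to within
  0–1 edits at 30× depth. `representative="seed"` restores the raw-seed
  behaviour.

The chimera screen processes amplicons in decreasing abundance and tests
each candidate against all pairs of already accepted amplicons with
abundance ≥ `skew` (default 2) times its own. For a parent pair the best
single-crossover model is scored as candidate identity (matches /
candidate length, from per-parent global alignments); the candidate is
chimeric when the model beats its best single parent by `min_gain`
(default 0.02) and reaches `min_model_identity` (default 0.99). This is a
transparent, testable replacement for a black-box chimera scorer. In
deep singleton-dominated HiFi data the skew condition rarely fires at the
amplicon level; chimeric reads then form low-abundance swarm clusters that
the abundance gate removes, so the two mechanisms are complementary.

The reference filter keeps clusters whose seed reaches ≥ 0.8 global
identity (matches / alignment columns, unit-cost alignment) to the best
sequence of a user-supplied panel — a self-contained stand-in for a
taxonomy-database screen, aimed at the same target: removing contaminant
clusters.

The abundance gate's `two_means` mode runs 1-D 2-means on log₁₀ cluster
abundance with centres initialised at the minimum and maximum and retains
the higher group — but only when the two group means end up ≥ 0.75 log₁₀
units apart. This bimodality guard exists because a 2-means partition of a
*unimodal* abundance sample (a clean run with no chimera/error debris)
always "finds" two groups and would amputate real copies; with the
generator's lognormal(σ = 0.5) copy depths a unimodal split yields a gap of
~0.35 log₁₀ units while debris-versus-copies gaps exceed ~1.2, so 0.75
separates the two regimes with margin on both sides. A `fixed_min` mode is
available where a hard count threshold is preferred. Known limitation: a
genuinely low-depth copy lying between the debris and the main group can
be gated away (or drag debris in); the ±1-copy tolerance of the recovery
tests reflects this.

Identical rDNA copies are inherently indistinguishable to any
sequence-based pipeline; the recovered copy count equals the number of
*distinct* true copies.

## SNP density

`map_reads` places each merged/short read inside the single reference by
unit-cost edit alignment (infix mode; `band` bounds the accepted edit
distance) and discards placements below 0.8 identity. The pileup counts
A/C/G/T/deletion per reference position; insertions have no reference
coordinate and are ignored. `call_snps` marks a position when depth ≥ 20
and some non-reference base has count ≥ 3 and fraction ≥ 0.05 — deliberate,
recorded defaults for intragenomic variant detection at high depth;
deletions are never SNPs. `density_track` uses window 100 bp / step 10 bp,
sized for a ~3-kb amplicon (genome-scale density defaults are meaningless
here); each interior SNP is counted in exactly window/step windows, which
the tests exploit as a counting invariant.

## Barcode gap

For each species: `max_intra` is the maximum conspecific pairwise distance
(undefined for singletons, which still contribute to other species'
minima), `min_inter` the nearest non-conspecific distance, and the gap
verdict is `min_inter > max_intra`. The "95% of conspecific pairs"
threshold is implemented as the q = 0.95 order statistic of all conspecific
pairwise distances (smallest d with ≥ q of pairs ≤ d, no interpolation).
An alternative reading — the fraction of *sequences* whose every
conspecific pair falls below the threshold — is computable from the same
partition but is not the default. Thresholds are non-decreasing in q by
construction.

## Problem sizes and tolerances in the test suite

The seeded test battery uses desk-scale sizes chosen to exercise every code
path while keeping the default run fast: 1000 random pairs for the distance
oracle, 200 random matrices (≤ 7 items) for the clustering oracles, 100
trials (≤ 50 amplicons) for the swarm/components equivalence, 20
single-strain simulations at 30× depth for copy recovery (pass condition:
count within ±1 of distinct truth in ≥ 90% of runs, every sequence within
1 edit), 40 constructed chimera trials (recall ≥ 0.95, false-positive rate
≤ 0.05), 20 seeds for the locus-ordering property, and one community each
for the barcode-gap and SNP-density properties. The acceptance script
reruns the same analyses at the same scale from a single command-line seed.
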