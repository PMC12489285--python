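# ribovar

Toolkit for analysing **intragenomic rDNA polymorphism** in organisms whose
nuclear ribosomal operon is *not* homogenised by concerted evolution — most
prominently arbuscular mycorrhizal fungi (AMF, Glomeromycota), where a single
genome carries a handful of divergent copies of the SSU–ITS1–5.8S–ITS2–LSU
operon spread over several chromosomes. That polymorphism breaks the usual
assumptions behind OTU thresholds, barcode gaps, and rDNA phylogenies, and
this package provides the pieces needed to measure it and to work around it:

* **Copy recovery from long amplicons** — a HiFi-read pipeline (primer
  trimming → length filter → dereplication → chimera screen → swarm
  clustering → reference-panel filter → abundance gate → consensus
  polishing) that reconstructs the individual rDNA copy sequences of a
  strain from a single sequencing library.
* **Gap-aware pairwise distances** — the *each-gap* dissimilarity
  (`calc=eachgap, countends=F` convention): every gapped column in the
  mutually covered span counts as one difference, terminal gaps from
  unequal lengths do not, N columns are excluded. For aligned rows `a`, `b`
  of an MSA,

  `d(a,b) = (# differing columns in span) / (# compared columns in span)`.

* **Locus anatomy** — reference-anchored projection of SSU/ITS1/5.8S/ITS2/LSU
  windows onto alignments, plus the ~1.5-kb "Krüger" taxonomic barcode
  window (last ~280 bp of SSU through the first 800 bp of LSU).
* **OTU threshold sweeps** — deterministic agglomerative clustering
  (nearest/average/furthest linkage) over a threshold grid, and the minimal
  threshold at which a strain's copies collapse into one cluster.
* **SNP density tracks** — pileup-based intragenomic SNP calling on a single
  rDNA reference with sliding-window densities.
* **Barcode-gap analysis** — per-species maximum intraspecific vs minimum
  (nearest non-conspecific) interspecific distance, and order-statistic
  conspecific distance thresholds (e.g. "95% of conspecific pairs differ by
  ≤ x%").
* **A fully seeded synthetic generator** — multi-copy rDNA communities with
  locus-specific copy divergence (SSU lowest, ITS highest), companion
  low-variability protein-coding genes, and HiFi-like reads with errors,
  PCR chimeras, and contaminants, so that every stage is testable without
  any downloads.

## Worked example

Recovering the rDNA copies of one simulated strain from noisy HiFi reads:

```python
from ribovar import (CommunitySpec, ReadSimSpec, RecoveryConfig,
                     simulate_community, simulate_hifi_reads, recover_copies,
                     edit_distance, percent)
from ribovar.simulate import per_locus_truth_distances

truth = simulate_community(CommunitySpec(n_species=1, strains_per_species=1, seed=7))
strain = truth.strains[0]
print(f"strain {strain.strain}: {len(strain.copies)} rDNA copies "
      f"({len(strain.distinct_copy_sequences())} distinct)")

table = per_locus_truth_distances(truth)
for _, row in table.iterrows():
    print(f"  {row.locus:>5}: mean intragenomic distance {percent(row.mean_distance)}%")

spec = ReadSimSpec(depth=30, seed=8)          # 5% chimeras, 2% contaminants
reads, _ = simulate_hifi_reads(truth, spec)
config = RecoveryConfig(fwd_primer=spec.fwd_primer, rev_primer=spec.rev_primer,
                        min_length=2500, max_length=3800,
                        reference_panel=[strain.copies[0].sequence])
result = recover_copies(reads, config)
print(f"{len(reads)} HiFi reads -> {len(result.copies)} recovered copies")
worst = max(min(edit_distance(c.residues, t) for t in strain.distinct_copy_sequences())
            for c in result.copies)
print(f"max edit distance to a true copy: {worst}")
```

Output:

```text
strain sp01_st01: 6 rDNA copies (6 distinct)
    SSU: mean intragenomic distance 0.3%
   ITS1: mean intragenomic distance 9.5%
   5.8S: mean intragenomic distance 2.9%
   ITS2: mean intragenomic distance 9.9%
    LSU: mean intragenomic distance 3.5%
199 HiFi reads -> 6 recovered copies
max edit distance to a true copy: 0
```

The per-locus means show the characteristic ordering of intragenomic rDNA
variation (SSU ≪ 5.8S < LSU < ITS1 ≈ ITS2); the pipeline returns exactly
the six true copy sequences despite per-read errors, chimeras, and
contaminant reads. `result.report` holds the per-stage read accounting.

The same operations are available from the shell:

```bash
ribovar simulate --out sim --seed 7
ribovar recover --reads sim/reads.fastq --panel sim/truth_copies.fasta --out rec
ribovar gap --fasta glomalin.fasta --manifest manifest.tsv --out gap
```

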