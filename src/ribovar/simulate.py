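"""Synthetic multi-copy rDNA communities and HiFi-like amplicon reads.

The generator emulates the salient genomics of arbuscular mycorrhizal fungi:
each strain carries a handful (default 6-11) of *divergent* copies of the
rDNA operon (SSU-ITS1-5.8S-ITS2-LSU) rather than a homogenised tandem array,
with locus-specific divergence among copies (SSU most conserved, ITS most
variable), plus low-variability single-copy protein-coding genes per strain.
Copies are star-shaped descendants of a strain ancestor — the simplest model
consistent with copy variation that is unstructured within strains.

Reads are HiFi-like: long amplicons with low substitution/indel error,
constant high Phred, plus PCR chimeras (two-parent crossovers) and divergent
contaminants at configurable rates.

Reproducibility: every stochastic operation consumes an explicitly seeded
``numpy`` generator; a master seed deterministically derives per-stage and
per-strain sub-seeds via ``SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import SequenceRecord, reverse_complement

LOCUS_ORDER = ("SSU", "ITS1", "5.8S", "ITS2", "LSU")

DEFAULT_LOCUS_LENGTHS = {"SSU": 1700, "ITS1": 250, "5.8S": 160, "ITS2": 250, "LSU": 800}
DEFAULT_COPY_DIVERGENCE = {
    "SSU": 0.001,
    "ITS1": 0.05,
    "5.8S": 0.01,
    "ITS2": 0.05,
    "LSU": 0.02,
}

# Synthetic placeholder amplification primers (ACGT-only stand-ins for the
# AMF-specific long-amplicon primer pair; real primer sequences can be
# supplied via config).
DEFAULT_FWD_PRIMER = "ATCAACTTTCGATGGTAGGATAGA"
DEFAULT_REV_PRIMER = "GCATATCAATAAGCGGAGGA"

_BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class GeneSpec:
    """A single-copy protein-coding marker gene."""

    name: str
    length: int
    interspecific_divergence: float
    intraspecific_divergence: float


DEFAULT_GENE_SPECS = (
    GeneSpec("glomalin", 900, 0.040, 0.004),
    GeneSpec("rpb1", 1100, 0.050, 0.005),
    GeneSpec("atpase", 1000, 0.050, 0.008),
)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the synthetic community.

    Defaults reflect the study system: 6-11 rDNA copies per strain, locus
    divergence ordered SSU < 5.8S < LSU < ITS1 = ITS2, species ancestors a
    few percent apart, strains of a species well under 1% apart, and three
    companion genes with low intraspecific variability.
    """

    n_species: int = 3
    strains_per_species: int = 2
    copies_per_strain: tuple[int, int] = (6, 11)
    locus_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LOCUS_LENGTHS)
    )
    species_divergence: float = 0.04
    strain_divergence: float = 0.003
    per_locus_copy_divergence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COPY_DIVERGENCE)
    )
    indel_prob: float = 0.0005
    gene_specs: tuple[GeneSpec, ...] = DEFAULT_GENE_SPECS
    abundance_sigma: float = 0.5  # lognormal sigma of true per-copy abundance
    long_insert_mode: bool = False  # "L variant": one long ITS block insertion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ValueError("need at least one species and one strain per species")
        lo, hi = self.copies_per_strain
        if not (1 <= lo <= hi <= 64):
            raise ValueError("copies_per_strain must satisfy 1 <= lo <= hi <= 64")
        for name in LOCUS_ORDER:
            if self.locus_lengths.get(name, 0) <= 0:
                raise ValueError(f"locus {name} must have positive length")
            if not 0 <= self.per_locus_copy_divergence.get(name, -1) <= 1:
                raise ValueError(f"locus {name} divergence must be in [0,1]")
        for p in (self.species_divergence, self.strain_divergence, self.indel_prob):
            if not 0 <= p <= 1:
                raise ValueError("divergence probabilities must be in [0,1]")
        for g in self.gene_specs:
            if g.length <= 0:
                raise ValueError(f"gene {g.name} must have positive length")


@dataclass(frozen=True)
class ReadSimSpec:
    """HiFi-like amplicon read simulation parameters."""

    depth: int = 30
    substitution_error: float = 0.002
    indel_error: float = 0.0005
    chimera_rate: float = 0.05
    contaminant_fraction: float = 0.02
    fwd_primer: Optional[str] = DEFAULT_FWD_PRIMER
    rev_primer: Optional[str] = DEFAULT_REV_PRIMER
    quality: int = 40
    contaminant_pool_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.substitution_error,
            self.indel_error,
            self.chimera_rate,
            self.contaminant_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError("rates must be in [0,1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.chimera_rate + self.contaminant_fraction >= 1:
            raise ValueError("chimera_rate + contaminant_fraction must be < 1")


@dataclass
class CopyTruth:
    id: str
    strain: str
    species: str
    sequence: str
    locus_map: list[tuple[str, int, int]]  # (locus, start, end), 0-based half-open
    abundance: float
    chromosome: int
    mutations: list[tuple]


@dataclass
class StrainTruth:
    strain: str
    species: str
    copies: list[CopyTruth]
    genes: dict[str, str]

    def distinct_copy_sequences(self) -> list[str]:
        return sorted(set(c.sequence for c in self.copies))


@dataclass
class SyntheticTruth:
    spec: CommunitySpec
    strains: list[StrainTruth]

    def all_copies(self) -> list[CopyTruth]:
        return [c for s in self.strains for c in s.copies]

    def strain(self, name: str) -> StrainTruth:
        for s in self.strains:
            if s.strain == name:
                return s
        raise KeyError(name)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def mutate_sequence(
    seq: str, sub_prob: float, indel_prob: float, rng: np.random.Generator
) -> tuple[str, list[tuple]]:
    """Apply iid per-site substitutions and 1-bp indels; return (seq, log).

    Each site is substituted with ``sub_prob`` (uniform over the three
    alternative bases) and independently hit by a 1-bp indel with
    ``indel_prob`` (insertion before the site / deletion of the site,
    equiprobable; inserted base uniform).  The log lists every event with its
    position in the *input* coordinate system.
    """
    if not 0 <= sub_prob <= 1 or not 0 <= indel_prob <= 1:
        raise ValueError("probabilities must be in [0,1]")
    log: list[tuple] = []
    if not seq:
        return seq, log
    n = len(seq)
    chars = list(seq)

    if sub_prob > 0:
        sub_pos = np.nonzero(rng.random(n) < sub_prob)[0]
        offsets = rng.integers(1, 4, size=len(sub_pos))
        for pos, off in zip(sub_pos, offsets):
            old = chars[pos]
            if old not in _BASE_TO_IDX:  # leave N untouched
                continue
            new = _BASES[(_BASE_TO_IDX[old] + off) % 4]
            chars[pos] = new
            log.append(("sub", int(pos), old, new))

    if indel_prob > 0:
        indel_pos = np.nonzero(rng.random(n) < indel_prob)[0]
        is_ins = rng.random(len(indel_pos)) < 0.5
        ins_bases = rng.integers(0, 4, size=len(indel_pos))
        events = []
        for pos, ins, base_i in zip(indel_pos, is_ins, ins_bases):
            if ins:
                events.append(("ins", int(pos), _BASES[base_i]))
            else:
                events.append(("del", int(pos), seq[pos]))
        # apply right-to-left so input positions stay valid
        for ev in sorted(events, key=lambda e: e[1], reverse=True):
            if ev[0] == "ins":
                chars.insert(ev[1], ev[2])
            else:
                del chars[ev[1]]
        log.extend(sorted(events, key=lambda e: e[1]))

    log.sort(key=lambda e: e[1])
    return "".join(chars), log


def _mutate_loci(
    loci: dict[str, str],
    rates: dict[str, float],
    indel_prob: float,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[tuple]]:
    out: dict[str, str] = {}
    log: list[tuple] = []
    for name in LOCUS_ORDER:
        mutated, events = mutate_sequence(loci[name], rates[name], indel_prob, rng)
        out[name] = mutated
        log.extend((name,) + ev for ev in events)
    return out, log


def simulate_community(spec: CommunitySpec) -> SyntheticTruth:
    """Generate the full community truth from a :class:`CommunitySpec`.

    Species ancestors descend from one root, strains from their species
    ancestor, copies from their strain ancestor (star-shaped, with per-locus
    substitution rates and 1-bp indels).  Genes follow the same hierarchy
    with their own rates and no indels (coding sequence).
    """
    master = np.random.SeedSequence(spec.seed)
    root_ss, tree_ss = master.spawn(2)
    root_rng = np.random.default_rng(root_ss)

    root_loci = {name: random_sequence(spec.locus_lengths[name], root_rng) for name in LOCUS_ORDER}
    root_genes = {g.name: random_sequence(g.length, root_rng) for g in spec.gene_specs}

    uniform = {name: spec.species_divergence for name in LOCUS_ORDER}
    strain_uniform = {name: spec.strain_divergence for name in LOCUS_ORDER}

    strains: list[StrainTruth] = []
    species_seeds = tree_ss.spawn(spec.n_species)
    for si in range(spec.n_species):
        species = f"sp{si + 1:02d}"
        sp_rng = np.random.default_rng(species_seeds[si])
        sp_loci, _ = _mutate_loci(root_loci, uniform, 0.0, sp_rng)
        sp_genes = {
            g.name: mutate_sequence(root_genes[g.name], g.interspecific_divergence, 0.0, sp_rng)[0]
            for g in spec.gene_specs
        }
        for ti in range(spec.strains_per_species):
            strain = f"{species}_st{ti + 1:02d}"
            # strains draw from the species rng in a fixed order -> reproducible
            st_loci, _ = _mutate_loci(sp_loci, strain_uniform, 0.0, sp_rng)
            st_genes = {
                g.name: mutate_sequence(sp_genes[g.name], g.intraspecific_divergence, 0.0, sp_rng)[0]
                for g in spec.gene_specs
            }
            n_copies = int(sp_rng.integers(spec.copies_per_strain[0], spec.copies_per_strain[1] + 1))
            n_chrom = int(sp_rng.integers(4, 7))
            raw_abund = np.exp(sp_rng.normal(0.0, spec.abundance_sigma, size=n_copies))
            abund = raw_abund / raw_abund.mean()
            long_insert_copy = (
                int(sp_rng.integers(0, n_copies)) if spec.long_insert_mode else -1
            )
            copies: list[CopyTruth] = []
            for ci in range(n_copies):
                copy_loci, log = _mutate_loci(
                    st_loci, spec.per_locus_copy_divergence, spec.indel_prob, sp_rng
                )
                if ci == long_insert_copy:
                    # "L variant": one long block inserted into an ITS region
                    target = "ITS1" if sp_rng.random() < 0.5 else "ITS2"
                    block = random_sequence(int(sp_rng.integers(100, 301)), sp_rng)
                    at = int(sp_rng.integers(0, len(copy_loci[target]) + 1))
                    copy_loci[target] = (
                        copy_loci[target][:at] + block + copy_loci[target][at:]
                    )
                    log.append((target, "long_insert", at, len(block)))
                seq_parts, locus_map, pos = [], [], 0
                for name in LOCUS_ORDER:
                    seq_parts.append(copy_loci[name])
                    locus_map.append((name, pos, pos + len(copy_loci[name])))
                    pos += len(copy_loci[name])
                copies.append(
                    CopyTruth(
                        id=f"{strain}_copy{ci + 1:02d}",
                        strain=strain,
                        species=species,
                        sequence="".join(seq_parts),
                        locus_map=locus_map,
                        abundance=float(abund[ci]),
                        chromosome=int(sp_rng.integers(1, n_chrom + 1)),
                        mutations=log,
                    )
                )
            strains.append(
                StrainTruth(strain=strain, species=species, copies=copies, genes=st_genes)
            )
    return SyntheticTruth(spec=spec, strains=strains)


def per_locus_truth_distances(truth: SyntheticTruth):
    """Mean intragenomic each-gap distance per strain x locus on the truth.

    Copy locus slices are taken from each copy's own boundary map, pairwise
    edit-aligned (unit costs; loci within a strain differ by a few sites so
    the alignment is unambiguous at this scale), and scored with the
    each-gap distance.  Returns a DataFrame (strain, locus, n_copies,
    mean_distance).
    """
    import edlib
    import pandas as pd

    from .distances import eachgap_distance

    rows = []
    for strain in truth.strains:
        slices: dict[str, list[str]] = {name: [] for name in LOCUS_ORDER}
        for copy in strain.copies:
            for name, start, end in copy.locus_map:
                slices[name].append(copy.sequence[start:end])
        for name in LOCUS_ORDER:
            seqs = slices[name]
            if len(seqs) < 2:
                rows.append((strain.strain, name, len(seqs), float("nan")))
                continue
            dists = []
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    if seqs[i] == seqs[j]:
                        dists.append(0.0)
                        continue
                    res = edlib.align(seqs[i], seqs[j], mode="NW", task="path")
                    nice = edlib.getNiceAlignment(res, seqs[i], seqs[j])
                    dists.append(
                        eachgap_distance(
                            nice["query_aligned"], nice["target_aligned"]
                        ).distance
                    )
            rows.append(
                (strain.strain, name, len(seqs), float(np.mean(dists)))
            )
    return pd.DataFrame(rows, columns=["strain", "locus", "n_copies", "mean_distance"])


def make_chimera(parent_a: str, parent_b: str, breakpoint: int) -> str:
    """Two-parent crossover: prefix of ``parent_a`` up to ``breakpoint`` then
    the suffix of ``parent_b`` from the homologous position (nearest ungapped
    coordinate, found by global edit alignment when lengths differ)."""
    if not 0 <= breakpoint <= len(parent_a):
        raise ValueError(
            f"breakpoint {breakpoint} outside [0, {len(parent_a)}]"
        )
    if breakpoint == 0:
        return parent_b
    if breakpoint == len(parent_a):
        return parent_a
    if len(parent_a) == len(parent_b):
        b_pos = breakpoint
    else:
        import edlib

        res = edlib.align(parent_a, parent_b, mode="NW", task="path")
        a_pos = b_pos = 0
        for count, op in _iter_cigar(res["cigar"]):
            if a_pos >= breakpoint:
                break
            if op in "=XM":
                step = min(count, breakpoint - a_pos)
                a_pos += step
                b_pos += step
            elif op == "I":  # consumes query (parent_a)
                a_pos += min(count, breakpoint - a_pos)
            elif op == "D":  # consumes target (parent_b)
                b_pos += count
    return parent_a[:breakpoint] + parent_b[b_pos:]


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


@dataclass(frozen=True)
class ReadOrigin:
    kind: str  # "copy" | "chimera" | "contaminant"
    strain: Optional[str] = None
    copy_id: Optional[str] = None
    parents: Optional[tuple[str, str]] = None
    breakpoint: Optional[int] = None


def simulate_hifi_reads(
    truth: SyntheticTruth, read_spec: ReadSimSpec
) -> tuple[list[SequenceRecord], list[ReadOrigin]]:
    """Simulate HiFi amplicon reads with per-read truth labels.

    Per-copy read counts are Poisson(depth x true relative abundance);
    substitution/indel errors are applied via :func:`mutate_sequence`;
    chimeras and contaminants are injected so that their expected share of
    the *total* read count equals the configured rates.  Amplification
    primers (when set) flank every read, contaminants included.  Qualities
    are a constant high Phred.  Fully reproducible from the seed.
    """
    if not truth.strains:
        raise ValueError("truth is empty")
    rng = np.random.default_rng(np.random.SeedSequence(read_spec.seed))
    fwd = read_spec.fwd_primer or ""
    rev_rc = reverse_complement(read_spec.rev_primer) if read_spec.rev_primer else ""

    def finish(template: str) -> str:
        read, _ = mutate_sequence(
            fwd + template + rev_rc,
            read_spec.substitution_error,
            read_spec.indel_error,
            rng,
        )
        return read

    reads: list[tuple[str, ReadOrigin]] = []
    all_copies = truth.all_copies()
    for strain in truth.strains:
        for copy in strain.copies:
            n = int(rng.poisson(read_spec.depth * copy.abundance))
            for _ in range(n):
                reads.append(
                    (finish(copy.sequence), ReadOrigin("copy", strain.strain, copy.id))
                )

    n_base = len(reads)
    denom = 1.0 - read_spec.chimera_rate - read_spec.contaminant_fraction
    n_chim = int(rng.binomial(n_base, read_spec.chimera_rate / denom)) if n_base else 0
    n_cont = (
        int(rng.binomial(n_base, read_spec.contaminant_fraction / denom)) if n_base else 0
    )

    for _ in range(n_chim):
        strain = truth.strains[int(rng.integers(len(truth.strains)))]
        pool = strain.copies if len(strain.copies) >= 2 else all_copies
        if len(pool) < 2:
            break
        weights = np.array([c.abundance for c in pool])
        i, j = rng.choice(len(pool), size=2, replace=False, p=weights / weights.sum())
        pa, pb = pool[int(i)], pool[int(j)]
        bp = int(rng.integers(1, len(pa.sequence)))
        reads.append(
            (
                finish(make_chimera(pa.sequence, pb.sequence, bp)),
                ReadOrigin("chimera", strain.strain, parents=(pa.id, pb.id), breakpoint=bp),
            )
        )

    mean_len = int(np.mean([len(c.sequence) for c in all_copies]))
    pool_rng = np.random.default_rng(np.random.SeedSequence(read_spec.seed).spawn(1)[0])
    contaminant_pool = [
        random_sequence(mean_len, pool_rng) for _ in range(read_spec.contaminant_pool_size)
    ]
    for _ in range(n_cont):
        src = contaminant_pool[int(rng.integers(len(contaminant_pool)))]
        reads.append((finish(src), ReadOrigin("contaminant")))

    order = rng.permutation(len(reads))
    records, origins = [], []
    for new_idx, old_idx in enumerate(order):
        seq, origin = reads[old_idx]
        records.append(
            SequenceRecord(
                id=f"read{new_idx + 1:06d}",
                residues=seq,
                qualities=[read_spec.quality] * len(seq),
            )
        )
        origins.append(origin)
    return records, origins
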