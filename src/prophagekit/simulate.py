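"""Synthetic genomes with planted prophages and particle-protected read sets.

The generator emulates the study design of a prophage-activity experiment:

* a host chromosome with i.i.d. base composition at a configurable GC,
* planted prophage regions, each with its own (typically lower) GC, flanked
  by a direct repeat (the attL/attR core, optionally degenerate) and
  carrying a cassette of phage genes — mutated, back-translated copies of
  proteins from a reference phage database,
* particle-protected DNA reads packaged in one of two modes:
  ``specific`` (fragments spanning one designated prophage, the behaviour
  of a genuine temperate phage packaging its own ~40-kb genome) or
  ``random_13kb`` (PBSX-like headful packaging of ~13-kb chromosomal
  fragments genome-wide, with an optional linear coverage bias towards the
  replication origin), plus a configurable background of free host DNA and
  a per-base substitution error rate.

Everything is deterministic given the config seed, and the truth object
records each read's placement so coverage statistics can be validated
without a mapping step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .genome import Genome, GenomicRegion
from .io import DbProtein

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_x] = _y

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


_CODONS = _codon_map()


@dataclass(frozen=True)
class ProphageSpec:
    """One prophage to plant: where, how large, and how phage-like."""

    position: int          # 1-based start of the region
    length: int            # bp including both repeat copies
    gc: float = 40.0       # percent, typically below the host's
    repeat_length: int = 18
    repeat_mismatches: int = 0
    n_phage_genes: int = 12
    source_phage: str = ""  # db phage to draw cassette proteins from


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults are a desk-scale analogue of the real system: a 500-kb host at
    GC 46.2 carrying one 40-kb prophage, 50,000 particle-protected reads of
    100 nt, 1% substitution errors (within the 2% divergence a short-read
    mapper tolerates) and 2% free host DNA surviving the nuclease step.
    """

    genome_length: int = 500_000
    background_gc: float = 46.2
    prophages: tuple = (ProphageSpec(position=200_001, length=40_000),)
    packaging_mode: str = "specific"          # or "random_13kb"
    packaged_region: str = ""                 # label; default first prophage
    fragment_mean: float | None = None        # None → mode default
    fragment_sd: float | None = None
    origin_bias: float = 1.0                  # fold-coverage at position 1
    read_length: int = 100
    n_reads: int = 50_000
    error_rate: float = 0.01
    background_dna_fraction: float = 0.02
    unmapped_fraction: float = 0.0
    gene_aa_substitution_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.02:
            raise ValueError("error_rate must be within [0, 0.02]")
        for frac in (self.background_dna_fraction, self.unmapped_fraction,
                     self.gene_aa_substitution_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be within [0, 1]")
        if self.packaging_mode not in {"specific", "random_13kb"}:
            raise ValueError(f"unknown packaging_mode {self.packaging_mode!r}")
        spans = sorted((p.position, p.position + p.length - 1)
                       for p in self.prophages)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("prophage intervals overlap")
        for s, e in spans:
            if s < 1 or e > self.genome_length:
                raise ValueError("prophage interval exceeds the genome")


@dataclass
class SimulationTruth:
    """Everything the generator knows: the genome, regions, genes, repeats."""

    genome: Genome
    regions: list[GenomicRegion]
    repeats: dict = field(default_factory=dict)   # label -> (length, mismatches)
    genes: list = field(default_factory=list)     # (start, end, strand, protein_id)
    config: SimulationConfig | None = None


@dataclass
class ReadOrigins:
    """Truth placements for one read set (1-based inclusive intervals)."""

    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray        # '+' stored as True
    is_background: np.ndarray
    n_unmapped: int


# ---------------------------------------------------------------------------
# genome generation


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    g = gc / 200.0
    a = (100.0 - gc) / 200.0
    return rng.choice(_BASES, size=n, p=[a, g, g, a])


def simulate_phage_db(
    rng: np.random.Generator | int,
    n_phages: int = 3,
    proteins_per_phage: int = 15,
    length_range: tuple[int, int] = (120, 360),
    family: str = "Siphoviridae",
) -> list[DbProtein]:
    """A synthetic phage protein database with ``id|phage|family`` records."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    records = []
    for p in range(n_phages):
        phage = f"phage{p + 1}"
        for i in range(proteins_per_phage):
            n = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "M" + "".join(rng.choice(list(_AA20), size=n - 1))
            records.append(DbProtein(id=f"{phage}_p{i + 1:03d}", phage=phage,
                                     family=family, sequence=seq))
    return records


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    if rate <= 0:
        return protein
    chars = list(protein)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if i == 0:
            continue  # keep the initiator Met
        chars[i] = _AA20[int(rng.integers(len(_AA20)))]
    return "".join(chars)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
              for aa in protein]
    return "".join(codons) + "TAA"


def simulate_genome(
    config: SimulationConfig,
    db: list[DbProtein] | None = None,
    genome_id: str = "simulated",
) -> SimulationTruth:
    """Generate the host genome with all configured prophages planted."""
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, config.genome_length, config.background_gc)
    regions: list[GenomicRegion] = []
    repeats: dict[str, tuple[int, int]] = {}
    genes: list[tuple[int, int, str, str]] = []

    for k, spec in enumerate(sorted(config.prophages, key=lambda p: p.position)):
        label = f"Pp{k + 1}"
        start0 = spec.position - 1
        body = _random_seq(rng, spec.length, spec.gc)

        rep = spec.repeat_length
        if rep > 0:
            att = _random_seq(rng, rep, spec.gc)
            body[:rep] = att
            att_r = att.copy()
            if spec.repeat_mismatches > 0:
                pos = rng.choice(rep, size=spec.repeat_mismatches, replace=False)
                for i in pos:
                    choices = _BASES[_BASES != att_r[i]]
                    att_r[i] = choices[int(rng.integers(3))]
            body[-rep:] = att_r
            repeats[label] = (rep, spec.repeat_mismatches)

        if spec.n_phage_genes > 0:
            proteins = _cassette_proteins(rng, db, spec)
            offset = rep + int(rng.integers(100, 400))
            for pid, protein in proteins:
                cds = _back_translate(
                    rng, _mutate_protein(rng, protein,
                                         config.gene_aa_substitution_rate))
                if offset + len(cds) > spec.length - rep - 100:
                    break
                body[offset : offset + len(cds)] = np.frombuffer(
                    cds.encode(), dtype=np.uint8)
                genes.append((spec.position + offset,
                              spec.position + offset + len(cds) - 1, "+", pid))
                offset += len(cds) + int(rng.integers(100, 1500))

        seq[start0 : start0 + spec.length] = body
        regions.append(GenomicRegion(label=label, start=spec.position,
                                     end=spec.position + spec.length - 1,
                                     genome_id=genome_id))

    genome = Genome(id=genome_id, sequence=seq.tobytes().decode())
    return SimulationTruth(genome=genome, regions=regions, repeats=repeats,
                           genes=genes, config=config)


def _cassette_proteins(rng, db, spec) -> list[tuple[str, str]]:
    """Pick cassette source proteins from the db (or synthesise them)."""
    if db:
        pool = [r for r in db if not spec.source_phage
                or r.phage == spec.source_phage]
        if not pool:
            raise ValueError(f"no db proteins for phage {spec.source_phage!r}")
        picked = [pool[i % len(pool)] for i in range(spec.n_phage_genes)]
        return [(r.id, r.sequence) for r in picked]
    synth = simulate_phage_db(rng, n_phages=1,
                              proteins_per_phage=spec.n_phage_genes)
    return [(r.id, r.sequence) for r in synth]


# ---------------------------------------------------------------------------
# read simulation


def sample_read_origins(truth: SimulationTruth,
                        config: SimulationConfig | None = None,
                        seed: int | None = None) -> ReadOrigins:
    """Draw truth read placements for one packaged-particle experiment.

    Fragments are drawn per read (one read per fragment), which yields the
    same coverage law as multi-read fragments at much lower bookkeeping.
    """
    config = config or truth.config
    if config is None:
        raise ValueError("no SimulationConfig available")
    if config.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed if seed is not None else config.seed + 1)
    L = truth.genome.length
    rl = config.read_length

    n_unmapped = int(round(config.n_reads * config.unmapped_fraction))
    n_mapped = config.n_reads - n_unmapped
    n_bg = int(round(n_mapped * config.background_dna_fraction))
    n_frag = n_mapped - n_bg

    if config.packaging_mode == "specific":
        region = _packaged_region(truth, config)
        span = region.end - region.start + 1
        mean = config.fragment_mean or float(span)
        sd = config.fragment_sd if config.fragment_sd is not None else 0.05 * mean
        frag_len = np.clip(rng.normal(mean, sd, n_frag).round().astype(np.int64),
                           rl, span)
        room = span - frag_len + 1
        frag_start = region.start + (rng.random(n_frag) * room).astype(np.int64)
    else:
        mean = config.fragment_mean or 13_000.0
        sd = config.fragment_sd if config.fragment_sd is not None else 1_000.0
        frag_len = np.clip(rng.normal(mean, sd, n_frag).round().astype(np.int64),
                           rl, L)
        frag_start = _biased_starts(rng, n_frag, L, config.origin_bias)
        frag_start = np.minimum(frag_start, L - frag_len + 1)

    read_start = frag_start + (rng.random(n_frag)
                               * (frag_len - rl + 1)).astype(np.int64)

    bg_start = 1 + (rng.random(n_bg) * (L - rl + 1)).astype(np.int64)
    starts = np.concatenate([read_start, bg_start])
    ends = starts + rl - 1
    strands = rng.random(n_mapped) < 0.5
    is_background = np.zeros(n_mapped, dtype=bool)
    is_background[n_frag:] = True
    return ReadOrigins(starts=starts, ends=ends, strands=strands,
                       is_background=is_background, n_unmapped=n_unmapped)


def _packaged_region(truth: SimulationTruth,
                     config: SimulationConfig) -> GenomicRegion:
    if not truth.regions:
        raise ValueError("specific packaging requires at least one prophage")
    if config.packaged_region:
        for r in truth.regions:
            if r.label == config.packaged_region:
                return r
        raise ValueError(f"no region labelled {config.packaged_region!r}")
    return truth.regions[0]


def _biased_starts(rng: np.random.Generator, n: int, L: int,
                   bias: float) -> np.ndarray:
    """Fragment starts with linear origin-proximity enrichment.

    Weight falls linearly from ``bias`` at position 1 to 1.0 at the antipode
    (circular distance), emulating the multi-copy effect of an active
    replication origin.  ``bias = 1`` is uniform.
    """
    if bias <= 0:
        raise ValueError("origin_bias must be positive")
    starts_unit = rng.random(n)
    if bias == 1.0:
        return 1 + (starts_unit * L).astype(np.int64)
    nbins = 1000
    centers = (np.arange(nbins) + 0.5) / nbins          # position / L
    dist = np.minimum(centers, 1.0 - centers) * 2.0     # 0 at origin, 1 antipode
    weights = bias - (bias - 1.0) * dist
    weights /= weights.sum()
    bins = rng.choice(nbins, size=n, p=weights)
    within = rng.random(n)
    pos = (bins + within) / nbins
    return 1 + (pos * L).astype(np.int64).clip(0, L - 1)


# ---------------------------------------------------------------------------
# sequence realisation and file output


def _read_matrix(truth: SimulationTruth, origins: ReadOrigins,
                 config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """(n_reads, read_length) uint8 read sequences with errors applied.

    Rows are in read orientation (minus-strand reads reverse-complemented).
    """
    genome_arr = np.frombuffer(truth.genome.sequence.encode(), dtype=np.uint8)
    rl = config.read_length
    idx = origins.starts[:, None] - 1 + np.arange(rl)[None, :]
    reads = genome_arr[idx].copy()
    minus = ~origins.strands
    reads[minus] = _COMPLEMENT[reads[minus][:, ::-1]]
    if config.error_rate > 0:
        err = rng.random(reads.shape) < config.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        base_idx = np.searchsorted(_BASES, reads[err])
        reads[err] = _BASES[(base_idx + shift) % 4]
    return reads


def simulate_particle_reads(
    truth: SimulationTruth,
    fastq_path,
    sam_path,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> ReadOrigins:
    """Write the simulated read set as FASTQ plus a truth SAM.

    The SAM records each read's true placement (MAPQ 60, full-length match
    CIGAR); unmapped reads are random sequences with the unmapped flag set.
    Returns the origins so callers can reconcile counts and coverage.
    """
    config = config or truth.config
    if config is None:
        raise ValueError("no SimulationConfig available")
    origins = sample_read_origins(truth, config, seed=seed)
    rng = np.random.default_rng((seed if seed is not None else config.seed) + 2)
    reads = _read_matrix(truth, origins, config, rng)
    rl = config.read_length
    qual = "I" * rl
    gid = truth.genome.id

    junk = rng.choice(_BASES, size=(origins.n_unmapped, rl))

    with open(fastq_path, "w") as fq, open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        sam.write(f"@SQ\tSN:{gid}\tLN:{truth.genome.length}\n")
        sam.write("@PG\tID:prophagekit\tPN:prophagekit\n")
        for i in range(reads.shape[0]):
            name = f"read{i + 1}"
            seq = reads[i].tobytes().decode()
            fq.write(f"@{name}\n{seq}\n+\n{qual}\n")
            flag = 0 if origins.strands[i] else 16
            ref_seq = seq if origins.strands[i] else reverse_complement(seq)
            sam.write(f"{name}\t{flag}\t{gid}\t{origins.starts[i]}\t60\t"
                      f"{rl}M\t*\t0\t0\t{ref_seq}\t{qual}\n")
        for j in range(origins.n_unmapped):
            name = f"unmapped{j + 1}"
            seq = junk[j].tobytes().decode()
            fq.write(f"@{name}\n{seq}\n+\n{qual}\n")
            sam.write(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
    return origins


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of the config under a different seed."""
    return replace(config, seed=seed)
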