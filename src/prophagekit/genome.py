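"""Core genome data model: sequences, 1-based inclusive regions, GC, in-silico PCR.

Coordinates follow the GenBank convention throughout the package: 1-based,
fully closed intervals, so a region ``start..end`` has length
``end - start + 1``.  Wrapping regions (``start > end``) are only meaningful
on circular genomes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import reverse_complement

_VALID_BASES = frozenset("ACGTN")
_PRIMER_BASES = frozenset("ACGT")


class GenomeError(ValueError):
    """Raised for malformed genomes, regions or primers."""


@dataclass(frozen=True)
class Genome:
    """A single named nucleotide sequence, optionally circular.

    The sequence is stored uppercase over the alphabet ``{A, C, G, T, N}``.
    """

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise GenomeError(f"genome {self.id!r} has an empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise GenomeError(
                f"genome {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicRegion:
    """A labelled 1-based inclusive interval on a genome.

    ``start > end`` denotes a wrap-around interval across the origin and is
    only valid on circular genomes.  ``metadata`` carries per-region results
    (GC, repeats, classification, activity) accumulated by the pipeline.
    """

    label: str
    start: int
    end: int
    genome_id: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise GenomeError(
                f"region {self.label!r}: coordinates are 1-based, "
                f"got start={self.start}, end={self.end}"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    @property
    def span(self) -> int:
        """Region length in bp for the non-wrapping case."""
        if self.wraps:
            raise GenomeError(
                f"region {self.label!r} wraps the origin; its length "
                "depends on the genome (use length_on)"
            )
        return self.end - self.start + 1

    def length_on(self, genome: Genome) -> int:
        self.validate(genome)
        if self.wraps:
            return (genome.length - self.start + 1) + self.end
        return self.span

    def validate(self, genome: Genome) -> None:
        if self.end > genome.length or self.start > genome.length:
            raise GenomeError(
                f"region {self.label!r} ({self.start}..{self.end}) exceeds "
                f"genome {genome.id!r} of length {genome.length}"
            )
        if self.wraps and not genome.circular:
            raise GenomeError(
                f"region {self.label!r} wraps the origin but genome "
                f"{genome.id!r} is linear"
            )


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse PCR primer pair (5'→3' on opposite strands)."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            s = seq.upper()
            object.__setattr__(self, name, s)
            if not s:
                raise GenomeError(f"{name} primer is empty")
            bad = set(s) - _PRIMER_BASES
            if bad:
                raise GenomeError(
                    f"{name} primer contains non-ACGT characters: {sorted(bad)}"
                )


def load_genome(path: str | os.PathLike, circular: bool = False) -> Genome:
    """Read a genome from a FASTA or GenBank flat file.

    Exactly one sequence record is required; multi-record files are an error
    because every downstream coordinate refers to a single replicon.
    """
    path = os.fspath(path)
    fmt = _sniff_format(path)
    records = list(SeqIO.parse(path, fmt))
    if not records:
        raise GenomeError(f"{path}: no sequence records found ({fmt})")
    if len(records) > 1:
        raise GenomeError(
            f"{path}: {len(records)} records found; this tool operates on a "
            "single replicon"
        )
    rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq), circular=circular)


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".gb", ".gbk", ".gbff", ".genbank"}:
        return "genbank"
    if ext in {".fa", ".fasta", ".fna"}:
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "genbank" if line.startswith("LOCUS") else "fasta"
    raise GenomeError(f"{path}: empty file")


def extract_region(genome: Genome, region: GenomicRegion) -> str:
    """Return the region's sequence (1-based inclusive; wraps on circular)."""
    region.validate(genome)
    if region.wraps:
        return genome.sequence[region.start - 1 :] + genome.sequence[: region.end]
    return genome.sequence[region.start - 1 : region.end]


def gc_content(seq: str) -> float:
    """GC percentage of a nucleotide sequence, with N excluded entirely.

    N bases count in neither numerator nor denominator, so assembly gaps do
    not bias the estimate.
    """
    if not seq:
        raise GenomeError("gc_content of an empty sequence is undefined")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise GenomeError("sequence contains no unambiguous bases")
    return 100.0 * gc / (gc + at)


def in_silico_pcr(
    genome: Genome, primers: PrimerPair, max_product: int = 5000
) -> list[int]:
    """Predict PCR product lengths for a primer pair on a genome.

    Primer binding is exact-match (no mismatches).  Both template
    orientations are scanned: a product is reported wherever one primer
    matches the plus strand and the other primer's reverse complement lies
    downstream within ``max_product``.  Product length spans both primer
    5' ends inclusive.  An empty list is a valid result.
    """
    if len(primers.forward) < 10 or len(primers.reverse) < 10:
        raise GenomeError("primers must be at least 10 nt long")
    template = genome.sequence
    if genome.circular:
        # expose products spanning the origin, then deduplicate modulo length
        template = template + template[: max_product]
    products: list[int] = []
    seen: set[tuple[int, int]] = set()
    for left, right in (
        (primers.forward, reverse_complement(primers.reverse)),
        (primers.reverse, reverse_complement(primers.forward)),
    ):
        for i in _find_all(template, left):
            window_end = i + max_product
            j = template.find(right, i + len(left))
            while j != -1 and j + len(right) <= window_end:
                length = j + len(right) - i
                key = (i % genome.length, length)
                if key not in seen:
                    seen.add(key)
                    products.append(length)
                j = template.find(right, j + 1)
    return sorted(products)


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
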