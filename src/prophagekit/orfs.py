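"""Open reading frame calling on both strands (bacterial genetic code).

Start codons ATG/GTG/TTG, stop codons TAA/TAG/TGA.  For every stop codon
the longest ORF ending at it (first start after the previous in-frame stop)
is reported, mirroring how standard prokaryotic ORF scanners define maximal
ORFs.  Alternative starts translate to methionine, as in a bacterial CDS.
ORF calling treats the genome as linear; genes spanning the origin of a
circular replicon are not called.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq, reverse_complement

from .genome import Genome

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_MIN_AA = 50


@dataclass(frozen=True)
class Orf:
    """A called open reading frame; coordinates are 1-based inclusive and
    include the stop codon.  ``protein`` has the stop removed."""

    start: int
    end: int
    strand: str
    protein: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


def call_orfs(genome: Genome, min_aa: int = DEFAULT_MIN_AA) -> list[Orf]:
    """All maximal ORFs on both strands with protein length >= min_aa."""
    if min_aa < 1:
        raise ValueError("min_aa must be positive")
    L = genome.length
    orfs: list[Orf] = []
    for strand, seq in (("+", genome.sequence),
                        ("-", reverse_complement(genome.sequence))):
        for frame in range(3):
            for s, e in _scan_frame(seq, frame, min_aa):
                protein = _translate_cds(seq[s : e + 1])
                if strand == "+":
                    orfs.append(Orf(start=s + 1, end=e + 1, strand="+",
                                    protein=protein))
                else:
                    # mirror reverse-strand coordinates back to the genome
                    orfs.append(Orf(start=L - e, end=L - s, strand="-",
                                    protein=protein))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _scan_frame(seq: str, frame: int, min_aa: int):
    """Yield (start_idx, end_idx) 0-based inclusive spans including the stop."""
    pending_start = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if pending_start is not None:
                n_aa = (i - pending_start) // 3  # codons before the stop
                if n_aa >= min_aa:
                    yield pending_start, i + 2
            pending_start = None
        elif pending_start is None and codon in START_CODONS:
            pending_start = i
    # ORFs running off the sequence end lack a stop codon and are dropped


def _translate_cds(cds: str) -> str:
    """Translate an ORF (with stop) to protein, forcing an initial Met."""
    protein = str(Seq(cds[:-3]).translate(table=11))
    return "M" + protein[1:]
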