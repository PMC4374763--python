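"""Candidate prophage prediction: homology search over ORFs plus clustering.

The search stage aligns every called ORF against a phage protein database
(k-mer seeded, then global alignment) and keeps hits reaching the full-length
similarity cutoff (30% by default — the same cutoff the classification stage
uses, so prediction and classification share one score).  Hits are then
chained along the genome: consecutive hit midpoints within ``max_spacing``
(5,500 bp default) belong to one chain, and chains with at least ``min_hits``
(5 default) hits become candidate prophages spanning their first to last ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import (DEFAULT_MIN_SIMILARITY, AlignmentError, global_align,
                    kmer_index, seed_candidates)
from .genome import GenomicRegion
from .orfs import Orf

DEFAULT_MAX_SPACING = 5500
DEFAULT_MIN_HITS = 5


@dataclass(frozen=True)
class ProteinHit:
    """A surviving ORF-vs-database alignment above the similarity cutoff."""

    orf: Orf
    db_record: str
    phage: str
    family: str
    similarity: float
    score: float

    @property
    def midpoint(self) -> int:
        return self.orf.midpoint


@dataclass(frozen=True)
class CandidateProphage:
    region: GenomicRegion
    n_hits: int
    hit_ids: tuple


def search_phage_proteins(
    orfs: list[Orf],
    db,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> list[ProteinHit]:
    """All ORF/database pairs whose global alignment reaches the cutoff."""
    if not db:
        raise AlignmentError("empty phage protein database")
    index = kmer_index(db)
    hits: list[ProteinHit] = []
    for orf in orfs:
        for idx in seed_candidates(orf.protein, index):
            rec = db[idx]
            res = global_align(orf.protein, rec.sequence)
            if res.similarity >= min_similarity:
                hits.append(ProteinHit(orf=orf, db_record=rec.id,
                                       phage=rec.phage, family=rec.family,
                                       similarity=res.similarity,
                                       score=res.score))
    hits.sort(key=lambda h: (h.midpoint, h.orf.start, h.db_record))
    return hits


def cluster_hits(
    hits: list[ProteinHit],
    max_spacing: int = DEFAULT_MAX_SPACING,
    min_hits: int = DEFAULT_MIN_HITS,
    genome_id: str = "",
) -> list[CandidateProphage]:
    """Greedy midpoint chaining of hits into candidate prophage regions.

    The gap is measured midpoint-to-midpoint; clustering is strand-agnostic
    since prophage genes lie on either strand.  An ORF hit by several
    database records contributes one position per hit but a candidate spans
    ORF extents, so duplicates never widen a region.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: h.midpoint)
    chains: list[list[ProteinHit]] = [[ordered[0]]]
    for hit in ordered[1:]:
        if hit.midpoint - chains[-1][-1].midpoint <= max_spacing:
            chains[-1].append(hit)
        else:
            chains.append([hit])
    candidates = []
    for i, chain in enumerate(c for c in chains if len(c) >= min_hits):
        start = min(h.orf.start for h in chain)
        end = max(h.orf.end for h in chain)
        region = GenomicRegion(label=f"candidate_{i + 1}", start=start, end=end,
                               genome_id=genome_id)
        candidates.append(CandidateProphage(
            region=region, n_hits=len(chain),
            hit_ids=tuple(h.db_record for h in chain)))
    return candidates


def predict_prophages(
    genome,
    db,
    min_aa: int = 50,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    max_spacing: int = DEFAULT_MAX_SPACING,
    min_hits: int = DEFAULT_MIN_HITS,
) -> list[CandidateProphage]:
    """ORF calling → homology search → clustering, in one call."""
    from .orfs import call_orfs

    orfs = call_orfs(genome, min_aa=min_aa)
    hits = search_phage_proteins(orfs, db, min_similarity=min_similarity)
    return cluster_hits(hits, max_spacing=max_spacing, min_hits=min_hits,
                        genome_id=genome.id)
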