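"""Global protein alignment, best-hit classification and region comparison.

The alignment engine performs Needleman–Wunsch global alignment with affine
gaps under BLOSUM62.  Conventions follow the EMBOSS ``needle`` defaults:
gap open 10.0, gap extend 0.5 (a gap of length L costs ``10 + 0.5·L``), end
gaps free, and

* identity   = 100 × identical columns / alignment length,
* similarity = 100 × columns with a positive substitution score / alignment
  length,

both denominators including gap columns, so a short fragment aligned inside
a long subject scores a low similarity.  This "full-length" behaviour is
what makes a single ≥30% similarity cutoff meaningful for homology calls.

All-vs-all alignment is gated by a k-mer seed prefilter: two proteins are
aligned only if they share at least ``min_seeds`` distinct amino-acid
k-mers (k = 4 by default), a conservative stand-in for a BLASTP candidate
search at this scale.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ALPHABET = frozenset(str(_BLOSUM62.alphabet))

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_MIN_SIMILARITY = 30.0
SEED_K = 4
MIN_SEEDS = 2

#: similarity-score classes used in region-vs-region comparison reports
SCORE_CLASSES = (("none", 0.0, 25.0), ("low", 25.0, 50.0),
                 ("medium", 50.0, 75.0), ("high", 75.0, 100.0))
SIGNIFICANT_SCORE = 30.0


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one global pairwise protein alignment."""

    score: float
    identity: float
    similarity: float
    aligned_length: int
    full_length: bool = True


@dataclass(frozen=True)
class BestHit:
    query_id: str
    subject_id: str
    subject_phage: str
    subject_family: str
    similarity: float
    score: float = 0.0


@dataclass(frozen=True)
class RegionClassification:
    """Majority-vote assignment of a prophage region to a reference phage."""

    region_label: str
    top_phage: str
    top_fraction: float
    family_votes: dict = field(default_factory=dict)
    best_hits: tuple = ()
    n_proteins: int = 0


@dataclass(frozen=True)
class SimilarityMatrixEntry:
    region_a: str
    protein_a: str
    region_b: str
    protein_b: str
    score: float
    score_class: str
    significant: bool


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    # EMBOSS convention: a gap of length L costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    # needle default endweight=false: terminal gaps are free
    aligner.end_gap_score = 0.0
    return aligner


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise AlignmentError(f"{name}: empty protein sequence")
    seq = seq.upper()
    bad = set(seq) - _AA_ALPHABET
    if bad:
        raise AlignmentError(f"{name}: non-amino-acid characters {sorted(bad)}")
    return seq


def global_align(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two proteins (affine gaps, BLOSUM62)."""
    a = _check_protein(a, "sequence a")
    b = _check_protein(b, "sequence b")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    length = len(row_a)
    matches = 0
    positives = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            matches += 1
        if _BLOSUM62[ca, cb] > 0:
            positives += 1
    return AlignmentResult(
        score=float(aln.score),
        identity=100.0 * matches / length,
        similarity=100.0 * positives / length,
        aligned_length=length,
        full_length=True,
    )


# ---------------------------------------------------------------------------
# k-mer seeding


def kmer_index(records, k: int = SEED_K) -> dict:
    """Map each amino-acid k-mer to the indices of records containing it."""
    index: dict[str, set[int]] = defaultdict(set)
    for i, rec in enumerate(records):
        seq = rec.sequence if hasattr(rec, "sequence") else rec
        for j in range(len(seq) - k + 1):
            index[seq[j : j + k]].add(i)
    return index


def seed_candidates(query: str, index: dict, k: int = SEED_K,
                    min_seeds: int = MIN_SEEDS) -> list[int]:
    """Record indices sharing >= min_seeds distinct k-mers with the query."""
    counts: dict[int, set[str]] = defaultdict(set)
    for j in range(len(query) - k + 1):
        kmer = query[j : j + k]
        for idx in index.get(kmer, ()):
            counts[idx].add(kmer)
    return sorted(i for i, kmers in counts.items() if len(kmers) >= min_seeds)


# ---------------------------------------------------------------------------
# classification


def best_hit_for(
    query_id: str,
    query_seq: str,
    db,
    db_index: dict,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> BestHit | None:
    """Best surviving database hit for one protein, or None.

    Ties on similarity break by raw score, then subject length (longer
    first), then lexicographic subject id — a fixed chain, so permuting the
    database order never changes the result.
    """
    best: tuple | None = None
    for idx in seed_candidates(query_seq, db_index):
        rec = db[idx]
        res = global_align(query_seq, rec.sequence)
        if res.similarity < min_similarity:
            continue
        key = (res.similarity, res.score, len(rec.sequence))
        if (best is None or key > best[0]
                or (key == best[0] and rec.id < best[1].id)):
            best = (key, rec, res)
    if best is None:
        return None
    _, rec, res = best
    return BestHit(query_id=query_id, subject_id=rec.id, subject_phage=rec.phage,
                   subject_family=rec.family, similarity=res.similarity,
                   score=res.score)


def classify_region(
    region_label: str,
    region_proteins: list[tuple[str, str]],
    db,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    db_index: dict | None = None,
) -> RegionClassification:
    """Assign a region to the phage collecting the most best hits.

    ``region_proteins`` is a list of ``(protein_id, sequence)``.  The top
    fraction is computed over *all* region proteins, hit or not, so a region
    where most proteins have no phage homolog cannot be confidently assigned.
    """
    if not region_proteins:
        raise AlignmentError(f"region {region_label!r}: no proteins to classify")
    if db_index is None:
        db_index = kmer_index(db)
    hits: list[BestHit] = []
    for pid, seq in region_proteins:
        hit = best_hit_for(pid, seq, db, db_index, min_similarity)
        if hit is not None:
            hits.append(hit)
    phage_votes: dict[str, int] = defaultdict(int)
    family_votes: dict[str, int] = defaultdict(int)
    for h in hits:
        phage_votes[h.subject_phage] += 1
        if h.subject_family:
            family_votes[h.subject_family] += 1
    if phage_votes:
        top_phage = max(sorted(phage_votes), key=lambda p: phage_votes[p])
        top_fraction = 100.0 * phage_votes[top_phage] / len(region_proteins)
    else:
        top_phage, top_fraction = "unclassified", 0.0
    return RegionClassification(
        region_label=region_label,
        top_phage=top_phage,
        top_fraction=top_fraction,
        family_votes=dict(family_votes),
        best_hits=tuple(hits),
        n_proteins=len(region_proteins),
    )


def score_class(score: float) -> str:
    for name, lo, hi in SCORE_CLASSES:
        if score <= hi:
            return name
    return "high"


def compare_regions(
    regions: dict[str, list[tuple[str, str]]],
) -> list[SimilarityMatrixEntry]:
    """All-vs-all inter-region protein similarity matrix.

    For every protein of every region, the best-matching protein in each
    *other* region is found (seeded search, then global alignment) and the
    similarity is binned into the none/low/medium/high classes.  The matrix
    is directional: paralogs make A→B differ from B→A.
    """
    if len(regions) < 2:
        raise AlignmentError("compare_regions needs at least two regions")
    indexes = {label: kmer_index([s for _, s in prots])
               for label, prots in regions.items()}
    entries: list[SimilarityMatrixEntry] = []
    for label_a, prots_a in regions.items():
        for label_b, prots_b in regions.items():
            if label_b == label_a:
                continue
            idx_b = indexes[label_b]
            for pid_a, seq_a in prots_a:
                best_score = 0.0
                best_pid = ""
                for j in seed_candidates(seq_a, idx_b):
                    pid_b, seq_b = prots_b[j]
                    res = global_align(seq_a, seq_b)
                    if res.similarity > best_score:
                        best_score, best_pid = res.similarity, pid_b
                entries.append(SimilarityMatrixEntry(
                    region_a=label_a, protein_a=pid_a,
                    region_b=label_b, protein_b=best_pid,
                    score=best_score, score_class=score_class(best_score),
                    significant=best_score > SIGNIFICANT_SCORE,
                ))
    return entries
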