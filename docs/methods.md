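# Methods

This note records the models, conventions and design choices behind
`prophagekit`, and what the synthetic studies do and do not demonstrate.

## Coordinates and sequence model

All coordinates are 1-based, fully closed (GenBank convention): a region
`start..end` has length `end − start + 1`. This is validated against the
workflow's own bookkeeping — the PBSX-like region spanning
1,317,754–1,345,262 has the printed size 27,509 bp only under this
convention. Wrap-around regions (`start > end`) are permitted on circular
genomes only. Genomes are single replicons over `{A,C,G,T,N}`; multi-contig
input is rejected rather than silently concatenated. Region tables are
read natively as 1-based inclusive TSV and as BED (0-based half-open,
converted on read); all writers emit the native convention, plus optional
BED/bedGraph.

GC content excludes `N` from both numerator and denominator, so assembly
gaps do not bias the estimate. Published region tables of this kind report
repeat-flanked regions with sizes that can differ slightly from the raw
coordinate span (depending on whether the insertion repeats are counted);
`prophagekit` reports the coordinate span and leaves repeat-exclusive
arithmetic to the caller, since the repeat coordinates are part of the
output.

## In-silico PCR

Primer binding is exact-match (typical for a designed control primer pair;
mismatch tolerance would require a melting model the workflow does not
need). Both orientations are scanned; the product length spans both primer
5′ ends inclusive; `max_product` defaults to 5,000 bp. On circular genomes
the origin junction is scanned by extending the template by `max_product`
and deduplicating modulo genome length.

## Prophage prediction

ORF calling reports, for every stop codon, the longest ORF ending at it
(first ATG/GTG/TTG after the previous in-frame stop), on both strands,
minimum protein length 50 aa by default. Alternative starts translate to
Met, as in a bacterial CDS. The genome is treated as linear for ORF calling;
genes spanning the origin are out of scope.

The homology search replaces a BLASTP + E-value stage with the same score
the classification stage uses: a full-length global alignment similarity
with a ≥ 30 % cutoff, prefiltered by shared amino-acid 4-mers (≥ 2 distinct
seeds before any alignment is attempted). One consistent score across
prediction and classification keeps the two stages mutually interpretable;
the seed gate keeps all-vs-all alignment tractable at desk scale and is a
conservative superset of BLAST candidates for the similarity levels that
survive the 30 % cutoff.

Clustering chains hits whose midpoints are within 5,500 bp (midpoint
spacing is robust to ORF length), strand-agnostically, and emits chains
with ≥ 5 hits as candidates spanning the first to last hit ORF. Raising the
hit threshold can only remove candidates (tested as a property).

## Global alignment and classification

Alignment is Needleman–Wunsch with affine gaps under BLOSUM62, gap open 10,
gap extend 0.5 (a gap of length L costs 10 + 0.5·L) and free terminal gaps
— the defaults of the EMBOSS `needle` tradition. Identity and similarity
are computed over the full alignment length including gap columns
(similarity = fraction of columns with a positive substitution score), so a
fragment aligned inside a longer subject scores low: this is what makes a
single "full-length similarity ≥ 30 %" rule meaningful. The engine is
Biopython's `PairwiseAligner`; the test suite checks its scores against an
independently written quadratic-time affine-gap dynamic program on random
short pairs, and a frozen reference pair.

Best-hit ties break by raw score, then subject length, then lexicographic
subject id — an arbitrary but fixed chain, so database order never affects
results. The classification fraction is computed over *all* region
proteins (hit or not): a region whose proteins mostly lack phage homologs
cannot be confidently assigned no matter how clean its few hits are.
Region-vs-region comparison bins best similarities into none (≤ 25),
low (25–50], medium (50–75], high (> 75) classes, with > 30 flagged
significant; the matrix is directional because paralogs make best-hit
mapping asymmetric.

## Direct-repeat detection

Windows of ±500 bp around each region boundary are compared over all
diagonals; the detector returns the longest substitution-only match with
≥ 15 bp and ≤ 10 % mismatches (ties: fewest mismatches). The per-diagonal
search is exact: for each allowed mismatch count k, the longest run with
≤ k mismatches is derived from the mismatch positions, and any qualifying
window is contained in such a run, so the optimum cannot be missed; the
test suite confirms equality with an exhaustive substring-pair oracle on
small windows. One consequence of the "longest qualifying" criterion is
that a planted exact repeat is typically reported a few bases longer than
planted, with the mismatch budget absorbed by random flank positions; the
reported window always contains the att core, and reports use the
`L −m bp` notation. No gapped (indel) repeat model is attempted.

## Coverage and activity statistics

Depth counts unique-mapping reads only: unmapped reads are tallied but add
nothing, secondary/supplementary alignments are skipped, and mapping
quality 0 (the common multi-mapper signature) is excluded from depth, so
repetitive loci appear as coverage gaps rather than noise. Reference
positions are those consumed by M/=/X; insertions and clips add nothing.

NPKM normalises region coverage for region length and sequencing depth:
`(aligned nt in region / region kb) / (total aligned nt / 10^6)`. Windowed
NPKM tiles the genome from base 1; the final partial window keeps its true
length in the kb term, which makes the length-weighted sum of all window
values exactly 10^6 — a conservation identity the tests check numerically.

Signal-to-noise statistics use mean per-base depth over the merged union of
prophage bases (signal) versus the complement (noise). The mean-depth
reading (total aligned nucleotides / region size) is used rather than a
read-count reading because it preserves the internal identity
`noise% × ratio = 100` that the published statistics obey. Zero noise
yields an infinite ratio with a warning; zero signal is an error.

The activity caller compares each region's mean depth with a background
estimated as the *median* of non-region 1-kb window means — robust against
the origin-proximal coverage bulge that replication imposes on
particle-protected DNA preparations. Default thresholds: a region is
active at ≥ 10× enrichment, and the dataset is flagged
`random_packaging_suspected` when genome-wide noise% exceeds 20 %. These
sit in the wide gap between the two regimes the statistics distinguish:
random-packaging-dominated datasets show ratios near 2 (noise ≈ 40 %),
while specific packaging shows ratios from ~25 upwards (noise ≤ 4 %). Both
thresholds are exposed as options.

## Simulator

The generator draws a background chromosome with i.i.d. bases at the
configured GC (default 46.2 %, a typical *Bacillus* value), then overwrites
each prophage interval with sequence at its own GC, plants a direct repeat
at the two boundaries (the right copy optionally carrying substitutions),
and inserts a cassette of phage genes: database proteins mutated at 10 %
amino-acid substitution by default and back-translated with uniform
synonymous codons (simplicity; region GC is controlled at the region
level, so heavily gene-loaded regions land near the ~50 % GC of uniform
codons rather than the configured region GC — GC-focused tests therefore
plant gene-free regions).

Reads (default 100 nt, matching the short-read platforms such assays use)
derive from fragments drawn per read: in `specific` mode fragments span the
designated prophage (mean ≈ region length, i.e. whole-genome packaging
without circular permutation); in `random_13kb` mode fragments of mean
13 kb are placed genome-wide, optionally with a linear origin-proximity
weight falling from a configured fold at position 1 to 1.0 at the antipode
of the circular map (the literature states only that origin-proximal
coverage is elevated; a linear decay in circular distance is the simplest
shape with one parameter). A configurable fraction of reads (default 2 %)
is uniform background host DNA — residual free DNA after nuclease
treatment — and an optional fraction is unmappable junk. Per-base
substitution errors default to 1 % and are capped at 2 %, the divergence a
short-read mapper tolerates. No indel errors, quality models or paired
ends are simulated. Everything is deterministic given the seed; truth SAM
and FASTQ reconcile with the recorded origins, and the direct-interval
coverage path is asserted equal to the SAM round trip.

## Study designs in the acceptance script

*Specific packaging recovery*: 20 seeds × (500-kb genome, one 40-kb
prophage, 50k reads, defaults as above); the caller must mark the planted
region active and three decoy control regions inactive — sensitivity and
specificity 1.0.

*Mixed random packaging*: the wild-type situation is a superposition of a
PBSX-like element packaging random 13-kb fragments genome-wide and a
co-resident phage packaging its own locus; its published signal-to-noise
ratios sit near 2.3–2.6 precisely because a majority of packaged DNA still
maps inside prophage annotations. The desk-scale analogue plants four
50-kb prophages on a 500-kb host (40 % prophage content), draws two thirds
of 50k reads as random 13-kb fragments (origin bias 2×) and one third as
specific packaging of the first prophage, so ~60 % of packaged DNA falls
inside prophage regions by construction. The expected ratio is
(0.6/0.4)/(0.4/0.6) ≈ 2.25; across 20 seeds the measured ratios must stay
within [1.5, 4] and every run must raise the random-packaging flag.

These studies show that the statistics and caller behave correctly under
the generative model they assume (uniform fragment placement, substitution
errors, known truth). They do not demonstrate performance on real
preparations, where library bias, in-situ replication tails downstream of
an induced prophage, and mapper artefacts add structure the simulator does
not emulate.

## Known limitations

Single replicon per run; no tRNA-integration-site detection; no BLAST
statistics (E-values/bit-scores) and no HMM remote homology; repeat
detection is ungapped; ORFs spanning a circular origin are not called; the
activity model reports enrichment ratios, not significance tests.
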