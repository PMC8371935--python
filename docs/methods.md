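# Methods

This note records the models, parameter choices and numerical conventions
behind `melcensus`, and what the synthetic benchmark does and does not
establish about real data.

## Translated search

The search is a self-contained functional equivalent of a tBLASTn scan.
All six frames of each contig are translated once per genome (assembly
`N`s become `X` and never count as identities). Seeding uses exact protein
4-mers with BLAST-style two-hit triggering: a diagonal is extended only
when two seed hits co-occur within a 40 aa window. Triggered diagonals
within 16 of each other share one extension, a full affine Smith–Waterman
(BLOSUM62, gap open 11 / extend 1) confined to a ±32 band around the seed
diagonals. The band matters twice over: it keeps extensions from bridging
introns with garbage columns (intron-induced diagonal shifts of 40+ aa lie
far outside it), and it makes per-exon HSPs clean enough that chained
regions report exon-level identity rather than intron-diluted identity.
Within the band the extension is exhaustive, so on intronless instances
the chained score equals the full six-frame Smith–Waterman optimum
(verified against Biopython's aligner).

Statistics use the standard gapped BLOSUM62(11,1) Karlin–Altschul pair
λ = 0.267, K = 0.041; bit score S′ = (λS − ln K)/ln 2 and
E = m · n · 2^(−S′) with n = 2 × genome length (six frames of length
L/3). HSPs with E ≤ `evalue_max` (default 10⁻⁵) enter chaining.

Chaining is greedy by descending score. An HSP joins a chain when contig
and strand match, query intervals progress with ≤ 10 aa overlap, and the
genomic gap is ≤ `max_intron_len` (20 kb; ≤ 30 bp genomic overlap
allowed). Local alignments at exon ends occasionally wander a few residues
past the splice site; when that pushes the query overlap beyond 10 aa the
incoming HSP's overlapping end is trimmed at match-column boundaries
(scores re-derived from the trimmed alignment) rather than discarded —
the standard chainer remedy. Region identity counts identities over all
alignment columns including gaps; "aligned ratio" is interpreted as query
coverage, the fraction of query residues aligned. Both conventions are
stated because reporting tools differ.

The accept/rescue/reject rule: accepted iff identity ≥ 50 % and coverage
≥ 50 %; else rescued iff both ≥ 45 % and the gene model is complete
(all five completeness flags); else rejected. The rescue window exists
because rapidly evolving family members can fall just below the headline
cutoff while still having a full-length, intact structure.

Loss verification re-runs the search with 3-mer seeds, a 60 aa two-hit
window and E ≤ 10⁻², excluding loci already assigned to other genes (a
paralog is not evidence against loss of its sister). A gene is reported
lost only when nothing ≥ 30 % identity survives; otherwise the surviving
candidate is reported so the call is auditable.

## Spliced gene modeling

The gene model DP has four state families per (query residue, DNA
position) cell: codon match, residue insertion/deletion (affine,
12 + 1 per column, matching the search scoring), and an intron state
enterable at `GT` and exitable at `AG` with a fixed opening cost of 40,
minimum length 30 bp and no per-base cost. Introns are phase-0 only
(codon-boundary): the generator plants phase-0 introns, so this is
lossless for the benchmark; phase-1/2 introns in real genes would be
modeled as slightly shifted boundaries. Codon boundaries may additionally
slip by ±1–2 bp at a frameshift penalty of 30, the device (shared with
GeneWise-class tools) that lets a model continue through a pseudogenic
indel instead of truncating at it — essential, because a truncated model
would hide the very frame remainder the pseudogene scanner needs.

Two cost interactions fix two other defaults. First, an intron of length
3k can also be crossed as k codon gaps at cost 12 + (k−1); with intron
open 40 this is cheaper for introns ≤ 87 bp, so the generator's intron
floor is 120 bp, keeping the intron state strictly preferred. Second,
an indel within ~5 codons of a splice site can be absorbed by shifting
the splice site 1–2 bp (cost ≈ 7 per misread codon, crossing the
frameshift penalty of 30 at ~5 codons); such lesions are formally
unidentifiable from shifted splicing by any sequence-based method, so the
generator plants indels ≥ 7 codons interior to exons (see below).

After traceback the model extends up to 90 bp beyond the aligned span in
each direction to capture the initiator ATG and the terminal stop (the
stop codon is included in the CDS). Completeness is five flags —
has_start, has_terminal_stop, no_internal_stop, no_frameshift,
canonical_splice_sites — with notes per failure; exons touching within
3 bp of a contig end add a `contig_edge` note and never claim a terminal
stop they cannot show. Ties in the DP resolve toward fewer introns and
leftmost placement via the fixed transition evaluation order, making
models deterministic.

A plain-Python reference DP implementing the identical model (re-derived
from this description, no shared code with the numba kernel) reproduces
kernel scores exactly on randomized instances; that equivalence is part
of the test suite.

## Pseudogene classification

Candidate CDS are compared to reference CDS through a protein-guided
codon alignment: global protein alignment (BLOSUM62, open 10 / extend 1),
expanded to whole-codon columns; a 1–2 bp frame remainder of the target
is kept aside so degapping reproduces the input byte-for-byte.

*Premature stop*: first in-frame target stop strictly upstream of the
reference terminal stop column (or reference end). Stops downstream of a
frameshift are artifacts of reading a shifted frame and are ignored.
Near-terminal stops are still reported; `truncation_fraction` (reference
codons at/after the lesion over total) lets consumers discount them,
since no principled minimum-truncation threshold exists.

*Frameshift*: diagnosed from the CDS length remainder mod 3 and located
at nucleotide level with an affine-gap DNA alignment (match +2, mismatch
−3, gap 7 + 2 per column). The affine costs are load-bearing: a unit-cost
edit distance will happily place compensating 1 bp indel pairs wherever
they save a mismatch, scattering phantom frameshifts through ordinary
point divergence; with gaps priced well above substitutions an indel is
placed only when decisively better. For a single small indel the
placement is then refined by an exact scan over all breakpoints; among
score-tied placements (repeats flanked by substitutions make ties
inevitable) a codon-boundary position is preferred as the canonical
representative of a codon-granular report. Two frame-breaking runs with a
net-zero remainder are reported as a compensated frameshift with a note.
Copies covering < 60 % of reference codons with no lesion are `partial`.

Lesions are reported by 0-based target codon index and 1-based exon
ordinal in transcription order of the copy's own gene model (a codon
spanning a junction belongs to the exon holding its first base). The
exon-numbering convention is model-based, not reference-based, because
the lesion physically resides in the carrier's exon.

## Orthology, census, trees

Each copy is labeled with the highest-identity reference paralog of its
family (global alignment identity over all columns). When the top two
references are within 3 percentage points, flanking-marker (synteny)
agreement votes; because the pre-duplication locus shares its markers
with the a-locus by descent, a flank tie falls back to identity rank, and
`ambiguous` is reserved for copies tied on both criteria. Ambiguous
copies count in totals but never inflate a specific paralog column.

The census matrix counts accepted + rescued copies per (species, label)
with pseudogene subcounts (`premature_stop`, `frameshift`, or both);
cells render "N" or "N (k)". Lineage aggregation sums by taxonomic class
with species counts.

Trees are distance-based by design: maximum-likelihood inference with
invariant sites and Γ rate heterogeneity is a project of its own, and the
census conclusions read off the trees — duplication-clade monophyly,
copy placement — are recoverable from distances at the divergences the
pipeline operates on. Intact copies only are used (frameshifted proteins
are garbage downstream of the lesion and distort distances). The multiple
alignment is progressive: pairwise Kimura distances
(d = −ln(1 − p − 0.2p²), capped at 10 beyond the formula's domain edge
p ≈ 0.8537), average-linkage guide tree, profile–profile merges under
sum-of-pairs BLOSUM62. Columns > 90 % gaps are trimmed (a conservative
threshold that cannot delete pairwise lesion evidence). Neighbor joining
uses the canonical Q criterion with lexicographic tie-breaking; trees are
rooted on the designated outgroup's copy or, when that species lost the
family, on any copy bearing the pre-duplication (unsuffixed) label, which
sits outside the WGD split by construction. Bootstraps resample columns;
replicate r is seeded `seed + r`, so supports are reproducible and
streams are parallel-safe. Adapters export trimmed alignments
(PHYLIP/FASTA) for external ML tools and import tabular hits from an
external translated-search tool; both are conveniences for real-data use
outside the tested surface.

## The synthetic benchmark

The generator emulates the statistical structure the census assumes:
species related by a known tree (branch lengths in substitutions/site), a
WGD on one clade's stem producing a/b pairs (each post-duplication copy
gets 0.05 extra stem divergence, separating the a/b references by enough
that identity margins are decisive), intron-containing genes evolving by
codon-position-aware point mutation (relative mutabilities 0.7/0.3/2.0
across codon positions — third positions are often synonymous — with
start/stop protected and in-frame stops resampled), species-specific
lesions on terminal branches (50 % stop point mutations, 25 % 1 bp
indels, 25 % 2 bp indels), whole-gene losses, and two conserved flanking
marker genes (60 codons, half rate) on each side of every locus, with the
b-locus carrying its own marker set. Defaults for the `benchmark`
benchmark: 12 species (six-species duplicated clade, five tetrapods, one
outgroup), six families (four duplicated), 4–6 exons of 40–80 codons,
introns 120–300 bp, p(pseudogene) = p(loss) = 0.1 per copy per species,
terminal divergences ≤ 0.1 substitutions/site. Everything derives from
one seed; a fixed seed reproduces genomes, truth and pipeline outputs
byte-for-byte.

Two placement rules encode identifiability limits rather than
convenience: indels are planted at codon boundaries ≥ 7 codons from
splice junctions (closer ones cannot be distinguished from 1–2 bp splice
shifts; the radius follows from the scoring arithmetic above), and
lesions sit ≥ 5 codons from the CDS termini.

What passing the benchmark does *not* show about real data: there is no
indel evolution outside planted lesions, no rate heterogeneity among
sites, no gene conversion between paralogs, no assembly error or gaps,
no non-canonical or phase-1/2 splicing, no tandem duplication, and every
locus sits on its own contig. Real assemblies will add false splits and
joins that this benchmark cannot expose; the benchmark establishes
algorithmic correctness under the model, not robustness to assembly
artifacts.

## Problem sizes and numerics

The shipped benchmark uses ~40 kb genomes per species (one locus per
contig), chosen so a complete census run with 100 bootstrap replicates
finishes in about a minute on one core while still containing ~96 gene
copies, ~13 lesions and ~13 losses. Oracle comparisons run on 50 search
instances (≤ 200 aa × ≤ 5 kb) and 30 spliced instances (≤ 100 aa ×
2 kb). All alignment scores are integers; distances and supports are
floats; every tie in every stage (HSP ordering, chaining, DP traceback,
Q-criterion, label assignment) has a stated deterministic resolution, and
the full pipeline is byte-reproducible for a fixed seed.
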