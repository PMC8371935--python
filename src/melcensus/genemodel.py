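"""Spliced gene-structure reconstruction within accepted hit regions.

The dynamic program aligns a reference protein to genomic DNA with states
for codon matches, residue insertions/deletions, and an intron state that
can only be entered at a GT donor and left at an AG acceptor (phase-0
introns, fixed opening cost, minimum length 30 bp).  Codon boundaries may
additionally slip by 1-2 bp at a frameshift penalty so that pseudogenic
indels do not truncate the model; slip events are recorded so completeness
can be assessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core_io import GenomeRecord, PipelineConfig, is_stop_codon, reverse_complement, translate
from .scoring import BLOSUM62, GAP_EXT, GAP_OPEN, AA_INDEX, encode_protein

INTRON_OPEN = 40
FRAMESHIFT_PENALTY = 30
MIN_INTRON = 30
TERMINUS_SCAN_BP = 90
FLANK_BP = 2000

_COMPLETENESS_FLAGS = (
    "has_start",
    "has_terminal_stop",
    "no_internal_stop",
    "no_frameshift",
    "canonical_splice_sites",
)


@dataclass
class GeneModel:
    """A reconstructed exon/intron gene structure on one contig."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # forward coords, 0-based half-open, sorted
    cds: str
    protein: str
    q_aln: str
    t_aln: str
    score: int
    identity_to_query: float
    fs_events: list[tuple[int, int]] = field(default_factory=list)  # (cds codon idx, bp delta)
    notes: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class CompletenessReport:
    has_start: bool
    has_terminal_stop: bool
    no_internal_stop: bool
    no_frameshift: bool
    canonical_splice_sites: bool
    notes: list[str] = field(default_factory=list)

    @property
    def overall_complete(self) -> bool:
        return all(getattr(self, f) for f in _COMPLETENESS_FLAGS)


def _prepare_dna(dna: str):
    """Pre-compute per-position codon translations and splice-site masks."""
    m = len(dna)
    aa_at = np.full(m + 1, -1, dtype=np.int8)
    x = AA_INDEX["X"]
    for j in range(3, m + 1):
        aa_at[j] = AA_INDEX.get(translate(dna[j - 3 : j]) or "X", x)
    donor = np.zeros(m + 1, dtype=np.bool_)
    acceptor = np.zeros(m + 1, dtype=np.bool_)
    for j in range(m - 1):
        if dna[j] == "G" and dna[j + 1] == "T":
            donor[j] = True
    for j in range(2, m + 1):
        if dna[j - 2] == "A" and dna[j - 1] == "G":
            acceptor[j] = True
    return aa_at, donor, acceptor


def spliced_align(
    query: str, region_dna: str, config: PipelineConfig, gene_id: str = "model"
) -> GeneModel | None:
    """Align ``query`` to ``region_dna`` (transcription orientation).

    Returns the highest-scoring local spliced model in region-local
    coordinates on strand '+', or None when nothing scores above zero.
    """
    if len(query) < 15:
        raise ValueError("query shorter than 15 aa")
    dna = region_dna.upper()
    aa_at, donor, acceptor = _prepare_dna(dna)
    qidx = encode_protein(query)
    score, nev, ev_type, ev_i, ev_j, ev_k = _kernels.spliced_sw(
        qidx,
        aa_at,
        donor,
        acceptor,
        BLOSUM62,
        GAP_OPEN + GAP_EXT,
        GAP_EXT,
        INTRON_OPEN,
        FRAMESHIFT_PENALTY,
        MIN_INTRON,
    )
    if nev == 0 or score <= 0:
        return None
    events = [
        (int(ev_type[a]), int(ev_i[a]), int(ev_j[a]), int(ev_k[a]))
        for a in range(nev - 1, -1, -1)
    ]
    # reconstruct exons, alignment strings and frameshift events
    first = events[0]  # a local alignment always starts on a codon match
    cur_start = first[2] - first[3] if first[0] == _kernels.EV_MATCH else first[2]
    exons: list[tuple[int, int]] = []
    q_aln: list[str] = []
    t_aln: list[str] = []
    fs_events: list[tuple[int, int]] = []
    consumed = 0  # bases of CDS emitted so far
    for etype, i, j, kk in events:
        if etype == _kernels.EV_MATCH:
            d = kk
            q_aln.append(query[i])
            t_aln.append(translate(dna[j - 3 : j]) or "X")
            if d != 3:
                fs_events.append((consumed // 3, d - 3))
            consumed += d
        elif etype == _kernels.EV_QGAP:
            q_aln.append(query[i])
            t_aln.append("-")
        elif etype == _kernels.EV_TGAP:
            q_aln.append("-")
            t_aln.append(translate(dna[j - 3 : j]) or "X")
            consumed += 3
        else:  # intron: close exon at donor kk, reopen at acceptor j
            exons.append((cur_start, kk))
            cur_start = j
    last_j = events[-1][2]
    exons.append((cur_start, last_j))
    exons = [e for e in exons if e[1] > e[0]]
    cds = "".join(dna[s:e] for s, e in exons)
    model = GeneModel(
        gene_id,
        "region",
        "+",
        exons,
        cds,
        translate(cds),
        "".join(q_aln),
        "".join(t_aln),
        int(score),
        _aln_identity("".join(q_aln), "".join(t_aln)),
        fs_events,
    )
    _extend_termini(model, dna)
    return model


def _aln_identity(qa: str, ta: str) -> float:
    if not qa:
        return 0.0
    matches = sum(1 for a, b in zip(qa, ta) if a == b and a not in ("-", "X"))
    return 100.0 * matches / len(qa)


def _extend_termini(model: GeneModel, dna: str) -> None:
    """Extend the model up to 90 bp each way to capture the ATG and stop codon."""
    s0, e0 = model.exons[0]
    # upstream: nearest in-frame ATG, stopping at any in-frame stop
    if not model.protein.startswith("M"):
        pos = s0 - 3
        while pos >= 0 and s0 - pos <= TERMINUS_SCAN_BP:
            codon = dna[pos : pos + 3]
            if is_stop_codon(codon):
                break
            if codon == "ATG":
                model.exons[0] = (pos, e0)
                break
            pos -= 3
    # downstream: first in-frame stop codon
    s1, e1 = model.exons[-1]
    pos = e1
    while pos + 3 <= len(dna) and pos - e1 < TERMINUS_SCAN_BP:
        codon = dna[pos : pos + 3]
        if is_stop_codon(codon):
            model.exons[-1] = (s1, pos + 3)
            break
        pos += 3
    model.cds = "".join(dna[s:e] for s, e in model.exons)
    model.protein = translate(model.cds)


def assess_completeness(model: GeneModel, at_contig_edge: bool = False) -> CompletenessReport:
    """Evaluate the five completeness flags of a gene model (pure function)."""
    protein = model.protein
    cds = model.cds
    has_start = protein.startswith("M")
    has_terminal_stop = len(cds) % 3 == 0 and len(cds) >= 3 and is_stop_codon(cds[-3:])
    interior = protein[:-1] if has_terminal_stop else protein
    no_internal_stop = "*" not in interior
    no_frameshift = len(cds) % 3 == 0 and not model.fs_events
    canonical = _canonical_splice(model)
    notes = []
    if not has_start:
        notes.append("no in-frame ATG at model start")
    if not has_terminal_stop:
        notes.append("no terminal stop codon")
    if not no_internal_stop:
        notes.append("premature stop codon in translation")
    if not no_frameshift:
        notes.append(f"frameshift: CDS length {len(cds)} % 3 != 0 or indel slip in alignment")
    if not canonical:
        notes.append("non-canonical splice site")
    if at_contig_edge:
        notes.append("contig_edge")
    report = CompletenessReport(
        has_start, has_terminal_stop, no_internal_stop, no_frameshift, canonical, notes
    )
    if at_contig_edge:
        report.has_terminal_stop = report.has_terminal_stop and len(model.cds) >= 3
    return report


def _canonical_splice(model: GeneModel) -> bool:
    # splice sites are enforced by the DP; models built elsewhere carry a note
    return "non_canonical_splice" not in model.notes


def extract_cds(model: GeneModel, genome: GenomeRecord) -> str:
    """Concatenate exon sequences in transcription order from the genome."""
    contig = genome.contigs.get(model.contig)
    if contig is None:
        raise ValueError(f"contig {model.contig!r} not in genome {genome.species}")
    for s, e in model.exons:
        if not (0 <= s < e <= len(contig)):
            raise ValueError(f"exon ({s},{e}) out of bounds for contig {model.contig}")
    parts = [contig[s:e] for s, e in sorted(model.exons)]
    if model.strand == "+":
        return "".join(parts)
    return reverse_complement("".join(parts))


def model_region(
    query: str,
    genome: GenomeRecord,
    region,
    config: PipelineConfig,
    gene_id: str = "model",
) -> GeneModel | None:
    """Build a gene model for a hit region (envelope +- 2 kb, strand-aware)."""
    contig = genome.contigs[region.contig]
    lo = max(0, region.g_start - FLANK_BP)
    hi = min(len(contig), region.g_end + FLANK_BP)
    window = contig[lo:hi]
    if region.strand == "-":
        window = reverse_complement(window)
    model = spliced_align(query, window, config, gene_id)
    if model is None:
        return None
    # map region-local exon coords back to forward contig coordinates
    if region.strand == "+":
        exons = [(lo + s, lo + e) for s, e in model.exons]
    else:
        W = len(window)
        exons = sorted((lo + W - e, lo + W - s) for s, e in model.exons)
    model.contig = region.contig
    model.strand = region.strand
    model.exons = exons
    if model.span[0] < 3 or model.span[1] > len(contig) - 3:
        model.notes.append("contig_edge")
    return model
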