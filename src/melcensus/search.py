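"""Translated homology search: locate candidate gene loci with protein queries.

A self-contained functional equivalent of a tBLASTn scan: all six reading
frames of each contig are translated, exact protein k-mer seeds (k=4) with
two-hit triggering select candidate diagonals, and each triggered diagonal
window is extended by a full affine-gap Smith-Waterman restricted to that
window (BLOSUM62, gap open 11 / extend 1).  High-scoring segment pairs
(HSPs) passing the E-value threshold are chained into colinear best-hit
regions, which the census filter then accepts (>=50% identity and query
coverage), rescues (45-50% with a complete gene structure) or rejects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core_io import GenomeRecord, PipelineConfig, reverse_complement, translate
from .scoring import (
    BLOSUM62,
    GAP_EXT,
    GAP_OPEN,
    GAPPED_K,
    GAPPED_LAMBDA,
    bit_score,
    encode_protein,
)

MIN_QUERY_LEN = 15
SEED_K = 4
TWO_HIT_WINDOW = 40
DIAG_MERGE = 16
BAND = 32  # extension half-band around the seed diagonals
MAX_QUERY_OVERLAP = 10  # aa overlap allowed between chained HSPs
MAX_GENOMIC_OVERLAP = 30  # bp


@dataclass
class Hsp:
    """One gapped local alignment between the query and a translated frame."""

    contig: str
    strand: str
    frame: int  # offset 0..2 within the strand
    g_start: int  # forward-strand genomic coords, 0-based half-open
    g_end: int
    q_start: int
    q_end: int
    raw_score: int
    bit_score: float
    evalue: float
    q_aln: str
    t_aln: str

    @property
    def n_columns(self) -> int:
        return len(self.q_aln)

    @property
    def n_identities(self) -> int:
        return sum(
            1 for a, b in zip(self.q_aln, self.t_aln) if a == b and a not in ("-", "X")
        )


@dataclass
class HitRegion:
    """A chained, colinear set of HSPs marking one candidate gene locus."""

    contig: str
    strand: str
    hsps: list[Hsp]
    query_id: str
    query_len: int
    status: str | None = None

    @property
    def g_start(self) -> int:
        return min(h.g_start for h in self.hsps)

    @property
    def g_end(self) -> int:
        return max(h.g_end for h in self.hsps)

    @property
    def raw_score(self) -> int:
        return sum(h.raw_score for h in self.hsps)

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.hsps)

    @property
    def identity_pct(self) -> float:
        cols = sum(h.n_columns for h in self.hsps)
        idents = sum(h.n_identities for h in self.hsps)
        return 100.0 * idents / cols if cols else 0.0

    @property
    def coverage_pct(self) -> float:
        covered: set[int] = set()
        for h in self.hsps:
            covered.update(range(h.q_start, h.q_end))
        return 100.0 * len(covered) / self.query_len if self.query_len else 0.0


@dataclass
class AbsenceReport:
    """Audit record of the relaxed-threshold re-scan behind a loss call."""

    query_id: str
    species: str
    lost: bool
    best_identity: float
    best_coverage: float
    best_region: HitRegion | None
    note: str


def evalue(bits: float, query_len: int, genome_len: int) -> float:
    """Karlin-Altschul expectation: E = m * n * 2^-bits.

    The search space n is the translated genome size over all six frames,
    genome_len/3 per frame, i.e. 2 * genome_len.
    """
    if query_len <= 0 or genome_len <= 0:
        raise ValueError("lengths must be positive")
    return query_len * (2.0 * genome_len) * math.pow(2.0, -bits)


class SearchEngine:
    """Six-frame translation and k-mer index of one genome, reused per query."""

    def __init__(self, genome: GenomeRecord, config: PipelineConfig):
        self.genome = genome
        self.config = config
        self.contig_ids = sorted(genome.contigs)
        self.frames: list[list[tuple[str, np.ndarray]]] = []
        for cid in self.contig_ids:
            seq = genome.contigs[cid]
            rc = reverse_complement(seq)
            per_contig = []
            for src in (seq, rc):
                for off in range(3):
                    tr = translate(src, off, config.genetic_code)
                    per_contig.append((tr, encode_protein(tr)))
            self.frames.append(per_contig)
        self._indexes: dict[int, dict[str, list[tuple[int, int, int]]]] = {}

    def _index(self, k: int) -> dict[str, list[tuple[int, int, int]]]:
        idx = self._indexes.get(k)
        if idx is None:
            idx = {}
            for ci, per_contig in enumerate(self.frames):
                for fi, (tr, _) in enumerate(per_contig):
                    for p in range(len(tr) - k + 1):
                        idx.setdefault(tr[p : p + k], []).append((ci, fi, p))
            self._indexes[k] = idx
        return idx

    def search(
        self,
        query: str,
        k: int = SEED_K,
        evalue_max: float | None = None,
        two_hit_window: int = TWO_HIT_WINDOW,
    ) -> list[Hsp]:
        if len(query) < max(MIN_QUERY_LEN, k):
            raise ValueError(f"query shorter than {MIN_QUERY_LEN} aa")
        if evalue_max is None:
            evalue_max = self.config.evalue_max
        qidx = encode_protein(query)
        n = len(query)
        index = self._index(k)
        # gather seeds per (contig, frame)
        seeds: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for p in range(n - k + 1):
            for ci, fi, tp in index.get(query[p : p + k], ()):
                seeds.setdefault((ci, fi), []).append((tp - p, tp))
        genome_len = self.genome.total_length
        hsps: list[Hsp] = []
        for (ci, fi), dlist in sorted(seeds.items()):
            tr, tidx = self.frames[ci][fi]
            # diagonals passing the two-hit rule
            dlist.sort()
            trig: list[int] = []
            for a in range(len(dlist)):
                d, tp = dlist[a]
                for b in range(a + 1, len(dlist)):
                    d2, tp2 = dlist[b]
                    if d2 != d:
                        break
                    if 0 < tp2 - tp <= two_hit_window:
                        trig.append(d)
                        break
            if not trig:
                continue
            # merge triggered diagonals into extension windows
            trig = sorted(set(trig))
            clusters: list[list[int]] = [[trig[0]]]
            for d in trig[1:]:
                if d - clusters[-1][-1] <= DIAG_MERGE:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            for cl in clusters:
                t_lo = max(0, cl[0] - BAND - 1)
                t_hi = min(len(tr), cl[-1] + n + BAND + 1)
                if t_hi - t_lo < k:
                    continue
                score, npath, pi, pj = _kernels.sw_affine_banded(
                    qidx,
                    tidx[t_lo:t_hi],
                    BLOSUM62,
                    GAP_OPEN + GAP_EXT,
                    GAP_EXT,
                    cl[0] - t_lo - BAND,
                    cl[-1] - t_lo + BAND,
                )
                if score <= 0 or npath == 0:
                    continue
                bits = bit_score(score)
                ev = evalue(bits, n, genome_len)
                if ev > evalue_max:
                    continue
                qa = "".join(query[i] if i >= 0 else "-" for i in pi[:npath])
                ta = "".join(tr[t_lo + j] if j >= 0 else "-" for j in pj[:npath])
                qs = int(min(i for i in pi[:npath] if i >= 0))
                qe = int(max(i for i in pi[:npath] if i >= 0)) + 1
                ts = int(t_lo + min(j for j in pj[:npath] if j >= 0))
                te = int(t_lo + max(j for j in pj[:npath] if j >= 0)) + 1
                hsps.append(
                    self._make_hsp(ci, fi, qs, qe, ts, te, int(score), bits, ev, qa, ta)
                )
        return _dedup(hsps)

    def _make_hsp(self, ci, fi, qs, qe, ts, te, score, bits, ev, qa, ta) -> Hsp:
        cid = self.contig_ids[ci]
        L = len(self.genome.contigs[cid])
        off = fi % 3
        if fi < 3:
            strand = "+"
            g0, g1 = off + 3 * ts, off + 3 * te
        else:
            strand = "-"
            g0, g1 = L - off - 3 * te, L - off - 3 * ts
        return Hsp(cid, strand, off, g0, g1, qs, qe, score, bits, ev, qa, ta)


def _dedup(hsps: list[Hsp]) -> list[Hsp]:
    """Drop HSPs essentially contained in a higher-scoring one on the same frame."""
    hsps = sorted(
        hsps, key=lambda h: (-h.raw_score, h.contig, h.strand, h.g_start, h.q_start)
    )
    kept: list[Hsp] = []
    for h in hsps:
        redundant = False
        for other in kept:
            if (h.contig, h.strand, h.frame) != (other.contig, other.strand, other.frame):
                continue
            qo = min(h.q_end, other.q_end) - max(h.q_start, other.q_start)
            go = min(h.g_end, other.g_end) - max(h.g_start, other.g_start)
            if qo >= 0.8 * (h.q_end - h.q_start) and go >= 0.8 * (h.g_end - h.g_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def seed_and_extend(query: str, genome: GenomeRecord, config: PipelineConfig) -> list[Hsp]:
    """One-shot search (builds a fresh :class:`SearchEngine`)."""
    return SearchEngine(genome, config).search(query)


def import_tabular_hits(path, query_lengths: dict[str, int]) -> dict[str, list[Hsp]]:
    """Adapter: load hits from an external translated-search tool.

    Expects BLAST-style tabular columns (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore, 1-based inclusive
    coordinates).  Alignment strings are unavailable in this format, so the
    returned HSPs carry placeholder alignments scaled to the reported
    identity; intended for driving the modeling stages on real data, not for
    the test surface.
    """
    hits: dict[str, list[Hsp]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            c = line.rstrip("\n").split("\t")
            qid, sid = c[0], c[1]
            pident, length = float(c[2]), int(c[3])
            qs, qe = int(c[6]) - 1, int(c[7])
            ss, se = int(c[8]), int(c[9])
            ev, bits = float(c[10]), float(c[11])
            strand = "+" if se >= ss else "-"
            g0, g1 = (ss - 1, se) if strand == "+" else (se - 1, ss)
            nid = round(length * pident / 100.0)
            qa = "A" * nid + "R" * (length - nid)
            ta = "A" * length
            raw = int(round((bits * math.log(2) + math.log(GAPPED_K)) / GAPPED_LAMBDA))
            hits.setdefault(qid, []).append(
                Hsp(sid, strand, 0, g0, g1, qs, qe, raw, bits, ev, qa, ta)
            )
    return hits


def _column_scores(q_aln: str, t_aln: str) -> list[int]:
    """Per-column scores of an HSP alignment (affine gaps, open on first col)."""
    from .scoring import AA_INDEX

    out = []
    in_gap = False
    for qa, ta in zip(q_aln, t_aln):
        if qa == "-" or ta == "-":
            out.append(-(GAP_EXT if in_gap else GAP_OPEN + GAP_EXT))
            in_gap = True
        else:
            out.append(int(BLOSUM62[AA_INDEX[qa], AA_INDEX[ta]]))
            in_gap = False
    return out


def _trim_hsp(h: Hsp, *, new_q_start: int | None = None, new_q_end: int | None = None) -> Hsp | None:
    """Copy of ``h`` with leading/trailing columns removed so its query
    interval fits inside [new_q_start, new_q_end); returns None if nothing
    with positive score remains.  Trims always end on a match column."""
    cols = list(zip(h.q_aln, h.t_aln, _column_scores(h.q_aln, h.t_aln)))
    lo, hi = 0, len(cols)
    q = h.q_start
    t_removed_front = 0
    if new_q_start is not None:
        while lo < hi and (q < new_q_start or "-" in cols[lo][:2]):
            qa, ta, _ = cols[lo]
            if qa != "-":
                q += 1
            if ta != "-":
                t_removed_front += 1
            lo += 1
    q_end = h.q_end
    t_removed_back = 0
    if new_q_end is not None:
        while hi > lo and (q_end > new_q_end or "-" in cols[hi - 1][:2]):
            qa, ta, _ = cols[hi - 1]
            if qa != "-":
                q_end -= 1
            if ta != "-":
                t_removed_back += 1
            hi -= 1
    if hi <= lo:
        return None
    score = sum(c[2] for c in cols[lo:hi])
    # re-open any gap that became leading after the cut was skipped above,
    # so the remaining alignment re-scores exactly
    if score <= 0:
        return None
    if h.strand == "+":
        g0 = h.g_start + 3 * t_removed_front
        g1 = h.g_end - 3 * t_removed_back
    else:
        g0 = h.g_start + 3 * t_removed_back
        g1 = h.g_end - 3 * t_removed_front
    return Hsp(
        h.contig, h.strand, h.frame, g0, g1, q, q_end, score,
        bit_score(score), h.evalue,
        "".join(c[0] for c in cols[lo:hi]),
        "".join(c[1] for c in cols[lo:hi]),
    )


def _fit_between(h: Hsp, left: Hsp | None, right: Hsp | None) -> Hsp | None:
    """Trim ``h`` so its query interval overlaps its chain neighbours by at
    most the allowed margin."""
    new_start = None
    new_end = None
    if left is not None and h.q_start < left.q_end - MAX_QUERY_OVERLAP:
        new_start = left.q_end - MAX_QUERY_OVERLAP
    if right is not None and h.q_end > right.q_start + MAX_QUERY_OVERLAP:
        new_end = right.q_start + MAX_QUERY_OVERLAP
    if new_start is None and new_end is None:
        return h
    return _trim_hsp(h, new_q_start=new_start, new_q_end=new_end)


def _chainable(prev: Hsp, nxt: Hsp, max_intron: int) -> bool:
    """prev has the smaller query interval; check colinearity on the genome."""
    if nxt.q_start < prev.q_end - MAX_QUERY_OVERLAP:
        return False
    if nxt.q_start < prev.q_start or nxt.q_end <= prev.q_end:
        return False
    if prev.strand == "+":
        gap = nxt.g_start - prev.g_end
    else:
        gap = prev.g_start - nxt.g_end
    return -MAX_GENOMIC_OVERLAP <= gap <= max_intron


def chain_hsps(
    hsps: list[Hsp], config: PipelineConfig, query_id: str = "", query_len: int = 0
) -> list[HitRegion]:
    """Greedily chain colinear HSPs into candidate gene regions.

    HSPs are consumed in descending score order; each joins the first chain
    it is colinear with (same contig and strand, genomic gap at most
    ``max_intron_len``, query overlap at most 10 aa), else founds a new one.
    """
    if not hsps:
        return []
    if not query_len:
        query_len = max(h.q_end for h in hsps)
    order = sorted(hsps, key=lambda h: (-h.raw_score, h.contig, h.g_start, h.q_start))
    chains: list[list[Hsp]] = []
    for h in order:
        placed = False
        for chain in chains:
            if (h.contig, h.strand) != (chain[0].contig, chain[0].strand):
                continue
            # locate h's slot by query order and trim overlap with neighbours
            left = max((x for x in chain if x.q_start <= h.q_start),
                       key=lambda x: x.q_start, default=None)
            right = min((x for x in chain if x.q_start > h.q_start),
                        key=lambda x: x.q_start, default=None)
            h2 = _fit_between(h, left, right)
            if h2 is None:
                continue
            trial = sorted(chain + [h2], key=lambda x: x.q_start)
            if all(
                _chainable(trial[i], trial[i + 1], config.max_intron_len)
                for i in range(len(trial) - 1)
            ):
                chain.append(h2)
                chain.sort(key=lambda x: x.q_start)
                placed = True
                break
        if not placed:
            chains.append([h])
    regions = [
        HitRegion(c[0].contig, c[0].strand, sorted(c, key=lambda x: x.q_start), query_id, query_len)
        for c in chains
    ]
    regions.sort(key=lambda r: (-r.raw_score, r.contig, r.g_start))
    return regions


def apply_filter(
    region: HitRegion, structure_complete: bool, config: PipelineConfig
) -> str:
    """Accept / rescue / reject one best-hit region.

    Accepted when identity and query coverage both reach the 50% threshold;
    rescued when both sit in the 45-50% window *and* the predicted gene
    structure is complete (the census re-examines such borderline hits on
    the grounds that rapidly evolving genes can dip below the main cutoff);
    rejected otherwise.
    """
    ident, cov = region.identity_pct, region.coverage_pct
    if ident >= config.identity_min and cov >= config.coverage_min:
        status = "accepted"
    elif (
        ident >= config.rescue_identity_lo
        and cov >= config.rescue_identity_lo
        and structure_complete
    ):
        status = "rescued"
    else:
        status = "rejected"
    region.status = status
    return status


RELAXED_EVALUE = 1e-2
RELAXED_K = 3
ABSENCE_IDENTITY = 30.0


def _overlaps_excluded(region: HitRegion, exclude) -> bool:
    for contig, s, e in exclude:
        if region.contig == contig and region.g_start < e and region.g_end > s:
            return True
    return False


def verify_absence(
    query_id: str,
    query: str,
    genome: GenomeRecord,
    config: PipelineConfig,
    exclude: list[tuple[str, int, int]] | None = None,
    engine: SearchEngine | None = None,
) -> AbsenceReport:
    """Automated re-check before declaring a gene lost.

    Re-runs the search with relaxed thresholds (E <= 1e-2, k=3 seeds, wider
    two-hit window) and reports the best surviving region outside loci
    already assigned to other genes, so every loss call is auditable.  The
    gene is reported lost only if nothing reaches 30% identity.  Refuses to
    run when the standard search still finds an acceptable region.
    """
    exclude = exclude or []
    if engine is None:
        engine = SearchEngine(genome, config)
    strict = [
        r
        for r in chain_hsps(engine.search(query), config, query_id, len(query))
        if not _overlaps_excluded(r, exclude)
    ]
    for r in strict:
        if r.identity_pct >= config.identity_min and r.coverage_pct >= config.coverage_min:
            raise ValueError(
                f"verify_absence precondition violated: acceptable region for "
                f"{query_id} at {r.contig}:{r.g_start}-{r.g_end}"
            )
    hsps = engine.search(query, k=RELAXED_K, evalue_max=RELAXED_EVALUE, two_hit_window=60)
    regions = [
        r
        for r in chain_hsps(hsps, config, query_id, len(query))
        if not _overlaps_excluded(r, exclude)
    ]
    best = max(regions, key=lambda r: r.identity_pct, default=None)
    if best is None:
        return AbsenceReport(
            query_id, genome.species, True, 0.0, 0.0, None,
            f"no candidate >={ABSENCE_IDENTITY:.0f}% identity",
        )
    lost = best.identity_pct < ABSENCE_IDENTITY
    note = (
        f"no candidate >={ABSENCE_IDENTITY:.0f}% identity"
        if lost
        else f"candidate at {best.contig}:{best.g_start}-{best.g_end} "
        f"({best.identity_pct:.1f}% id); loss not called"
    )
    return AbsenceReport(
        query_id, genome.species, lost, best.identity_pct, best.coverage_pct, best, note
    )
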