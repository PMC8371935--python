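"""Codon-alignment pseudogene detection.

A candidate CDS is compared to its reference CDS through a protein-guided
codon alignment: the two translations are globally aligned (BLOSUM62,
affine open 10 / extend 1) and the alignment expanded back to whole-codon
columns.  A copy is called ``premature_stop`` when an in-frame stop sits
strictly upstream of the reference terminal stop, and ``frameshift`` when
the CDS carries an indel run of length not divisible by three (located at
the nucleotide level).  Lesions are reported by 0-based codon index and,
when a gene model is supplied, by 1-based exon ordinal — the coordinate in
which statements like "a nonsense mutation in the sixth exon" are made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import is_stop_codon, translate
from .genemodel import GeneModel
from .scoring import BLOSUM62, GLOBAL_GAP_EXT, GLOBAL_GAP_OPEN, encode_protein
from . import _kernels

PARTIAL_COVERAGE_MIN = 0.60
# DNA alignment scoring for indel localisation: gaps are priced well above
# substitutions so point divergence never masquerades as compensating indels
DNA_MATCH = 2.0
DNA_MISMATCH = -3.0
DNA_GAP_OPEN = 7.0  # first gap column
DNA_GAP_EXT = 2.0


@dataclass
class CodonAlignment:
    """Codon-atomic pairwise alignment (each cell one codon or '---')."""

    names: list[str]
    rows: list[list[str]]  # aligned codon cells per sequence
    target_tail: str = ""  # 1-2 bp frame remainder of the target CDS

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degap(self, row: int) -> str:
        seq = "".join(c for c in self.rows[row] if c != "---")
        if row == len(self.rows) - 1:
            seq += self.target_tail
        return seq

    def codon_index(self, row: int, column: int) -> int | None:
        """Original codon ordinal of the cell at ``column`` (None for a gap)."""
        if self.rows[row][column] == "---":
            return None
        return sum(1 for c in self.rows[row][:column] if c != "---")


@dataclass
class PseudogeneCall:
    species: str
    gene: str
    copy_label: str
    verdict: str  # intact | premature_stop | frameshift | premature_stop+frameshift | partial
    lesion_codon_index: int | None = None
    lesion_exon_ordinal: int | None = None
    truncation_fraction: float = 0.0
    notes: list[str] = field(default_factory=list)

    @property
    def is_pseudogene(self) -> bool:
        return self.verdict in ("premature_stop", "frameshift", "premature_stop+frameshift")


def _split_codons(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]


def align_proteins(a: str, b: str) -> tuple[float, str, str]:
    """Global protein alignment; returns (score, aligned_a, aligned_b)."""
    if not a or not b:
        raise ValueError("empty sequence")
    ai, bi = encode_protein(a), encode_protein(b)
    smat = BLOSUM62[ai[:, None], bi[None, :]].astype(np.float64)
    score, npath, pi, pj = _kernels.nw_affine_matrix(
        smat, float(GLOBAL_GAP_OPEN + GLOBAL_GAP_EXT), float(GLOBAL_GAP_EXT)
    )
    aa = "".join(a[i] if i >= 0 else "-" for i in pi[:npath])
    bb = "".join(b[j] if j >= 0 else "-" for j in pj[:npath])
    return float(score), aa, bb


def protein_identity(a: str, b: str) -> float:
    """Percent identity over all columns of the global alignment."""
    _, aa, bb = align_proteins(a, b)
    matches = sum(1 for x, y in zip(aa, bb) if x == y and x not in ("-", "X"))
    return 100.0 * matches / len(aa) if aa else 0.0


def build_codon_alignment(ref_cds: str, target_cds: str) -> CodonAlignment:
    """Protein-guided codon alignment of a target CDS against its reference.

    The reference must be a clean reading frame (length divisible by 3); the
    target may carry a 1-2 bp frame remainder, which is kept aside as
    ``target_tail`` so that degapping reproduces the input byte-identically.
    """
    if not ref_cds or not target_cds:
        raise ValueError("empty sequence")
    if len(ref_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    tail_len = len(target_cds) % 3
    tail = target_cds[len(target_cds) - tail_len :] if tail_len else ""
    ref_codons = _split_codons(ref_cds)
    tgt_codons = _split_codons(target_cds)
    ref_prot = translate(ref_cds)
    tgt_prot = translate(target_cds)
    _, ar, at = align_proteins(ref_prot, tgt_prot)
    rows: list[list[str]] = [[], []]
    ri = ti = 0
    for x, y in zip(ar, at):
        if x == "-":
            rows[0].append("---")
        else:
            rows[0].append(ref_codons[ri])
            ri += 1
        if y == "-":
            rows[1].append("---")
        else:
            rows[1].append(tgt_codons[ti])
            ti += 1
    return CodonAlignment(["ref", "target"], rows, tail)


def trim_alignment(rows: list[str], gap_frac_max: float = 0.9) -> list[str]:
    """Remove MSA columns whose gap fraction exceeds ``gap_frac_max``."""
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    n = len(rows[0])
    keep = [
        c
        for c in range(n)
        if sum(1 for r in rows if r[c] == "-") / len(rows) <= gap_frac_max
    ]
    return ["".join(r[c] for c in keep) for r in rows]


def _dna_indel_runs(ref_cds: str, target_cds: str) -> list[tuple[int, int, str]]:
    """Locate indel runs via affine-gap nucleotide alignment.

    Returns (target_pos, length, kind) with kind 'I' (insertion in the
    target) or 'D' (deletion from the target); target_pos is the 0-based
    target coordinate at the start of the run.
    """
    t = np.frombuffer(target_cds.encode(), dtype=np.uint8)
    r = np.frombuffer(ref_cds.encode(), dtype=np.uint8)
    smat = np.where(t[:, None] == r[None, :], DNA_MATCH, DNA_MISMATCH)
    _, npath, pi, pj = _kernels.nw_affine_matrix(smat, DNA_GAP_OPEN, DNA_GAP_EXT)
    runs: list[tuple[int, int, str]] = []
    cur_kind = None
    cur_start = 0
    cur_len = 0
    tpos = 0
    for k in range(npath):
        i, j = pi[k], pj[k]
        if i >= 0 and j >= 0:
            kind = None
        elif j < 0:
            kind = "I"  # target base unaligned
        else:
            kind = "D"  # reference base missing from target
        if kind != cur_kind:
            if cur_kind is not None:
                runs.append((cur_start, cur_len, cur_kind))
            cur_kind = kind
            cur_start = tpos
            cur_len = 0
        if kind is not None:
            cur_len += 1
        if i >= 0:
            tpos += 1
    if cur_kind is not None:
        runs.append((cur_start, cur_len, cur_kind))
    return runs


def _locate_single_indel(ref_cds: str, target_cds: str, delta: int) -> int:
    """Best placement (target coordinate) of one indel of ``delta`` bp.

    Minimises substitution count over every possible breakpoint; among tied
    placements a codon-boundary position is preferred (lesion reporting is
    codon-granular), then the leftmost.
    """
    t = np.frombuffer(target_cds.encode(), dtype=np.uint8)
    r = np.frombuffer(ref_cds.encode(), dtype=np.uint8)
    d = abs(delta)
    if delta > 0:  # insertion in target: target[:p] ~ ref[:p], target[p+d:] ~ ref[p:]
        n = min(len(r), len(t) - d)
        head = np.cumsum(np.concatenate(([0], (t[:n] != r[:n]).astype(np.int32))))
        tailm = (t[d : d + n] != r[:n]).astype(np.int32)
    else:  # deletion from target: target[:p] ~ ref[:p], target[p:] ~ ref[p+d:]
        n = min(len(t), len(r) - d)
        head = np.cumsum(np.concatenate(([0], (t[:n] != r[:n]).astype(np.int32))))
        tailm = (t[:n] != r[d : d + n]).astype(np.int32)
    tail = np.concatenate((np.cumsum(tailm[::-1])[::-1], [0]))
    cost = head[: n + 1] + tail[: n + 1]
    best = int(cost.min())
    cands = np.nonzero(cost == best)[0]
    on_boundary = cands[cands % 3 == 0]
    return int(on_boundary[0]) if len(on_boundary) else int(cands[0])


def classify_pseudogene(
    aln: CodonAlignment, model: GeneModel | None = None,
    species: str = "", gene: str = "", copy_label: str = "",
) -> PseudogeneCall:
    """Classify one gene copy from its codon alignment (and optional model).

    Premature stops are in-frame stop codons strictly upstream of the
    reference terminal stop; frameshifts are diagnosed from the CDS frame
    remainder and located at the nucleotide level.  Compensated double
    frameshifts (indel runs summing to a multiple of three) are reported as
    frameshift with a note only when the indel interpretation is decisively
    better than a substitution-only reading, so point divergence alone can
    never produce a frameshift call.
    """
    ref_cds = aln.degap(0)
    target_cds = aln.degap(1)
    ref_codons = _split_codons(ref_cds)
    n_ref = len(ref_codons)
    notes: list[str] = []

    # --- frameshift -------------------------------------------------------
    fs_codon: int | None = None
    remainder = len(target_cds) % 3
    if remainder != 0:
        all_runs = _dna_indel_runs(ref_cds, target_cds)
        runs = [r for r in all_runs if r[1] % 3 != 0]
        delta = len(target_cds) - len(ref_cds)
        if len(all_runs) == 1 and runs and abs(delta) == runs[0][1] and abs(delta) <= 2:
            # single small indel: exact placement scan (codon-boundary ties
            # snap to the boundary, the canonical codon-granular position)
            fs_codon = _locate_single_indel(ref_cds, target_cds, delta) // 3
        else:
            fs_codon = runs[0][0] // 3 if runs else 0
    else:
        runs = [r for r in _dna_indel_runs(ref_cds, target_cds) if r[1] % 3 != 0]
        if len(runs) >= 2:
            # the affine-gap DNA alignment only places indels when they beat a
            # substitution-only reading, so two frame-breaking runs with a net
            # zero remainder are a compensated double frameshift
            fs_codon = runs[0][0] // 3
            notes.append("compensated")

    # --- premature stop ---------------------------------------------------
    # reference terminal-stop column (or alignment end when absent)
    ref_stop_col = aln.n_columns
    for c in range(aln.n_columns - 1, -1, -1):
        cell = aln.rows[0][c]
        if cell != "---":
            if is_stop_codon(cell):
                ref_stop_col = c
            break
    fs_col_limit = aln.n_columns
    if fs_codon is not None:
        # ignore in-frame "stops" downstream of the frameshift: they are
        # artefacts of reading a shifted frame
        fs_col_limit = _column_of_target_codon(aln, fs_codon)
    stop_codon_idx: int | None = None
    stop_col: int | None = None
    for c in range(aln.n_columns):
        cell = aln.rows[1][c]
        if cell == "---" or not is_stop_codon(cell):
            continue
        if c >= ref_stop_col or c >= fs_col_limit:
            continue
        stop_col = c
        stop_codon_idx = aln.codon_index(1, c)
        break

    # --- assemble verdict -------------------------------------------------
    lesion: int | None = None
    if stop_codon_idx is not None and fs_codon is not None:
        verdict = "premature_stop+frameshift"
        lesion = min(stop_codon_idx, fs_codon)
    elif stop_codon_idx is not None:
        verdict = "premature_stop"
        lesion = stop_codon_idx
    elif fs_codon is not None:
        verdict = "frameshift"
        lesion = fs_codon
    else:
        covered = sum(
            1
            for c in range(aln.n_columns)
            if aln.rows[0][c] != "---" and aln.rows[1][c] != "---"
        )
        if n_ref and covered / n_ref < PARTIAL_COVERAGE_MIN:
            verdict = "partial"
        else:
            verdict = "intact"

    truncation = 0.0
    if lesion is not None and n_ref:
        col = stop_col if verdict == "premature_stop" else _column_of_target_codon(aln, lesion)
        ref_codons_before = sum(1 for c in range(col) if aln.rows[0][c] != "---")
        truncation = max(0.0, (n_ref - ref_codons_before) / n_ref)

    exon_ord = None
    if lesion is not None and model is not None:
        try:
            exon_ord = locate_exon_of_codon(model, lesion)
        except ValueError:
            exon_ord = None
    return PseudogeneCall(
        species, gene, copy_label, verdict, lesion, exon_ord, truncation, notes
    )


def _column_of_target_codon(aln: CodonAlignment, codon_idx: int) -> int:
    seen = 0
    for c in range(aln.n_columns):
        if aln.rows[1][c] != "---":
            if seen == codon_idx:
                return c
            seen += 1
    return aln.n_columns


def locate_exon_of_codon(model: GeneModel, codon_index: int) -> int:
    """1-based exon ordinal (transcription order) holding a CDS codon.

    A codon spanning a splice junction belongs to the exon holding its
    first base.
    """
    if not model.exons:
        raise ValueError("model has no exons")
    base = 3 * codon_index
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    cum = 0
    for ordinal, (s, e) in enumerate(exons, 1):
        if base < cum + (e - s):
            return ordinal
        cum += e - s
    raise ValueError(f"codon {codon_index} beyond CDS ({cum} bases)")
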