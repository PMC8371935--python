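"""Human-readable summaries: census tables and annotated alignment views.

The alignment views mirror the figure style of comparative pseudogene
reports: reference and target codon rows around a lesion, with ``*``
marking premature stop columns and ``!`` marking frameshift indel columns;
multi-copy species are legended ``c1``/``c2``.
"""

from __future__ import annotations

from pathlib import Path

from .census import CopyNumberMatrix
from .core_io import is_stop_codon
from .pseudogene import CodonAlignment, PseudogeneCall, _column_of_target_codon


def render_alignment_view(
    aln: CodonAlignment, call: PseudogeneCall, window: int = 5
) -> str:
    """Fixed-width codon block around the lesion (+- ``window`` codons)."""
    if window <= 0:
        raise ValueError("window must be positive")
    if call.lesion_codon_index is not None:
        center = _column_of_target_codon(aln, call.lesion_codon_index)
    else:
        center = 0
    lo = max(0, center - window)
    hi = min(aln.n_columns, center + window + 1)
    name_w = max(len(n) for n in aln.names) + 2
    lines = [
        f"# {call.species or 'target'} {call.gene} {call.copy_label or ''} "
        f"verdict={call.verdict} codons {lo}-{hi - 1}"
    ]
    for name, row in zip(aln.names, aln.rows):
        cells = " ".join(row[c] for c in range(lo, hi))
        lines.append(f"{name:<{name_w}}{cells}")
    marks = []
    tgt = aln.rows[-1]
    fs_col = None
    if "frameshift" in call.verdict and call.lesion_codon_index is not None:
        fs_col = _column_of_target_codon(aln, call.lesion_codon_index)
    for c in range(lo, hi):
        cell = tgt[c]
        if fs_col is not None and c == fs_col:
            marks.append("!!!")
        elif cell != "---" and is_stop_codon(cell) and "stop" in call.verdict:
            marks.append("***")
        else:
            marks.append("   ")
    lines.append(" " * name_w + " ".join(marks))
    legend = []
    if "stop" in call.verdict:
        legend.append("*** premature stop codon")
    if "frameshift" in call.verdict:
        legend.append(f"!!! frameshift indel (remainder {len(aln.degap(1)) % 3} bp)")
    if call.is_pseudogene:
        legend.append(f"{call.species}: melanin-gene lesion")
    if legend:
        lines.append("# " + "; ".join(legend))
    return "\n".join(lines) + "\n"


def summarize(
    matrix: CopyNumberMatrix, calls: list[PseudogeneCall], out_dir: str | Path
) -> list[Path]:
    """Write the species-level census TSV and the pseudogene-event TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species_path = out_dir / "copy_matrix.tsv"
    matrix.to_tsv(species_path)
    events_path = out_dir / "pseudogene_events.tsv"
    with open(events_path, "w") as fh:
        fh.write(
            "species\tgene\tcopy\tverdict\tlesion_codon_index\t"
            "lesion_exon_ordinal\ttruncation_fraction\tnotes\n"
        )
        for c in sorted(calls, key=lambda c: (c.species, c.gene, c.copy_label)):
            if not c.is_pseudogene:
                continue
            fh.write(
                f"{c.species}\t{c.gene}\t{c.copy_label}\t{c.verdict}\t"
                f"{'' if c.lesion_codon_index is None else c.lesion_codon_index}\t"
                f"{'' if c.lesion_exon_ordinal is None else c.lesion_exon_ordinal}\t"
                f"{c.truncation_fraction:.3f}\t{';'.join(c.notes)}\n"
            )
    return [species_path, events_path]


def write_views(result, out_dir: str | Path) -> None:
    """Render one alignment view per lesion call (pipeline convenience)."""
    from .pseudogene import build_codon_alignment

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # lazily re-build codon alignments for lesioned copies only
    for c in sorted(result.copies, key=lambda c: (c.species, c.family, c.label or "")):
        if c.call is None or not c.call.is_pseudogene:
            continue
        refs = result.refs
        if refs is None:
            continue
        ref_label = c.label if c.label in refs.cds else c.family
        aln = build_codon_alignment(refs.cds[ref_label], c.model.cds)
        text = render_alignment_view(aln, c.call, window=5)
        (out_dir / f"{c.species}_{c.label}.txt").write_text(text)
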