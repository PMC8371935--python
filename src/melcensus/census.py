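"""Copy-number census: orthology labels, species x gene matrices, lineage tables.

Cells follow the "N (k)" convention: N gene copies of which k are
pseudogenes, the parenthetical omitted when k = 0.  WGD-derived paralogs
carry a/b labels; a copy is assigned the reference paralog it is most
similar to, with flanking-marker (synteny) agreement breaking narrow
identity margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import SpeciesMeta
from .pseudogene import PseudogeneCall, protein_identity

IDENTITY_MARGIN = 3.0  # percentage points below which flanks decide


@dataclass
class GeneCopy:
    """One located gene copy, as it flows through orthology and the census."""

    species: str
    contig: str
    strand: str
    g_start: int
    g_end: int
    family: str
    label: str | None = None  # reference paralog name, or "ambiguous"
    protein: str = ""
    status: str = ""  # accepted | rescued
    call: PseudogeneCall | None = None
    ref_identities: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    model: object | None = None
    region: object | None = None


def assign_orthology(
    copies: list[GeneCopy],
    ref_proteins: dict[str, str],
    family_labels: dict[str, list[str]],
    locus_markers: dict[str, set[str]] | None = None,
    contig_markers: dict[tuple[str, str], set[str]] | None = None,
) -> list[GeneCopy]:
    """Label each copy with its reference paralog (e.g. tyra vs tyrb).

    The label is the highest-identity reference of the copy's family.  When
    the top two identities differ by less than 3 percentage points the
    flanking-marker vote decides: each candidate label scores the number of
    its expected locus markers observed near the copy.  A flank tie falls
    back to identity rank; "ambiguous" is reserved for copies whose
    candidates tie on both criteria.
    """
    locus_markers = locus_markers or {}
    contig_markers = contig_markers or {}
    for copy in copies:
        candidates = family_labels.get(copy.family, [copy.family])
        prot = copy.protein.rstrip("*")
        idents = {
            lab: protein_identity(prot, ref_proteins[lab])
            for lab in candidates
            if lab in ref_proteins
        }
        copy.ref_identities = idents
        if not idents:
            copy.label = "ambiguous"
            copy.notes.append("no reference for family")
            continue
        ranked = sorted(idents.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) == 1 or ranked[0][1] - ranked[1][1] >= IDENTITY_MARGIN:
            copy.label = ranked[0][0]
            continue
        tied = [lab for lab, v in ranked if ranked[0][1] - v < IDENTITY_MARGIN]
        observed = contig_markers.get((copy.species, copy.contig), set())
        votes = {lab: len(observed & locus_markers.get(lab, set())) for lab in tied}
        best_vote = max(votes.values())
        winners = sorted(lab for lab, v in votes.items() if v == best_vote)
        if len(winners) == 1:
            copy.label = winners[0]
            copy.notes.append("label decided by flanking markers")
        else:
            # flanks cannot separate; fall back to identity rank unless tied
            top = [lab for lab in winners if idents[lab] == ranked[0][1]]
            if len(top) == 1 or abs(idents[winners[0]] - idents[winners[1]]) > 1e-9:
                copy.label = max(winners, key=lambda lab: (idents[lab], lab))
                copy.notes.append("narrow identity margin; flank vote tied")
            else:
                copy.label = "ambiguous"
                copy.notes.append("unresolved orthology")
    return copies


@dataclass
class CopyNumberMatrix:
    """Species x gene-symbol counts with pseudogene subcounts."""

    totals: pd.DataFrame  # int
    pseudo: pd.DataFrame  # int

    def cell(self, species: str, gene: str) -> tuple[int, int]:
        return int(self.totals.loc[species, gene]), int(self.pseudo.loc[species, gene])

    def render(self) -> pd.DataFrame:
        out = self.totals.astype(str).copy()
        for sp in self.totals.index:
            for g in self.totals.columns:
                n, k = self.cell(sp, g)
                out.loc[sp, g] = f"{n} ({k})" if k else f"{n}"
        return out

    def to_tsv(self, path) -> None:
        self.render().to_csv(path, sep="\t", index_label="species")


def build_copy_matrix(
    copies: list[GeneCopy],
    species_meta: dict[str, SpeciesMeta],
    columns: list[str] | None = None,
) -> CopyNumberMatrix:
    """Tabulate labeled copies into a species x gene-symbol matrix.

    Totals count accepted and rescued copies; the pseudogene subcount
    counts premature-stop / frameshift verdicts.  Ambiguous labels are
    tallied in a dedicated "ambiguous" column so paralog columns are never
    silently inflated.
    """
    for copy in copies:
        if copy.species not in species_meta:
            raise ValueError(f"species {copy.species!r} missing from species table")
    species = sorted(species_meta)
    if columns is None:
        columns = sorted({c.label for c in copies if c.label})
    cols = list(columns)
    if any(c.label == "ambiguous" for c in copies) and "ambiguous" not in cols:
        cols.append("ambiguous")
    totals = pd.DataFrame(0, index=species, columns=cols, dtype=int)
    pseudo = pd.DataFrame(0, index=species, columns=cols, dtype=int)
    for copy in copies:
        if copy.status not in ("accepted", "rescued") or not copy.label:
            continue
        lab = copy.label if copy.label in cols else "ambiguous"
        totals.loc[copy.species, lab] += 1
        if copy.call is not None and copy.call.is_pseudogene:
            pseudo.loc[copy.species, lab] += 1
    return CopyNumberMatrix(totals, pseudo)


def aggregate_by_lineage(
    matrix: CopyNumberMatrix, species_meta: dict[str, SpeciesMeta]
) -> pd.DataFrame:
    """Sum the census by taxonomic class (lineage-table layout).

    One row per class with its species count and, per gene, the summed
    total rendered "N" or "N (k)" when k pseudogene copies are included.
    """
    classes: dict[str, list[str]] = {}
    for sp in matrix.totals.index:
        classes.setdefault(species_meta[sp].taxon_class, []).append(sp)
    rows = []
    for cls in sorted(classes):
        sps = classes[cls]
        row: dict[str, object] = {"taxon_class": cls, "n_species": len(sps)}
        for g in matrix.totals.columns:
            n = int(matrix.totals.loc[sps, g].sum())
            k = int(matrix.pseudo.loc[sps, g].sum())
            row[g] = f"{n} ({k})" if k else f"{n}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon_class")
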