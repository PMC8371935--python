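"""Shared I/O, translation, configuration and species metadata.

All genomic coordinates inside the package are 0-based half-open on the
forward strand of a contig; minus-strand features carry forward-strand
coordinates plus a strand flag.  GFF3 output converts to the standard
1-based inclusive convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Data import CodonTable

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TAXON_CLASSES = (
    "Actinopterygii",
    "Mammals",
    "Birds",
    "Reptiles",
    "Amphibians",
    "Chondrichthyes",
    "Synthetic",
)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header, empty or duplicate record)."""


@dataclass
class SequenceRecord:
    """One FASTA record; ``seq`` is an uppercase DNA or protein string."""

    id: str
    description: str
    seq: str


@dataclass
class GenomeRecord:
    """One assembly: named contigs plus species-level metadata."""

    species: str
    contigs: dict[str, str]
    taxon_class: str = "Synthetic"

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class SpeciesMeta:
    species: str
    taxon_class: str
    is_outgroup: bool = False

    def __post_init__(self) -> None:
        if self.taxon_class not in TAXON_CLASSES:
            raise ValueError(f"unknown taxon class {self.taxon_class!r} for {self.species}")


@dataclass
class PipelineConfig:
    """Run parameters of the census pipeline.

    The defaults encode the filtering scheme of the census: translated hits
    kept at E <= 1e-5, best-hit regions accepted at >=50% identity and
    >=50% query coverage, with a 45-50% rescue window that additionally
    requires a complete gene structure.
    """

    evalue_max: float = 1e-5
    identity_min: float = 50.0
    coverage_min: float = 50.0
    rescue_identity_lo: float = 45.0
    max_intron_len: int = 20000
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.rescue_identity_lo < self.identity_min <= 100):
            raise ValueError("require 0 < rescue_identity_lo < identity_min <= 100")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, dna: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercased and wrapped lines joined.  Duplicate ids, empty
    sequences, or (with ``dna=True``) non-DNA characters raise
    :class:`FastaParseError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        if dna and not set(seq) <= DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise FastaParseError(f"{path}: record {rec.id!r} has non-DNA characters {bad}")
        records.append(SequenceRecord(rec.id, rec.description, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description and rec.description != rec.id else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genome(path: str | Path, species: str, taxon_class: str = "Synthetic") -> GenomeRecord:
    recs = read_fasta(path, dna=True)
    return GenomeRecord(species, {r.id: r.seq for r in recs}, taxon_class)


# ---------------------------------------------------------------------------
# Translation

_CODE_CACHE: dict[int, dict[str, str]] = {}


def _codon_table(code: int) -> dict[str, str]:
    table = _CODE_CACHE.get(code)
    if table is None:
        ct = CodonTable.unambiguous_dna_by_id[code]
        table = dict(ct.forward_table)
        for stop in ct.stop_codons:
            table[stop] = "*"
        _CODE_CACHE[code] = table
    return table


def translate(dna: str, frame: int = 0, code: int = 1) -> str:
    """Translate ``dna`` from ``frame`` under NCBI table ``code``.

    One amino acid per complete codon; stop codons render ``*``; any codon
    containing a character outside {A,C,G,T} (assembly ``N`` in particular)
    renders ``X``.  The trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    table = _codon_table(code)
    s = dna.upper()
    out = []
    for i in range(frame, len(s) - 2, 3):
        out.append(table.get(s[i : i + 3], "X"))
    return "".join(out)


def reverse_complement(dna: str) -> str:
    bad = set(dna.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return dna.translate(_COMPLEMENT)[::-1]


def is_stop_codon(codon: str, code: int = 1) -> bool:
    return _codon_table(code).get(codon.upper()) == "*"


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon/CDS subset used by this package)

@dataclass
class GffGene:
    """Minimal gene structure as round-tripped through GFF3."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, forward coords, sorted


def _check_exons(exons: Sequence[tuple[int, int]], gene_id: str) -> None:
    prev_end = -1
    for s, e in exons:
        if s >= e:
            raise ValueError(f"{gene_id}: empty exon interval ({s},{e})")
        if s < prev_end:
            raise ValueError(f"{gene_id}: overlapping or unsorted exons")
        prev_end = e


def write_gff3(models: Iterable, path: str | Path) -> None:
    """Write gene models (anything with gene_id/contig/strand/exons) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            exons = sorted(m.exons)
            _check_exons(exons, m.gene_id)
            g0, g1 = exons[0][0], exons[-1][1]
            gid, mid = m.gene_id, m.gene_id + ".t1"
            base = f"{m.contig}\tmelcensus"
            fh.write(f"{base}\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID={gid}\n")
            fh.write(f"{base}\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID={mid};Parent={gid}\n")
            tx_order = exons if m.strand == "+" else exons[::-1]
            phase = 0
            phases = {}
            for s, e in tx_order:
                phases[(s, e)] = phase
                phase = (3 - ((e - s) - phase) % 3) % 3
            for i, (s, e) in enumerate(exons, 1):
                fh.write(
                    f"{base}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )
                fh.write(
                    f"{base}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phases[(s, e)]}\t"
                    f"ID={mid}.cds;Parent={mid}\n"
                )


def read_gff3(path: str | Path) -> list[GffGene]:
    """Read back the GFF3 subset written by :func:`write_gff3`."""
    genes: dict[str, GffGene] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = cols
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = GffGene(gid, contig, strand, [])
            elif ftype == "exon":
                gid = attr["Parent"].rsplit(".t1", 1)[0]
                genes[gid].exons.append((int(start) - 1, int(end)))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


# ---------------------------------------------------------------------------
# Species metadata table (TSV: species, taxon_class, is_outgroup)

def read_species_table(path: str | Path) -> dict[str, SpeciesMeta]:
    metas: dict[str, SpeciesMeta] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            sp = cols[idx["species"]]
            if sp in metas:
                raise ValueError(f"{path}: species {sp!r} listed twice")
            metas[sp] = SpeciesMeta(
                sp,
                cols[idx["taxon_class"]],
                cols[idx["is_outgroup"]].strip().lower() in ("1", "true", "yes"),
            )
    return metas


def write_species_table(metas: Iterable[SpeciesMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\ttaxon_class\tis_outgroup\n")
        for m in metas:
            fh.write(f"{m.species}\t{m.taxon_class}\t{str(m.is_outgroup).lower()}\n")
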