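"""Synthetic multi-species genomes with planted gene families and truth sets.

The generator emulates the data structure a vertebrate gene-family census
operates on: a set of species related by a known tree, a whole-genome
duplication on the stem of one clade producing a/b paralog pairs,
intron-containing gene copies diverging by codon-aware point mutation,
species-specific pseudogenization events (premature stop codons, 1-2 bp
indels at codon boundaries), whole-gene losses, and conserved flanking
marker genes for synteny checks.  Every event is logged in a
machine-readable truth set, and the true gene structures are emitted as
GFF3, so pipeline recovery can be scored exactly.

The "benchmark" preset models 12 species — a six-species ray-finned clade
carrying a/b duplicates of tyr, tyrp1, pmel and mitf but single-copy tyrp2
and slc24a5, five tetrapods, and a cartilaginous-fish outgroup.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_io import (
    GenomeRecord,
    GffGene,
    SequenceRecord,
    SpeciesMeta,
    reverse_complement,
    translate,
    write_fasta,
    write_gff3,
    write_species_table,
)
from .phylo import Node, parse_newick

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
# relative mutability of the three codon positions (mean 1); third positions
# are often synonymous, so protein identity decays slower than DNA identity
CODON_POS_WEIGHTS = (0.7, 0.3, 2.0)
MARKER_CODONS = 60
MARKER_RATE_FACTOR = 0.5  # flanking markers are conserved genes
DUP_EXTRA_DIVERGENCE = 0.05  # added to each post-WGD copy on the stem


@dataclass
class SimParams:
    species_tree: str
    wgd_clade: set[str] = field(default_factory=set)
    families: list[str] = field(default_factory=lambda: [f"fam{i}" for i in range(1, 7)])
    duplicated_families: set[str] = field(default_factory=set)
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (40, 200)  # codons
    intron_len: tuple[int, int] = (120, 500)  # bp; floor keeps introns cheaper than codon gaps
    intergenic_len: int = 300
    p_pseudogene: float = 0.1
    p_loss: float = 0.1
    pseudo_event_mix: dict[str, float] = field(
        default_factory=lambda: {"stop_point_mutation": 0.5, "indel_1bp": 0.25, "indel_2bp": 0.25}
    )
    flank_markers: int = 2
    gc_content: float = 0.42
    seed: int = 0
    taxon_classes: dict[str, str] = field(default_factory=dict)
    outgroup: str | None = None

    def __post_init__(self) -> None:
        for p in (self.p_pseudogene, self.p_loss):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0,1]")
        if abs(sum(self.pseudo_event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("pseudo_event_mix must sum to 1")
        for lo, hi in (self.exons_per_gene, self.exon_len, self.intron_len):
            if lo > hi or lo <= 0:
                raise ValueError("ranges must be nonempty and positive")
        tree = parse_newick(self.species_tree)
        leaves = set(tree.leaves())
        if not self.wgd_clade <= leaves:
            raise ValueError("wgd_clade must be a subset of the species-tree leaves")
        if self.duplicated_families and not self.wgd_clade:
            raise ValueError("duplicated families require a wgd_clade")
        if self.intergenic_len < 50:
            raise ValueError("intergenic_len too small to separate flank markers")

    @property
    def species(self) -> list[str]:
        return parse_newick(self.species_tree).leaves()


@dataclass
class TruthEvent:
    species: str
    family: str
    copy_label: str
    event: str  # present_intact | pseudogene_stop | pseudogene_frameshift | lost
    lesion_codon_index: int | None = None
    lesion_exon_ordinal: int | None = None
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None


@dataclass
class ReferenceSet:
    """Reference queries and locus context handed to the pipeline."""

    proteins: dict[str, str]  # label -> protein (no terminal stop)
    cds: dict[str, str]  # label -> CDS incl. terminal stop
    markers: dict[str, str]  # marker name -> protein
    locus_markers: dict[str, set[str]]  # label -> expected flank marker names
    family_labels: dict[str, list[str]]  # family -> candidate labels

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [SequenceRecord(k, k, v) for k, v in sorted(self.proteins.items())],
            outdir / "ref_proteins.fasta",
        )
        write_fasta(
            [SequenceRecord(k, k, v) for k, v in sorted(self.cds.items())],
            outdir / "ref_cds.fasta",
        )
        write_fasta(
            [SequenceRecord(k, k, v) for k, v in sorted(self.markers.items())],
            outdir / "ref_markers.fasta",
        )
        with open(outdir / "ref_context.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "locus_markers": {k: sorted(v) for k, v in self.locus_markers.items()},
                    "family_labels": self.family_labels,
                },
                fh,
            )

    @classmethod
    def load(cls, outdir: str | Path) -> "ReferenceSet":
        from .core_io import read_fasta

        outdir = Path(outdir)
        prot = {r.id: r.seq for r in read_fasta(outdir / "ref_proteins.fasta")}
        cds = {r.id: r.seq for r in read_fasta(outdir / "ref_cds.fasta")}
        markers = {r.id: r.seq for r in read_fasta(outdir / "ref_markers.fasta")}
        with open(outdir / "ref_context.yaml") as fh:
            ctx = yaml.safe_load(fh)
        return cls(
            prot,
            cds,
            markers,
            {k: set(v) for k, v in ctx["locus_markers"].items()},
            ctx["family_labels"],
        )


@dataclass
class SimResult:
    params: SimParams
    genomes: dict[str, GenomeRecord]
    refs: ReferenceSet
    truth: list[TruthEvent]
    truth_models: dict[str, list[GffGene]]
    species_meta: dict[str, SpeciesMeta]


# ---------------------------------------------------------------------------
# sequence-level primitives

def random_dna(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon (n_codons total)."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def evolve_protein_coding(cds: str, branch_len: float, rng: np.random.Generator | int) -> str:
    """Apply codon-position-aware point mutations at rate ``branch_len``/site.

    The start codon and terminal stop are preserved and no internal in-frame
    stop is ever introduced (mutations creating one are resampled).
    """
    if branch_len < 0:
        raise ValueError("branch length must be >= 0")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if branch_len == 0:
        return cds
    seq = list(cds)
    n = len(seq)
    w = np.array(CODON_POS_WEIGHTS)
    probs = np.minimum(1.0, branch_len * np.resize(w, n))
    hits = np.nonzero(rng.random(n) < probs)[0]
    for i in hits:
        if i < 3 or i >= n - 3:
            continue  # protect start and terminal stop
        old = seq[i]
        choices = [b for b in BASES if b != old]
        for _ in range(8):
            seq[i] = choices[rng.integers(0, 3)]
            cstart = (i // 3) * 3
            if "".join(seq[cstart : cstart + 3]) not in STOP_CODONS:
                break
            seq[i] = old
    return "".join(seq)


def plant_lesion(
    cds: str, kind: str, rng: np.random.Generator | int, avoid: set[int] | None = None
) -> tuple[str, int]:
    """Plant one pseudogenizing lesion; returns (mutated CDS, codon index).

    ``stop_point_mutation`` edits at most two bases of one internal codon to
    a stop; ``indel_1bp``/``indel_2bp`` insert or delete 1-2 bases at a
    codon boundary.  The lesion lands between codon 5 and len-5; ``avoid``
    excludes codon indices (the generator keeps indels clear of splice
    junctions, where an indel is not distinguishable from a shifted splice
    site by any sequence-based method).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    L = len(cds) // 3
    if L < 30:
        raise ValueError("CDS too short to plant a lesion (need >= 30 codons)")
    pool = [c for c in range(5, L - 5) if not avoid or c not in avoid]
    if not pool:
        raise ValueError("no codon position available for a lesion")
    c = int(pool[rng.integers(0, len(pool))])
    if kind == "stop_point_mutation":
        codon = cds[3 * c : 3 * c + 3]
        dists = [(sum(a != b for a, b in zip(codon, s)), s) for s in STOP_CODONS]
        best = min(d for d, _ in dists)
        target = [s for d, s in dists if d == best]
        stop = target[rng.integers(0, len(target))]
        return cds[: 3 * c] + stop + cds[3 * c + 3 :], c
    if kind in ("indel_1bp", "indel_2bp"):
        d = 1 if kind == "indel_1bp" else 2
        if rng.random() < 0.5:  # insertion
            ins = "".join(BASES[i] for i in rng.integers(0, 4, size=d))
            return cds[: 3 * c] + ins + cds[3 * c :], c
        return cds[: 3 * c] + cds[3 * c + d :], c
    raise ValueError(f"unknown lesion kind {kind!r}")


# ---------------------------------------------------------------------------
# dataset generation

def _evolve_over_tree(
    root_seq: str, tree: Node, rng: np.random.Generator, rate_factor: float = 1.0
) -> dict[str, str]:
    """Evolve a CDS down the tree; returns leaf name -> CDS."""
    out: dict[str, str] = {}

    def walk(node: Node, seq: str) -> None:
        for child in sorted(node.children, key=lambda c: min(c.leaves())):
            child_seq = evolve_protein_coding(seq, child.length * rate_factor, rng)
            if child.is_leaf:
                out[child.name] = child_seq
            else:
                walk(child, child_seq)

    walk(tree, root_seq)
    return out


def _subtree(tree: Node, leaves: set[str]) -> Node:
    """Smallest clade containing exactly ``leaves`` (must be monophyletic)."""
    for node in _iter_nodes(tree):
        if set(node.leaves()) == leaves:
            return node
    raise ValueError("wgd_clade is not a clade of the species tree")


def _iter_nodes(node: Node):
    yield node
    for c in node.children:
        yield from _iter_nodes(c)


def _stem_length(tree: Node, clade: Node) -> float:
    return clade.length


def _exon_base_lengths(exon_codons: list[int], lesion_codon: int | None, delta: int) -> list[int]:
    """Per-exon base counts after applying an indel of ``delta`` bp at a codon boundary."""
    lengths = [3 * c for c in exon_codons]
    if lesion_codon is None or delta == 0:
        return lengths
    cum = 0
    for e, ncod in enumerate(exon_codons):
        if lesion_codon < cum + ncod:
            lengths[e] += delta
            return lengths
        cum += ncod
    lengths[-1] += delta
    return lengths


def _exon_ordinal(exon_codons: list[int], lesion_codon: int) -> int:
    cum = 0
    for e, ncod in enumerate(exon_codons, 1):
        if lesion_codon < cum + ncod:
            return e
        cum += ncod
    return len(exon_codons)


def simulate_dataset(params: SimParams) -> SimResult:
    """Generate genomes, reference queries, truth events and truth GFF models."""
    tree = parse_newick(params.species_tree)
    species = tree.leaves()
    wgd = params.wgd_clade
    wgd_node = _subtree(tree, wgd) if wgd else None

    ref_proteins: dict[str, str] = {}
    ref_cds: dict[str, str] = {}
    marker_prot: dict[str, str] = {}
    locus_markers: dict[str, set[str]] = {}
    family_labels: dict[str, list[str]] = {}
    truth: list[TruthEvent] = []
    truth_models: dict[str, list[GffGene]] = {sp: [] for sp in species}
    contigs: dict[str, dict[str, str]] = {sp: {} for sp in species}

    # leaf CDS per (family, copy): copy '' (ancestral/single), 'a', 'b'
    for fidx, fam in enumerate(params.families):
        rng = np.random.default_rng([params.seed, fidx])
        n_exons = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        exon_codons = [
            int(rng.integers(params.exon_len[0], params.exon_len[1] + 1))
            for _ in range(n_exons)
        ]
        total_codons = sum(exon_codons)
        root = random_cds(rng, total_codons)
        duplicated = fam in params.duplicated_families

        copies: dict[str, dict[str, str]] = {}  # copy suffix -> leaf -> cds
        if duplicated:
            stem = wgd_node.length
            a_anc = evolve_protein_coding(root, stem + DUP_EXTRA_DIVERGENCE, rng)
            b_anc = evolve_protein_coding(root, stem + DUP_EXTRA_DIVERGENCE, rng)
            copies["a"] = _evolve_over_tree(a_anc, wgd_node, rng)
            copies["b"] = _evolve_over_tree(b_anc, wgd_node, rng)
            outside = _evolve_over_tree(root, tree, rng)
            copies[""] = {sp: s for sp, s in outside.items() if sp not in wgd}
            ref_proteins[fam] = translate(root)[:-1]
            ref_cds[fam] = root
            ref_proteins[f"{fam}_a"] = translate(a_anc)[:-1]
            ref_cds[f"{fam}_a"] = a_anc
            ref_proteins[f"{fam}_b"] = translate(b_anc)[:-1]
            ref_cds[f"{fam}_b"] = b_anc
            family_labels[fam] = [fam, f"{fam}_a", f"{fam}_b"]
        else:
            copies[""] = _evolve_over_tree(root, tree, rng)
            ref_proteins[fam] = translate(root)[:-1]
            ref_cds[fam] = root
            family_labels[fam] = [fam]

        # flanking markers: the ancestral locus (shared with the a-copy) and,
        # for duplicated families, a distinct b-locus marker set
        marker_sets: dict[str, list[str]] = {}
        marker_leaf_cds: dict[str, dict[str, str]] = {}
        for locus_kind in ("anc",) + (("b",) if duplicated else ()):
            names = []
            for side in ("u", "d"):
                for i in range(1, params.flank_markers + 1):
                    names.append(f"{fam}_mk{locus_kind}_{side}{i}")
            marker_sets[locus_kind] = names
            for name in names:
                mroot = random_cds(rng, MARKER_CODONS)
                marker_prot[name] = translate(mroot)[:-1]
                marker_leaf_cds[name] = _evolve_over_tree(
                    mroot, tree, rng, rate_factor=MARKER_RATE_FACTOR
                )
        locus_markers[fam] = set(marker_sets["anc"])
        if duplicated:
            locus_markers[f"{fam}_a"] = set(marker_sets["anc"])
            locus_markers[f"{fam}_b"] = set(marker_sets["b"])

        # per-species loci
        for copy_suffix, leaf_cds in sorted(copies.items()):
            label = fam if copy_suffix == "" else f"{fam}_{copy_suffix}"
            locus_kind = "b" if copy_suffix == "b" else "anc"
            strand_flip = bool(rng.random() < 0.4)
            for sp in species:
                if sp not in leaf_cds:
                    continue
                ev_rng = np.random.default_rng(
                    [params.seed, fidx, {"": 0, "a": 1, "b": 2}[copy_suffix], species.index(sp)]
                )
                cds = leaf_cds[sp]
                u = ev_rng.random()
                event = "present"
                lesion_codon = None
                lesion_kind = None
                if u < params.p_loss:
                    event = "lost"
                elif u < params.p_loss + params.p_pseudogene:
                    kinds = sorted(params.pseudo_event_mix)
                    probs = np.array([params.pseudo_event_mix[k] for k in kinds])
                    lesion_kind = kinds[ev_rng.choice(len(kinds), p=probs / probs.sum())]
                    avoid: set[int] = set()
                    if lesion_kind != "stop_point_mutation":
                        # keep indels clear of splice junctions: within ~5-6
                        # codons of a boundary a 1-2 bp indel is cheaper to
                        # explain as a shifted splice site than as a frameshift,
                        # for this aligner and for GeneWise-class tools alike
                        cum = 0
                        for ncod in exon_codons[:-1]:
                            cum += ncod
                            avoid.update(range(cum - 7, cum + 8))
                    cds, lesion_codon = plant_lesion(cds, lesion_kind, ev_rng, avoid)
                    event = (
                        "pseudogene_stop"
                        if lesion_kind == "stop_point_mutation"
                        else "pseudogene_frameshift"
                    )
                contig_id = f"{sp}|{label}"
                seq, gene_iv, exon_ivs = _build_locus(
                    ev_rng,
                    params,
                    cds if event != "lost" else None,
                    exon_codons,
                    lesion_codon,
                    lesion_kind,
                    [marker_leaf_cds[m][sp] for m in marker_sets[locus_kind]],
                )
                strand = "+"
                if strand_flip and event != "lost":
                    L = len(seq)
                    seq = reverse_complement(seq)
                    gene_iv = (L - gene_iv[1], L - gene_iv[0])
                    exon_ivs = sorted((L - e, L - s) for s, e in exon_ivs)
                    strand = "-"
                contigs[sp][contig_id] = seq
                if event == "lost":
                    truth.append(TruthEvent(sp, fam, label, "lost"))
                    continue
                exon_ord = (
                    _exon_ordinal(exon_codons, lesion_codon)
                    if lesion_codon is not None
                    else None
                )
                truth.append(
                    TruthEvent(
                        sp,
                        fam,
                        label,
                        "present_intact" if event == "present" else event,
                        lesion_codon,
                        exon_ord,
                        contig_id,
                        gene_iv[0],
                        gene_iv[1],
                        strand,
                    )
                )
                truth_models[sp].append(
                    GffGene(f"{sp}|{label}|gene", contig_id, strand, exon_ivs)
                )

    genomes = {}
    species_meta = {}
    for sp in species:
        cls = params.taxon_classes.get(sp, "Synthetic")
        genomes[sp] = GenomeRecord(sp, contigs[sp], cls)
        species_meta[sp] = SpeciesMeta(sp, cls, sp == params.outgroup)

    refs = ReferenceSet(ref_proteins, ref_cds, marker_prot, locus_markers, family_labels)
    return SimResult(params, genomes, refs, truth, truth_models, species_meta)


def _build_locus(
    rng: np.random.Generator,
    params: SimParams,
    cds: str | None,
    exon_codons: list[int],
    lesion_codon: int | None,
    lesion_kind: str | None,
    marker_cds: list[str],
) -> tuple[str, tuple[int, int], list[tuple[int, int]]]:
    """Assemble one locus contig: markers, intergenic spacers and the gene."""
    ig = params.intergenic_len
    n_up = len(marker_cds) // 2
    parts: list[str] = []
    pos = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        iv = (pos, pos + len(seq))
        pos += len(seq)
        return iv

    def spacer() -> None:
        emit(random_dna(rng, ig, params.gc_content))

    spacer()
    for m in marker_cds[:n_up]:
        emit(m)
        spacer()
    gene_iv = (pos, pos)
    exon_ivs: list[tuple[int, int]] = []
    if cds is not None:
        delta = 0
        if lesion_kind == "indel_1bp":
            delta = len(cds) - 3 * sum(exon_codons)
        elif lesion_kind == "indel_2bp":
            delta = len(cds) - 3 * sum(exon_codons)
        exon_lens = _exon_base_lengths(exon_codons, lesion_codon, delta)
        gene_start = pos
        offset = 0
        for e, blen in enumerate(exon_lens):
            iv = emit(cds[offset : offset + blen])
            exon_ivs.append(iv)
            offset += blen
            if e < len(exon_lens) - 1:
                ilen = int(rng.integers(params.intron_len[0], params.intron_len[1] + 1))
                body = random_dna(rng, ilen - 4, params.gc_content)
                emit("GT" + body + "AG")
        gene_iv = (gene_start, pos)
        spacer()
    for m in marker_cds[n_up:]:
        emit(m)
        spacer()
    return "".join(parts), gene_iv, exon_ivs


# ---------------------------------------------------------------------------
# presets and serialization

BENCHMARK_TREE = (
    "(((tel1:0.02,tel2:0.02):0.01,((tel3:0.02,tel4:0.02):0.01,"
    "(tel5:0.02,tel6:0.02):0.01):0.005):0.03,"
    "((mam1:0.03,(mam2:0.02,mam3:0.02):0.01):0.02,"
    "(bird1:0.03,bird2:0.03):0.02):0.02,shark:0.1);"
)

BENCHMARK_CLASSES = {
    **{f"tel{i}": "Actinopterygii" for i in range(1, 7)},
    "mam1": "Mammals",
    "mam2": "Mammals",
    "mam3": "Mammals",
    "bird1": "Birds",
    "bird2": "Birds",
    "shark": "Chondrichthyes",
}


def benchmark_params(seed: int = 42) -> SimParams:
    """The benchmark preset: 12 species, 6 melanin-pathway families, TWGD clade."""
    return SimParams(
        species_tree=BENCHMARK_TREE,
        wgd_clade={f"tel{i}" for i in range(1, 7)},
        families=["tyr", "tyrp1", "tyrp2", "pmel", "mitf", "slc24a5"],
        duplicated_families={"tyr", "tyrp1", "pmel", "mitf"},
        exons_per_gene=(4, 6),
        exon_len=(40, 80),
        intron_len=(120, 300),
        intergenic_len=250,
        p_pseudogene=0.1,
        p_loss=0.1,
        flank_markers=2,
        gc_content=0.42,
        seed=seed,
        taxon_classes=BENCHMARK_CLASSES,
        outgroup="shark",
    )


MINI_TREE = "((sA:0.02,sB:0.02):0.02,(sC:0.03,sD:0.03):0.01);"


def mini_params(seed: int = 0) -> SimParams:
    """A 4-species, 2-family preset for fast smoke runs and determinism checks."""
    return SimParams(
        species_tree=MINI_TREE,
        wgd_clade={"sA", "sB"},
        families=["fam1", "fam2"],
        duplicated_families={"fam1"},
        exons_per_gene=(3, 4),
        exon_len=(40, 60),
        intron_len=(120, 250),
        intergenic_len=200,
        p_pseudogene=0.15,
        p_loss=0.1,
        flank_markers=2,
        seed=seed,
        taxon_classes={"sA": "Synthetic", "sB": "Synthetic", "sC": "Synthetic", "sD": "Synthetic"},
        outgroup="sD",
    )


def truth_copy_matrix(
    truth: list[TruthEvent], species_meta, columns: list[str]
):
    """Expected copy-number matrix implied by a truth log (for benchmarking)."""
    from .census import CopyNumberMatrix
    import pandas as pd

    species = sorted(species_meta)
    totals = pd.DataFrame(0, index=species, columns=list(columns), dtype=int)
    pseudo = pd.DataFrame(0, index=species, columns=list(columns), dtype=int)
    for ev in truth:
        if ev.event == "lost" or ev.copy_label not in totals.columns:
            continue
        totals.loc[ev.species, ev.copy_label] += 1
        if ev.event.startswith("pseudogene"):
            pseudo.loc[ev.species, ev.copy_label] += 1
    return CopyNumberMatrix(totals, pseudo)


def write_dataset(result: SimResult, outdir: str | Path) -> None:
    """Write genomes, references, truth GFF3/TSV and a params echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gdir = outdir / "genomes"
    gdir.mkdir(exist_ok=True)
    for sp, genome in sorted(result.genomes.items()):
        write_fasta(
            [SequenceRecord(cid, cid, seq) for cid, seq in sorted(genome.contigs.items())],
            gdir / f"{sp}.fasta",
        )
        write_gff3(sorted(result.truth_models[sp], key=lambda m: m.gene_id),
                   gdir / f"{sp}.truth.gff3")
    result.refs.save(outdir / "refs")
    write_species_table(
        [result.species_meta[sp] for sp in sorted(result.species_meta)],
        outdir / "species.tsv",
    )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "species\tfamily\tcopy_label\tevent\tlesion_codon_index\t"
            "lesion_exon_ordinal\tcontig\tstart\tend\tstrand\n"
        )
        for ev in result.truth:
            fh.write(
                "\t".join(
                    "" if v is None else str(v)
                    for v in (
                        ev.species, ev.family, ev.copy_label, ev.event,
                        ev.lesion_codon_index, ev.lesion_exon_ordinal,
                        ev.contig, ev.start, ev.end, ev.strand,
                    )
                )
                + "\n"
            )
    params = dataclasses.asdict(result.params)
    params["wgd_clade"] = sorted(params["wgd_clade"])
    params["duplicated_families"] = sorted(params["duplicated_families"])
    params["exons_per_gene"] = list(params["exons_per_gene"])
    params["exon_len"] = list(params["exon_len"])
    params["intron_len"] = list(params["intron_len"])
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
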