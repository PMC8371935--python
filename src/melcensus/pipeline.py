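"""End-to-end census pipeline: search -> model -> filter -> orthology ->
pseudogene scan -> copy-number census -> absence verification -> trees.

Every stage is deterministic for a fixed configuration seed; two runs over
the same inputs produce byte-identical TSV/GFF3/newick artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .census import CopyNumberMatrix, GeneCopy, aggregate_by_lineage, assign_orthology, build_copy_matrix
from .core_io import GenomeRecord, PipelineConfig, SpeciesMeta, SequenceRecord, write_fasta, write_gff3
from .genemodel import assess_completeness, model_region
from .pseudogene import build_codon_alignment, classify_pseudogene
from .phylo import GeneTree, bootstrap_support, progressive_msa
from .pseudogene import trim_alignment
from .search import AbsenceReport, HitRegion, SearchEngine, apply_filter, chain_hsps, verify_absence
from .simulate import ReferenceSet


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_checksums: dict[str, str]
    counts: dict[str, int]

    def check(self) -> None:
        c = self.counts
        if any(v < 0 for v in c.values()):
            raise ValueError("negative stage count")
        if c["models"] > c["regions_accepted"] + c["regions_rescued"]:
            raise ValueError("more models than accepted+rescued regions")
        if c["calls"] != c["models"]:
            raise ValueError("every model must receive exactly one pseudogene call")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    manifest: RunManifest
    copies: list[GeneCopy]
    matrix: CopyNumberMatrix
    lineage: object
    absences: list[AbsenceReport]
    trees: dict[str, GeneTree]
    regions: list[HitRegion]
    refs: ReferenceSet | None = None


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _merge_loci(regions: list[HitRegion]) -> list[list[HitRegion]]:
    """Group regions on the same contig/strand whose envelopes overlap."""
    groups: list[list[HitRegion]] = []
    by_key: dict[tuple[str, str], list[HitRegion]] = {}
    for r in regions:
        by_key.setdefault((r.contig, r.strand), []).append(r)
    for key in sorted(by_key):
        rs = sorted(by_key[key], key=lambda r: (r.g_start, r.g_end, r.query_id))
        cur = [rs[0]]
        cur_end = rs[0].g_end
        for r in rs[1:]:
            if r.g_start < cur_end:
                cur.append(r)
                cur_end = max(cur_end, r.g_end)
            else:
                groups.append(cur)
                cur = [r]
                cur_end = r.g_end
        groups.append(cur)
    return groups


def run_pipeline(
    config: PipelineConfig,
    genomes: dict[str, GenomeRecord],
    refs: ReferenceSet,
    species_meta: dict[str, SpeciesMeta],
    out_dir: str | Path | None = None,
) -> PipelineResult:
    if not genomes:
        raise PipelineError("input", "no genomes")
    for sp in genomes:
        if sp not in species_meta:
            raise PipelineError("input", f"species {sp!r} missing from species table")
    label_family = {
        lab: fam for fam, labs in refs.family_labels.items() for lab in labs
    }
    all_labels = sorted(label_family)

    all_regions: list[HitRegion] = []
    copies: list[GeneCopy] = []
    absences: list[AbsenceReport] = []
    contig_markers: dict[tuple[str, str], set[str]] = {}
    n_acc = n_res = 0

    for sp in sorted(genomes):
        genome = genomes[sp]
        engine = SearchEngine(genome, config)
        sp_regions: list[HitRegion] = []
        try:
            for label in all_labels:
                prot = refs.proteins[label]
                hsps = engine.search(prot)
                sp_regions.extend(chain_hsps(hsps, config, label, len(prot)))
            for mname in sorted(refs.markers):
                mprot = refs.markers[mname]
                for r in chain_hsps(engine.search(mprot), config, mname, len(mprot)):
                    if r.identity_pct >= config.identity_min and r.coverage_pct >= config.coverage_min:
                        contig_markers.setdefault((sp, r.contig), set()).add(mname)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("search", f"{sp}: {exc}") from exc
        all_regions.extend(sp_regions)

        try:
            for gi, group in enumerate(_merge_loci(sp_regions)):
                best = min(group, key=lambda r: (-r.raw_score, r.query_id, r.g_start))
                model = model_region(
                    refs.proteins[best.query_id], genome, best,
                    config, gene_id=f"{sp}|{best.contig}|L{gi}",
                )
                complete = False
                if model is not None:
                    report = assess_completeness(model, "contig_edge" in model.notes)
                    complete = report.overall_complete
                status = apply_filter(best, complete, config)
                for r in group:
                    if r is not best:
                        r.status = "rejected"
                if status == "accepted":
                    n_acc += 1
                elif status == "rescued":
                    n_res += 1
                if status in ("accepted", "rescued") and model is not None:
                    copies.append(
                        GeneCopy(
                            species=sp,
                            contig=best.contig,
                            strand=best.strand,
                            g_start=model.span[0],
                            g_end=model.span[1],
                            family=label_family[best.query_id],
                            protein=model.protein,
                            status=status,
                            model=model,
                            region=best,
                        )
                    )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("model", f"{sp}: {exc}") from exc

    try:
        assign_orthology(
            copies, refs.proteins, refs.family_labels, refs.locus_markers, contig_markers
        )
    except Exception as exc:
        raise PipelineError("orthology", str(exc)) from exc

    try:
        for c in copies:
            ref_label = c.label if c.label in refs.cds else c.family
            aln = build_codon_alignment(refs.cds[ref_label], c.model.cds)
            c.call = classify_pseudogene(
                aln, c.model, species=c.species, gene=c.family, copy_label=c.label
            )
            c.call.species = c.species
    except Exception as exc:
        raise PipelineError("pseudogene", str(exc)) from exc

    try:
        engines: dict[str, SearchEngine] = {}
        for sp in sorted(genomes):
            present = {c.label for c in copies if c.species == sp}
            exclude = [
                (c.contig, c.g_start, c.g_end) for c in copies if c.species == sp
            ]
            engine = engines.setdefault(sp, SearchEngine(genomes[sp], config))
            for label in all_labels:
                if label in present:
                    continue
                try:
                    absences.append(
                        verify_absence(
                            label, refs.proteins[label], genomes[sp], config, exclude, engine
                        )
                    )
                except ValueError as exc:
                    absences.append(
                        AbsenceReport(label, sp, False, 0.0, 0.0, None, str(exc))
                    )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("absence", str(exc)) from exc

    try:
        matrix = build_copy_matrix(copies, species_meta, columns=all_labels)
        lineage = aggregate_by_lineage(matrix, species_meta)
    except Exception as exc:
        raise PipelineError("census", str(exc)) from exc

    try:
        trees = build_family_trees(copies, refs, species_meta, config)
    except Exception as exc:
        raise PipelineError("trees", str(exc)) from exc

    checksums = {
        sp: _sha256("".join(f">{cid}{seq}" for cid, seq in sorted(g.contigs.items())))
        for sp, g in sorted(genomes.items())
    }
    checksums["refs"] = _sha256(json.dumps(sorted(refs.proteins.items())))
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.rng_seed,
        version=__version__,
        input_checksums=checksums,
        counts={
            "genomes": len(genomes),
            "queries": len(all_labels) + len(refs.markers),
            "hit_regions": len(all_regions),
            "regions_accepted": n_acc,
            "regions_rescued": n_res,
            "models": len(copies),
            "calls": sum(1 for c in copies if c.call is not None),
            "absences": len(absences),
        },
    )
    manifest.check()
    result = PipelineResult(
        manifest, copies, matrix, lineage, absences, trees, all_regions, refs
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            write_artifacts(result, out_dir)
        except Exception as exc:
            # keep whatever was written, marked as incomplete
            for p in sorted(out_dir.rglob("*")):
                if p.is_file() and not p.name.endswith(".partial"):
                    p.rename(p.with_name(p.name + ".partial"))
            raise PipelineError("write", str(exc)) from exc
    return result


def build_family_trees(
    copies: list[GeneCopy],
    refs: ReferenceSet,
    species_meta: dict[str, SpeciesMeta],
    config: PipelineConfig,
) -> dict[str, GeneTree]:
    """Bootstrapped NJ tree per gene family from the recovered proteins."""
    outgroup_sp = next(
        (sp for sp, m in sorted(species_meta.items()) if m.is_outgroup), None
    )
    trees: dict[str, GeneTree] = {}
    for fam in sorted(refs.family_labels):
        seqs: dict[str, str] = {}
        for c in copies:
            if c.family != fam or c.label == "ambiguous":
                continue
            if c.call is not None and c.call.verdict != "intact":
                continue  # truncated/frameshifted proteins distort distances
            prot = c.protein.rstrip("*").replace("*", "X")
            if len(prot) >= 30:
                seqs[f"{c.species}|{c.label}"] = prot
        if len(seqs) < 4:
            continue
        labels, rows = progressive_msa(seqs)
        rows = trim_alignment(rows)
        # root on the designated outgroup species when it retains the family;
        # otherwise any copy carrying the pre-duplication (unsuffixed) label
        # sits outside the WGD split and roots it equally well
        outgroup = None
        if outgroup_sp is not None:
            cands = [l for l in labels if l.startswith(outgroup_sp + "|")]
            outgroup = cands[0] if cands else None
        if outgroup is None:
            cands = sorted(l for l in labels if l.split("|", 1)[1] == fam)
            outgroup = cands[0] if cands else None
        trees[fam] = bootstrap_support(
            rows, labels, config.bootstrap_reps, config.rng_seed, outgroup
        )
    return trees


def write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    from .report import summarize, write_views

    out_dir.mkdir(parents=True, exist_ok=True)
    # hit regions
    with open(out_dir / "hits.tsv", "w") as fh:
        fh.write(
            "species_contig\tquery\tstrand\tstart\tend\tscore\tevalue\t"
            "identity_pct\tcoverage_pct\tstatus\n"
        )
        for r in sorted(
            result.regions, key=lambda r: (r.contig, r.g_start, r.query_id)
        ):
            fh.write(
                f"{r.contig}\t{r.query_id}\t{r.strand}\t{r.g_start}\t{r.g_end}\t"
                f"{r.raw_score}\t{r.best_evalue:.3g}\t{r.identity_pct:.1f}\t"
                f"{r.coverage_pct:.1f}\t{r.status or 'unfiltered'}\n"
            )
    models = [c.model for c in result.copies]
    write_gff3(sorted(models, key=lambda m: m.gene_id), out_dir / "models.gff3")
    write_fasta(
        [SequenceRecord(m.gene_id, m.gene_id, m.cds) for m in
         sorted(models, key=lambda m: m.gene_id)],
        out_dir / "models_cds.fasta",
    )
    write_fasta(
        [SequenceRecord(m.gene_id, m.gene_id, m.protein or "X") for m in
         sorted(models, key=lambda m: m.gene_id)],
        out_dir / "models_protein.fasta",
    )
    with open(out_dir / "absence.tsv", "w") as fh:
        fh.write("species\tgene\tlost\tbest_identity\tbest_coverage\tnote\n")
        for a in sorted(result.absences, key=lambda a: (a.species, a.query_id)):
            fh.write(
                f"{a.species}\t{a.query_id}\t{str(a.lost).lower()}\t"
                f"{a.best_identity:.1f}\t{a.best_coverage:.1f}\t{a.note}\n"
            )
    summarize(result.matrix, [c.call for c in result.copies if c.call], out_dir)
    result.lineage.to_csv(out_dir / "lineage_table.tsv", sep="\t")
    tdir = out_dir / "trees"
    tdir.mkdir(exist_ok=True)
    for fam, tree in sorted(result.trees.items()):
        (tdir / f"{fam}.nwk").write_text(tree.newick() + "\n")
    write_views(result, out_dir / "views")
    result.manifest.to_json(out_dir / "manifest.json")
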