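import numpy as np
import pytest

from melcensus.core_io import GenomeRecord, PipelineConfig, reverse_complement, translate
from melcensus.genemodel import (
    GeneModel,
    assess_completeness,
    extract_cds,
    model_region,
    spliced_align,
)
from melcensus.search import HitRegion, Hsp
from melcensus.simulate import (
    evolve_protein_coding,
    plant_lesion,
    random_cds,
    random_dna,
)
from tests.oracles import spliced_best_score


@pytest.fixture(scope="module")
def cfg():
    return PipelineConfig()


def _gene_with_introns(rng, cds, exon_codons, intron_range=(120, 300)):
    """Assemble gene DNA + truth exon intervals (gene starts at position 0)."""
    parts, exons, pos, off = [], [], 0, 0
    for i, ncod in enumerate(exon_codons):
        seg = cds[off : off + 3 * ncod]
        off += 3 * ncod
        exons.append((pos, pos + len(seg)))
        parts.append(seg)
        pos += len(seg)
        if i < len(exon_codons) - 1:
            intron = "GT" + random_dna(rng, int(rng.integers(*intron_range)) - 4) + "AG"
            parts.append(intron)
            pos += len(intron)
    return "".join(parts), exons


class TestSplicedAlign:
    def test_intronless_gene_is_single_exon_global_match(self, cfg):
        rng = np.random.default_rng(0)
        cds = random_cds(rng, 80)
        query = translate(cds)[:-1]
        dna = random_dna(rng, 400) + cds + random_dna(rng, 400)
        m = spliced_align(query, dna, cfg)
        assert len(m.exons) == 1
        assert m.exons[0] == (400, 400 + len(cds))  # includes the stop codon
        assert m.protein == translate(cds)

    def test_three_exon_boundaries_exactly_recovered(self, cfg):
        rng = np.random.default_rng(1)
        cds = random_cds(rng, 150)
        query = translate(cds)[:-1]
        gene, exons = _gene_with_introns(rng, cds, [50, 60, 40])
        dna = random_dna(rng, 300) + gene + random_dna(rng, 300)
        m = spliced_align(query, dna, cfg)
        assert m.exons == [(s + 300, e + 300) for s, e in exons]
        assert m.protein == translate(cds)

    def test_boundary_recovery_under_divergence(self, cfg):
        """>=95% of exon boundaries recovered exactly at 0.1 subs/site."""
        rng = np.random.default_rng(2)
        total = exact = 0
        for _ in range(15):
            ncods = [int(rng.integers(40, 70)) for _ in range(3)]
            cds = random_cds(rng, sum(ncods))
            query = translate(cds)[:-1]
            diverged = evolve_protein_coding(cds, 0.1, rng)
            gene, exons = _gene_with_introns(rng, diverged, ncods)
            dna = random_dna(rng, 200) + gene + random_dna(rng, 200)
            m = spliced_align(query, dna, cfg)
            want = [(s + 200, e + 200) for s, e in exons]
            for iv in want:
                total += 1
                exact += iv in m.exons
        assert exact / total >= 0.95

    def test_score_matches_exhaustive_oracle(self, cfg):
        """Kernel score equals the plain-Python spliced DP on small instances."""
        rng = np.random.default_rng(3)
        for trial in range(4):
            ncods = [int(rng.integers(30, 50)) for _ in range(2)]
            cds = random_cds(rng, sum(ncods))
            query = translate(cds)[:-1][:100]
            diverged = evolve_protein_coding(cds, rng.uniform(0, 0.1), rng)
            gene, _ = _gene_with_introns(rng, diverged, ncods, (120, 200))
            pad = max(0, 1500 - len(gene))
            dna = (random_dna(rng, pad // 2) + gene + random_dna(rng, pad // 2))[:2000]
            m = spliced_align(query, dna, cfg)
            assert m is not None and m.score == spliced_best_score(query, dna)

    def test_unrelated_sequence_yields_no_model(self, cfg):
        m = spliced_align("P" * 30, "A" * 600, cfg)
        assert m is None

    def test_short_query_rejected(self, cfg):
        with pytest.raises(ValueError):
            spliced_align("MKL", "ATG" * 100, cfg)


class TestCompleteness:
    def _model_for(self, cfg, cds, rng):
        query = translate(cds if len(cds) % 3 == 0 else cds[: len(cds) - len(cds) % 3])
        query = query.rstrip("*").replace("*", "X")
        dna = random_dna(rng, 300) + cds + random_dna(rng, 300)
        return spliced_align(query, dna, cfg)

    def test_intact_gene_all_flags_true(self, cfg):
        rng = np.random.default_rng(4)
        cds = random_cds(rng, 80)
        rep = assess_completeness(self._model_for(cfg, cds, np.random.default_rng(5)))
        assert rep.overall_complete and not rep.notes

    def test_stop_lesion_flips_only_internal_stop_flag(self, cfg):
        rng = np.random.default_rng(6)
        cds = random_cds(rng, 80)
        lesioned, _ = plant_lesion(cds, "stop_point_mutation", rng)
        query = translate(cds)[:-1]
        dna = random_dna(rng, 300) + lesioned + random_dna(rng, 300)
        rep = assess_completeness(spliced_align(query, dna, cfg))
        assert not rep.no_internal_stop
        assert rep.has_start and rep.has_terminal_stop and rep.no_frameshift

    def test_frameshift_lesion_flips_frameshift_flag(self, cfg):
        rng = np.random.default_rng(7)
        cds = random_cds(rng, 80)
        lesioned, _ = plant_lesion(cds, "indel_1bp", rng)
        query = translate(cds)[:-1]
        dna = random_dna(rng, 300) + lesioned + random_dna(rng, 300)
        rep = assess_completeness(spliced_align(query, dna, cfg))
        assert not rep.no_frameshift

    def test_assessment_is_pure(self, cfg):
        rng = np.random.default_rng(8)
        m = self._model_for(cfg, random_cds(rng, 60), rng)
        assert assess_completeness(m) == assess_completeness(m)


class TestExtractCds:
    def test_forward_single_exon_is_substring(self):
        genome = GenomeRecord("t", {"c": "A" * 10 + "ATGCCCTAA" + "G" * 10})
        m = GeneModel("g", "c", "+", [(10, 19)], "", "", "", "", 0, 0.0)
        assert extract_cds(m, genome) == "ATGCCCTAA"

    def test_minus_strand_reverse_complements(self):
        contig = "A" * 10 + "ATGCCCTAA" + "G" * 10
        genome = GenomeRecord("t", {"c": contig})
        m = GeneModel("g", "c", "-", [(10, 19)], "", "", "", "", 0, 0.0)
        assert extract_cds(m, genome) == reverse_complement("ATGCCCTAA")

    def test_out_of_bounds_rejected(self):
        genome = GenomeRecord("t", {"c": "ACGT" * 10})
        m = GeneModel("g", "c", "+", [(30, 50)], "", "", "", "", 0, 0.0)
        with pytest.raises(ValueError, match="out of bounds"):
            extract_cds(m, genome)


def test_minus_strand_region_modeling_round_trip(cfg):
    """A gene planted on the minus strand is modeled with forward coordinates
    whose extracted CDS translates back to the query protein."""
    rng = np.random.default_rng(9)
    cds = random_cds(rng, 90)
    query = translate(cds)[:-1]
    gene, exons = _gene_with_introns(rng, cds, [40, 50])
    fwd = random_dna(rng, 300) + gene + random_dna(rng, 300)
    contig = reverse_complement(fwd)
    genome = GenomeRecord("t", {"c": contig})
    hsp = Hsp("c", "-", 0, 0, len(contig), 0, len(query), 0, 0.0, 0.0, "", "")
    region = HitRegion("c", "-", [hsp], "q", len(query))
    m = model_region(query, genome, region, cfg)
    assert m.strand == "-"
    assert extract_cds(m, genome) == "".join(
        gene[s:e] for s, e in exons
    )
    assert translate(extract_cds(m, genome)) == translate(cds)
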