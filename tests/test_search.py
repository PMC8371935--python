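import numpy as np
import pytest

from melcensus.core_io import GenomeRecord, PipelineConfig, translate, reverse_complement
from melcensus.scoring import BLOSUM62, AA_INDEX
from melcensus.search import (
    Hsp,
    SearchEngine,
    apply_filter,
    chain_hsps,
    evalue,
    seed_and_extend,
    verify_absence,
)
from melcensus.simulate import evolve_protein_coding, random_cds, random_dna


@pytest.fixture(scope="module")
def cfg():
    return PipelineConfig()


def _planted_genome(rng, n_codons=60, flank=1000):
    cds = random_cds(rng, n_codons + 1)[: 3 * n_codons]  # drop the stop codon
    left = random_dna(rng, flank)
    right = random_dna(rng, flank)
    contig = left + cds + right
    return translate(cds), contig, (flank, flank + len(cds))


class TestSeedAndExtend:
    def test_exact_planted_match_recovered(self, cfg):
        rng = np.random.default_rng(0)
        query, contig, (s, e) = _planted_genome(rng)
        genome = GenomeRecord("t", {"c": contig})
        hsps = seed_and_extend(query, genome, cfg)
        best = max(hsps, key=lambda h: h.raw_score)
        assert (best.g_start, best.g_end) == (s, e)
        assert best.strand == "+" and best.q_aln == best.t_aln == query
        assert best.evalue <= 1e-5

    def test_strand_symmetry(self, cfg):
        rng = np.random.default_rng(1)
        query, contig, (s, e) = _planted_genome(rng)
        fwd = max(
            seed_and_extend(query, GenomeRecord("t", {"c": contig}), cfg),
            key=lambda h: h.raw_score,
        )
        rc = max(
            seed_and_extend(
                query, GenomeRecord("t", {"c": reverse_complement(contig)}), cfg
            ),
            key=lambda h: h.raw_score,
        )
        assert rc.raw_score == fwd.raw_score
        assert rc.strand == "-"
        L = len(contig)
        assert (rc.g_start, rc.g_end) == (L - fwd.g_end, L - fwd.g_start)

    def test_short_query_rejected(self, cfg):
        genome = GenomeRecord("t", {"c": "ACGT" * 100})
        with pytest.raises(ValueError, match="shorter"):
            seed_and_extend("MKL", genome, cfg)

    def test_hsp_score_matches_rescoring_of_alignment(self, cfg):
        """Raw score equals re-scoring the aligned pair under BLOSUM62 + gaps."""
        rng = np.random.default_rng(2)
        cds = random_cds(rng, 80)
        query = translate(cds)[:-1]
        diverged = evolve_protein_coding(cds, 0.08, rng)[:-3]
        contig = random_dna(rng, 600) + diverged + random_dna(rng, 600)
        hsps = seed_and_extend(query, GenomeRecord("t", {"c": contig}), cfg)
        for h in hsps:
            score = 0
            in_gap = False
            for qa, ta in zip(h.q_aln, h.t_aln):
                if qa == "-" or ta == "-":
                    score -= 1 if in_gap else 12
                    in_gap = True
                else:
                    score += int(BLOSUM62[AA_INDEX[qa], AA_INDEX[ta]])
                    in_gap = False
            assert score == h.raw_score


class TestEvalue:
    def test_extra_bit_halves_expectation(self):
        assert evalue(31.0, 100, 10000) == pytest.approx(evalue(30.0, 100, 10000) / 2)

    def test_zero_bits_gives_search_space_size(self):
        assert evalue(0.0, 100, 9000) == pytest.approx(100 * 2 * 9000)

    def test_strictly_decreasing_in_bit_score(self):
        vals = [evalue(b, 200, 50000) for b in range(0, 100, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_positive_lengths_required(self):
        with pytest.raises(ValueError):
            evalue(10.0, 0, 100)


def _mk_hsp(q0, q1, g0, g1, strand="+", score=100, contig="c"):
    n = q1 - q0
    return Hsp(contig, strand, 0, g0, g1, q0, q1, score, 50.0, 1e-10, "A" * n, "A" * n)


class TestChaining:
    def test_two_exon_chain_full_coverage(self, cfg):
        h1 = _mk_hsp(0, 50, 1000, 1150)
        h2 = _mk_hsp(50, 100, 1350, 1500)
        (region,) = chain_hsps([h1, h2], cfg, "q", 100)
        assert region.coverage_pct == 100.0
        assert (region.g_start, region.g_end) == (1000, 1500)

    def test_opposite_strands_never_chain(self, cfg):
        h1 = _mk_hsp(0, 50, 1000, 1150, "+")
        h2 = _mk_hsp(50, 100, 1350, 1500, "-")
        assert len(chain_hsps([h1, h2], cfg, "q", 100)) == 2

    def test_gap_beyond_max_intron_splits_regions(self, cfg):
        h1 = _mk_hsp(0, 50, 1000, 1150)
        h2 = _mk_hsp(50, 100, 1150 + cfg.max_intron_len + 1, 1150 + cfg.max_intron_len + 151)
        assert len(chain_hsps([h1, h2], cfg, "q", 100)) == 2

    def test_minus_strand_chains_in_reverse_genomic_order(self, cfg):
        h1 = _mk_hsp(0, 50, 2000, 2150, "-")
        h2 = _mk_hsp(50, 100, 1000, 1150, "-")
        (region,) = chain_hsps([h1, h2], cfg, "q", 100)
        assert len(region.hsps) == 2

    def test_empty_input(self, cfg):
        assert chain_hsps([], cfg, "q", 100) == []

    def test_self_hit_has_perfect_identity_and_coverage(self, cfg):
        """A reference protein searched against its own exact gene chains to
        a region with 100% identity and coverage, split across introns."""
        rng = np.random.default_rng(3)
        cds = random_cds(rng, 120)[:-3]
        query = translate(cds)
        gene = cds[:150] + "GT" + random_dna(rng, 200) + "AG" + cds[150:]
        contig = random_dna(rng, 500) + gene + random_dna(rng, 500)
        genome = GenomeRecord("t", {"c": contig})
        regions = chain_hsps(seed_and_extend(query, genome, cfg), cfg, "q", len(query))
        best = regions[0]
        assert best.identity_pct == 100.0
        assert best.coverage_pct == 100.0


class TestFilter:
    @pytest.mark.parametrize(
        "ident,cov,complete,expected",
        [
            (55.0, 60.0, False, "accepted"),
            (48.0, 48.0, True, "rescued"),
            (48.0, 48.0, False, "rejected"),
            (44.9, 60.0, True, "rejected"),
            (50.0, 50.0, False, "accepted"),
        ],
    )
    def test_accept_rescue_reject_rule(self, cfg, ident, cov, complete, expected):
        region = chain_hsps([_mk_hsp(0, 50, 0, 150)], cfg, "q", 100)[0]
        # override measured stats via monkeypatched properties
        class R:
            identity_pct = ident
            coverage_pct = cov
            status = None

        assert apply_filter(R(), complete, cfg) == expected


class TestVerifyAbsence:
    def test_truly_deleted_gene_reported_lost(self, cfg):
        rng = np.random.default_rng(4)
        query = translate(random_cds(rng, 150))[:-1]
        genome = GenomeRecord("t", {"c": random_dna(rng, 3000)})
        rep = verify_absence("q", query, genome, cfg)
        assert rep.lost and "no candidate" in rep.note

    def test_diverged_gene_surfaces_and_blocks_loss_call(self, cfg):
        """A copy diverged to ~45% identity is found by the relaxed re-scan
        so the loss call is withheld."""
        rng = np.random.default_rng(0)
        cds = random_cds(rng, 150)
        query = translate(cds)[:-1]
        diverged = evolve_protein_coding(cds, 0.5, rng)
        contig = random_dna(rng, 500) + diverged + random_dna(rng, 500)
        rep = verify_absence("q", query, GenomeRecord("t", {"c": contig}), cfg)
        assert not rep.lost
        assert rep.best_identity >= 30.0

    def test_refuses_when_gene_clearly_present(self, cfg):
        rng = np.random.default_rng(5)
        query, contig, _ = _planted_genome(rng, n_codons=100)
        with pytest.raises(ValueError, match="precondition"):
            verify_absence("q", query, GenomeRecord("t", {"c": contig}), cfg)


def test_strand_invariance_of_region_statistics(cfg):
    """Reverse-complementing every contig leaves region scores and stats unchanged."""
    rng = np.random.default_rng(6)
    cds = random_cds(rng, 100)
    query = translate(cds)[:-1]
    diverged = evolve_protein_coding(cds, 0.06, rng)
    gene = diverged[:120] + "GT" + random_dna(rng, 150) + "AG" + diverged[120:]
    contig = random_dna(rng, 400) + gene + random_dna(rng, 400)

    def stats(c):
        genome = GenomeRecord("t", {"c": c})
        regions = chain_hsps(seed_and_extend(query, genome, cfg), cfg, "q", len(query))
        r = regions[0]
        return (r.raw_score, round(r.identity_pct, 6), round(r.coverage_pct, 6))

    assert stats(contig) == stats(reverse_complement(contig))
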