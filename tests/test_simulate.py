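import numpy as np
import pytest
from scipy import stats

from melcensus.core_io import reverse_complement, translate
from melcensus.phylo import parse_newick
from melcensus.simulate import (
    SimParams,
    evolve_protein_coding,
    mini_params,
    benchmark_params,
    plant_lesion,
    random_cds,
    simulate_dataset,
)

STOPS = ("TAA", "TAG", "TGA")


def _truth_cds(result, ev):
    """Extract one truth copy's CDS from the generated genome."""
    model = next(
        m for m in result.truth_models[ev.species] if m.contig == ev.contig
    )
    contig = result.genomes[ev.species].contigs[ev.contig]
    cds = "".join(contig[s:e] for s, e in model.exons)
    return reverse_complement(cds) if ev.strand == "-" else cds


class TestSimulateDataset:
    def test_same_seed_is_byte_identical(self):
        a = simulate_dataset(mini_params(3))
        b = simulate_dataset(mini_params(3))
        assert {s: g.contigs for s, g in a.genomes.items()} == {
            s: g.contigs for s, g in b.genomes.items()
        }
        assert a.truth == b.truth

    def test_total_loss_leaves_only_markers(self):
        params = mini_params(5)
        params.p_loss, params.p_pseudogene = 1.0, 0.0
        result = simulate_dataset(params)
        assert all(ev.event == "lost" for ev in result.truth)
        assert all(not models for models in result.truth_models.values())

    def test_truth_gff_consistent_with_genomes(self, mini_sim):
        """Extracting every truth CDS reproduces the recorded lesion state."""
        for ev in mini_sim.truth:
            if ev.event == "lost":
                continue
            cds = _truth_cds(mini_sim, ev)
            if ev.event == "pseudogene_frameshift":
                assert len(cds) % 3 != 0
                continue
            protein = translate(cds)
            assert protein.endswith("*")
            internal_stops = protein[:-1].count("*")
            if ev.event == "present_intact":
                assert internal_stops == 0
            else:  # pseudogene_stop
                assert internal_stops >= 1
                assert protein[ev.lesion_codon_index] == "*"

    def test_ab_copies_confined_to_wgd_clade(self, benchmark_sim):
        wgd = benchmark_sim.params.wgd_clade
        for ev in benchmark_sim.truth:
            if ev.copy_label.endswith(("_a", "_b")):
                assert ev.species in wgd
            elif ev.family in benchmark_sim.params.duplicated_families:
                assert ev.species not in wgd

    def test_pseudogene_fraction_within_binomial_ci(self, benchmark_sim):
        """Planted event rate matches p_pseudogene within a 95% binomial CI."""
        n = len(benchmark_sim.truth)
        k = sum(1 for e in benchmark_sim.truth if e.event.startswith("pseudogene"))
        p = benchmark_sim.params.p_pseudogene
        lo, hi = stats.binom.interval(0.95, n, p)
        assert lo <= k <= hi

    def test_introns_are_canonical(self, mini_sim):
        for sp, models in mini_sim.truth_models.items():
            for m in models:
                contig = mini_sim.genomes[sp].contigs[m.contig]
                exons = m.exons
                for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                    intron = contig[e1:s2]
                    if m.strand == "-":
                        intron = reverse_complement(intron)
                    assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_flank_markers_conserved_in_order(self, mini_sim):
        # every locus contig carries its 4 marker genes in fixed layout:
        # marker hits appear at increasing coordinates on the forward build
        refs = mini_sim.refs
        assert refs.locus_markers["fam1_a"] == refs.locus_markers["fam1"]
        assert refs.locus_markers["fam1_b"] != refs.locus_markers["fam1_a"]

    def test_contradictory_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(species_tree="(a:1,b:1);", intergenic_len=10)
        with pytest.raises(ValueError):
            SimParams(species_tree="(a:1,b:1);", wgd_clade={"zzz"})
        with pytest.raises(ValueError):
            SimParams(
                species_tree="(a:1,b:1);",
                pseudo_event_mix={"stop_point_mutation": 0.5},
            )


class TestEvolve:
    def test_zero_branch_is_identity(self):
        cds = random_cds(np.random.default_rng(0), 100)
        assert evolve_protein_coding(cds, 0.0, 1) == cds

    def test_negative_branch_rejected(self):
        cds = random_cds(np.random.default_rng(0), 100)
        with pytest.raises(ValueError):
            evolve_protein_coding(cds, -0.1, 1)

    def test_no_internal_stops_ever(self):
        rng = np.random.default_rng(2)
        cds = random_cds(rng, 120)
        for rep in range(50):
            out = evolve_protein_coding(cds, 0.2, rng)
            assert "*" not in translate(out)[:-1]
            assert out.startswith("ATG") and out[-3:] in STOPS

    def test_protein_identity_above_80pct_at_short_branch(self):
        """At 0.05 subs/site a 300-codon protein stays >80% identical."""
        rng = np.random.default_rng(3)
        cds = random_cds(rng, 300)
        prot = translate(cds)
        ok = 0
        reps = 200
        for _ in range(reps):
            out = translate(evolve_protein_coding(cds, 0.05, rng))
            ident = sum(a == b for a, b in zip(prot, out)) / len(prot)
            ok += ident > 0.80
        assert ok / reps >= 0.95

    def test_identity_decays_with_tree_distance(self, benchmark_sim):
        """Mean protein identity between species falls with path length."""
        tree = parse_newick(benchmark_sim.params.species_tree)

        def path_len(a, b):
            # distance through the tree via leaf depths and common ancestor
            def depth_map(node, d, out):
                if node.is_leaf:
                    out[node.name] = d + node.length
                for c in node.children:
                    depth_map(c, d + node.length, out)
                return out

            def lca_depth(node, d):
                names = set(node.leaves())
                if a in names and b in names:
                    for c in node.children:
                        r = lca_depth(c, d + c.length)
                        if r is not None:
                            return r
                    return d
                return None

            depths = depth_map(tree, 0.0, {})
            return depths[a] + depths[b] - 2 * lca_depth(tree, 0.0)

        # use the intact copies of the single-copy family tyrp2
        prots = {}
        for ev in benchmark_sim.truth:
            if ev.copy_label == "tyrp2" and ev.event == "present_intact":
                prots[ev.species] = translate(_truth_cds(benchmark_sim, ev))
        species = sorted(prots)
        idents, dists = [], []
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                pa, pb = prots[a], prots[b]
                idents.append(sum(x == y for x, y in zip(pa, pb)) / len(pa))
                dists.append(path_len(a, b))
        rho = stats.spearmanr(dists, idents).statistic
        assert rho < 0


class TestPlantLesion:
    def test_stop_mutation_creates_one_new_stop(self):
        rng = np.random.default_rng(4)
        cds = random_cds(rng, 80)
        out, c = plant_lesion(cds, "stop_point_mutation", rng)
        assert translate(out)[c] == "*"
        assert translate(out).count("*") == translate(cds).count("*") + 1
        assert 5 <= c < 75

    @pytest.mark.parametrize("kind,delta", [("indel_1bp", 1), ("indel_2bp", 2)])
    def test_indel_lengths(self, kind, delta):
        rng = np.random.default_rng(5)
        cds = random_cds(rng, 80)
        out, c = plant_lesion(cds, kind, rng)
        assert abs(len(out) - len(cds)) == delta
        assert 5 <= c < 75

    def test_short_cds_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="too short"):
            plant_lesion(random_cds(rng, 20), "indel_1bp", rng)

    def test_avoid_set_respected(self):
        rng = np.random.default_rng(7)
        cds = random_cds(rng, 80)
        avoid = set(range(5, 40))
        for _ in range(10):
            _, c = plant_lesion(cds, "indel_1bp", rng, avoid)
            assert c >= 40
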