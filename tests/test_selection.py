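import math

import numpy as np
import pytest

from ilstools.coalescent import MSCSimulator, SitePattern, pattern_matches_group
from ilstools.selection import (
    CodonAlignmentSet,
    GroupSpec,
    classify_codon_site,
    estimate_ils_pattern_probability,
    find_shared_substitutions,
    fix_species_sequence,
    phylogwas_pvalue,
    translate_codon,
)
from ilstools.trees import COAL, SNAQ, SpeciesTreeCU


class TestFixSpeciesSequence:
    def test_identical_individuals(self):
        assert fix_species_sequence(["ATG", "ATG"]) == "ATG"

    def test_polymorphic_site_is_missing(self):
        assert fix_species_sequence(["ATG", "ATA"]) == "ATN"

    def test_ambiguity_code_is_not_fixed(self):
        assert fix_species_sequence(["ATG", "ATR"]) == "ATN"

    def test_missing_individual_ignored(self):
        assert fix_species_sequence(["ATG", "ATN"]) == "ATG"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fix_species_sequence(["ATG", "ATGA"])


class TestClassifyCodonSite:
    def test_two_states_retained(self):
        col = {f"s{i}": ("AAA" if i < 3 else "AGA") for i in range(9)}
        c = classify_codon_site(col)
        assert c.n_states == 2 and c.retained

    def test_three_states_filtered(self):
        col = {"a": "AAA", "b": "AGA", "c": "GAA", "d": "AAA"}
        c = classify_codon_site(col)
        assert c.n_states == 3 and not c.retained

    def test_excess_missing_filtered(self):
        col = {"a": "AAA", "b": "NNN", "c": "A-A", "d": "ANA", "e": "AAA"}
        c = classify_codon_site(col)
        assert c.missing == frozenset({"b", "c", "d"})
        assert not c.retained

    def test_synonymous_codons_are_one_state(self):
        # Leu from two codon families
        c = classify_codon_site({"a": "CTA", "b": "TTG", "c": "CTG"})
        assert c.n_states == 1

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            classify_codon_site({"a": "AXA"})


def toy_alignments():
    """Three genes over five species; gene g2 carries one diagnostic site
    for the paraphyletic group {A, C} at codon 1 (K vs R)."""
    return CodonAlignmentSet(
        {
            # monomorphic gene
            "g1": {sp: "ATGGCT" for sp in "ABCDE"},
            # codon0: monomorphic; codon1: AAA(K) in A,C vs AGA(R) in B,D,E
            "g2": {
                "A": "ATGAAA",
                "B": "ATGAGA",
                "C": "ATGAAA",
                "D": "ATGAGA",
                "E": "ATGAGA",
            },
            # variable but not group-diagnostic (A shares with B)
            "g3": {
                "A": "ATGAAA",
                "B": "ATGAAA",
                "C": "ATGAGA",
                "D": "ATGAGA",
                "E": "ATGAGA",
            },
        }
    )


class TestFindSharedSubstitutions:
    def test_toy_fixture_recovers_known_site(self):
        rep = find_shared_substitutions(toy_alignments(), GroupSpec(["A", "C"]))
        assert rep.s_genes == 1 and rep.s_sites == 1
        site = rep.sites[0]
        assert (site.gene, site.codon_index) == ("g2", 1)
        assert {site.focal_aa, site.other_aa} == {"K", "R"}
        assert rep.n_var == 2  # g2 codon 1 and g3 codon 1

    def test_group_of_all_species_rejected(self):
        with pytest.raises(ValueError):
            find_shared_substitutions(
                toy_alignments(), GroupSpec(list("ABCDE"))
            )

    def test_masked_required_species_removes_site(self):
        genes = toy_alignments().genes
        genes["g2"]["C"] = "ATGNNN"
        rep = find_shared_substitutions(
            CodonAlignmentSet(genes), GroupSpec(["A", "C"])
        )
        assert rep.s_genes == 0

    def test_masked_nonrequired_taxon_still_counts(self):
        genes = toy_alignments().genes
        genes["g2"]["E"] = "ATGNNN"
        rep = find_shared_substitutions(
            CodonAlignmentSet(genes), GroupSpec(["A", "C"])
        )
        assert rep.s_genes == 1
        assert rep.sites[0].missing == frozenset({"E"})

    def test_three_state_site_not_counted(self):
        genes = toy_alignments().genes
        genes["g2"]["E"] = "ATGGAA"  # adds a third amino acid at codon 1
        rep = find_shared_substitutions(
            CodonAlignmentSet(genes), GroupSpec(["A", "C"])
        )
        assert rep.s_sites == 0

    def test_vectorised_scan_matches_scalar_classifier(self):
        """Cross-check the numpy column scan against classify_codon_site."""
        rng = np.random.default_rng(15)
        bases = np.array(list("ACGTN"))
        species = [f"s{i}" for i in range(6)]
        genes = {}
        for g in range(5):
            length = 30
            seqs = {}
            for sp in species:
                s = bases[rng.integers(0, 5, size=length)]
                seqs[sp] = "".join(s)
            genes[f"g{g}"] = seqs
        aln = CodonAlignmentSet(genes)
        group = GroupSpec(["s0", "s3"], max_missing=2)
        rep = find_shared_substitutions(aln, group)
        expected_nvar = 0
        for gene, seqs in aln.genes.items():
            for c in range(10):
                col = {sp: seq[3 * c : 3 * c + 3] for sp, seq in seqs.items()}
                cls = classify_codon_site(col)
                if cls.retained and cls.n_states == 2:
                    expected_nvar += 1
        assert rep.n_var == expected_nvar

    def test_missing_config_freqs_sum_to_one(self):
        rep = find_shared_substitutions(toy_alignments(), GroupSpec(["A", "C"]))
        assert sum(rep.missing_config_freqs.values()) == pytest.approx(1.0)


class TestILSPatternProbability:
    species_tree = SpeciesTreeCU.from_newick(
        "((A:1,B:1):0.3,(C:1,D:1):0.3);", units=COAL
    )

    def test_brute_force_oracle_raw(self):
        """Raw p-hat against exhaustive mutation placement on stored trees."""
        import random

        group = GroupSpec(["A", "C"], max_missing=0)
        sim = MSCSimulator(self.species_tree, sample=2)
        g_mask = np.uint64(sim.species_mask(["A", "C"]))
        full = np.uint64(sim.full_mask)
        rand = random.Random(33)
        exact = 0.0
        n_trees = 3000
        for _ in range(n_trees):
            g = sim._sim_genealogy(rand)
            num = sum(
                l
                for c, l in zip(g.edge_child, g.edge_length)
                if g.node_mask[c] in (int(g_mask), int(full & ~g_mask))
            )
            exact += num / g.total_length
        exact /= n_trees
        est = estimate_ils_pattern_probability(
            self.species_tree, group, n_sims=60_000, seed=6, conditional=False
        )
        bound = 3 * (est.se + math.sqrt(exact * (1 - exact) / n_trees))
        assert abs(est.p_hat - exact) < bound

    def test_brute_force_oracle_conditional(self):
        """Conditional p-hat = P(match)/P(testable site), checked against
        exhaustive mutation placement with species-consensus collapse."""
        import random

        group = GroupSpec(["A", "C"])
        sim = MSCSimulator(self.species_tree, sample=2)
        species = sorted(set(sim.chrom_species))
        mask = {sp: sim.species_mask([sp]) for sp in species}
        rand = random.Random(99)
        num = den = 0.0
        n_trees = 8000
        for _ in range(n_trees):
            g = sim._sim_genealogy(rand)
            tot = g.total_length
            for c, l in zip(g.edge_child, g.edge_length):
                m = g.node_mask[c]
                stat = {}
                for sp in species:
                    overlap = m & mask[sp]
                    stat[sp] = (
                        "d" if overlap == mask[sp] else "a" if overlap == 0 else "s"
                    )
                if set(stat.values()) != {"d", "a"}:
                    continue  # split species or invariant at species level
                den += l / tot
                if (
                    stat["A"] == stat["C"]
                    and stat["B"] == stat["D"]
                    and stat["A"] != stat["B"]
                ):
                    num += l / tot
        exact = num / den
        est = estimate_ils_pattern_probability(
            self.species_tree, group, n_sims=100_000, seed=7
        )
        assert est.conditional
        assert abs(est.p_hat - exact) < 3 * est.se + 0.005

    def test_conditional_exceeds_raw(self):
        group = GroupSpec(["A", "C"])
        cond = estimate_ils_pattern_probability(
            self.species_tree, group, n_sims=30_000, seed=6
        )
        raw = estimate_ils_pattern_probability(
            self.species_tree, group, n_sims=30_000, seed=6, conditional=False
        )
        assert cond.p_hat > raw.p_hat

    def test_monte_carlo_consistency_across_sizes(self):
        group = GroupSpec(["A", "C"])
        small = estimate_ils_pattern_probability(
            self.species_tree, group, n_sims=10_000, seed=7
        )
        large = estimate_ils_pattern_probability(
            self.species_tree, group, n_sims=200_000, seed=8
        )
        assert abs(small.p_hat - large.p_hat) < 3 * (small.se + large.se)

    def test_ignoring_taxa_can_only_add_matches(self):
        group = GroupSpec(["A", "C"])
        base = estimate_ils_pattern_probability(
            self.species_tree, group, n_sims=50_000, seed=9, conditional=False
        )
        relaxed = estimate_ils_pattern_probability(
            self.species_tree,
            group,
            {frozenset({"B"}): 1.0},
            n_sims=50_000,
            seed=9,
            conditional=False,
        )
        assert relaxed.p_hat >= base.p_hat

    def test_required_species_config_contributes_zero(self):
        group = GroupSpec(["A", "C"], required_present=["B"])
        est = estimate_ils_pattern_probability(
            self.species_tree,
            group,
            {frozenset(): 0.5, frozenset({"B"}): 0.5},
            n_sims=20_000,
            seed=10,
        )
        assert est.per_config_rates[frozenset({"B"})] == 0.0
        with pytest.raises(ValueError, match="required"):
            estimate_ils_pattern_probability(
                self.species_tree,
                group,
                {frozenset(): 0.5, frozenset({"B"}): 0.5},
                n_sims=1000,
                seed=10,
                strict=True,
            )

    def test_dispersed_group_rarer_than_sister_group(self):
        """A clean split is more probable for a clade than for a
        phylogenetically dispersed group."""
        sister = GroupSpec(["A", "B"])
        dispersed = GroupSpec(["A", "C"])
        p_sister = estimate_ils_pattern_probability(
            self.species_tree, sister, n_sims=50_000, seed=11
        ).p_hat
        p_disp = estimate_ils_pattern_probability(
            self.species_tree, dispersed, n_sims=50_000, seed=11
        ).p_hat
        assert p_sister > p_disp


class TestPhylogwasPvalue:
    def test_observed_zero_gives_one(self):
        assert phylogwas_pvalue(0, 100, 0.01).p_value == 1.0

    def test_binomial_tail_against_exact_sum(self):
        # independent exact tail: 1 - sum_{k<5} C(1000,k) p^k (1-p)^(1000-k)
        p = 0.001
        exact = 1.0 - sum(
            math.comb(1000, k) * p**k * (1 - p) ** (1000 - k) for k in range(5)
        )
        res = phylogwas_pvalue(5, 1000, p)
        assert res.p_value == pytest.approx(exact, rel=1e-9)
        assert res.p_value == pytest.approx(0.00366, abs=5e-5)

    def test_grouping_agrees_with_binomial(self):
        st = SpeciesTreeCU.from_newick("((A:1,B:1):0.3,(C:1,D:1):0.3);", units=COAL)
        group = GroupSpec(["A", "B"])
        null = estimate_ils_pattern_probability(st, group, n_sims=100_000, seed=12)
        n_var, observed, n_datasets = 200, 3, 500
        grp = phylogwas_pvalue(
            observed, n_var, null, method="dataset-grouping",
            n_datasets=n_datasets, seed=13,
        )
        binom = phylogwas_pvalue(observed, n_var, null, method="binomial-tail")
        se = math.sqrt(max(grp.p_value * (1 - grp.p_value), 1e-6) / n_datasets)
        assert abs(grp.p_value - binom.p_value) < 3 * se + 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            phylogwas_pvalue(1, 0, 0.1)
        with pytest.raises(ValueError):
            phylogwas_pvalue(5, 1000, 0.001, method="dataset-grouping")


class TestTranslateCodon:
    @pytest.mark.parametrize(
        "codon,aa", [("ATG", "M"), ("TAA", "*"), ("AAA", "K"), ("AGA", "R")]
    )
    def test_standard_code(self, codon, aa):
        assert translate_codon(codon) == aa

    def test_unresolved_codons(self):
        assert translate_codon("ATN") is None
        assert translate_codon("A-G") is None
        assert translate_codon("ATR") is None
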