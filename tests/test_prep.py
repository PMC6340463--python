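import pytest
from Bio.Seq import Seq

from ilstools.prep import (
    GeneTreeRecord,
    GeneTreeSet,
    build_supermatrix,
    extract_fourfold_sites,
    filter_alignment,
    fourfold_prefixes,
    outgroup_monophyly_filter,
    partition_file,
    select_transcript_per_cluster,
)
from ilstools.trees import parse_newick


class TestFilterAlignment:
    def test_empty_column_removed(self):
        aln = {f"s{i}": ("-" + "ACGT" * 2) for i in range(10)}
        res = filter_alignment(aln)
        assert res.removed_columns == [0]
        assert all(len(s) == 8 for s in res.alignment.values())

    def test_low_occupancy_column_removed(self):
        # column 0 occupied in 1/10 rows < 10%? 1/10 = 10% -> kept;
        # occupied in 0 rows -> removed
        aln = {f"s{i}": (("A" if i == 0 else "-") + "ACGTACGT") for i in range(11)}
        res = filter_alignment(aln)  # 1/11 < 0.10
        assert res.removed_columns == [0]

    def test_gappy_sequence_removed_after_columns(self):
        aln = {f"s{i}": "ACGTACGTAC" for i in range(4)}
        aln["gappy"] = "AC--------"  # 80% gaps
        res = filter_alignment(aln)
        assert res.removed_sequences == ["gappy"]
        assert res.retained

    def test_boundary_gap_fraction_kept(self):
        # exactly 50% gaps is not "more than 50%"
        aln = {f"s{i}": "ACGTACGT" for i in range(4)}
        aln["half"] = "ACGT----"
        res = filter_alignment(aln)
        assert "half" in res.alignment

    def test_too_few_species_discarded(self):
        aln = {"a": "ACGT", "b": "ACGT", "c": "ACGT"}
        res = filter_alignment(aln)
        assert res.status == "discarded"
        assert res.alignment is None
        assert "4" in res.reason

    def test_species_map_collapses_individuals(self):
        aln = {f"sp1_i{i}": "ACGT" for i in range(5)}
        res = filter_alignment(aln, species_map={k: "sp1" for k in aln})
        assert res.status == "discarded"

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_alignment({"a": "ACGT"}, min_col_occupancy=1.5)

    def test_idempotent(self):
        aln = {f"s{i}": "ACGTACGTAC" for i in range(8)}
        aln["gappy"] = "AC--------"
        aln["s0"] = "-CGTACGTAC"
        first = filter_alignment(aln)
        second = filter_alignment(first.alignment)
        assert second.alignment == first.alignment
        assert second.removed_columns == [] and second.removed_sequences == []


def tree_set(newicks, outgroup="out", tip_map=None):
    records = [
        GeneTreeRecord(f"g{i}", f"c{i}", parse_newick(nw))
        for i, nw in enumerate(newicks)
    ]
    return GeneTreeSet(records=records, tip_map=tip_map or {}, outgroup=outgroup)


class TestOutgroupMonophylyFilter:
    tip_map = {
        "out1": "out", "out2": "out", "a": "A", "b": "B", "c": "C",
    }

    def test_monophyletic_outgroup_retained(self):
        gts = tree_set(
            ["((out1:1,out2:1):1,(a:1,b:1):1);"], tip_map=self.tip_map
        )
        assert len(outgroup_monophyly_filter(gts).records) == 1

    def test_paraphyletic_outgroup_discarded(self):
        gts = tree_set(
            ["((out1:1,a:1):1,(out2:1,b:1):1);"], tip_map=self.tip_map
        )
        assert len(outgroup_monophyly_filter(gts).records) == 0

    def test_zero_or_one_outgroup_tip_passes_vacuously(self):
        gts = tree_set(
            ["((a:1,b:1):1,c:1);", "((out1:1,a:1):1,b:1);"],
            tip_map=self.tip_map,
        )
        assert len(outgroup_monophyly_filter(gts).records) == 2

    def test_missing_outgroup_designation_rejected(self):
        gts = tree_set(["(a:1,b:1);"], outgroup=None)
        with pytest.raises(ValueError):
            outgroup_monophyly_filter(gts)


class TestSelectTranscriptPerCluster:
    def build(self, entries):
        records = [
            GeneTreeRecord(gene, cluster, parse_newick(nw))
            for gene, cluster, nw in entries
        ]
        return GeneTreeSet(records=records)

    def test_most_supported_tree_wins(self):
        gts = self.build(
            [
                ("tA", "c1", "(((a:1,b:1)95:1,c:1)80:1,d:1);"),  # 2 nodes >10
                ("tB", "c1", "(((a:1,b:1)95:1,c:1)5:1,d:1);"),  # 1 node >10
            ]
        )
        kept = select_transcript_per_cluster(gts)
        assert [r.gene_id for r in kept.records] == ["tA"]

    def test_cluster_without_supported_nodes_dropped(self):
        gts = self.build([("tA", "c1", "((a:1,b:1)5:1,c:1);")])
        assert select_transcript_per_cluster(gts).records == []

    def test_tie_broken_lexicographically(self):
        nw = "((a:1,b:1)95:1,c:1);"
        gts = self.build([("tB", "c1", nw), ("tA", "c1", nw)])
        kept = select_transcript_per_cluster(gts)
        assert [r.gene_id for r in kept.records] == ["tA"]

    def test_threshold_is_strict(self):
        gts = self.build([("tA", "c1", "((a:1,b:1)10:1,c:1);")])
        assert select_transcript_per_cluster(gts, 10).records == []


class TestBuildSupermatrix:
    def test_concatenation_and_partitions(self):
        genes = {
            "g1": {"A": "ACGTACGTA", "B": "ACGTACGTA"},
            "g2": {"A": "ACGTACGTACGT", "B": "ACGTACGTACGT"},
        }
        matrix, parts = build_supermatrix(genes)
        assert len(matrix["A"]) == 21
        assert parts == [("g1", 1, 9), ("g2", 10, 21)]

    def test_missing_species_filled(self):
        genes = {
            "g1": {"A": "ACGTACGTA", "B": "ACGTACGTA"},
            "g2": {"A": "ACGTACGTACGT"},
        }
        matrix, _ = build_supermatrix(genes)
        assert matrix["B"][9:] == "N" * 12

    def test_empty_and_duplicate_rejected(self):
        with pytest.raises(ValueError):
            build_supermatrix({})
        with pytest.raises(ValueError, match="duplicate"):
            build_supermatrix([("g1", {"A": "AC"}), ("g1", {"A": "AC"})])

    def test_width_equals_sum_of_partitions(self):
        genes = {f"g{i}": {"A": "A" * (3 * i + 3)} for i in range(5)}
        matrix, parts = build_supermatrix(genes)
        assert len(matrix["A"]) == sum(b - a + 1 for _, a, b in parts)

    def test_partition_file_format(self):
        text = partition_file([("g1", 1, 9), ("g2", 10, 21)])
        assert text == "DNA, g1 = 1-9\nDNA, g2 = 10-21\n"


class TestExtractFourfoldSites:
    def test_fourfold_family_emitted(self):
        sites, prov = extract_fourfold_sites(
            {"g1": {"A": "GCA", "B": "GCT", "C": "GCG"}}
        )
        assert sites == {"A": "A", "B": "T", "C": "G"}
        assert prov == [("g1", 0)]

    def test_twofold_codon_excludes_column(self):
        sites, prov = extract_fourfold_sites(
            {"g1": {"A": "GCA", "B": "AAA", "C": "GCG"}}
        )
        assert prov == []

    def test_missing_species_ignored(self):
        sites, prov = extract_fourfold_sites(
            {"g1": {"A": "GCA", "B": "NNN", "C": "GCG"}}
        )
        assert prov == [("g1", 0)]
        assert sites["B"] == "N"

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            extract_fourfold_sites({"g1": {"A": "GCAA"}})

    def test_degeneracy_table_against_biopython(self):
        """Every emitted prefix really is 4-fold under the standard code."""
        for prefix in fourfold_prefixes():
            aas = {str(Seq(prefix + b3).translate()) for b3 in "ACGT"}
            assert len(aas) == 1

    def test_substituting_third_base_never_changes_protein(self):
        sites, prov = extract_fourfold_sites(
            {
                "g1": {
                    "A": "GCAGTTCCGAAA",
                    "B": "GCGGTACCCAAG",
                    "C": "GCCGTGCCTAAA",
                }
            }
        )
        # provenance excludes the Lys (AAA/AAG, 2-fold) codon
        assert ("g1", 3) not in prov
        for gene, codon_idx in prov:
            assert codon_idx in (0, 1, 2)
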