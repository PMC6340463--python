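"""Deterministic data-preparation filters for phylotranscriptomic input.

These are the quality-control rules applied between raw per-gene
alignments/trees and the downstream coalescent analyses: alignment
occupancy filtering, discarding gene trees with non-monophyletic
outgroup individuals, keeping one transcript per gene cluster by
node-support count, concatenating fixed-nucleotide sequences into a
supermatrix, and extracting 4-fold degenerate third codon positions.

All operations are deterministic and idempotent; discard decisions are
reported with reason codes rather than silently dropping data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import dendropy
from Bio.Data import CodonTable

from .trees import is_exclusive_clade, node_support

__all__ = [
    "GeneTreeRecord",
    "GeneTreeSet",
    "AlignmentFilterResult",
    "filter_alignment",
    "outgroup_monophyly_filter",
    "select_transcript_per_cluster",
    "build_supermatrix",
    "partition_file",
    "extract_fourfold_sites",
    "fourfold_prefixes",
]

_GAP_CHARS = set("-?")
_MISSING_CHARS = set("N-?n")


@dataclass
class GeneTreeRecord:
    gene_id: str
    cluster_id: str
    tree: dendropy.Tree


@dataclass
class GeneTreeSet:
    """Gene trees grouped by cluster, with a tip -> species map.

    ``cluster_id`` groups alternative transcripts of one gene;
    node-support values (SH-like, 0-100) are read from internal-node
    labels where present.
    """

    records: list[GeneTreeRecord]
    tip_map: Dict[str, str] = field(default_factory=dict)
    outgroup: Optional[str] = None

    def species_of(self, tip_label: str) -> str:
        return self.tip_map.get(tip_label, tip_label)

    def trees(self) -> list[dendropy.Tree]:
        return [r.tree for r in self.records]


@dataclass
class AlignmentFilterResult:
    status: str  # "retained" or "discarded"
    alignment: Optional[Dict[str, str]]
    reason: Optional[str]
    removed_columns: list[int]
    removed_sequences: list[str]

    @property
    def retained(self) -> bool:
        return self.status == "retained"


def filter_alignment(
    alignment: Mapping[str, str],
    min_col_occupancy: float = 0.10,
    max_seq_gap_frac: float = 0.50,
    min_species: int = 4,
    species_map: Optional[Mapping[str, str]] = None,
) -> AlignmentFilterResult:
    """Occupancy filtering of a multiple sequence alignment.

    Columns with occupancy below ``min_col_occupancy`` are removed
    first (ambiguity codes and N count as occupied; only gap characters
    do not), then sequences whose remaining gap fraction exceeds
    ``max_seq_gap_frac``, and finally the alignment is discarded outright
    if fewer than ``min_species`` species survive.
    """
    for name, value in (
        ("min_col_occupancy", min_col_occupancy),
        ("max_seq_gap_frac", max_seq_gap_frac),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    if not alignment:
        raise ValueError("empty alignment")
    names = list(alignment)
    seqs = [alignment[n] for n in names]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences differ in length")
    n_rows = len(seqs)
    length = len(seqs[0])

    removed_columns = []
    kept_columns = []
    for j in range(length):
        occupied = sum(1 for s in seqs if s[j] not in _GAP_CHARS)
        if occupied / n_rows < min_col_occupancy:
            removed_columns.append(j)
        else:
            kept_columns.append(j)

    filtered = {
        n: "".join(s[j] for j in kept_columns) for n, s in zip(names, seqs)
    }
    removed_sequences = []
    if kept_columns:
        for n in names:
            gaps = sum(1 for ch in filtered[n] if ch in _GAP_CHARS)
            if gaps / len(kept_columns) > max_seq_gap_frac:
                removed_sequences.append(n)
    else:
        removed_sequences = list(names)
    for n in removed_sequences:
        filtered.pop(n)

    species = {
        (species_map[n] if species_map else n) for n in filtered
    }
    if len(species) < min_species:
        return AlignmentFilterResult(
            "discarded", None, f"<{min_species} species", removed_columns, removed_sequences
        )
    return AlignmentFilterResult(
        "retained", filtered, None, removed_columns, removed_sequences
    )


def outgroup_monophyly_filter(gene_trees: GeneTreeSet) -> GeneTreeSet:
    """Drop trees whose present outgroup tips are not an exclusive clade.

    Trees with one or zero outgroup tips pass vacuously (there is no
    monophyly to violate).
    """
    if gene_trees.outgroup is None:
        raise ValueError("gene tree set has no designated outgroup species")
    kept = []
    for rec in gene_trees.records:
        tips = [
            leaf.taxon.label
            for leaf in rec.tree.leaf_node_iter()
            if gene_trees.species_of(leaf.taxon.label) == gene_trees.outgroup
        ]
        if len(tips) <= 1 or is_exclusive_clade(rec.tree, tips):
            kept.append(rec)
    return replace(gene_trees, records=kept)


def _qualifying_nodes(tree: dendropy.Tree, threshold: float) -> int:
    count = 0
    for node in tree.preorder_internal_node_iter():
        sup = node_support(node)
        if sup is not None and sup > threshold:
            count += 1
    return count


def select_transcript_per_cluster(
    gene_trees: GeneTreeSet, support_threshold: float = 10.0
) -> GeneTreeSet:
    """Keep, per cluster, the transcript tree with most well-supported nodes.

    Trees with no node above the support threshold are dropped; ties are
    broken by lexicographic gene id, so the selection is deterministic.
    """
    best: Dict[str, Tuple[int, str, GeneTreeRecord]] = {}
    for rec in gene_trees.records:
        n = _qualifying_nodes(rec.tree, support_threshold)
        if n == 0:
            continue
        cur = best.get(rec.cluster_id)
        if cur is None or (n, _NegStr(rec.gene_id)) > (cur[0], _NegStr(cur[1])):
            best[rec.cluster_id] = (n, rec.gene_id, rec)
    kept = [best[c][2] for c in sorted(best)]
    return replace(gene_trees, records=kept)


class _NegStr(str):
    """String ordering reversed, so max-by-count prefers the
    lexicographically smallest gene id on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def build_supermatrix(
    alignments: Union[Mapping[str, Mapping[str, str]], Sequence[Tuple[str, Mapping[str, str]]]],
    species: Optional[Sequence[str]] = None,
    missing_char: str = "N",
) -> Tuple[Dict[str, str], list[Tuple[str, int, int]]]:
    """Concatenate per-gene species sequences into one matrix.

    Returns the per-species concatenation and a partition table of
    1-based inclusive coordinate ranges ``(gene, start, end)``. Genes
    absent for a species are filled with ``missing_char``.
    """
    if isinstance(alignments, Mapping):
        items = list(alignments.items())
    else:
        items = list(alignments)
    if not items:
        raise ValueError("empty gene list")
    gene_ids = [g for g, _ in items]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = {g for g in gene_ids if gene_ids.count(g) > 1}
        raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
    if species is None:
        universe: set[str] = set()
        for _, seqs in items:
            universe |= set(seqs)
        species = sorted(universe)
    rows: Dict[str, list[str]] = {sp: [] for sp in species}
    partitions: list[Tuple[str, int, int]] = []
    pos = 0
    for gene, seqs in items:
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene!r}: unequal sequence lengths")
        (length,) = lengths
        for sp in species:
            rows[sp].append(seqs.get(sp, missing_char * length))
        partitions.append((gene, pos + 1, pos + length))
        pos += length
    return {sp: "".join(parts) for sp, parts in rows.items()}, partitions


def partition_file(partitions: Sequence[Tuple[str, int, int]]) -> str:
    """RAxML-style partition definitions ("DNA, gene = start-end")."""
    return "".join(f"DNA, {g} = {a}-{b}\n" for g, a, b in partitions)


def fourfold_prefixes(
    table: Union[str, CodonTable.CodonTable] = "Standard"
) -> set[str]:
    """Two-base codon prefixes whose four completions are synonymous."""
    if isinstance(table, str):
        table = CodonTable.unambiguous_dna_by_name[table]

    def aa(codon: str) -> str:
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    out = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {aa(b1 + b2 + b3) for b3 in "ACGT"}
            if len(aas) == 1 and "*" not in aas:
                out.add(b1 + b2)
    return out


def extract_fourfold_sites(
    alignments: Union[Mapping[str, Mapping[str, str]], Sequence[Tuple[str, Mapping[str, str]]]],
    table: Union[str, CodonTable.CodonTable] = "Standard",
    missing_char: str = "N",
) -> Tuple[Dict[str, str], list[Tuple[str, int]]]:
    """Third positions of codons that are 4-fold degenerate in every
    non-missing species.

    A species is missing at a codon when any of its three bases is not
    an unambiguous A/C/G/T. Columns where any non-missing species falls
    outside a 4-fold family, or where every species is missing, are
    excluded. Returns per-species concatenated site strings plus the
    ``(gene, codon_index)`` provenance of each emitted column.
    """
    if isinstance(alignments, Mapping):
        items = list(alignments.items())
    else:
        items = list(alignments)
    prefixes = fourfold_prefixes(table)
    universe: set[str] = set()
    for _, seqs in items:
        universe |= set(seqs)
    species = sorted(universe)
    columns: Dict[str, list[str]] = {sp: [] for sp in species}
    provenance: list[Tuple[str, int]] = []
    for gene, seqs in items:
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene!r}: unequal sequence lengths")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"gene {gene!r}: length {length} violates codon frame")
        for c in range(length // 3):
            third: Dict[str, str] = {}
            ok = True
            any_present = False
            for sp in species:
                seq = seqs.get(sp)
                codon = seq[3 * c : 3 * c + 3].upper() if seq else missing_char * 3
                if any(ch not in "ACGT" for ch in codon):
                    third[sp] = missing_char
                    continue
                if codon[:2] not in prefixes:
                    ok = False
                    break
                third[sp] = codon[2]
                any_present = True
            if ok and any_present:
                for sp in species:
                    columns[sp].append(third[sp])
                provenance.append((gene, c))
    return {sp: "".join(cols) for sp, cols in columns.items()}, provenance
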