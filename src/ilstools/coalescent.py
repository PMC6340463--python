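"""Multispecies-coalescent simulation of gene trees and site patterns.

Gene genealogies are simulated with a censored Kingman coalescent run
branch-by-branch over a species tree whose lengths are in coalescent
units: within each species-tree branch the lineages present coalesce
pairwise, and survivors are handed to the parent branch; remaining
lineages merge in the root population. Internally all rates are on the
``ms`` time scale (time in units of 4 Ne generations, so a pair of
lineages coalesces at rate 2 and the expected pairwise time within one
population is 0.5); species trees in any convention are converted on
entry.

A branch length of ``inf`` forces monophyly: every lineage entering the
branch coalesces before its end.

Site patterns model a gene with a single segregating site: one mutation
is placed on the realized genealogy with probability proportional to
branch length (the behaviour of ``ms -s 1``), and the induced binary
derived/ancestral partition of the sampled chromosomes is returned.

Non-ultrametric species trees are legal. Each branch contributes
exactly its stated length of coalescent opportunity, and every gene-tree
lineage accrues branch length equal to the opportunity time it has
itself experienced, so expected topology frequencies depend only on the
stated internal lengths.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np

from .trees import MS, SpeciesTreeCU, convert_branch_lengths

__all__ = [
    "Genealogy",
    "SitePattern",
    "MSCSimulator",
    "simulate_gene_tree",
    "simulate_site_pattern",
    "pattern_matches_group",
    "derive_seed",
    "site_patterns_to_tsv",
]

#: pairwise coalescence rate on the ms time scale (1 / (0.5 units))
_PAIR_RATE = 2.0


def derive_seed(root_seed: int, *indices: int) -> int:
    """Deterministic per-task substream seed from one root seed.

    Uses numpy's SeedSequence spawning arithmetic so that (seed, gene
    index) pairs map to independent, platform-stable streams.
    """
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=tuple(indices))
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFFFFFFFFFF)


@dataclass
class Genealogy:
    """A realized binary gene genealogy over sampled chromosomes.

    Tips are numbered ``0..n_tips-1``; internal nodes continue upward in
    order of creation (time order). ``edge_child``/``edge_length`` list
    every finalized edge; ``tip_masks[i] = 1 << i``, and the clade below
    an edge is the bitwise OR of its tip masks.
    """

    tip_labels: list[str]
    tip_species: list[str]
    children: dict[int, tuple[int, int]]
    edge_child: list[int]
    edge_length: list[float]
    node_mask: list[int]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_length(self) -> float:
        return float(sum(self.edge_length))

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        lengths = {c: l for c, l in zip(self.edge_child, self.edge_length)}
        nodes: dict[int, dendropy.Node] = {}
        for i, label in enumerate(self.tip_labels):
            nd = dendropy.Node(taxon=taxa.get_taxon(label))
            nd.edge.length = lengths.get(i, 0.0)
            nodes[i] = nd
        for parent in sorted(self.children):
            nd = dendropy.Node()
            nd.edge.length = lengths.get(parent, 0.0)
            a, b = self.children[parent]
            nd.add_child(nodes[a])
            nd.add_child(nodes[b])
            nodes[parent] = nd
        root = nodes[max(self.children)] if self.children else nodes[0]
        root.edge.length = None
        tree.seed_node = root
        tree.is_rooted = True
        return tree


@dataclass
class SitePattern:
    """Binary derived-allele pattern from one simulated mutation."""

    chromosomes: tuple[str, ...]
    derived: tuple[int, ...]
    mutated_clade_mask: int

    def __post_init__(self) -> None:
        if len(self.derived) != len(self.chromosomes):
            raise ValueError("derived vector length != chromosome count")
        s = sum(self.derived)
        if s == 0 or s == len(self.derived):
            raise ValueError("site pattern must be segregating")

    @property
    def derived_mask(self) -> int:
        m = 0
        for i, d in enumerate(self.derived):
            if d:
                m |= 1 << i
        return m


class MSCSimulator:
    """Censored-coalescent simulator over one species tree.

    Parameters
    ----------
    species_tree:
        Species tree with coalescent-unit branch lengths (any
        convention; converted to the ms scale internally).
    sample:
        Chromosomes per species: a single integer applied to every
        species, or a mapping species -> count. Species mapped to 0 are
        not sampled.
    """

    def __init__(
        self,
        species_tree: SpeciesTreeCU,
        sample: Union[int, Mapping[str, int]] = 1,
    ) -> None:
        ms_tree = convert_branch_lengths(species_tree, MS)
        # postorder arrays over species-tree nodes
        self._durations: list[float] = []
        self._children_idx: list[list[int]] = []
        self._leaf_species: list[Optional[str]] = []
        index = {}
        for node in ms_tree.tree.postorder_node_iter():
            idx = len(self._durations)
            index[node] = idx
            if node.parent_node is None:
                dur = math.inf
            else:
                dur = node.edge.length if node.edge.length is not None else 0.0
                if dur < 0:
                    raise ValueError("negative branch length in species tree")
            self._durations.append(dur)
            self._children_idx.append([index[c] for c in node.child_nodes()])
            self._leaf_species.append(
                node.taxon.label if node.is_leaf() else None
            )
        self._root_idx = len(self._durations) - 1

        species = [s for s in self._leaf_species if s is not None]
        if isinstance(sample, int):
            counts = {s: sample for s in species}
        else:
            counts = {s: int(sample.get(s, 0)) for s in species}
        if any(c < 0 for c in counts.values()):
            raise ValueError("chromosome counts must be >= 0")
        if sum(counts.values()) < 2:
            raise ValueError("need at least two sampled chromosomes in total")

        self.chromosomes: list[str] = []
        self.chrom_species: list[str] = []
        self._leaf_chroms: list[list[int]] = []  # per species-tree node
        for i, sp in enumerate(self._leaf_species):
            chroms: list[int] = []
            if sp is not None:
                n = counts[sp]
                for k in range(n):
                    label = sp if n == 1 else f"{sp}.{k + 1}"
                    chroms.append(len(self.chromosomes))
                    self.chromosomes.append(label)
                    self.chrom_species.append(sp)
            self._leaf_chroms.append(chroms)
        self.n_chromosomes = len(self.chromosomes)

    # -- mask helpers -------------------------------------------------

    def species_mask(self, species: Iterable[str]) -> int:
        wanted = set(species)
        unknown = wanted - set(self.chrom_species)
        if unknown:
            raise ValueError(f"species not sampled: {sorted(unknown)}")
        m = 0
        for i, sp in enumerate(self.chrom_species):
            if sp in wanted:
                m |= 1 << i
        return m

    @property
    def full_mask(self) -> int:
        return (1 << self.n_chromosomes) - 1

    # -- core simulation ----------------------------------------------

    def _sim_masks(self, rand: random.Random) -> list[int]:
        """Merge-event masks only (fast path for clade-frequency tests)."""
        expo = rand.expovariate
        rint = rand.randrange
        merged: list[int] = []
        # lineages per species-tree node, bottom-up
        pools: list[Optional[list[int]]] = [None] * len(self._durations)
        for idx in range(len(self._durations)):
            lineages: list[int] = [1 << c for c in self._leaf_chroms[idx]]
            for ci in self._children_idx[idx]:
                lineages.extend(pools[ci])  # type: ignore[arg-type]
                pools[ci] = None
            dur = self._durations[idx]
            k = len(lineages)
            t = 0.0
            while k > 1:
                t += expo(_PAIR_RATE * k * (k - 1) / 2.0)
                if t >= dur:
                    break
                i = rint(k)
                j = rint(k - 1)
                if j >= i:
                    j += 1
                m = lineages[i] | lineages[j]
                merged.append(m)
                lineages[i] = m
                lineages[j] = lineages[k - 1]
                lineages.pop()
                k -= 1
            pools[idx] = lineages
        return merged

    def _sim_genealogy(self, rand: random.Random) -> Genealogy:
        expo = rand.expovariate
        rint = rand.randrange
        children: dict[int, tuple[int, int]] = {}
        edge_child: list[int] = []
        edge_length: list[float] = []
        node_mask: list[int] = list([0] * self.n_chromosomes)
        for i in range(self.n_chromosomes):
            node_mask[i] = 1 << i
        next_id = self.n_chromosomes
        pools: list[Optional[list[list[float]]]] = [None] * len(self._durations)
        # lineage record: [node_id, accrued_length]
        for idx in range(len(self._durations)):
            lineages: list[list[float]] = [
                [c, 0.0] for c in self._leaf_chroms[idx]
            ]
            for ci in self._children_idx[idx]:
                lineages.extend(pools[ci])  # type: ignore[arg-type]
                pools[ci] = None
            dur = self._durations[idx]
            k = len(lineages)
            t = 0.0
            while k > 1:
                wait = expo(_PAIR_RATE * k * (k - 1) / 2.0)
                if t + wait >= dur:
                    break
                t += wait
                for lin in lineages:
                    lin[1] += wait
                i = rint(k)
                j = rint(k - 1)
                if j >= i:
                    j += 1
                a, alen = lineages[i]
                b, blen = lineages[j]
                children[next_id] = (int(a), int(b))
                node_mask.append(node_mask[int(a)] | node_mask[int(b)])
                edge_child.append(int(a))
                edge_length.append(alen)
                edge_child.append(int(b))
                edge_length.append(blen)
                lineages[i] = [next_id, 0.0]
                lineages[j] = lineages[k - 1]
                lineages.pop()
                next_id += 1
                k -= 1
            if k > 1 and math.isfinite(dur):
                left = dur - t
                for lin in lineages:
                    lin[1] += left
            pools[idx] = lineages
        return Genealogy(
            tip_labels=list(self.chromosomes),
            tip_species=list(self.chrom_species),
            children=children,
            edge_child=edge_child,
            edge_length=edge_length,
            node_mask=node_mask,
        )

    # -- public sampling API ------------------------------------------

    def rand(self, seed: int) -> random.Random:
        return random.Random(seed)

    def gene_tree(self, seed: int) -> Genealogy:
        return self._sim_genealogy(random.Random(seed))

    def gene_trees(self, n: int, seed: int) -> Iterator[Genealogy]:
        for i in range(n):
            yield self._sim_genealogy(random.Random(derive_seed(seed, i)))

    def _place_mutation(
        self, g: Genealogy, rand: random.Random
    ) -> int:
        """Pick an edge proportional to length; return its clade mask."""
        total = g.total_length
        full = self.full_mask
        while True:
            r = rand.random() * total
            acc = 0.0
            mask = 0
            for child, length in zip(g.edge_child, g.edge_length):
                acc += length
                if r < acc:
                    mask = g.node_mask[child]
                    break
            else:  # numerical edge case: r == total
                mask = g.node_mask[g.edge_child[-1]]
            if 0 < mask < full:
                return mask

    def site_pattern(self, seed: int) -> SitePattern:
        rand = random.Random(seed)
        g = self._sim_genealogy(rand)
        mask = self._place_mutation(g, rand)
        derived = tuple(
            1 if mask >> i & 1 else 0 for i in range(self.n_chromosomes)
        )
        return SitePattern(tuple(self.chromosomes), derived, mask)

    def site_pattern_masks(self, n: int, seed: int) -> np.ndarray:
        """Derived-allele bitmasks for ``n`` single-mutation genes.

        One deterministic stream drives the whole batch.
        """
        rand = random.Random(seed)
        out = np.empty(n, dtype=np.uint64)
        for i in range(n):
            g = self._sim_genealogy(rand)
            out[i] = self._place_mutation(g, rand)
        return out

    def pair_exclusive_fraction(self, pair: Sequence[str], n_trees: int, seed: int) -> float:
        """Fraction of simulated gene trees in which the two species'
        chromosomes form an exclusive clade."""
        a, b = pair
        target = self.species_mask([a]) | self.species_mask([b])
        rand = random.Random(seed)
        hits = 0
        for _ in range(n_trees):
            for m in self._sim_masks(rand):
                if m == target:
                    hits += 1
                    break
                if (m & target) and (m & ~target):
                    # a pair chromosome merged with an outsider first:
                    # the exclusive clade can no longer form
                    break
        return hits / n_trees


# ---------------------------------------------------------------------------
# Module-level convenience operations
# ---------------------------------------------------------------------------

def simulate_gene_tree(
    species_tree: SpeciesTreeCU,
    sample: Union[int, Mapping[str, int]] = 1,
    seed: int = 0,
) -> dendropy.Tree:
    """One gene tree under the MSC, as a dendropy tree (lengths in ms units)."""
    return MSCSimulator(species_tree, sample).gene_tree(seed).to_dendropy()


def simulate_site_pattern(
    species_tree: SpeciesTreeCU,
    sample: Union[int, Mapping[str, int]] = 1,
    seed: int = 0,
) -> SitePattern:
    """One single-mutation site pattern under the MSC."""
    return MSCSimulator(species_tree, sample).site_pattern(seed)


def pattern_matches_group(
    pattern: SitePattern,
    group: Iterable[str],
    required_present: Iterable[str] = (),
    ignored: Iterable[str] = (),
    polarity: str = "either",
) -> bool:
    """Does the pattern split the focal group cleanly from everything else?

    Restricting to chromosomes of non-ignored species, all focal-group
    chromosomes must carry one state and all other chromosomes the other
    state (both polarities accepted unless ``polarity='derived'``). The
    within-species fixation requirement of the diploid null is implicit:
    both chromosomes of a species must agree for the equality to hold.
    """
    group = set(group)
    ignored = set(ignored)
    required = set(required_present)
    if group & ignored:
        raise ValueError("group and ignored sets must be disjoint")
    if required & ignored:
        raise ValueError("required-present species cannot be ignored")
    if polarity not in ("either", "derived"):
        raise ValueError("polarity must be 'either' or 'derived'")

    species = {}
    for i, label in enumerate(pattern.chromosomes):
        sp = label.rsplit(".", 1)[0]
        species.setdefault(sp, 0)
        species[sp] |= 1 << i
    unknown = (group | ignored | required) - set(species)
    if unknown:
        raise ValueError(f"species not in pattern: {sorted(unknown)}")

    full = (1 << len(pattern.chromosomes)) - 1
    ignored_mask = 0
    for sp in ignored:
        ignored_mask |= species[sp]
    rest = full & ~ignored_mask
    group_mask = 0
    for sp in group:
        group_mask |= species[sp]
    if (rest & ~group_mask) == 0:
        raise ValueError("group covers every non-ignored species; pattern undefined")
    d = pattern.derived_mask & rest
    if d == group_mask & rest:
        return True
    if polarity == "either" and d == rest & ~group_mask:
        return True
    return False


def site_patterns_to_tsv(patterns: Sequence[SitePattern]) -> str:
    """0/1 matrix TSV, one row per pattern, chromosome labels as header."""
    if not patterns:
        raise ValueError("no patterns")
    header = "\t".join(patterns[0].chromosomes)
    lines = [header]
    for p in patterns:
        if p.chromosomes != patterns[0].chromosomes:
            raise ValueError("patterns have differing chromosome sets")
        lines.append("\t".join(str(d) for d in p.derived))
    return "\n".join(lines) + "\n"
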