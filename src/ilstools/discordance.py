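"""Coalescent-null discordance tests.

Two analyses share the multispecies-coalescent null:

1. *Clade-frequency test* — how often does a focal species pair form an
   exclusive clade in gene trees simulated from the species tree? Used
   to ask whether an observed (e.g. mitochondrial) sister relationship
   could be produced by incomplete lineage sorting alone; the mean
   per-replicate clustering frequency is read directly as a P value.

2. *Quartet concordance factors* — observed topology proportions over
   gene trees versus the closed-form MSC expectation
   ``CF_major = 1 - (2/3) e^{-t}``, ``CF_minor = (1/3) e^{-t}`` (t is
   the internal branch length of the induced quartet on the scale where
   that formula holds), compared with a Pearson chi-squared
   goodness-of-fit. A non-significant fit means the species tree plus
   ILS adequately explains the discordance, arguing against
   introgression.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy import stats

from .coalescent import MSCSimulator, derive_seed
from .trees import COAL, SpeciesTreeCU, convert_branch_lengths

__all__ = [
    "QuartetCF",
    "CladeFrequencyResult",
    "CFGoodnessOfFit",
    "clade_frequency_test",
    "observed_quartet_cfs",
    "expected_quartet_cfs",
    "cf_goodness_of_fit",
    "cf_table_tsv",
]


@dataclass(frozen=True)
class QuartetCF:
    """Concordance factors for one species quartet.

    ``species`` is sorted; ``cfs`` follows the canonical topology order
    ``(s1 s2 | s3 s4, s1 s3 | s2 s4, s1 s4 | s2 s3)``.
    """

    species: tuple[str, str, str, str]
    cfs: tuple[float, float, float]
    n: int

    def __post_init__(self) -> None:
        if tuple(sorted(self.species)) != self.species:
            raise ValueError("species must be in sorted order")
        if abs(sum(self.cfs) - 1.0) > 1e-9:
            raise ValueError(f"concordance factors must sum to 1, got {sum(self.cfs)}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class CladeFrequencyResult:
    pair: tuple[str, str]
    replicate_freqs: list[float]
    n_reps: int
    trees_per_rep: int

    @property
    def p_value(self) -> float:
        return float(sum(self.replicate_freqs) / len(self.replicate_freqs))


@dataclass
class CFGoodnessOfFit:
    statistic: float
    df: int
    p_value: float
    n_quartets: int
    note: str = (
        "quartets extracted from shared gene trees are not independent; "
        "the chi-squared P value is approximate"
    )


def clade_frequency_test(
    species_tree: SpeciesTreeCU,
    pair: Sequence[str],
    organelle: bool = False,
    n_reps: int = 100,
    trees_per_rep: int = 100_000,
    seed: int = 0,
) -> CladeFrequencyResult:
    """ILS-null probability that a species pair clusters in gene trees.

    With ``organelle=True`` the branch lengths receive the quarter-Ne
    organelle correction during unit conversion (which cancels the
    nuclear-to-ms rescaling exactly) and one chromosome per species is
    sampled, matching a mitochondrial locus.
    """
    a, b = pair
    if a == b:
        raise ValueError("pair species must differ")
    if n_reps < 1 or trees_per_rep < 1:
        raise ValueError("replicate counts must be positive")
    from .trees import MS

    tree_ms = convert_branch_lengths(species_tree, MS, organelle=organelle)
    sim = MSCSimulator(tree_ms, sample=1)
    freqs = [
        sim.pair_exclusive_fraction((a, b), trees_per_rep, derive_seed(seed, rep))
        for rep in range(n_reps)
    ]
    return CladeFrequencyResult((a, b), freqs, n_reps, trees_per_rep)


# ---------------------------------------------------------------------------
# Quartet concordance factors
# ---------------------------------------------------------------------------

def _pairing_index(species: Sequence[str], pair: frozenset) -> int:
    """Canonical topology index of the pairing containing species[0]."""
    s1, s2, s3, s4 = species
    if pair in (frozenset((s1, s2)), frozenset((s3, s4))):
        return 0
    if pair in (frozenset((s1, s3)), frozenset((s2, s4))):
        return 1
    return 2


def _quartet_topology(node_masks: Iterable[int], tip_bits: Mapping[str, int]) -> Optional[frozenset]:
    """Pairing displayed for four chosen tips, or None if unresolved.

    ``tip_bits`` maps the four tip labels to their bit in the tree's
    leaf-set masks. An edge whose below-clade contains exactly two of
    the four tips certifies the quartet split.
    """
    quartet_mask = 0
    for bit in tip_bits.values():
        quartet_mask |= bit
    for m in node_masks:
        r = m & quartet_mask
        if r and bin(r).count("1") == 2:
            return frozenset(l for l, b in tip_bits.items() if b & r)
    return None


def _leafset_masks(tree: dendropy.Tree) -> tuple[dict[str, int], list[int]]:
    """Bit per leaf; per-node masks of the clade below (postorder)."""
    bits: dict[str, int] = {}
    masks: list[int] = []
    node_mask: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            bit = 1 << len(bits)
            bits[node.taxon.label] = bit
            node_mask[id(node)] = bit
        else:
            m = 0
            for c in node.child_nodes():
                m |= node_mask[id(c)]
            node_mask[id(node)] = m
            masks.append(m)
    return bits, masks


def observed_quartet_cfs(
    gene_trees: Sequence[dendropy.Tree],
    quartet: Sequence[str],
    tip_map: Optional[Mapping[str, str]] = None,
) -> QuartetCF:
    """Across-gene mean quartet topology proportions.

    For every gene tree, each combination of one tip per quartet species
    is reduced to its displayed quartet topology; unresolved
    combinations (polytomies) are excluded. Per-gene proportions over
    combinations are averaged with equal weight across informative
    genes.
    """
    species = tuple(sorted(quartet))
    if len(set(species)) != 4:
        raise ValueError("quartet must contain four distinct species")
    sums = np.zeros(3)
    n_inf = 0
    for tree in gene_trees:
        bits, masks = _leafset_masks(tree)
        per_species: list[list[str]] = []
        for sp in species:
            tips = [t for t in bits if (tip_map[t] if tip_map else t) == sp]
            per_species.append(tips)
        if any(not tips for tips in per_species):
            continue
        counts = np.zeros(3)
        resolved = 0
        for combo in itertools.product(*per_species):
            tip_bits = {sp: bits[t] for sp, t in zip(species, combo)}
            pairing = _quartet_topology(masks, tip_bits)
            if pairing is None:
                continue
            counts[_pairing_index(species, pairing)] += 1
            resolved += 1
        if resolved == 0:
            continue
        sums += counts / resolved
        n_inf += 1
    if n_inf == 0:
        raise ValueError("no gene tree is informative for this quartet")
    cfs = sums / n_inf
    return QuartetCF(species, tuple(float(c) for c in cfs), n_inf)


def expected_quartet_cfs(
    species_tree: SpeciesTreeCU, quartet: Sequence[str]
) -> QuartetCF:
    """MSC-expected concordance factors from the species tree.

    The internal branch length ``t`` of the induced quartet is measured
    on the scale where the minor-topology probability is
    ``(1/3) e^{-t}``; the major topology is the one displayed by the
    species tree.
    """
    species = tuple(sorted(quartet))
    if len(set(species)) != 4:
        raise ValueError("quartet must contain four distinct species")
    coal = convert_branch_lengths(species_tree, COAL)
    present = set(l.taxon.label for l in coal.tree.leaf_node_iter())
    missing = set(species) - present
    if missing:
        raise ValueError(f"quartet species not in species tree: {sorted(missing)}")
    bits, _ = _leafset_masks(coal.tree)
    quartet_mask = 0
    tip_bits = {}
    for sp in species:
        tip_bits[sp] = bits[sp]
        quartet_mask |= bits[sp]
    # sum lengths of all edges on the induced internal path: edges whose
    # below-clade restricted to the quartet holds exactly two species
    t = 0.0
    pairing: Optional[frozenset] = None
    node_mask: dict[int, int] = {}
    for node in coal.tree.postorder_node_iter():
        if node.is_leaf():
            node_mask[id(node)] = bits[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= node_mask[id(c)]
            node_mask[id(node)] = m
        if node.parent_node is None:
            continue
        r = node_mask[id(node)] & quartet_mask
        if r and bin(r).count("1") == 2:
            t += node.edge.length or 0.0
            pairing = frozenset(sp for sp in species if tip_bits[sp] & r)
    if pairing is None:  # star-like: every split mixes the quartet
        return QuartetCF(species, (1 / 3, 1 / 3, 1 / 3), 1)
    minor = (1.0 / 3.0) * math.exp(-t)
    major = 1.0 - 2.0 * minor
    cfs = [minor, minor, minor]
    cfs[_pairing_index(species, pairing)] = major
    return QuartetCF(species, tuple(cfs), 1)


def cf_goodness_of_fit(
    observed: Sequence[QuartetCF],
    expected: Sequence[QuartetCF],
    floor: float = 1e-8,
) -> CFGoodnessOfFit:
    """Pearson chi-squared comparison of observed and expected CFs.

    Counts ``n * CF`` are compared per quartet (2 degrees of freedom
    each) and summed into a global statistic. Expected proportions are
    floored at ``floor`` to avoid division by zero in the no-ILS limit.
    """
    if not observed:
        raise ValueError("empty quartet list")
    if len(observed) != len(expected):
        raise ValueError("observed and expected lists differ in length")
    stat = 0.0
    for obs, exp in zip(observed, expected):
        if obs.species != exp.species:
            raise ValueError(
                f"quartet mismatch: {obs.species} vs {exp.species}"
            )
        n = obs.n
        for o_cf, e_cf in zip(obs.cfs, exp.cfs):
            if e_cf <= 0 and o_cf > 0 and floor <= 0:
                raise ValueError(
                    "expected CF of 0 with nonzero observed count; "
                    "set a positive continuity floor"
                )
            e = n * max(e_cf, floor)
            o = n * o_cf
            stat += (o - e) ** 2 / e
    df = 2 * len(observed)
    p = float(stats.chi2.sf(stat, df))
    return CFGoodnessOfFit(float(stat), df, p, len(observed))


def cf_table_tsv(cfs: Sequence[QuartetCF]) -> str:
    """Concordance factors as TSV (taxa, cf1..cf3 in canonical order, n)."""
    lines = ["taxon1\ttaxon2\ttaxon3\ttaxon4\tcf12_34\tcf13_24\tcf14_23\tn"]
    for q in cfs:
        lines.append(
            "\t".join(q.species)
            + "\t"
            + "\t".join(f"{c:.6g}" for c in q.cfs)
            + f"\t{q.n}"
        )
    return "\n".join(lines) + "\n"
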