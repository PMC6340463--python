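"""Tree data model, newick I/O, and coalescent-unit conventions.

Rooted trees are held as :class:`dendropy.Tree` objects throughout the
package; this module adds the validation, the support-value conventions
and the branch-length unit bookkeeping that the downstream analyses rely
on.

Coalescent-unit conventions
---------------------------
Branch lengths of a species tree may be expressed on several scales, all
of the form ``generations / (k * Ne)`` for a convention-specific
multiplier ``k``:

========  ======  =====================================================
name      k       origin
========  ======  =====================================================
SNAQ      1       network-inference output (generations / Ne)
COAL      2       the scale on which the multispecies-coalescent quartet
                  formula ``CF_minor = (1/3) exp(-t)`` holds
MS        4       Hudson's ``ms`` simulator (generations / 4 Ne)
TIME      --      absolute time (My); not convertible without Ne and a
                  generation time
========  ======  =====================================================

Converting a length from convention A to B multiplies by ``k_A / k_B``.
Organelle (mitochondrial) genomes have an effective population size one
quarter of the nuclear value, so their lengths are first multiplied by 4
before the convention change; for SNAQ -> MS the two factors cancel and
the lengths pass through unchanged.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy

__all__ = [
    "UnitConvention",
    "SNAQ",
    "COAL",
    "MS",
    "TIME",
    "SpeciesTreeCU",
    "TimeTree",
    "NewickError",
    "parse_newick",
    "parse_newick_list",
    "serialize_newick",
    "node_support",
    "convert_branch_lengths",
    "is_exclusive_clade",
    "collapse_low_support",
    "root_to_tip_depths",
    "root_to_tip_variance",
    "tip_depth_table",
]


class NewickError(ValueError):
    """Raised for malformed newick input or invalid tree structure."""


@dataclass(frozen=True)
class UnitConvention:
    """A branch-length scale of the form generations / (k * Ne).

    ``gens_per_unit_ne`` is the multiplier ``k``; ``None`` marks an
    absolute-time scale that cannot be converted without demographic
    information.
    """

    name: str
    gens_per_unit_ne: Optional[float]

    def __post_init__(self) -> None:
        if self.gens_per_unit_ne is not None and self.gens_per_unit_ne <= 0:
            raise ValueError("generations-per-unit multiplier must be positive")


SNAQ = UnitConvention("SNAQ", 1.0)
COAL = UnitConvention("COAL", 2.0)
MS = UnitConvention("MS", 4.0)
TIME = UnitConvention("TIME", None)

_CONVENTIONS = {c.name: c for c in (SNAQ, COAL, MS, TIME)}


def get_convention(name: str) -> UnitConvention:
    try:
        return _CONVENTIONS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown unit convention {name!r}; known: {sorted(_CONVENTIONS)}"
        ) from None


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _validate_and_normalise(tree: dendropy.Tree, warn_missing_lengths: bool) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
    missing = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            node.edge.length = 0.0
            missing += 1
        elif node.edge.length < 0:
            raise NewickError(f"negative branch length {node.edge.length}")
    if missing and warn_missing_lengths:
        warnings.warn(
            f"{missing} branch length(s) absent in newick; defaulting to 0",
            stacklevel=3,
        )
    return tree


def parse_newick(text: str, warn_missing_lengths: bool = True) -> dendropy.Tree:
    """Parse a single rooted newick tree.

    Internal-node labels are interpreted as support values (the common
    dialect written by RAxML/FastTree); absent branch lengths default to
    0 with a warning so that topology-only (e.g. ASTRAL) trees load.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed newick: {exc}") from exc
    return _validate_and_normalise(tree, warn_missing_lengths)


def parse_newick_list(
    source: str, warn_missing_lengths: bool = False
) -> list[dendropy.Tree]:
    """Parse a multi-tree newick string (one semicolon-terminated tree each)."""
    try:
        trees = dendropy.TreeList.get(
            data=source,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise NewickError(f"malformed newick: {exc}") from exc
    return [_validate_and_normalise(t, warn_missing_lengths) for t in trees]


def serialize_newick(tree: dendropy.Tree) -> str:
    """Serialize with support values as internal-node labels.

    ``parse_newick(serialize_newick(t))`` preserves topology, lengths
    and supports.
    """
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.strip() + "\n"


def node_support(node: dendropy.Node) -> Optional[float]:
    """Support value of an internal node, parsed from its newick label."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Typed trees
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeCU:
    """A rooted species tree with branch lengths in coalescent units.

    Infinite branch lengths are legal and mean "forced monophyly": in a
    simulation all lineages entering that branch coalesce before its end.
    """

    tree: dendropy.Tree
    units: UnitConvention = SNAQ

    @classmethod
    def from_newick(cls, text: str, units: UnitConvention | str = SNAQ) -> "SpeciesTreeCU":
        if isinstance(units, str):
            units = get_convention(units)
        return cls(parse_newick(text, warn_missing_lengths=False), units)

    def clone(self) -> "SpeciesTreeCU":
        return SpeciesTreeCU(self.tree.clone(depth=1), self.units)

    def species(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


@dataclass
class TimeTree:
    """A dated tree with branch lengths in millions of years."""

    tree: dendropy.Tree
    ultrametric: bool = False
    _TOL = 1e-6

    def __post_init__(self) -> None:
        if self.ultrametric:
            depths = root_to_tip_depths(self.tree)
            if depths and max(depths) - min(depths) > self._TOL:
                raise ValueError(
                    "tree flagged ultrametric but root-to-tip depths differ by "
                    f"{max(depths) - min(depths):.3g}"
                )

    @classmethod
    def from_newick(cls, text: str, ultrametric: bool = False) -> "TimeTree":
        return cls(parse_newick(text, warn_missing_lengths=False), ultrametric)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def convert_branch_lengths(
    species_tree: SpeciesTreeCU,
    target: UnitConvention | str,
    organelle: bool = False,
) -> SpeciesTreeCU:
    """Rescale branch lengths from one coalescent-unit convention to another.

    ``organelle=True`` applies the quarter-Ne correction for organelle
    genomes (lengths x4) before the convention change, so SNAQ -> MS with
    the flag set is the identity on lengths.
    """
    if isinstance(target, str):
        target = get_convention(target)
    src = species_tree.units
    if src.gens_per_unit_ne is None or target.gens_per_unit_ne is None:
        raise ValueError(
            "cannot convert to/from the TIME convention without Ne and a "
            "generation time"
        )
    factor = (4.0 if organelle else 1.0) * src.gens_per_unit_ne / target.gens_per_unit_ne
    out = species_tree.clone()
    for edge in out.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    out.units = target
    return out


def _tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_exclusive_clade(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """True iff the smallest clade containing ``taxa`` contains nothing else."""
    taxa = set(taxa)
    present = _tip_labels(tree)
    missing = taxa - present
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if taxa == present:
        return True
    mrca = tree.mrca(taxon_labels=sorted(taxa))
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == taxa


def collapse_low_support(
    tree: dendropy.Tree,
    threshold: float,
    collapse_unsupported: bool = False,
) -> dendropy.Tree:
    """Contract internal branches whose child node support is below threshold.

    Nodes lacking a support value are collapsed only when
    ``collapse_unsupported`` is set. The tip set is never changed and the
    operation is idempotent.
    """
    if threshold < 0:
        raise ValueError("support threshold must be non-negative")
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is None:
            if collapse_unsupported:
                to_collapse.append(node)
        elif sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def root_to_tip_depths(tree: dendropy.Tree) -> list[float]:
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return depths


def root_to_tip_variance(tree: dendropy.Tree) -> float:
    """Population variance of root-to-tip path lengths (clock-likeness)."""
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    depths = root_to_tip_depths(tree)
    if len(depths) <= 1:
        return 0.0
    mean = sum(depths) / len(depths)
    return sum((d - mean) ** 2 for d in depths) / len(depths)


def tip_depth_table(tree: dendropy.Tree) -> str:
    """TSV of per-tip root-to-tip depths."""
    buf = io.StringIO()
    buf.write("tip\tdepth\n")
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        buf.write(f"{leaf.taxon.label}\t{d:.10g}\n")
    return buf.getvalue()
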