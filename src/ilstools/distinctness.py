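"""Evolutionary distinctness (ED) and EDGE conservation scores.

ED apportions the total branch length of a dated tree among its tips.
The default is the fair-proportion scheme: each branch's length is
divided equally among the tips descending from it, and a tip's ED is
the sum of its shares along the root-to-tip path, in the same units as
the tree (here My). The equal-splits alternative instead halves (more
generally, divides by the out-degree) the carried value at every
descent through a node.

The EDGE score combines ED with the IUCN threat category::

    EDGE = ln(1 + ED) + GE * ln 2

where GE encodes the category (LC=0, NT=1, VU=2, EN=3, CR=4). One GE
step doubles the weight on endangerment relative to distinctness.
Data-deficient species have an ED but no defined EDGE score.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional, Union

import dendropy
import pandas as pd

from .trees import TimeTree

__all__ = [
    "GE_CATEGORIES",
    "ge_from_category",
    "evolutionary_distinctness",
    "edge_score",
    "edge_table",
]

GE_CATEGORIES: Dict[str, Optional[int]] = {
    "LC": 0, "LEAST CONCERN": 0,
    "NT": 1, "NEAR-THREATENED": 1, "NEAR THREATENED": 1,
    "VU": 2, "VULNERABLE": 2,
    "EN": 3, "ENDANGERED": 3,
    "CR": 4, "CRITICALLY ENDANGERED": 4,
    "DD": None, "DATA DEFICIENT": None, "DATA-DEFICIENT": None,
}


def ge_from_category(category: str) -> Optional[int]:
    """GE value (0-4) for an IUCN red-list category; None if data-deficient."""
    key = category.strip().upper()
    if key not in GE_CATEGORIES:
        raise ValueError(f"unknown IUCN category {category!r}")
    return GE_CATEGORIES[key]


def _as_tree(tree: Union[dendropy.Tree, TimeTree]) -> dendropy.Tree:
    return tree.tree if isinstance(tree, TimeTree) else tree


def evolutionary_distinctness(
    tree: Union[dendropy.Tree, TimeTree],
    method: str = "fair-proportion",
) -> Dict[str, float]:
    """Per-tip evolutionary distinctness.

    Fair proportion conserves total length exactly: the ED values of
    all tips sum to the sum of branch lengths.
    """
    t = _as_tree(tree)
    for edge in t.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    ed: Dict[str, float] = {}
    if method == "fair-proportion":
        n_desc: Dict[int, int] = {}
        for node in t.postorder_node_iter():
            if node.is_leaf():
                n_desc[id(node)] = 1
            else:
                n_desc[id(node)] = sum(n_desc[id(c)] for c in node.child_nodes())
        share: Dict[int, float] = {id(t.seed_node): 0.0}
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                share[id(node)] = share[id(node.parent_node)] + (
                    node.edge.length or 0.0
                ) / n_desc[id(node)]
            if node.is_leaf():
                ed[node.taxon.label] = share[id(node)]
    elif method == "equal-splits":
        carry: Dict[int, float] = {id(t.seed_node): 0.0}
        for node in t.preorder_node_iter():
            k = len(node.child_nodes())
            for child in node.child_nodes():
                carry[id(child)] = carry[id(node)] / k + (child.edge.length or 0.0)
            if node.is_leaf():
                ed[node.taxon.label] = carry[id(node)]
    else:
        raise ValueError("method must be 'fair-proportion' or 'equal-splits'")
    return ed


def edge_score(ed: float, ge: Optional[int]) -> Optional[float]:
    """``ln(1 + ED) + GE * ln 2``; undefined (None) for missing GE."""
    if ed < 0:
        raise ValueError("ED must be non-negative")
    if ge is None:
        return None
    if ge not in (0, 1, 2, 3, 4):
        raise ValueError(f"GE must be an integer in 0..4, got {ge!r}")
    return math.log1p(ed) + ge * math.log(2.0)


def edge_table(
    tree: Union[dendropy.Tree, TimeTree],
    iucn: Mapping[str, str],
    method: str = "fair-proportion",
) -> pd.DataFrame:
    """Species table with ED, IUCN category, GE, and EDGE.

    ``iucn`` maps species to red-list category strings; species absent
    from the mapping, or data-deficient, get ED but no EDGE.
    """
    ed = evolutionary_distinctness(tree, method=method)
    rows = []
    for sp in sorted(ed):
        cat = iucn.get(sp)
        ge = ge_from_category(cat) if cat is not None else None
        score = edge_score(ed[sp], ge)
        rows.append(
            {
                "species": sp,
                "ED": ed[sp],
                "iucn_category": cat,
                "GE": ge,
                "EDGE": score,
            }
        )
    return pd.DataFrame(rows)
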