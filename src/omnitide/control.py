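"""Structural controllability of directed networks via maximum matching.

A directed network's minimum driver-node count N_D follows from the maximum
matching M on its bipartite representation (out-copies vs in-copies; one
bipartite edge per directed link): unmatched nodes must receive external
inputs, and N_D = max(N - |M|, 1) — a perfectly matched network still needs
one input. Single-node removal re-analysis classifies each node:

* indispensable — removal increases N_D (a control node),
* neutral       — removal leaves N_D unchanged,
* dispensable   — removal decreases N_D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from networkx.algorithms.bipartite import hopcroft_karp_matching

logger = logging.getLogger(__name__)

INDISPENSABLE = "indispensable"
NEUTRAL = "neutral"
DISPENSABLE = "dispensable"


@dataclass
class MatchingResult:
    matching: set[tuple[str, str]]  # directed edges (u, v) in the matching
    n_nodes: int
    driver_set: frozenset[str]

    @property
    def n_drivers(self) -> int:
        return max(self.n_nodes - len(self.matching), 1)


def bipartite_mapping(g: nx.DiGraph) -> nx.Graph:
    """Bipartite representation: left part = out-copies ('+', v), right part
    = in-copies ('-', v); one undirected edge per directed link. Self-loops
    are removed first (self-dynamics is treated separately by convention)."""
    b = nx.Graph()
    n_self = 0
    for v in g.nodes:
        b.add_node(("+", v), bipartite=0)
        b.add_node(("-", v), bipartite=1)
    for u, v in g.edges:
        if u == v:
            n_self += 1
            continue
        b.add_edge(("+", u), ("-", v))
    if n_self:
        logger.info("bipartite_mapping: removed %d self-loops", n_self)
    return b


def max_matching(g: nx.DiGraph) -> MatchingResult:
    """Maximum-cardinality matching (Hopcroft-Karp) on the bipartite mapping.

    The driver set witness is the set of nodes whose in-copy is unmatched;
    it is deterministic only up to matching ties — N_D and the node classes
    are the stable contract.
    """
    b = bipartite_mapping(g)
    left = {n for n, d in b.nodes(data=True) if d["bipartite"] == 0}
    match = hopcroft_karp_matching(b, top_nodes=left)
    edges = {
        (u[1], v[1]) for u, v in match.items() if u[0] == "+" and v[0] == "-"
    }
    matched_targets = {v for _, v in edges}
    drivers = frozenset(sorted(set(g.nodes) - matched_targets))
    return MatchingResult(edges, g.number_of_nodes(), drivers)


def classify_nodes(g: nx.DiGraph) -> pd.DataFrame:
    """Single-node-removal control classification.

    For every node v, recompute the matching on G - v and compare N'_D with
    the intact network's N_D. Returns a frame indexed by node with columns
    ``n_drivers_removed`` and ``class``.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes to classify")
    base = max_matching(g)
    nd = base.n_drivers
    rows = {}
    for v in sorted(g.nodes, key=str):
        h = g.copy()
        h.remove_node(v)
        nd_removed = max_matching(h).n_drivers
        if nd_removed > nd:
            cls = INDISPENSABLE
        elif nd_removed < nd:
            cls = DISPENSABLE
        else:
            cls = NEUTRAL
        rows[v] = {"n_drivers_removed": nd_removed, "class": cls}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["n_drivers"] = nd
    return df


def controller_fraction(classification: pd.DataFrame) -> float:
    """|indispensable| / N."""
    if classification.empty:
        raise ValueError("empty classification")
    return float((classification["class"] == INDISPENSABLE).mean())
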