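"""Rooted prize-collecting Steiner forests on a directed typed interactome.

The scaffold is a directed graph whose edges carry confidence weights
w(e) = 1 / kout(source) and costs c(e) = 1 - w(e), so hubs with many
outgoing links yield expensive edges. Nodes that change significantly
(|log2FC| > 1 at some timepoint up to t) receive a uniform binary prize
(cumulative over time). The solver seeks a forest F(V_F, E_F) of trees
rooted at designated receptor nodes minimizing

    f(F) = sum_{v not in V_F} (beta * p(v) - mu * k(v))
         + sum_{e in E_F} c(e) + omega * kappa

subject to directed reachability from each tree's root and a maximum hop
depth D. Rooting is realized by a dummy node attached to the roots with
cost-omega edges; charging omega per opened tree is the equivalent
formulation used internally.

Two solvers are provided: an exact branch-and-bound over parent assignments
(small instances; the oracle) and a deterministic cheapest-path accretion
heuristic.
"""

from __future__ import annotations

import heapq
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DUMMY = "__DUMMY__"
_EXACT_EDGE_CAP = 24

_SITE_RE = re.compile(r"_S\d+$")


@dataclass
class PCSFParams:
    beta: float = 10.0
    mu: float = 0.0
    omega: float = 5.0
    depth: int = 5
    roots: tuple[str, ...] = ("TGFBR1", "TGFBR2")

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.omega <= 0 or self.depth < 1 or self.mu < 0:
            raise ValueError("require beta > 0, omega > 0, D >= 1, mu >= 0")


@dataclass
class Forest:
    """A rooted forest: node depths, selected edges, per-tree roots, and the
    objective value reported by the solver."""

    nodes: dict[str, int]  # node -> depth (root depth 0)
    edges: list[tuple[str, str]]
    roots_used: list[str]
    objective: float

    @property
    def kappa(self) -> int:
        return len(self.roots_used)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.nodes) - self.kappa:
            raise ValueError("not a forest: |E_F| != |V_F| - kappa")


# ---------------------------------------------------------------------------
# interactome construction
# ---------------------------------------------------------------------------


def assign_edge_weights(edge_list: pd.DataFrame) -> nx.DiGraph:
    """Build the weighted scaffold from a (source, target, type[, sign])
    edge table.

    Self-loops are dropped; duplicate rows within a type are deduplicated;
    parallel edges of different types collapse onto one directed edge
    carrying the sorted tuple of types. w(e) = 1/kout(source) on the
    resulting simple digraph; c(e) = 1 - w(e).
    """
    required = {"source", "target"}
    if not required.issubset(edge_list.columns):
        missing = required - set(edge_list.columns)
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    g = nx.DiGraph()
    n_self = 0
    for ln, row in enumerate(edge_list.itertuples(index=False)):
        u, v = str(row.source), str(row.target)
        if not u or not v or u == "nan" or v == "nan":
            raise ValueError(f"malformed edge row at line {ln}")
        if u == v:
            n_self += 1
            continue
        etype = str(getattr(row, "type", "signaling"))
        sign = getattr(row, "sign", None)
        if g.has_edge(u, v):
            types = set(g[u][v]["types"])
            types.add(etype)
            g[u][v]["types"] = tuple(sorted(types))
            old_sign = g[u][v].get("sign")
            if sign is not None and old_sign not in (None, sign):
                g[u][v]["sign"] = "conflict"
                g[u][v]["sign_conflict"] = True
                logger.warning("conflicting signs on edge %s->%s", u, v)
            elif sign is not None:
                g[u][v]["sign"] = sign
        else:
            g.add_edge(u, v, types=(etype,), sign=sign)
    if n_self:
        logger.info("assign_edge_weights: dropped %d self-loops", n_self)
    for u in g.nodes:
        kout = g.out_degree(u)
        for _, v in g.out_edges(u):
            w = 1.0 / kout
            g[u][v]["weight"] = w
            g[u][v]["cost"] = 1.0 - w
    for v in g.nodes:
        g.nodes[v]["degree"] = g.degree(v)
    return g


def merge_causal_edges(
    edge_list: pd.DataFrame, signed_edges: pd.DataFrame | None
) -> pd.DataFrame:
    """Append a precomputed signed directed edge list (e.g. the output of a
    causal-inference tool) to the scaffold edge table; weights must be
    recomputed on the merged graph (assign_edge_weights does that)."""
    if signed_edges is None or len(signed_edges) == 0:
        return edge_list.copy()
    extra = signed_edges.copy()
    if "type" not in extra.columns:
        extra["type"] = "signaling"
    merged = pd.concat([edge_list, extra], ignore_index=True)
    merged = merged.drop_duplicates(subset=["source", "target", "type", "sign"]
                                    if "sign" in merged.columns
                                    else ["source", "target", "type"])
    return merged.reset_index(drop=True)


def attach_dummy(g: nx.DiGraph, params: PCSFParams) -> nx.DiGraph:
    """Augment the scaffold with the dummy root: DUMMY -> r with cost omega
    for every designated root r. Removal of DUMMY after solving leaves each
    tree rooted at a root node (depth 0)."""
    if not params.roots:
        raise ValueError("roots must be non-empty")
    missing = [r for r in params.roots if r not in g]
    if missing:
        raise ValueError(f"missing root nodes: {missing}")
    aug = g.copy()
    for r in params.roots:
        aug.add_edge(DUMMY, r, cost=params.omega, weight=0.0, types=("dummy",))
    return aug


# ---------------------------------------------------------------------------
# prizes
# ---------------------------------------------------------------------------


def default_node_map(feature: str) -> str:
    """Collapse phosphosite ids (GENE_S<k>) onto their parent protein."""
    return _SITE_RE.sub("", str(feature))


def cumulative_prizes(
    lfc_tables: dict[str, pd.DataFrame],
    threshold: float = 1.0,
    node_map=None,
) -> pd.DataFrame:
    """Binary cumulative prize schedule p(v, t) from per-layer log2FC tables.

    A node's per-timepoint magnitude is the max |log2FC| over all its
    measurements (multiple layers, multiple phosphosites); p(v, t) = 1 iff
    that magnitude strictly exceeds ``threshold`` at some timepoint i <= t,
    so prizes are monotone (once prized, always prized).
    """
    mapper = node_map or default_node_map
    frames = []
    for layer, lfc in lfc_tables.items():
        df = lfc.abs().copy()
        df.index = [mapper(f) if not isinstance(mapper, dict) else mapper.get(f, f)
                    for f in df.index]
        frames.append(df)
    allmag = pd.concat(frames)
    mag = allmag.groupby(level=0).max()
    cols = sorted(mag.columns, key=lambda c: int(str(c).lstrip("t")))
    mag = mag[cols]
    hit = (mag > threshold).to_numpy()
    cum = np.logical_or.accumulate(hit, axis=1).astype(int)
    return pd.DataFrame(cum, index=mag.index, columns=cols)


# ---------------------------------------------------------------------------
# objective (independent of any solver)
# ---------------------------------------------------------------------------


def _gain(v: str, prizes: dict[str, float], params: PCSFParams, g: nx.DiGraph) -> float:
    return params.beta * prizes.get(v, 0.0) - params.mu * g.degree(v)


def forest_objective(
    forest: Forest, prizes: dict[str, float], params: PCSFParams, g: nx.DiGraph
) -> float:
    """Recompute f(F) from parts; raises on an invalid certificate
    (non-forest edges, unreachable nodes, depth violations)."""
    depth = dict(forest.nodes)
    for r in forest.roots_used:
        if depth.get(r) != 0:
            raise ValueError(f"root {r} missing or not at depth 0")
        if r not in params.roots:
            raise ValueError(f"{r} is not a designated root")
    indeg: dict[str, int] = {v: 0 for v in depth}
    for u, v in forest.edges:
        if u not in depth or v not in depth:
            raise ValueError(f"edge ({u}, {v}) leaves the forest node set")
        if not g.has_edge(u, v):
            raise ValueError(f"edge ({u}, {v}) not in the scaffold")
        if depth[v] != depth[u] + 1:
            raise ValueError(f"edge ({u}, {v}) violates depth labels")
        indeg[v] += 1
    for v in depth:
        is_root = v in forest.roots_used
        if is_root and indeg[v] != 0:
            raise ValueError(f"tree root {v} has an incoming forest edge")
        if not is_root and indeg[v] != 1:
            raise ValueError(f"node {v} has in-degree {indeg[v]} != 1")
        if depth[v] > params.depth:
            raise ValueError(f"node {v} at depth {depth[v]} > D={params.depth}")
    excluded = [v for v in g.nodes if v not in depth and v != DUMMY]
    f = sum(_gain(v, prizes, params, g) for v in excluded)
    f += sum(g[u][v]["cost"] for u, v in forest.edges)
    f += params.omega * forest.kappa
    return float(f)


# ---------------------------------------------------------------------------
# exact solver: branch and bound over parent assignments
# ---------------------------------------------------------------------------


def _solve_exact(
    g: nx.DiGraph, prizes: dict[str, float], params: PCSFParams
) -> Forest:
    if g.number_of_edges() > _EXACT_EDGE_CAP:
        raise ValueError(
            f"exact mode refuses instances with > {_EXACT_EDGE_CAP} edges "
            f"(got {g.number_of_edges()}); use mode='heuristic'"
        )
    roots = [r for r in params.roots if r in g]
    # order: roots first, then BFS from roots, then leftovers (sorted)
    order: list[str] = list(dict.fromkeys(roots))
    seen = set(order)
    frontier = list(order)
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(g.successors(u)):
                if v not in seen:
                    seen.add(v)
                    order.append(v)
                    nxt.append(v)
        frontier = nxt
    order += sorted(set(g.nodes) - seen)

    base = sum(_gain(v, prizes, params, g) for v in g.nodes)
    # per-node options: (delta_cost, kind, payload)
    options: dict[str, list[tuple[float, str, object]]] = {}
    optimistic: dict[str, float] = {}
    for v in order:
        opts: list[tuple[float, str, object]] = [(0.0, "out", None)]
        gain = _gain(v, prizes, params, g)
        if v in roots:
            opts.append((params.omega - gain, "root", None))
        for u in sorted(g.predecessors(v)):
            opts.append((g[u][v]["cost"] - gain, "edge", u))
        options[v] = opts
        optimistic[v] = min(0.0, min(d for d, _, _ in opts))
    suffix_bound = np.zeros(len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        suffix_bound[i] = suffix_bound[i + 1] + optimistic[order[i]]

    best = {"f": float("inf"), "assign": None}
    assign: dict[str, tuple[str, object]] = {}

    def valid_and_depths(a: dict[str, tuple[str, object]]):
        depth: dict[str, int] = {}

        def resolve(v, trail):
            if v in depth:
                return depth[v]
            kind, payload = a[v]
            if kind == "out":
                return None
            if kind == "root":
                depth[v] = 0
                return 0
            u = payload
            if u in trail or u not in a:
                return -1  # cycle or dangling
            d_u = resolve(u, trail | {v})
            if d_u is None or d_u < 0:
                return -1
            depth[v] = d_u + 1
            return depth[v]

        for v, (kind, _) in a.items():
            if kind == "out":
                continue
            d = resolve(v, frozenset())
            if d is None or d < 0 or d > params.depth:
                return None
        return depth

    def dfs(i: int, partial: float):
        if partial + suffix_bound[i] >= best["f"] - 1e-12:
            return
        if i == len(order):
            depth = valid_and_depths(assign)
            if depth is None:
                return
            f = base + partial
            if f < best["f"] - 1e-12:
                best["f"] = f
                best["assign"] = dict(assign)
            return
        v = order[i]
        for delta, kind, payload in options[v]:
            if kind == "edge":
                u = payload
                # prune: parent already decided as excluded
                if u in assign and assign[u][0] == "out":
                    continue
            assign[v] = (kind, payload)
            dfs(i + 1, partial + delta)
        del assign[v]

    dfs(0, 0.0)
    a = best["assign"] or {}
    depth = valid_and_depths({v: kv for v, kv in a.items()}) or {}
    edges = [(payload, v) for v, (kind, payload) in a.items() if kind == "edge"]
    roots_used = sorted(v for v, (kind, _) in a.items() if kind == "root")
    nodes = {v: depth[v] for v in depth}
    return Forest(nodes, sorted(edges), roots_used, float(best["f"]))


# ---------------------------------------------------------------------------
# heuristic solver: deterministic cheapest-path accretion
# ---------------------------------------------------------------------------


def _accrete(
    g: nx.DiGraph,
    prizes: dict[str, float],
    params: PCSFParams,
    depth: dict[str, int],
    edges: list[tuple[str, str]],
    roots_used: list[str],
    banned_roots: frozenset[str] = frozenset(),
) -> None:
    """Cheapest-path accretion (in place): repeatedly attach the prized node
    whose depth-feasible min-cost directed path from the current forest (or
    an unopened root, charged omega) has the best (most negative) margin,
    where the path cost credits the prize gain of every new node it picks up.
    Ties break lexicographically; fully deterministic. ``banned_roots`` may
    not open new trees (used by the local-improvement tabu move)."""
    roots = [r for r in params.roots if r in g and r not in banned_roots]
    D = params.depth
    prized = sorted(v for v in g.nodes if prizes.get(v, 0.0) > 0.0)
    while True:
        dist: dict[tuple[str, int], float] = {}
        parent: dict[tuple[str, int], tuple[str, int] | None] = {}
        for v, d in depth.items():
            dist[(v, d)] = 0.0
            parent[(v, d)] = None
        for r in roots:
            if r not in depth:
                key = (r, 0)
                # tree-opening charge minus the root's own gain
                c0 = params.omega - _gain(r, prizes, params, g)
                if c0 < dist.get(key, np.inf):
                    dist[key] = c0
                    parent[key] = None

        def on_chain(state: tuple[str, int] | None, node: str) -> bool:
            while state is not None:
                if state[0] == node:
                    return True
                state = parent[state]
            return False

        # one sweep per depth layer over (node, depth) states; adjusted step
        # costs may be negative (prize credit), but depth strictly increases
        # and chain nodes are never revisited, so paths stay simple; O(D * E)
        for d in range(0, D):
            frontier = sorted(
                (u for (u, du) in dist if du == d), key=str
            )
            for u in frontier:
                d_u = dist[(u, d)]
                for v in sorted(g.successors(u)):
                    if v == DUMMY or v in depth:
                        continue
                    nd = d_u + g[u][v]["cost"] - _gain(v, prizes, params, g)
                    key = (v, d + 1)
                    if nd < dist.get(key, np.inf) - 1e-15 and not on_chain(
                        (u, d), v
                    ):
                        dist[key] = nd
                        parent[key] = (u, d)

        best_margin, best_key = np.inf, None
        for v in prized:
            if v in depth:
                continue
            for d in range(D + 1):
                if (v, d) not in dist:
                    continue
                m = dist[(v, d)]
                if m < best_margin - 1e-15 or (
                    abs(m - best_margin) <= 1e-15
                    and best_key is not None
                    and (v, d) < best_key
                ):
                    best_margin, best_key = m, (v, d)
        if best_key is None or best_margin >= -1e-12:
            break
        # walk the path back to a source (existing forest node or new root)
        path: list[tuple[str, int]] = []
        cur: tuple[str, int] | None = best_key
        while cur is not None and cur[0] not in depth:
            path.append(cur)
            cur = parent[cur]
        path.reverse()
        for i, (v, d) in enumerate(path):
            depth[v] = d
            if i == 0 and cur is None:
                roots_used.append(v)  # started a new tree at this root
            else:
                u = cur[0] if i == 0 else path[i - 1][0]
                edges.append((u, v))


def _state_objective(
    g: nx.DiGraph,
    prizes: dict[str, float],
    params: PCSFParams,
    depth: dict[str, int],
    edges: list[tuple[str, str]],
    roots_used: list[str],
) -> float:
    f = sum(
        _gain(v, prizes, params, g) for v in g.nodes if v not in depth and v != DUMMY
    )
    f += sum(g[u][v]["cost"] for u, v in edges)
    f += params.omega * len(roots_used)
    return float(f)


def _reroute(
    g: nx.DiGraph,
    params: PCSFParams,
    depth: dict[str, int],
    edges: list[tuple[str, str]],
    roots_used: list[str],
    cap: int = 200_000,
):
    """Re-optimize the routing of a FIXED node set: minimum-cost depth-bounded
    arborescence forest on the induced subgraph (exact branch-and-bound).
    Accretion commits to greedy paths; on small node sets the optimal routing
    is cheap to recover. Returns (depth, edges, roots_used), unchanged if the
    instance is too large or no better routing exists."""
    nodes = sorted(depth, key=str)
    if not nodes:
        return depth, edges, roots_used
    node_set = set(nodes)
    options: dict[str, list[tuple[float, str | None]]] = {}
    est = 1
    for v in nodes:
        opts: list[tuple[float, str | None]] = []
        if v in params.roots:
            opts.append((params.omega, None))  # open a tree here
        for u in sorted(g.predecessors(v)):
            if u in node_set:
                opts.append((g[u][v]["cost"], u))
        if not opts:
            return depth, edges, roots_used
        options[v] = opts
        est *= len(opts)
        if est > cap:
            return depth, edges, roots_used
    lower = np.zeros(len(nodes) + 1)
    for i in range(len(nodes) - 1, -1, -1):
        lower[i] = lower[i + 1] + min(c for c, _ in options[nodes[i]])
    cur_cost = sum(g[u][v]["cost"] for u, v in edges) + params.omega * len(roots_used)
    best = {"cost": cur_cost, "assign": None}
    assign: dict[str, str | None] = {}

    def resolve_depths(a: dict[str, str | None]) -> dict[str, int] | None:
        dd: dict[str, int] = {}

        def rec(v: str, trail: frozenset) -> int:
            if v in dd:
                return dd[v]
            u = a[v]
            if u is None:
                dd[v] = 0
                return 0
            if u in trail:
                return -1
            d_u = rec(u, trail | {v})
            if d_u < 0:
                return -1
            dd[v] = d_u + 1
            return dd[v]

        for v in a:
            if rec(v, frozenset()) < 0 or dd[v] > params.depth:
                return None
        return dd

    def dfs(i: int, cost: float) -> None:
        if cost + lower[i] >= best["cost"] - 1e-12:
            return
        if i == len(nodes):
            dd = resolve_depths(assign)
            if dd is None:
                return
            best["cost"] = cost
            best["assign"] = dict(assign)
            return
        v = nodes[i]
        for c, u in options[v]:
            assign[v] = u
            dfs(i + 1, cost + c)
        del assign[v]

    dfs(0, 0.0)
    if best["assign"] is None:
        return depth, edges, roots_used
    a = best["assign"]
    dd = resolve_depths(a)
    new_edges = sorted((u, v) for v, u in a.items() if u is not None)
    new_roots = sorted(v for v, u in a.items() if u is None)
    return dict(dd), new_edges, new_roots


def _improve(
    g: nx.DiGraph,
    prizes: dict[str, float],
    params: PCSFParams,
    depth: dict[str, int],
    edges: list[tuple[str, str]],
    roots_used: list[str],
):

    # local improvement: tentatively dissolve the subtree under each forest
    # node (whole trees when the node is a root) and re-accrete; a subtree
    # grown early along an expensive path often re-attaches more cheaply once
    # the rest of the forest exists
    def subtree(pivots: tuple[str, ...]) -> set[str]:
        children: dict[str, list[str]] = {}
        for u, v in edges:
            children.setdefault(u, []).append(v)
        members: set[str] = set()
        stack = list(pivots)
        while stack:
            w = stack.pop()
            if w in members:
                continue
            members.add(w)
            stack.extend(children.get(w, ()))
        return members

    def try_dissolve(pivots: tuple[str, ...]):
        members = subtree(pivots)
        t_depth = {v: d for v, d in depth.items() if v not in members}
        t_edges = [e for e in edges if e[0] not in members and e[1] not in members]
        t_roots = [x for x in roots_used if x not in members]
        banned = frozenset(p for p in pivots if p in roots_used)
        _accrete(g, prizes, params, t_depth, t_edges, t_roots, banned)
        return _reroute(g, params, t_depth, t_edges, t_roots)

    improved = True
    while improved:
        improved = False
        cur_obj = _state_objective(g, prizes, params, depth, edges, roots_used)
        # single-subtree moves first, then pairs (covers a mis-routed branch
        # that only pays off once a separately opened tree is dissolved too)
        pivots_1 = [(p,) for p in sorted(depth, key=str)]
        pivots_2 = [
            (a, b)
            for i, a in enumerate(sorted(depth, key=str))
            for b in sorted(depth, key=str)[i + 1 :]
        ]
        for pivots in pivots_1 + pivots_2:
            t_depth, t_edges, t_roots = try_dissolve(pivots)
            t_obj = _state_objective(g, prizes, params, t_depth, t_edges, t_roots)
            if t_obj < cur_obj - 1e-12:
                depth, edges, roots_used = t_depth, t_edges, t_roots
                improved = True
                break
    return depth, edges, roots_used


def _solve_heuristic(
    g: nx.DiGraph, prizes: dict[str, float], params: PCSFParams
) -> Forest:
    # deterministic multi-start over root subsets: greedy margins cannot see
    # that opening an extra tree near the prizes saves depth budget, so each
    # subset of designated roots is tried pre-opened (omega charged up front;
    # a useless tree is dissolved again by the improvement pass)
    roots_in_g = [r for r in params.roots if r in g][:4]
    subsets: list[tuple[str, ...]] = [()]
    for r in roots_in_g:
        subsets += [s + (r,) for s in subsets]
    best_state = None
    best_obj = np.inf
    for forced in sorted(subsets, key=lambda s: (len(s), s)):
        depth = {r: 0 for r in forced}
        edges: list[tuple[str, str]] = []
        roots_used = list(forced)
        _accrete(g, prizes, params, depth, edges, roots_used)
        depth, edges, roots_used = _reroute(g, params, depth, edges, roots_used)
        depth, edges, roots_used = _improve(
            g, prizes, params, depth, edges, roots_used
        )
        obj = _state_objective(g, prizes, params, depth, edges, roots_used)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_state = (depth, edges, roots_used)
    depth, edges, roots_used = best_state
    forest = Forest(dict(depth), sorted(edges), sorted(roots_used), 0.0)
    forest.objective = forest_objective(forest, prizes, params, g)
    return forest


# ---------------------------------------------------------------------------
# public solving interface
# ---------------------------------------------------------------------------


def solve_pcsf(
    g: nx.DiGraph,
    prizes: dict[str, float] | pd.Series,
    params: PCSFParams,
    mode: str = "heuristic",
) -> Forest:
    """Minimize the rooted prize-collecting forest objective at one timepoint.

    ``prizes`` maps node -> prize (0/1 in the standard pipeline). Prized
    nodes unreachable within depth D are simply left out (their penalty is
    paid); that is never an error. ``mode='exact'`` is guaranteed optimal but
    refuses large instances.
    """
    if isinstance(prizes, pd.Series):
        prizes = prizes.to_dict()
    prizes = {k: float(v) for k, v in prizes.items() if float(v) != 0.0}
    if mode == "exact":
        forest = _solve_exact(g, prizes, params)
    elif mode == "heuristic":
        forest = _solve_heuristic(g, prizes, params)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if forest.nodes:
        check = forest_objective(forest, prizes, params, g)
        if abs(check - forest.objective) > 1e-9:
            raise AssertionError(
                f"solver-reported objective {forest.objective} != recomputed {check}"
            )
    else:
        forest.objective = forest_objective(forest, prizes, params, g)
    return forest


def run_temporal_series(
    g: nx.DiGraph,
    prize_schedule: pd.DataFrame,
    params: PCSFParams,
    mode: str = "heuristic",
) -> tuple[dict[str, Forest], pd.Series]:
    """Solve independently at every timepoint with cumulative prizes; also
    report each node's first appearance time (network growth)."""
    forests: dict[str, Forest] = {}
    first_seen: dict[str, str] = {}
    cols = sorted(prize_schedule.columns, key=lambda c: int(str(c).lstrip("t")))
    for col in cols:
        pz = prize_schedule[col]
        pz = pz[pz > 0]
        forests[col] = solve_pcsf(g, pz, params, mode=mode)
        for v in forests[col].nodes:
            first_seen.setdefault(v, col)
    return forests, pd.Series(first_seen, dtype=object)
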