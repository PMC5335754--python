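"""Reference subnetwork searchers over an aggregate z-score.

Both searchers maximize the aggregate score z_A = (Σ_{i∈A} z_i) / √|A| of a
connected node set A, the scoring statistic of the classical
active-modules approach (an imported formula, not original here).  No
Monte-Carlo background calibration of z_A is applied — the raw aggregate
only, which is a stated limitation of these baselines.

``greedy_search`` grows a module from the best seed by locally optimal
additions within a hop radius; ``simulated_annealing_search`` toggles node
inclusion under a geometric cooling schedule and returns the best-seen
connected component.  Tie-breaking is lexicographic by node identifier
throughout, so both are deterministic given their inputs (and seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .metrics import SubnetworkResult

logger = logging.getLogger(__name__)


@dataclass
class SAConfig:
    """Geometric annealing schedule: T ← cooling·T each iteration."""

    t_initial: float = 2.0
    cooling: float = 0.999
    iterations: int = 5000


@dataclass
class SearchParams:
    """Knobs shared by the searchers.

    max_depth : hop radius for greedy candidate nodes (1–3 validated by
        default; set ``allow_deep=True`` to lift the cap)
    seeds : optional start nodes for greedy (default: highest-z node)
    max_modules : number of disjoint modules to return (default 1)
    sa : annealing schedule
    rng_seed : seed for the annealing RNG
    """

    max_depth: int = 1
    seeds: Optional[list] = None
    max_modules: int = 1
    sa: SAConfig = field(default_factory=SAConfig)
    rng_seed: int = 0
    allow_deep: bool = False

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.max_depth > 3 and not self.allow_deep:
            raise ValueError("max_depth > 3; pass allow_deep=True to widen")
        if self.max_modules < 1:
            raise ValueError("max_modules must be >= 1")


def subnetwork_score(nodes: Iterable, z: pd.Series) -> float:
    """Aggregate z-score z_A = Σz_i / √|A| of a nonempty node set."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("cannot score an empty node set")
    return float(z.loc[nodes].sum() / math.sqrt(len(nodes)))


def _check_z(net: nx.Graph, z: pd.Series) -> None:
    missing = set(net.nodes()) - set(z.index)
    if missing:
        raise ValueError(f"z-scores missing for nodes: {sorted(missing)[:5]}")


def _candidates_with_paths(net: nx.Graph, subset: set, depth: int) -> dict:
    """Nodes within ``depth`` hops of the subset → shortest connecting path
    (nodes strictly between candidate and subset, possibly empty)."""
    # Multi-source BFS from the subset.
    dist = {n: 0 for n in subset}
    parent: dict = {}
    frontier = list(subset)
    for d in range(1, depth + 1):
        nxt = []
        for u in frontier:
            for v in net.adj[u]:
                if v not in dist:
                    dist[v] = d
                    parent[v] = u
                    nxt.append(v)
        frontier = nxt
    out = {}
    for v, d in dist.items():
        if d == 0:
            continue
        path = []
        u = parent[v]
        while u not in subset:
            path.append(u)
            u = parent[u]
        out[v] = path
    return out


def greedy_search(net: nx.Graph, z: pd.Series,
                  params: Optional[SearchParams] = None) -> SubnetworkResult:
    """Greedy module growth maximizing the aggregate z-score.

    Starts from the highest-z node (ties lexicographic) or from each node in
    ``params.seeds``, keeping the best-scoring outcome.  At each step the
    candidate within ``max_depth`` hops whose addition (together with a
    shortest connecting path, for depth > 1) most increases the score is
    added; growth stops when no addition improves the score.  The score
    trajectory is strictly increasing and the result connected.
    """
    params = params or SearchParams()
    _check_z(net, z)
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")

    zd = {n: float(z[n]) for n in net.nodes()}

    def grow(start, allowed: set) -> tuple[set, float]:
        subset = {start}
        total = zd[start]
        score = total  # = total / sqrt(1)
        depth1 = params.max_depth == 1
        frontier = {v for v in net.adj[start] if v in allowed} - subset
        while True:
            if depth1:
                cands = {c: () for c in frontier}
            else:
                cands = _candidates_with_paths(net.subgraph(allowed), subset,
                                               params.max_depth)
            best = None  # (score, str(candidate), candidate, path)
            for c, path in cands.items():
                s = ((total + zd[c] + sum(zd[u] for u in path))
                     / math.sqrt(len(subset) + 1 + len(path)))
                key = (s, str(c))
                if best is None or s > best[0] or (s == best[0]
                                                   and str(c) < best[1]):
                    best = (s, str(c), c, path)
            if best is None or best[0] <= score:
                return subset, score
            score = best[0]
            added = {best[2], *best[3]}
            subset |= added
            total += sum(zd[u] for u in added)
            if depth1:
                frontier.discard(best[2])
                frontier |= {v for v in net.adj[best[2]]
                             if v in allowed} - subset
        return subset, score

    def best_module(allowed: set) -> tuple[set, float]:
        if params.seeds is not None:
            starts = [s for s in params.seeds if s in allowed]
            if not starts:
                raise ValueError("no provided seed is available")
        else:
            zs = z.loc[sorted(allowed)]
            starts = [min(zs.index[zs == zs.max()], key=str)]
        outcomes = [grow(s, allowed) for s in starts]
        return max(outcomes, key=lambda o: (o[1], -len(o[0])))

    allowed = set(net.nodes())
    modules: list[set] = []
    for _ in range(params.max_modules):
        if not allowed:
            break
        try:
            subset, score = best_module(allowed)
        except ValueError:
            break
        logger.info("greedy module: %d nodes, score %.4f", len(subset), score)
        modules.append(subset)
        allowed -= subset
    selected = set().union(*modules) if modules else set()
    return SubnetworkResult.from_nodes("greedy", selected, net)


def _largest_component(adj: dict, included: set, zd: dict) -> set:
    """Largest connected component of the included-node-induced subgraph.

    Size ties are broken by the higher aggregate z-score, then by the
    lexicographically smallest member, so the choice is deterministic.
    """
    seen: set = set()
    best: set = set()
    best_key = None
    for start in included:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v in included and v not in seen:
                    seen.add(v)
                    comp.add(v)
                    stack.append(v)
        key = (len(comp), sum(zd[n] for n in comp),
               [str(n) for n in sorted(comp, key=str)])
        # larger size wins; then higher score; then lexicographically
        # smaller member list (note: reversed comparison for the list)
        if best_key is None or (key[0], key[1]) > (best_key[0], best_key[1]) \
                or ((key[0], key[1]) == (best_key[0], best_key[1])
                    and key[2] < best_key[2]):
            best, best_key = comp, key
    return best


def simulated_annealing_search(net: nx.Graph, z: pd.Series,
                               params: Optional[SearchParams] = None
                               ) -> SubnetworkResult:
    """Annealed search over node-inclusion states.

    Every node carries a binary inclusion flag, initialized by a fair coin
    from the seeded RNG.  Each iteration toggles one uniformly random node;
    the move is accepted if the aggregate score of the largest included
    connected component improves, and otherwise with probability
    exp(Δ/T) under geometric cooling.  The best-seen component is returned;
    its score is monotone non-decreasing over iterations.
    """
    params = params or SearchParams()
    _check_z(net, z)
    nodes = sorted(net.nodes(), key=str)
    if not nodes:
        raise ValueError("empty network")
    adj = {n: sorted(net.adj[n], key=str) for n in nodes}
    rng = np.random.default_rng(params.rng_seed)

    zd = {n: float(z[n]) for n in nodes}
    included = {n for n, keep in zip(nodes, rng.random(len(nodes)) < 0.5)
                if keep}
    if not included:
        included = {max(nodes, key=lambda n: (z[n], str(n)))}

    def current_score(inc: set) -> tuple[float, set]:
        comp = _largest_component(adj, inc, zd)
        if not comp:
            return -math.inf, comp
        return subnetwork_score(comp, z), comp

    score, comp = current_score(included)
    best_score, best_comp = score, set(comp)
    t = params.sa.t_initial
    idx = rng.integers(0, len(nodes), size=params.sa.iterations)
    accept_u = rng.random(params.sa.iterations)
    for it in range(params.sa.iterations):
        node = nodes[idx[it]]
        if node in included:
            included.discard(node)
        else:
            included.add(node)
        new_score, new_comp = current_score(included)
        delta = new_score - score
        if delta > 0 or (t > 0 and accept_u[it] < math.exp(
                min(0.0, delta) / t)):
            score, comp = new_score, new_comp
            if score > best_score:
                best_score, best_comp = score, set(comp)
        else:  # revert the toggle
            if node in included:
                included.discard(node)
            else:
                included.add(node)
        t *= params.sa.cooling
    logger.info("annealing best module: %d nodes, score %.4f",
                len(best_comp), best_score)
    return SubnetworkResult.from_nodes("simulated_annealing", best_comp, net)
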