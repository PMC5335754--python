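"""Protein-protein interaction network I/O and ground-truth selection.

A PPI network is held as an undirected simple :class:`networkx.Graph` whose
nodes are gene symbols (opaque, case-sensitive strings).  Functions here read
the two common plain-text dialects (two-column edge lists and SIF), extract
the largest connected component, and plant a ground-truth differential
subnetwork — the connected gene set whose expression the simulator will
perturb and which searchers are later scored against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[str], Iterable[str]]


class ParseError(ValueError):
    """Raised when an input line cannot be interpreted."""


@dataclass(frozen=True)
class GroundTruthSpec:
    """A planted differential subnetwork: the node set and how it was drawn.

    Attributes
    ----------
    nodes
        Gene identifiers of the planted subnetwork (``G0``).
    seed
        RNG seed used to draw the set.
    mode
        ``"connected"`` (random-walk expansion, induced subgraph connected)
        or ``"uniform"`` (plain uniform sample, connectivity not enforced).
    """

    nodes: frozenset = field(default_factory=frozenset)
    seed: int = 0
    mode: str = "connected"

    def __len__(self) -> int:
        return len(self.nodes)


def _iter_lines(source: Source) -> Iterator[tuple[int, str]]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from enumerate(fh, start=1)
    else:
        yield from enumerate(source, start=1)


def load_ppi(source: Source, *, dialect: str = "edgelist",
             drop_self_loops: bool = True) -> nx.Graph:
    """Read a PPI network from an edge list or SIF text source.

    Parameters
    ----------
    source
        Path, open text handle, or iterable of lines.
    dialect
        ``"edgelist"``: the first two whitespace-separated tokens of each
        line are the edge endpoints (extra columns ignored).
        ``"sif"``: ``node relation node [node ...]`` — one edge from the
        first node to each node after the relation token.
    drop_self_loops
        Remove edges whose endpoints coincide (default on).

    Returns
    -------
    networkx.Graph
        Simple undirected graph; duplicate lines collapse to one edge.

    Raises
    ------
    ParseError
        On a malformed line (fewer than two tokens, naming the line
        number) or entirely empty input.
    """
    if dialect not in ("edgelist", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    g = nx.Graph()
    n_lines = 0
    for lineno, raw in _iter_lines(source):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        n_lines += 1
        if dialect == "edgelist":
            if len(tokens) < 2:
                raise ParseError(f"line {lineno}: expected at least 2 "
                                 f"columns, got {len(tokens)}: {line!r}")
            pairs = [(tokens[0], tokens[1])]
        else:
            # SIF allows isolated nodes (a single token) and fan-out edges.
            if len(tokens) == 1:
                g.add_node(tokens[0])
                continue
            if len(tokens) == 2:
                raise ParseError(f"line {lineno}: SIF line with 2 tokens has "
                                 f"a relation but no target: {line!r}")
            pairs = [(tokens[0], t) for t in tokens[2:]]
        for a, b in pairs:
            if a == b:
                if drop_self_loops:
                    g.add_node(a)
                    continue
            g.add_edge(a, b)
    if n_lines == 0:
        raise ParseError("empty input: no edge lines found")
    if not drop_self_loops:
        # Self-loops are never meaningful in a binary interaction network;
        # the flag only controls whether they are silently dropped or kept
        # as nodes. Keep graph simple regardless.
        g.remove_edges_from(nx.selfloop_edges(g))
    logger.info("loaded PPI network: %d nodes, %d edges",
                g.number_of_nodes(), g.number_of_edges())
    return g


def write_edge_list(net: nx.Graph, path: Union[str, Path]) -> None:
    """Write the network as a sorted two-column TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(nx.isolates(net)):
            fh.write(f"{node}\t{node}\n")  # re-read as an ignored self-loop


def read_gene_list(source: Source) -> list[str]:
    """Read a one-symbol-per-line gene list ('#' comments allowed)."""
    genes = []
    for _, raw in _iter_lines(source):
        line = raw.strip()
        if line and not line.startswith("#"):
            genes.append(line.split()[0])
    return genes


def write_gene_list(genes: Iterable[str], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component.

    Ties on size are broken by the lexicographically smallest member node,
    so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    components = sorted(nx.connected_components(net),
                        key=lambda c: (-len(c), min(c)))
    return net.subgraph(components[0]).copy()


def sample_ground_truth(net: nx.Graph, m: int, seed: int, *,
                        mode: str = "connected") -> GroundTruthSpec:
    """Draw the planted differential subnetwork ``G0``.

    In ``"connected"`` mode (default) the set is grown by random-walk
    expansion: start from a uniformly chosen node of the largest component
    and repeatedly add a uniformly random node adjacent to the current
    subset, so the induced subgraph is connected.  ``"uniform"`` mode draws
    ``m`` nodes uniformly without the connectivity constraint (useful for
    sensitivity analysis).
    """
    if m < 1:
        raise ValueError("m must be positive")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        nodes = sorted(net.nodes())
        if m > len(nodes):
            raise ValueError(f"m={m} exceeds network size {len(nodes)}")
        chosen = rng.choice(len(nodes), size=m, replace=False)
        return GroundTruthSpec(frozenset(nodes[i] for i in chosen),
                               seed=seed, mode=mode)
    if mode != "connected":
        raise ValueError(f"unknown ground-truth mode {mode!r}")
    lcc = largest_connected_component(net)
    if m > lcc.number_of_nodes():
        raise ValueError(f"m={m} exceeds largest component size "
                         f"{lcc.number_of_nodes()}")
    nodes = sorted(lcc.nodes())
    subset = {nodes[rng.integers(len(nodes))]}
    frontier = set(lcc.adj[next(iter(subset))]) - subset
    while len(subset) < m:
        candidates = sorted(frontier)
        pick = candidates[rng.integers(len(candidates))]
        subset.add(pick)
        frontier |= set(lcc.adj[pick])
        frontier -= subset
    return GroundTruthSpec(frozenset(subset), seed=seed, mode=mode)
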