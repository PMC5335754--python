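"""Toy network generation for tests and desk-scale benchmark runs."""

from __future__ import annotations

import logging

import networkx as nx

from .network import largest_connected_component

logger = logging.getLogger(__name__)

MODELS = ("erdos_renyi", "barabasi_albert", "grid")


def make_toy_network(n_nodes: int, model: str = "barabasi_albert",
                     seed: int = 0, **model_params) -> nx.Graph:
    """Generate a connected simple graph with string node labels g0001, ...

    Models: ``erdos_renyi`` (param ``p``, default giving mean degree ~6),
    ``barabasi_albert`` (param ``m``, default 3 — a scale-free graph whose
    degree distribution resembles a PPI network), ``grid`` (2-D lattice;
    ``rows``/``cols`` defaulting to a near-square layout).  If the model
    yields a disconnected graph, the largest component is taken (its size
    may then be below ``n_nodes``).
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if model == "erdos_renyi":
        p = model_params.pop("p", min(1.0, 6.0 / (n_nodes - 1)))
        g = nx.erdos_renyi_graph(n_nodes, p, seed=seed)
    elif model == "barabasi_albert":
        m = model_params.pop("m", min(3, n_nodes - 1))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "grid":
        rows = model_params.pop("rows", None)
        cols = model_params.pop("cols", None)
        if rows is None or cols is None:
            rows = int(n_nodes ** 0.5)
            cols = (n_nodes + rows - 1) // rows
        g = nx.convert_node_labels_to_integers(nx.grid_2d_graph(rows, cols))
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model_params:
        raise ValueError(f"unknown model parameters: {sorted(model_params)}")
    width = max(4, len(str(g.number_of_nodes())))
    g = nx.relabel_nodes(g, {i: f"g{i+1:0{width}d}" for i in g.nodes()})
    if not nx.is_connected(g):
        g = largest_connected_component(g)
    logger.info("toy network (%s): %d nodes, %d edges", model,
                g.number_of_nodes(), g.number_of_edges())
    return g
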