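"""Markov-random-field sampling of binary differential-expression states.

Each gene carries a binary state X_i (1 = differentially expressed, DE;
0 = equally expressed, EE).  Starting from a planted subnetwork G0 with
X_{G0} = 1 and X = 0 elsewhere, single-site updates draw each state from

    p_i(k | rest) ∝ exp(γ_k − β μ_i(1−k)),   k ∈ {0, 1},

where μ_i(1−k) measures disagreement between state k and gene i's
neighborhood, modified by a self-retention weight w that pulls each gene
toward its current (initially planted) state.  Three μ variants are
available (``mu_mode``):

``discordance`` (default)
    μ = (w·X_i^{1−k} + Σ_{j∈N_i} X_j^{1−k}) / (w + |N_i|) — the fraction of
    the w-weighted closed neighborhood disagreeing with k.  Bounded in
    [0, 1]; w trades self-retention against neighborhood smoothing.
``count``
    The unnormalized numerator w·X_i^{1−k} + Σ_j X_j^{1−k}.  With w = 0
    this is the exact Gibbs conditional of the Ising-type Boltzmann joint
    P(X) ∝ exp(Σ_i γ_{X_i} − β Σ_{(i,j)∈E} 1{X_i≠X_j}) on any graph, and
    as w → ∞ the initial states are retained exactly.
``literal``
    μ = (w·(1−X_i^{1−k}) + Σ_j (1−X_j^{1−k})) / (w + |N_i|): the numerator
    counts *agreement* with k, so large w flips states — kept for
    completeness, not recommended.

Here X^1 = X and X^0 = 1 − X.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import GroundTruthSpec

logger = logging.getLogger(__name__)

MU_MODES = ("discordance", "count", "literal")


@dataclass
class MRFParams:
    """Parameters of the state-sampling model.

    gamma0, gamma1 : external field favouring state 0 / 1 (default 0, 0)
    beta : coupling strength, ≥ 0 (default 1)
    w : self-retention weight, ≥ 0 (default 50)
    n_sweeps : full update passes over all nodes (default 1)
    mu_mode : one of ``discordance`` / ``count`` / ``literal``
    update_order : ``sorted`` (deterministic scan) or ``random_scan``
    seed : RNG seed
    """

    gamma0: float = 0.0
    gamma1: float = 0.0
    beta: float = 1.0
    w: float = 50.0
    n_sweeps: int = 1
    mu_mode: str = "discordance"
    update_order: str = "sorted"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.w < 0:
            raise ValueError("w must be nonnegative")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.mu_mode not in MU_MODES:
            raise ValueError(f"mu_mode must be one of {MU_MODES}")
        if self.update_order not in ("sorted", "random_scan"):
            raise ValueError("update_order must be 'sorted' or 'random_scan'")
        for name in ("gamma0", "gamma1", "beta", "w"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _mu(mode: str, w: float, x_self_1mk: int, n_neigh_1mk: int,
        degree: int) -> float:
    # x_self_1mk = X_i^{1-k} at the current state; n_neigh_1mk = number of
    # neighbors currently in state 1-k.
    if mode == "discordance":
        return (w * x_self_1mk + n_neigh_1mk) / (w + degree) if w + degree else 0.0
    if mode == "count":
        return w * x_self_1mk + n_neigh_1mk
    # literal: numerator counts agreement with k; denominator Σ(X^{1-k}+X^k)
    # over neighbors is identically |N_i|.
    return ((w * (1 - x_self_1mk) + (degree - n_neigh_1mk)) / (w + degree)
            if w + degree else 0.0)


def mu_stat(node, k: int, states: pd.Series, net: nx.Graph, w: float,
            mode: str = "discordance") -> float:
    """The neighborhood statistic μ_i(1−k) for one gene.

    ``states`` maps every network node to its current binary state.
    """
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    if mode not in MU_MODES:
        raise ValueError(f"mode must be one of {MU_MODES}")
    if k not in (0, 1):
        raise ValueError("k must be 0 or 1")
    xi = int(states[node])
    neigh = list(net.adj[node])
    n_1mk = sum(int(states[j]) == 1 - k for j in neigh)
    x_self_1mk = int(xi == 1 - k)
    return _mu(mode, w, x_self_1mk, n_1mk, len(neigh))


def _p1(gamma0: float, gamma1: float, beta: float, mu0: float,
        mu1: float) -> float:
    # P(X_i = 1 | rest) with the max exponent subtracted for stability.
    a1 = gamma1 - beta * mu0  # exponent for k = 1 (disagreement stat mu_i(0))
    a0 = gamma0 - beta * mu1
    m = max(a0, a1)
    e1 = math.exp(a1 - m)
    return e1 / (math.exp(a0 - m) + e1)


def conditional_p1(node, states: pd.Series, net: nx.Graph,
                   params: MRFParams) -> float:
    """P(X_i = 1 | all other states) under the single-site conditional."""
    mu0 = mu_stat(node, 1, states, net, params.w, params.mu_mode)
    mu1 = mu_stat(node, 0, states, net, params.w, params.mu_mode)
    return _p1(params.gamma0, params.gamma1, params.beta, mu0, mu1)


def gibbs_sample_states(net: nx.Graph, g0: GroundTruthSpec,
                        params: MRFParams) -> pd.Series:
    """Run the state sampler and return the final states.

    Initializes X = 1 on ``g0.nodes`` and 0 elsewhere, then performs
    ``params.n_sweeps`` full sweeps of single-site updates.  The node order
    is the sorted identifier order (or a seeded permutation per sweep when
    ``update_order='random_scan'``).  Same inputs and seed give a
    bit-identical result.

    Returns a :class:`pandas.Series` of 0/1 ints indexed by node, in sorted
    node order.
    """
    extra = set(g0.nodes) - set(net.nodes())
    if extra:
        raise ValueError(f"ground-truth nodes not in network: {sorted(extra)[:5]}")
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    neigh = [np.array([index[j] for j in net.adj[n]], dtype=np.intp)
             for n in nodes]
    degree = np.array([len(a) for a in neigh])
    x = np.zeros(len(nodes), dtype=np.int8)
    g0_idx = np.array(sorted(index[n] for n in g0.nodes), dtype=np.intp)
    x[g0_idx] = 1
    in_g0 = np.zeros(len(nodes), dtype=bool)
    in_g0[g0_idx] = True

    rng = np.random.default_rng(params.seed)
    g0c, g1c, beta, w, mode = (params.gamma0, params.gamma1, params.beta,
                               params.w, params.mu_mode)
    for sweep in range(params.n_sweeps):
        order = (range(len(nodes)) if params.update_order == "sorted"
                 else rng.permutation(len(nodes)))
        u = rng.random(len(nodes))
        for pos, i in enumerate(order):
            xi = int(x[i])
            n1 = int(x[neigh[i]].sum())
            d = int(degree[i])
            # mu_i(0) is the stat against k=1; mu_i(1) against k=0
            mu0 = _mu(mode, w, 1 - xi, d - n1, d)
            mu1 = _mu(mode, w, xi, n1, d)
            x[i] = 1 if u[pos] < _p1(g0c, g1c, beta, mu0, mu1) else 0
        de_in = int(x[in_g0].sum())
        de_out = int(x[~in_g0].sum())
        logger.info("sweep %d: DE inside G0 %d/%d (retained), DE outside %d "
                    "(false positives)", sweep + 1, de_in, len(g0_idx), de_out)
    return pd.Series(x.astype(int), index=nodes, name="state")


def write_states(states: pd.Series, path) -> None:
    """Two-column TSV (gene, state)."""
    states.rename_axis("gene").to_csv(path, sep="\t", header=True)


def read_states(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int).rename("state")
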