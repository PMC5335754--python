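"""End-to-end benchmark orchestration.

One :class:`SimulationConfig` drives the full loop: load or generate a PPI
network → plant a ground-truth subnetwork → sample DE/EE states from the
MRF → generate Gamma-Gamma expression → per-gene differential test → run
the enabled searchers → score everything → write a comparison table.  All
stage outputs land in the output directory together with a manifest of
every seed and parameter, from which any run can be reproduced
byte-for-byte.

Per-stage RNG seeds are derived from the global seed by stable hashing of
the stage name, so enabling or disabling a searcher never changes the
simulated data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import yaml

from . import expression, fixtures, metrics, mrf, network, search

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class SimulationConfig:
    """Full description of one benchmark run."""

    network_path: Optional[str] = None       # edge list / SIF; None → fixture
    network_dialect: str = "edgelist"
    fixture_nodes: int = 1000
    fixture_model: str = "barabasi_albert"
    ground_truth_size: int = 274
    ground_truth_mode: str = "connected"
    mrf: mrf.MRFParams = field(default_factory=mrf.MRFParams)
    gg: expression.GGParams = field(default_factory=expression.GGParams)
    search: search.SearchParams = field(default_factory=search.SearchParams)
    de_test: str = "welch"
    searchers: tuple = ("greedy", "simulated_annealing")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["searchers"] = list(self.searchers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (("mrf", mrf.MRFParams), ("gg", expression.GGParams)):
            if isinstance(d.get(key), dict):
                d[key] = sub(**d[key])
        if isinstance(d.get("search"), dict):
            s = dict(d["search"])
            if isinstance(s.get("sa"), dict):
                s["sa"] = search.SAConfig(**s["sa"])
            d["search"] = search.SearchParams(**s)
        if "searchers" in d:
            d["searchers"] = tuple(d["searchers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class BenchmarkRun:
    """Materialized artifacts of one benchmark run."""

    config: SimulationConfig
    net: nx.Graph
    ground_truth: network.GroundTruthSpec
    states: "pd.Series"  # noqa: F821 - documented type, imported lazily
    expr: expression.ExpressionMatrix
    de: "pd.DataFrame"  # noqa: F821
    results: list
    reports: list


def _load_or_generate_network(config: SimulationConfig) -> nx.Graph:
    if config.network_path is not None:
        return network.load_ppi(config.network_path,
                                dialect=config.network_dialect)
    return fixtures.make_toy_network(config.fixture_nodes,
                                     model=config.fixture_model,
                                     seed=stage_seed(config.seed, "fixture"))


def run_benchmark(config: SimulationConfig,
                  outdir: Optional[str] = None) -> BenchmarkRun:
    """Execute the whole simulation-and-search loop.

    Writes every stage output plus ``report.tsv`` and ``manifest.yaml`` to
    ``outdir`` when given.  Two runs with the same config are byte-identical.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"benchmark stage {name!r} failed: {exc}") from exc

    net = stage("network", _load_or_generate_network, config)
    g0 = stage("ground_truth", network.sample_ground_truth, net,
               config.ground_truth_size,
               stage_seed(config.seed, "ground_truth"),
               mode=config.ground_truth_mode)
    mrf_params = dataclasses.replace(config.mrf,
                                     seed=stage_seed(config.seed, "mrf"))
    states = stage("mrf", mrf.gibbs_sample_states, net, g0, mrf_params)
    gg_params = dataclasses.replace(config.gg,
                                    seed=stage_seed(config.seed, "expression"))
    genes = sorted(net.nodes())
    expr = stage("expression", expression.generate_expression, genes, states,
                 gg_params)
    de = stage("de_test", expression.differential_test, expr, config.de_test)
    z = de["z_score"]

    results = []
    for name in config.searchers:
        sp = dataclasses.replace(
            config.search, rng_seed=stage_seed(config.seed, f"search:{name}"))
        if name == "greedy":
            results.append(stage(name, search.greedy_search, net, z, sp))
        elif name == "simulated_annealing":
            results.append(stage(name, search.simulated_annealing_search,
                                 net, z, sp))
        else:
            raise RuntimeError(f"unknown searcher {name!r}")
    reports = [metrics.evaluate(r, ground=g0.nodes) for r in results]

    run = BenchmarkRun(config, net, g0, states, expr, de, results, reports)
    if outdir is not None:
        _write_run(run, Path(outdir))
    return run


def _write_run(run: BenchmarkRun, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    network.write_edge_list(run.net, outdir / "network.tsv")
    network.write_gene_list(run.ground_truth.nodes,
                            outdir / "ground_truth.txt")
    mrf.write_states(run.states, outdir / "states.tsv")
    run.expr.write(outdir / "expression.tsv", outdir / "sample_labels.tsv")
    expression.write_de_results(run.de, outdir / "de_results.tsv")
    for res in run.results:
        res.write(outdir / f"{res.method_name}_nodes.txt",
                  outdir / f"{res.method_name}_edges.tsv")
    metrics.write_report_table(run.reports, outdir / "report.tsv")
    manifest = {
        "config": run.config.to_dict(),
        "stage_seeds": {s: stage_seed(run.config.seed, s)
                        for s in ("fixture", "ground_truth", "mrf",
                                  "expression")}
        | {f"search:{n}": stage_seed(run.config.seed, f"search:{n}")
           for n in run.config.searchers},
        "network": {"nodes": run.net.number_of_nodes(),
                    "edges": run.net.number_of_edges()},
        "ground_truth_size": len(run.ground_truth),
        "de_state_count": int(run.states.sum()),
    }
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def evaluate_external(result_files: Iterable, *, ground=None, reference=None,
                      n_network: Optional[int] = None,
                      n_reference: Optional[int] = None,
                      universe: Optional[set] = None) -> list:
    """Score node-list files produced by external tools.

    Each file becomes one :class:`~subnetbench.metrics.EvalReport` row (the
    method name is the file stem).  Genes not in ``universe`` (when given)
    are excluded with a warning.
    """
    reports = []
    for path in result_files:
        path = Path(path)
        nodes = set(network.read_gene_list(path))
        if universe is not None:
            unknown = nodes - set(universe)
            if unknown:
                logger.warning("%s: %d genes not in the network, excluded",
                               path.name, len(unknown))
                nodes -= unknown
        if not nodes:
            logger.warning("%s: empty selection", path.name)
        result = metrics.SubnetworkResult(path.stem, frozenset(nodes))
        reports.append(metrics.evaluate(result, ground=ground,
                                        reference=reference,
                                        n_network=n_network,
                                        n_reference=n_reference))
    return reports
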