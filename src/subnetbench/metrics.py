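"""Scoring of recovered subnetworks.

Against a planted ground-truth gene set: precision TP/(TP+FP), recall
TP/(TP+FN) and their harmonic mean (F-measure).  Against a reference
disease-gene list: fold enrichment
(recovered · n_network) / (n_reference · selected), the over-representation
of reference genes among the selected nodes relative to the whole network.
Metrics operate on node sets only; induced-edge counts are reported but
never scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubnetworkResult:
    """A candidate subnetwork produced by any search method."""

    method_name: str
    selected_nodes: frozenset
    induced_edges: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_nodes(cls, method_name: str, nodes: Iterable, net=None
                   ) -> "SubnetworkResult":
        nodes = frozenset(nodes)
        edges = frozenset()
        if net is not None:
            edges = frozenset(
                frozenset((a, b)) for a, b in net.subgraph(nodes).edges())
        return cls(method_name, nodes, edges)

    def write(self, nodes_path, edges_path=None) -> None:
        with open(nodes_path, "w", encoding="utf-8") as fh:
            for n in sorted(self.selected_nodes):
                fh.write(f"{n}\n")
        if edges_path is not None:
            with open(edges_path, "w", encoding="utf-8") as fh:
                for e in sorted(tuple(sorted(e)) for e in self.induced_edges):
                    fh.write(f"{e[0]}\t{e[1]}\n")


@dataclass
class EvalReport:
    """Confusion counts and summary metrics for one method run."""

    method_name: str = ""
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f_measure: float = 0.0
    selected_count: int = 0
    edge_count: int = 0
    recovered_in_reference: Optional[int] = None
    n_network: Optional[int] = None
    n_reference: Optional[int] = None
    fold_enrichment: Optional[float] = None


def confusion_counts(recovered: Iterable, ground: Iterable
                     ) -> tuple[int, int, int]:
    """(TP, FP, FN) of a recovered node set against the ground truth."""
    recovered, ground = set(recovered), set(ground)
    tp = len(recovered & ground)
    return tp, len(recovered) - tp, len(ground) - tp


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision and recall from confusion counts.

    An empty recovered set has undefined precision; it is reported as 0
    (with a warning) so comparison tables always tabulate.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp == 0:
        logger.warning("empty recovered set: precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def fold_enrichment(recovered_in_ref: int, selected: int, n_network: int,
                    n_reference: int) -> float:
    """(recovered · n_network) / (n_reference · selected).

    Undefined for an empty selection (``selected = 0``) → ValueError.
    """
    if selected <= 0:
        raise ValueError("fold enrichment undefined for an empty selection")
    if n_reference <= 0 or n_network <= 0:
        raise ValueError("n_network and n_reference must be positive")
    return float(Fraction(recovered_in_ref * n_network,
                          n_reference * selected))


def evaluate(result: SubnetworkResult,
             ground: Optional[Iterable] = None,
             reference: Optional[Iterable] = None,
             n_network: Optional[int] = None,
             n_reference: Optional[int] = None) -> EvalReport:
    """Full evaluation of one subnetwork result.

    ``ground`` enables precision/recall/F; ``reference`` (plus counts, which
    default to the reference size) enables fold enrichment.  Either or both
    may be given.
    """
    rep = EvalReport(method_name=result.method_name,
                     selected_count=len(result.selected_nodes),
                     edge_count=len(result.induced_edges))
    if ground is not None:
        rep.tp, rep.fp, rep.fn = confusion_counts(result.selected_nodes,
                                                  ground)
        rep.precision, rep.recall = precision_recall(rep.tp, rep.fp, rep.fn)
        rep.f_measure = f_measure(rep.precision, rep.recall)
    if reference is not None:
        reference = set(reference)
        rep.recovered_in_reference = len(result.selected_nodes & reference)
        rep.n_reference = n_reference if n_reference else len(reference)
        rep.n_network = n_network
        if rep.n_network is None:
            raise ValueError("n_network is required for fold enrichment")
        if rep.selected_count > 0:
            rep.fold_enrichment = fold_enrichment(
                rep.recovered_in_reference, rep.selected_count,
                rep.n_network, rep.n_reference)
        else:
            logger.warning("empty selection for %s: fold enrichment "
                           "undefined", result.method_name)
    return rep


_TABLE_COLUMNS = ["method", "selected", "edges", "tp", "precision", "recall",
                  "f_measure", "recovered_in_reference", "fold_enrichment"]


def report_table(reports: Iterable[EvalReport]) -> pd.DataFrame:
    """One row per method; reals rounded half-even to 3 decimals."""
    rows = []
    for r in reports:
        rows.append({
            "method": r.method_name,
            "selected": r.selected_count,
            "edges": r.edge_count,
            "tp": r.tp,
            "precision": round(r.precision, 3),
            "recall": round(r.recall, 3),
            "f_measure": round(r.f_measure, 3),
            "recovered_in_reference": r.recovered_in_reference,
            "fold_enrichment": (None if r.fold_enrichment is None
                                else round(r.fold_enrichment, 3)),
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_report_table(reports: Iterable[EvalReport], path) -> None:
    report_table(reports).to_csv(path, sep="\t", index=False)
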