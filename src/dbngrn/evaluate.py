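"""Convert learned 2TBN structures to regulatory networks and score them.

A transition structure becomes a gene regulatory network by mapping every
inter-slice edge ``X[t] -> Y[t+1]`` (and, by default, every intra-slice
edge ``X[t+1] -> Y[t+1]``) to the directed gene edge ``X -> Y``; the
self-persistence edge ``X[t] -> X[t+1]`` is dropped, as are duplicates.
Initial-slice (B0) edges never enter the reported network: they describe
the start of the time course, not a regulatory step.

Predictions are scored against a truth network with direction-sensitive
edge counts: Ce true positives, Me false negatives, Fe false positives;
precision ``P = Ce / (Ce + Fe)`` and recall ``R = Ce / (Ce + Me)``, each
defined as 0 when its denominator is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

from .core import SAME, GeneNetwork, TwoSliceStructure


@dataclass(frozen=True)
class EdgeConfusion:
    """Directed-edge confusion counts against a truth network."""

    ce: int  # true positives
    me: int  # false negatives
    fe: int  # false positives


def transition_to_grn(
    structure: TwoSliceStructure, include_same: bool = True
) -> GeneNetwork:
    """Collapse a transition template onto gene-level directed edges."""
    edges = set()
    for parent, tag, child in structure.trans_edges():
        if tag == SAME and not include_same:
            continue
        if parent == child:  # self-persistence, not a regulatory edge
            continue
        edges.add((parent, child))
    return GeneNetwork(structure.genes, edges)


def edge_confusion(truth: GeneNetwork, predicted: GeneNetwork) -> EdgeConfusion:
    """Exact set arithmetic on directed edge sets (node sets reconciled by id)."""
    t, p = truth.edges, predicted.edges
    return EdgeConfusion(ce=len(t & p), me=len(t - p), fe=len(p - t))


def precision_recall(conf: EdgeConfusion) -> tuple[float, float]:
    p = conf.ce / (conf.ce + conf.fe) if (conf.ce + conf.fe) else 0.0
    r = conf.ce / (conf.ce + conf.me) if (conf.ce + conf.me) else 0.0
    return p, r


def random_guess_precision(truth: GeneNetwork) -> float:
    """Precision of a uniform random directed-edge guess without self-loops."""
    n = truth.n_nodes
    possible = n * (n - 1)
    return len(truth.edges) / possible if possible else 0.0


def round_report(x: float) -> float:
    """Two-decimal, half-up rounding used in report tables."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


REPORT_COLUMNS = ("method", "n_genes", "seed", "ce", "me", "fe", "precision", "recall")


def evaluation_row(
    method: str, truth: GeneNetwork, predicted: GeneNetwork, seed: int | None = None
) -> dict:
    """One machine-readable report row (full precision retained)."""
    conf = edge_confusion(truth, predicted)
    p, r = precision_recall(conf)
    return {
        "method": method,
        "n_genes": truth.n_nodes,
        "seed": seed,
        "ce": conf.ce,
        "me": conf.me,
        "fe": conf.fe,
        "precision": p,
        "recall": r,
    }


def write_report(rows: Iterable[Mapping], path: str | Path) -> None:
    """TSV report: method, n_genes, seed, Ce, Me, Fe, P, R (two decimals)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    [
                        str(row["method"]),
                        str(row["n_genes"]),
                        "" if row.get("seed") is None else str(row["seed"]),
                        str(row["ce"]),
                        str(row["me"]),
                        str(row["fe"]),
                        f"{round_report(row['precision']):.2f}",
                        f"{round_report(row['recall']):.2f}",
                    ]
                )
                + "\n"
            )
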