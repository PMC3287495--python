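"""Core containers for time-series expression data and 2TBN structures.

The modelling target throughout this package is a first-order, stationary
dynamic Bayesian network given as a pair ``(B0, B->)``: an initial-slice
Bayesian network over the variables at time 0, plus a transition network
that gives each variable at slice ``t+1`` parents at slice ``t`` (tagged
:data:`PREV`) and/or slice ``t+1`` (tagged :data:`SAME`).  Stationarity
means a single transition template describes every ``t -> t+1`` step, so
transition statistics pool over all time points and all replicate
sequences.

:class:`ExpressionMatrix` holds raw continuous measurements
(gene x time x replicate); the learners operate on a
:class:`DiscreteDataset`, a collection of complete discrete observation
sequences.  :class:`GeneNetwork` is a directed graph over gene identifiers
used for true, prior and predicted regulatory networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

#: Tag for a transition parent read at slice t (inter-slice edge).
PREV = "PREV"
#: Tag for a transition parent read at slice t+1 (intra-slice edge).
SAME = "SAME"
TAGS = (PREV, SAME)

#: A transition parent: (gene identifier, PREV or SAME).
TaggedParent = tuple[str, str]


class DbnGrnError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(DbnGrnError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(DbnGrnError):
    """An in-memory object violates a structural invariant."""


class DiscretizationError(DbnGrnError):
    """Discretization could not produce the requested number of levels."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = set()
    for n in names:
        if n in seen:
            raise ValidationError(f"duplicate {what}: {n!r}")
        seen.add(n)


@dataclass(eq=False)
class ExpressionMatrix:
    """Continuous expression values indexed by gene x time x replicate.

    Parameters
    ----------
    genes
        Ordered, unique gene identifiers.
    times
        Ordered (strictly increasing) integer time indices; "slice 0" is the
        first measured time point.
    values
        Array of shape ``(n_genes, n_times, n_replicates)``.  Every cell must
        be present and finite: the learners assume complete observations.
    """

    genes: list[str]
    times: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.times = [int(t) for t in self.times]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.genes, "gene identifier")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("time indices must be strictly increasing")
        if self.values.ndim != 3:
            raise ValidationError("values must be a (genes, times, replicates) array")
        if self.values.shape[:2] != (len(self.genes), len(self.times)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.times)} times"
            )
        if self.values.shape[2] < 1:
            raise ValidationError("need at least one replicate")
        if not np.all(np.isfinite(self.values)):
            g, t, r = [int(x[0]) for x in np.nonzero(~np.isfinite(self.values))]
            raise ValidationError(
                f"non-finite value for gene {self.genes[g]!r} at time "
                f"{self.times[t]}, replicate {r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_replicates(self) -> int:
        return int(self.values.shape[2])

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise ValidationError(f"unknown gene: {gene!r}") from None

    def replicate_mean(self) -> np.ndarray:
        """Mean over replicates; shape ``(n_genes, n_times)``."""
        return self.values.mean(axis=2)


@dataclass(eq=False)
class DiscreteDataset:
    """Complete discrete observation sequences over a fixed gene set.

    ``sequences`` holds ``N_seq`` independent sequences; sequence ``l`` is an
    integer array of shape ``(N_l + 1, n_genes)`` whose rows are consecutive
    time slices.  ``N = sum_l N_l`` is the total number of slice-to-slice
    transitions pooled across sequences, the sample size behind every
    transition-family statistic.
    """

    genes: list[str]
    arities: list[int]
    sequences: list[np.ndarray]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.arities = [int(r) for r in self.arities]
        _check_unique(self.genes, "gene identifier")
        if len(self.arities) != len(self.genes):
            raise ValidationError("one arity per gene required")
        if any(r < 2 for r in self.arities):
            raise ValidationError("arities must be >= 2")
        if not self.sequences:
            raise ValidationError("need at least one observation sequence")
        seqs = []
        arr = np.asarray(self.arities)
        for l, s in enumerate(self.sequences):
            s = np.asarray(s, dtype=np.int64)
            if s.ndim != 2 or s.shape[1] != len(self.genes):
                raise ValidationError(
                    f"sequence {l} must have shape (length, {len(self.genes)})"
                )
            if s.shape[0] < 2:
                raise ValidationError(f"sequence {l} has no transition")
            if np.any(s < 0) or np.any(s >= arr[None, :]):
                raise ValidationError(f"sequence {l} has a level outside its gene's arity")
            seqs.append(s)
        self.sequences = seqs
        self._cache: dict[str, np.ndarray] = {}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_seq(self) -> int:
        """Number of observation sequences (replicates)."""
        return len(self.sequences)

    @property
    def n_transitions(self) -> int:
        """Total transitions N pooled over all sequences."""
        return sum(s.shape[0] - 1 for s in self.sequences)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise ValidationError(f"unknown gene: {gene!r}") from None

    def arity(self, gene: str) -> int:
        return self.arities[self.gene_index(gene)]

    @property
    def arity_map(self) -> dict[str, int]:
        return dict(zip(self.genes, self.arities))

    def slice0_matrix(self) -> np.ndarray:
        """Initial-slice observations; shape ``(N_seq, n_genes)``."""
        if "s0" not in self._cache:
            self._cache["s0"] = np.stack([s[0] for s in self.sequences])
        return self._cache["s0"]

    def prev_matrix(self) -> np.ndarray:
        """Slice-t rows of every pooled transition; shape ``(N, n_genes)``."""
        if "prev" not in self._cache:
            self._cache["prev"] = np.concatenate([s[:-1] for s in self.sequences])
        return self._cache["prev"]

    def next_matrix(self) -> np.ndarray:
        """Slice-(t+1) rows of every pooled transition; shape ``(N, n_genes)``."""
        if "next" not in self._cache:
            self._cache["next"] = np.concatenate([s[1:] for s in self.sequences])
        return self._cache["next"]


class GeneNetwork:
    """Directed graph over gene identifiers (no self-loops).

    Used for true networks, timing priors and predicted regulatory networks.
    Edges are ordered ``(regulator, target)`` pairs over declared nodes.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        meta: Mapping[str, object] | None = None,
    ) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        _check_unique(self.nodes, "node")
        self._node_set = set(self.nodes)
        self.edges: set[tuple[str, str]] = set()
        self.meta: dict[str, object] = dict(meta or {})
        for u, v in edges:
            self.add_edge(u, v)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None
    ) -> "GeneNetwork":
        edges = list(edges)
        if nodes is None:
            seen: list[str] = []
            for u, v in edges:
                for g in (u, v):
                    if g not in seen:
                        seen.append(g)
            nodes = seen
        return cls(nodes, edges)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValidationError(f"self-loop not allowed: {u!r}")
        for g in (u, v):
            if g not in self._node_set:
                raise ValidationError(f"edge references undeclared node {g!r}")
        self.edges.add((u, v))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def out_degree(self, gene: str) -> int:
        return sum(1 for u, _ in self.edges if u == gene)

    def in_degree(self, gene: str) -> int:
        return sum(1 for _, v in self.edges if v == gene)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def __hash__(self):  # pragma: no cover - mutable container
        raise TypeError("GeneNetwork is unhashable")

    def __repr__(self) -> str:
        return f"GeneNetwork({len(self.nodes)} nodes, {len(self.edges)} edges)"


@dataclass(eq=False)
class TwoSliceStructure:
    """A 2TBN structure: initial network B0 plus the transition template.

    ``b0_parents[g]`` is the set of slice-0 parents of ``g`` at time 0 and
    must induce a DAG.  ``trans_parents[g]`` is a set of tagged parents of
    ``g`` at slice ``t+1``: ``(p, PREV)`` reads ``p`` at slice ``t`` (these
    edges can never create a cycle), ``(p, SAME)`` reads ``p`` at slice
    ``t+1`` and the SAME-tagged subgraph must be a DAG.  One table describes
    every transition (stationarity).
    """

    genes: list[str]
    b0_parents: dict[str, set[str]] = field(default_factory=dict)
    trans_parents: dict[str, set[TaggedParent]] = field(default_factory=dict)
    meta: dict[str, object] = field(default_factory=dict)

    @classmethod
    def empty(cls, genes: Iterable[str]) -> "TwoSliceStructure":
        genes = list(genes)
        return cls(
            genes=genes,
            b0_parents={g: set() for g in genes},
            trans_parents={g: set() for g in genes},
        )

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        _check_unique(self.genes, "gene identifier")
        for g in self.genes:
            self.b0_parents.setdefault(g, set())
            self.trans_parents.setdefault(g, set())
        self.validate()

    def validate(self) -> None:
        node_set = set(self.genes)
        b0 = nx.DiGraph()
        b0.add_nodes_from(self.genes)
        for child, parents in self.b0_parents.items():
            if child not in node_set:
                raise ValidationError(f"unknown gene in b0_parents: {child!r}")
            for p in parents:
                if p not in node_set:
                    raise ValidationError(f"unknown b0 parent {p!r} of {child!r}")
                if p == child:
                    raise ValidationError(f"b0 self-loop on {child!r}")
                b0.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(b0):
            raise ValidationError("b0_parents induces a cycle")
        same = nx.DiGraph()
        same.add_nodes_from(self.genes)
        for child, parents in self.trans_parents.items():
            if child not in node_set:
                raise ValidationError(f"unknown gene in trans_parents: {child!r}")
            for p, tag in parents:
                if p not in node_set:
                    raise ValidationError(f"unknown transition parent {p!r} of {child!r}")
                if tag not in TAGS:
                    raise ValidationError(f"bad parent tag {tag!r} (expected PREV or SAME)")
                if tag == SAME:
                    if p == child:
                        raise ValidationError(f"SAME self-cycle on {child!r}")
                    same.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(same):
            raise ValidationError("SAME-tagged transition edges induce a cycle")

    def b0_edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self.b0_parents.items() for p in ps}

    def trans_edges(self) -> set[tuple[str, str, str]]:
        """Edges as ``(parent, tag, child)`` triples."""
        return {(p, tag, c) for c, ps in self.trans_parents.items() for p, tag in ps}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TwoSliceStructure):
            return NotImplemented
        return (
            set(self.genes) == set(other.genes)
            and self.b0_edges() == other.b0_edges()
            and self.trans_edges() == other.trans_edges()
        )

    def __repr__(self) -> str:
        return (
            f"TwoSliceStructure({len(self.genes)} genes, "
            f"{len(self.b0_edges())} b0 edges, {len(self.trans_edges())} transition edges)"
        )


@dataclass(eq=False)
class FamilyCounts:
    """Sufficient statistics ``N_{j,k}`` for one child and one parent set.

    ``table[j, k]`` counts observations with parent configuration ``j``
    (mixed-radix index over the parents' arities, first parent most
    significant) and child level ``k``.  ``total`` is ``N_seq`` for
    initial-slice families and ``N`` for transition families.
    """

    child: str
    parents: tuple
    table: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.ndim != 2:
            raise ValidationError("counts table must be 2-D (configs x child levels)")
        if np.any(self.table < 0):
            raise ValidationError("negative count")
        if int(self.table.sum()) != int(self.total):
            raise ValidationError("counts do not sum to the declared total")

    @property
    def n_configs(self) -> int:
        return int(self.table.shape[0])

    @property
    def r_child(self) -> int:
        return int(self.table.shape[1])
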