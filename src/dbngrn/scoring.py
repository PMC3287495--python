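"""Sufficient statistics and the decomposable BIC score for 2TBNs.

The score of a structure ``G`` on complete data ``D`` is the maximized
multinomial log-likelihood penalized by model dimension:

    BIC(G : D) = l(theta_hat : D) - (log M / 2) * Dim[G]

and it splits exactly into an initial-slice part and a transition part,
``BIC = BIC0 + BIC->``, because the likelihood factorizes over the two
components.  The initial part is penalized with ``M = N_seq`` (number of
sequences: one slice-0 observation each) and the transition part with
``M = N`` (total pooled transitions).  Both parts further decompose over
child families, so structure search only ever rescores single families.

Dimension uses the declared-arity convention,
``Dim = (r_child - 1) * prod(r_parent)``, independent of which levels were
actually observed.  Logarithms are natural (scores in nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, prod
from typing import Iterable, Mapping

import numpy as np

from .core import (
    PREV,
    SAME,
    TAGS,
    DiscreteDataset,
    FamilyCounts,
    TaggedParent,
    TwoSliceStructure,
    ValidationError,
)


def _tally(
    parent_cols: list[np.ndarray],
    parent_arities: list[int],
    child_col: np.ndarray,
    r_child: int,
) -> np.ndarray:
    """Count table (parent configs x child levels) by mixed-radix encoding."""
    code = np.zeros(child_col.shape[0], dtype=np.int64)
    for col, r in zip(parent_cols, parent_arities):
        code = code * r + col
    n_cfg = prod(parent_arities) if parent_arities else 1
    flat = np.bincount(code * r_child + child_col, minlength=n_cfg * r_child)
    return flat.reshape(n_cfg, r_child)


def count_initial(
    dataset: DiscreteDataset, child: str, parents: Iterable[str] = ()
) -> FamilyCounts:
    """Tally ``N0_{j,k}`` over the slice-0 row of each sequence.

    Parents are untagged slice-0 genes.  The table total is ``N_seq``.
    """
    parents = tuple(parents)
    if child in parents:
        raise ValidationError(f"child {child!r} cannot be its own slice-0 parent")
    s0 = dataset.slice0_matrix()
    ci = dataset.gene_index(child)
    cols = [s0[:, dataset.gene_index(p)] for p in parents]
    table = _tally(cols, [dataset.arity(p) for p in parents], s0[:, ci], dataset.arities[ci])
    return FamilyCounts(child=child, parents=parents, table=table, total=dataset.n_seq)


def count_transition(
    dataset: DiscreteDataset, child: str, parents: Iterable[TaggedParent] = ()
) -> FamilyCounts:
    """Tally ``N->_{j,k}`` pooled over every transition of every sequence.

    The child is read at slice ``t+1``; a ``(gene, PREV)`` parent is read at
    slice ``t`` and a ``(gene, SAME)`` parent at slice ``t+1``.  Counts pool
    over all ``t`` (stationarity), so the table total is ``N``.  The child
    may appear as its own PREV parent (persistence) but not SAME.
    """
    parents = tuple((g, tag) for g, tag in parents)
    for g, tag in parents:
        if tag not in TAGS:
            raise ValidationError(f"bad parent tag {tag!r}")
        if tag == SAME and g == child:
            raise ValidationError(f"child {child!r} tagged SAME in its own parent set")
    prev_m, next_m = dataset.prev_matrix(), dataset.next_matrix()
    ci = dataset.gene_index(child)
    cols = [
        (prev_m if tag == PREV else next_m)[:, dataset.gene_index(g)]
        for g, tag in parents
    ]
    table = _tally(
        cols, [dataset.arity(g) for g, _ in parents], next_m[:, ci], dataset.arities[ci]
    )
    return FamilyCounts(
        child=child, parents=parents, table=table, total=dataset.n_transitions
    )


def family_loglik(counts: FamilyCounts, pseudo_count: float = 0.0) -> float:
    """Maximized multinomial log-likelihood of one family, in nats.

    Plugs the MLE ``theta_hat_{j,k} = N_{j,k} / N_{j,.}`` back into the
    likelihood: ``sum_{j,k} N_{j,k} log(N_{j,k} / N_{j,.})`` with the
    conventions ``0 log 0 = 0`` and empty parent configurations contributing
    nothing.  A positive ``pseudo_count`` smooths theta (not the weights):
    ``theta = (N + a) / (N_{j,.} + a * r_child)``.
    """
    table = counts.table.astype(float)
    rows = table.sum(axis=1, keepdims=True)
    if pseudo_count > 0.0:
        theta = (table + pseudo_count) / (rows + pseudo_count * counts.r_child)
        mask = table > 0
        return float((table[mask] * np.log(theta[mask])).sum())
    mask = table > 0
    row_b = np.broadcast_to(rows, table.shape)
    return float((table[mask] * (np.log(table[mask]) - np.log(row_b[mask]))).sum())


def family_dim(r_child: int, parent_arities: Iterable[int]) -> int:
    """Independent parameters of a family: ``(r_child - 1) * prod(r_parent)``."""
    return (r_child - 1) * prod(parent_arities, start=1)


@dataclass(frozen=True)
class FamilyScore:
    """Penalized score of one family.

    ``penalized = loglik - (log M / 2) * dim`` where ``M`` is ``N_seq`` for
    initial-slice families and ``N`` for transition families.
    """

    child: str
    parents: tuple
    loglik: float
    dim: int
    penalized: float


def family_bic(
    counts: FamilyCounts,
    m: int,
    arities: Mapping[str, int] | None = None,
    pseudo_count: float = 0.0,
) -> FamilyScore:
    """BIC-penalized family score with sample size ``m``.

    ``arities`` may override the dimensions implied by the counts table
    (declared arities); by default the table shape — which was built from
    declared arities — is used.
    """
    if m < 1:
        raise ValidationError("sample size m must be >= 1")
    if arities is None:
        dim = (counts.r_child - 1) * counts.n_configs
    else:
        names = [p[0] if isinstance(p, tuple) else p for p in counts.parents]
        dim = family_dim(arities[counts.child], [arities[g] for g in names])
    ll = family_loglik(counts, pseudo_count=pseudo_count)
    return FamilyScore(
        child=counts.child,
        parents=counts.parents,
        loglik=ll,
        dim=dim,
        penalized=ll - 0.5 * log(m) * dim,
    )


def initial_family_score(
    dataset: DiscreteDataset,
    child: str,
    parents: Iterable[str] = (),
    pseudo_count: float = 0.0,
) -> FamilyScore:
    counts = count_initial(dataset, child, parents)
    return family_bic(counts, dataset.n_seq, pseudo_count=pseudo_count)


def transition_family_score(
    dataset: DiscreteDataset,
    child: str,
    parents: Iterable[TaggedParent] = (),
    pseudo_count: float = 0.0,
) -> FamilyScore:
    counts = count_transition(dataset, child, parents)
    return family_bic(counts, dataset.n_transitions, pseudo_count=pseudo_count)


def bic_initial(structure: TwoSliceStructure, dataset: DiscreteDataset) -> float:
    """BIC0: sum of penalized slice-0 family scores, M = N_seq."""
    return sum(
        initial_family_score(dataset, g, sorted(structure.b0_parents[g])).penalized
        for g in structure.genes
    )


def bic_transition(structure: TwoSliceStructure, dataset: DiscreteDataset) -> float:
    """BIC->: sum of penalized transition family scores, M = N."""
    return sum(
        transition_family_score(dataset, g, sorted(structure.trans_parents[g])).penalized
        for g in structure.genes
    )


def bic_total(structure: TwoSliceStructure, dataset: DiscreteDataset) -> float:
    """Total score; exactly ``bic_initial + bic_transition`` (decomposability)."""
    return bic_initial(structure, dataset) + bic_transition(structure, dataset)
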