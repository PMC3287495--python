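"""REVEAL baseline: mutual-information lattice search for parent sets.

REVEAL scores a candidate parent set for a child by the ratio of the mutual
information between the parents (read at slice t) and the child (read at
slice t+1) to the child's marginal entropy.  It scans the subset lattice by
increasing size and accepts the first set whose ratio reaches 1 — i.e. the
parents determine the child exactly in the data.  With noisy data no set
reaches 1; the search then falls back to the best-ratio set found (flagged
``sub_threshold``), so the baseline still yields a network.

All quantities are plug-in (empirical) estimates in nats over the pooled
transitions; parent sets are inter-slice (PREV) only, matching the classic
DBN usage of the algorithm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import prod
from typing import Iterable, Sequence

import numpy as np

from .core import (
    PREV,
    DiscreteDataset,
    GeneNetwork,
    TwoSliceStructure,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Acceptance threshold on the MI/entropy ratio.  In exact arithmetic a
#: deterministic family reaches exactly 1; the epsilon absorbs float error.
RATIO_TOLERANCE = 1e-9


@dataclass(frozen=True)
class MutualInfoResult:
    """Outcome of the lattice search for one child."""

    child: str
    parents: tuple[str, ...]
    mi: float
    child_entropy: float
    ratio: float
    sub_threshold: bool = False


def _entropy_of_codes(code: np.ndarray, n_states: int) -> float:
    counts = np.bincount(code, minlength=n_states).astype(float)
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def _columns(dataset: DiscreteDataset, genes: Sequence[str], slices: Sequence[str]):
    prev_m, next_m = dataset.prev_matrix(), dataset.next_matrix()
    cols, arities = [], []
    for g, sl in zip(genes, slices):
        if sl not in ("prev", "next"):
            raise ValidationError(f"bad slice spec {sl!r} (expected 'prev' or 'next')")
        m = prev_m if sl == "prev" else next_m
        cols.append(m[:, dataset.gene_index(g)])
        arities.append(dataset.arity(g))
    return cols, arities


def empirical_entropy(
    dataset: DiscreteDataset,
    genes: Sequence[str],
    slice_spec: str | Sequence[str] = "next",
) -> float:
    """Plug-in joint entropy (nats) of the named variables over pooled transitions.

    ``slice_spec`` is ``"prev"`` / ``"next"`` applied to every gene, or a
    per-gene sequence of those tags.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("empirical_entropy requires at least one gene")
    slices = [slice_spec] * len(genes) if isinstance(slice_spec, str) else list(slice_spec)
    if len(slices) != len(genes):
        raise ValidationError("slice_spec length must match genes")
    cols, arities = _columns(dataset, genes, slices)
    code = np.zeros(cols[0].shape[0], dtype=np.int64)
    for col, r in zip(cols, arities):
        code = code * r + col
    return _entropy_of_codes(code, prod(arities))


def mutual_information(
    dataset: DiscreteDataset, child: str, parents: Sequence[str]
) -> tuple[float, float]:
    """(MI(parents[t]; child[t+1]), H(child[t+1])) in nats."""
    h_child = empirical_entropy(dataset, [child], "next")
    if not parents:
        return 0.0, h_child
    h_parents = empirical_entropy(dataset, parents, "prev")
    h_joint = empirical_entropy(
        dataset, list(parents) + [child], ["prev"] * len(parents) + ["next"]
    )
    return h_parents + h_child - h_joint, h_child


def reveal_parents(
    dataset: DiscreteDataset,
    child: str,
    max_parents: int = 3,
    candidate_filter: GeneNetwork | None = None,
    include_self: bool = True,
) -> MutualInfoResult:
    """Lattice search for one child's parent set.

    Evaluates all candidate sets of size 1, then 2, ... up to
    ``max_parents`` and returns the first whose MI/entropy ratio reaches 1
    (within :data:`RATIO_TOLERANCE`).  If none does, returns the
    best-ratio set found, flagged sub-threshold.  Ties are resolved by the
    scan order: smaller sets first, lexicographic parent names within a
    level.  A constant child is returned with an empty parent set and
    ratio 1 by convention.
    """
    if max_parents < 1:
        raise ValidationError("max_parents must be >= 1")
    candidates = sorted(
        g
        for g in dataset.genes
        if (g == child and include_self)
        or (g != child and (candidate_filter is None or candidate_filter.has_edge(g, child)))
    )
    if not candidates:
        raise ValidationError(f"no candidate parents available for {child!r} under the filter")

    h_child = empirical_entropy(dataset, [child], "next")
    if h_child <= 0.0:
        return MutualInfoResult(child, (), 0.0, 0.0, 1.0)

    best: MutualInfoResult | None = None
    for size in range(1, max_parents + 1):
        for combo in itertools.combinations(candidates, size):
            mi, _ = mutual_information(dataset, child, combo)
            ratio = mi / h_child
            if best is None or ratio > best.ratio + RATIO_TOLERANCE:
                best = MutualInfoResult(child, combo, mi, h_child, ratio)
            if ratio >= 1.0 - RATIO_TOLERANCE:
                return MutualInfoResult(child, combo, mi, h_child, ratio)
    assert best is not None
    return MutualInfoResult(
        child, best.parents, best.mi, best.child_entropy, best.ratio, sub_threshold=True
    )


def reveal_network(
    dataset: DiscreteDataset,
    max_parents: int = 3,
    candidate_filter: GeneNetwork | None = None,
    include_self: bool = True,
    keep_sub_threshold: bool = True,
) -> TwoSliceStructure:
    """Apply :func:`reveal_parents` to every gene independently.

    All parents are PREV-tagged; B0 is left empty (REVEAL has no notion of
    an initial-slice network).  Children that only reached a sub-threshold
    ratio are listed in the result's ``meta["sub_threshold"]``; with
    ``keep_sub_threshold=False`` such children get no parents at all — the
    classic behavior of the algorithm, which only ever accepts a parent set
    whose score reaches 1.0.
    """
    structure = TwoSliceStructure.empty(dataset.genes)
    sub: list[str] = []
    ratios: dict[str, float] = {}
    for child in dataset.genes:
        res = reveal_parents(
            dataset,
            child,
            max_parents=max_parents,
            candidate_filter=candidate_filter,
            include_self=include_self,
        )
        if res.sub_threshold and not keep_sub_threshold:
            structure.trans_parents[child] = set()
        else:
            structure.trans_parents[child] = {(p, PREV) for p in res.parents}
        ratios[child] = res.ratio
        if res.sub_threshold:
            sub.append(child)
        log.info(
            "REVEAL family %s: parents=%s ratio=%.6f%s",
            child,
            list(res.parents),
            res.ratio,
            " (sub-threshold)" if res.sub_threshold else "",
        )
    structure.validate()
    structure.meta.update(
        {
            "method": "reveal",
            "max_parents": max_parents,
            "filtered": candidate_filter is not None,
            "sub_threshold": sub,
            "ratios": ratios,
        }
    )
    return structure
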