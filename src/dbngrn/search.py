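"""Greedy K2-style structure search for 2TBNs, plus an exhaustive oracle.

The search maximizes the decomposable BIC family by family.  Classic K2
takes a node ordering and grows each node's parent set greedily with the
single parent that most increases the family score, stopping when no
addition improves it.  The 2TBN adaptation learns B0 and the transition
template independently:

* B0 phase — candidates for a child are genes earlier in the ordering
  (guaranteeing a DAG), scored against slice-0 counts with ``M = N_seq``.
* transition phase — candidates are every gene tagged PREV (inter-slice
  edges, including the child's own persistence edge, can never create a
  cycle) plus earlier-in-order genes tagged SAME, scored against pooled
  transition counts with ``M = N``.

An optional candidate filter (e.g. a timing prior network) restricts which
(regulator, target) pairs may be proposed; the child's own PREV edge is
always admissible.  Acceptance requires a strict score increase, so the
per-family score trace is strictly increasing and ties favor not adding.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Callable, Hashable, Iterable, Sequence

from .core import (
    PREV,
    SAME,
    DiscreteDataset,
    GeneNetwork,
    TaggedParent,
    TwoSliceStructure,
    ValidationError,
)
from .scoring import initial_family_score, transition_family_score

log = logging.getLogger(__name__)

_ORACLE_MAX_GENES = 6


def _check_order(dataset: DiscreteDataset, order: Sequence[str] | None) -> list[str]:
    if order is None:
        return list(dataset.genes)
    order = list(order)
    if sorted(order) != sorted(dataset.genes):
        raise ValidationError("order must be a permutation of the dataset's genes")
    return order


def _check_filter(dataset: DiscreteDataset, flt: GeneNetwork | None) -> None:
    if flt is None:
        return
    unknown = set(flt.nodes) - set(dataset.genes)
    if unknown:
        raise ValidationError(f"candidate filter references unknown genes: {sorted(unknown)}")


def _greedy_family(
    score_fn: Callable[[tuple], float],
    candidates: Sequence[Hashable],
    max_parents: int,
) -> tuple[tuple, list[float]]:
    """Grow one parent set greedily; returns (parents, score trace)."""
    current: tuple = ()
    cur_score = score_fn(())
    trace = [cur_score]
    candidates = sorted(candidates)
    while len(current) < max_parents:
        best_c = None
        best_s = cur_score
        for c in candidates:
            if c in current:
                continue
            s = score_fn(tuple(sorted(current + (c,))))
            if s > best_s:  # strict improvement; ties favor not adding
                best_s, best_c = s, c
        if best_c is None:
            break
        current = tuple(sorted(current + (best_c,)))
        cur_score = best_s
        trace.append(cur_score)
    return current, trace


def k2_dbn(
    dataset: DiscreteDataset,
    order: Sequence[str] | None = None,
    max_parents: int = 3,
    candidate_filter: GeneNetwork | None = None,
    filter_same: bool = True,
) -> TwoSliceStructure:
    """Learn a 2TBN by greedy BIC-maximizing parent addition.

    Parameters
    ----------
    dataset
        Discrete observation sequences.
    order
        K2 node ordering (permutation of the dataset's genes); defaults to
        the dataset's own gene order.
    max_parents
        Cap on parents per family.  The default of 3 keeps conditional
        probability tables estimable at the few hundred transitions typical
        of replicated microarray time courses.
    candidate_filter
        Optional network restricting admissible (regulator, target) pairs;
        self-persistence PREV edges are always admissible.
    filter_same
        Whether the filter also restricts SAME-tagged (intra-slice)
        candidates, not just PREV ones.
    """
    order = _check_order(dataset, order)
    _check_filter(dataset, candidate_filter)
    if max_parents < 0:
        raise ValidationError("max_parents must be >= 0")
    pos = {g: i for i, g in enumerate(order)}

    def allowed(parent: str, child: str) -> bool:
        return candidate_filter is None or candidate_filter.has_edge(parent, child)

    structure = TwoSliceStructure.empty(dataset.genes)
    b0_cache: dict[tuple, float] = {}
    tr_cache: dict[tuple, float] = {}
    b0_traces: dict[str, list[float]] = {}
    tr_traces: dict[str, list[float]] = {}

    for child in dataset.genes:
        def b0_score(parents: tuple, _child=child) -> float:
            key = (_child, parents)
            if key not in b0_cache:
                b0_cache[key] = initial_family_score(dataset, _child, parents).penalized
            return b0_cache[key]

        b0_cands = [g for g in order[: pos[child]] if allowed(g, child)]
        parents, trace = _greedy_family(b0_score, b0_cands, max_parents)
        structure.b0_parents[child] = set(parents)
        b0_traces[child] = trace
        log.info("B0 family %s: parents=%s score=%.6f", child, list(parents), trace[-1])

        def tr_score(parents: tuple, _child=child) -> float:
            key = (_child, parents)
            if key not in tr_cache:
                tr_cache[key] = transition_family_score(dataset, _child, parents).penalized
            return tr_cache[key]

        tr_cands: list[TaggedParent] = [
            (g, PREV) for g in dataset.genes if g == child or allowed(g, child)
        ]
        tr_cands += [
            (g, SAME)
            for g in order[: pos[child]]
            if g != child and (allowed(g, child) or not filter_same)
        ]
        parents, trace = _greedy_family(tr_score, tr_cands, max_parents)
        structure.trans_parents[child] = set(parents)
        tr_traces[child] = trace
        log.info(
            "transition family %s: parents=%s score=%.6f", child, list(parents), trace[-1]
        )

    structure.validate()
    structure.meta.update(
        {
            "method": "friedman-k2",
            "order": list(order),
            "max_parents": max_parents,
            "filtered": candidate_filter is not None,
            "b0_score_traces": b0_traces,
            "trans_score_traces": tr_traces,
        }
    )
    return structure


def exhaustive_oracle(
    dataset: DiscreteDataset,
    order: Sequence[str] | None = None,
    max_parents: int = 3,
    candidate_filter: GeneNetwork | None = None,
    filter_same: bool = True,
) -> TwoSliceStructure:
    """Per-family exhaustive argmax over all admissible parent sets.

    A testing oracle: searches the same admissible space as :func:`k2_dbn`
    but enumerates every parent set of size <= ``max_parents`` per family
    independently.  Ties are broken toward the smaller set, then
    lexicographically smaller parent names.  Refuses datasets with more
    than 6 genes (the enumeration is exponential).
    """
    if dataset.n_genes > _ORACLE_MAX_GENES:
        raise ValidationError(
            f"exhaustive oracle limited to {_ORACLE_MAX_GENES} genes; "
            f"got {dataset.n_genes}"
        )
    order = _check_order(dataset, order)
    _check_filter(dataset, candidate_filter)
    pos = {g: i for i, g in enumerate(order)}

    def allowed(parent: str, child: str) -> bool:
        return candidate_filter is None or candidate_filter.has_edge(parent, child)

    def argmax(score_fn, candidates: Sequence) -> tuple:
        best_set: tuple = ()
        best = score_fn(())
        for size in range(1, max_parents + 1):
            for combo in itertools.combinations(sorted(candidates), size):
                s = score_fn(combo)
                if s > best:  # iteration order implements the tie-break
                    best, best_set = s, combo
        return best_set

    structure = TwoSliceStructure.empty(dataset.genes)
    for child in dataset.genes:
        b0_cands = [g for g in order[: pos[child]] if allowed(g, child)]
        structure.b0_parents[child] = set(
            argmax(lambda ps, c=child: initial_family_score(dataset, c, ps).penalized, b0_cands)
        )
        tr_cands: list[TaggedParent] = [
            (g, PREV) for g in dataset.genes if g == child or allowed(g, child)
        ]
        tr_cands += [
            (g, SAME)
            for g in order[: pos[child]]
            if g != child and (allowed(g, child) or not filter_same)
        ]
        structure.trans_parents[child] = set(
            argmax(
                lambda ps, c=child: transition_family_score(dataset, c, ps).penalized,
                tr_cands,
            )
        )
    structure.validate()
    structure.meta.update(
        {"method": "exhaustive-oracle", "order": list(order), "max_parents": max_parents}
    )
    return structure


METHOD_NAMES = ("friedman", "friedman-k2", "k2", "reveal")


def learn(dataset: DiscreteDataset, method: str, **options) -> TwoSliceStructure:
    """Uniform entry point dispatching to a structure learner.

    ``method`` is one of ``friedman`` / ``friedman-k2`` / ``k2`` (all the
    greedy BIC search) or ``reveal``.  Options are forwarded; provenance
    (method name and options) is recorded in the result's ``meta``.
    """
    name = method.lower()
    if name in ("friedman", "friedman-k2", "k2"):
        structure = k2_dbn(dataset, **options)
    elif name == "reveal":
        from .reveal import reveal_network

        structure = reveal_network(dataset, **options)
    else:
        raise ValidationError(
            f"unknown method {method!r}; valid names: {', '.join(METHOD_NAMES)}"
        )
    structure.meta["requested_method"] = method
    structure.meta["options"] = {
        k: (v if not isinstance(v, GeneNetwork) else f"<network {len(v.edges)} edges>")
        for k, v in options.items()
    }
    return structure


def write_structure(structure: TwoSliceStructure, path: str | Path) -> None:
    """Serialize a structure: [GENES], [B0] edge lines, [TRANS] tagged lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("[GENES]\n")
        for g in structure.genes:
            fh.write(g + "\n")
        fh.write("[B0]\n")
        for p, c in sorted(structure.b0_edges()):
            fh.write(f"{p}\t{c}\n")
        fh.write("[TRANS]\n")
        for p, tag, c in sorted(structure.trans_edges()):
            fh.write(f"{p}\t{tag}\t{c}\n")


def read_structure(path: str | Path) -> TwoSliceStructure:
    path = Path(path)
    genes: list[str] = []
    b0: list[tuple[str, str]] = []
    trans: list[tuple[str, str, str]] = []
    section = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line in ("[GENES]", "[B0]", "[TRANS]"):
            section = line
            continue
        parts = line.split("\t")
        if section == "[GENES]":
            genes.append(line.strip())
        elif section == "[B0]":
            if len(parts) != 2:
                raise ValidationError(f"{path}:{ln}: expected 'parent<TAB>child'")
            b0.append((parts[0], parts[1]))
        elif section == "[TRANS]":
            if len(parts) != 3 or parts[1] not in (PREV, SAME):
                raise ValidationError(
                    f"{path}:{ln}: expected 'parent<TAB>PREV|SAME<TAB>child'"
                )
            trans.append((parts[0], parts[1], parts[2]))
        else:
            raise ValidationError(f"{path}:{ln}: line outside any section")
    structure = TwoSliceStructure.empty(genes)
    for p, c in b0:
        structure.b0_parents[c].add(p)
    for p, tag, c in trans:
        structure.trans_parents[c].add((p, tag))
    structure.validate()
    return structure
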