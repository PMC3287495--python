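"""Shared fixtures and small discrete-DBN simulators used as test oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dbngrn import DiscreteDataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(sequences, arities=None, genes=None) -> DiscreteDataset:
    """Build a DiscreteDataset from plain nested lists/arrays."""
    seqs = [np.asarray(s, dtype=np.int64) for s in sequences]
    n = seqs[0].shape[1]
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    if arities is None:
        arities = [max(2, int(max(s[:, i].max() for s in seqs)) + 1) for i in range(n)]
    return DiscreteDataset(genes=genes, arities=list(arities), sequences=seqs)


def simulate_discrete_dbn(
    genes: list[str],
    arities: list[int],
    parents: dict[str, list[str]],
    cpts: dict[str, np.ndarray],
    n_seq: int,
    n_transitions: int,
    rng: np.random.Generator,
) -> DiscreteDataset:
    """Sample sequences from a PREV-only discrete 2TBN (independent oracle).

    ``parents[g]`` lists g's slice-t parents; ``cpts[g]`` has one row per
    mixed-radix parent configuration (first parent most significant) giving
    the distribution of g at slice t+1.  Slice 0 is uniform independent.
    """
    idx = {g: i for i, g in enumerate(genes)}
    seqs = []
    for _ in range(n_seq):
        rows = [rng.integers(0, arities)]
        for _ in range(n_transitions):
            prev = rows[-1]
            new = np.empty(len(genes), dtype=np.int64)
            for gi, g in enumerate(genes):
                code = 0
                for p in parents.get(g, []):
                    code = code * arities[idx[p]] + prev[idx[p]]
                new[gi] = rng.choice(arities[gi], p=cpts[g][code])
            rows.append(new)
        seqs.append(np.stack(rows))
    return DiscreteDataset(genes=genes, arities=list(arities), sequences=seqs)


def random_single_parent_dbn(n_genes: int, rng: np.random.Generator, strength=0.85):
    """A random binary 2TBN where every gene has at most one PREV parent.

    Children copy their parent with probability ``strength``; roots are
    near-uniform.  Returns (genes, arities, parents, cpts).
    """
    genes = [f"g{i}" for i in range(n_genes)]
    arities = [2] * n_genes
    parents: dict[str, list[str]] = {}
    cpts: dict[str, np.ndarray] = {}
    for i, g in enumerate(genes):
        if i > 0 and rng.random() < 0.8:
            p = genes[int(rng.integers(0, i))]
            parents[g] = [p]
            cpts[g] = np.array([[strength, 1 - strength], [1 - strength, strength]])
        else:
            parents[g] = []
            cpts[g] = np.array([[0.5, 0.5]])
    return genes, arities, parents, cpts


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def xor_dataset(n_transitions: int = 64) -> DiscreteDataset:
    """Three binary genes where C[t+1] = A[t] XOR B[t], noise-free.

    Built as length-2 sequences enumerating every combination of
    ``(A[0], B[0], A[1], B[1])`` equally often, so the inputs are exactly
    balanced, every parent configuration is observed, and the empirical
    mutual information between C[t+1] and any single variable — at either
    slice — vanishes exactly.
    """
    import itertools

    if n_transitions % 16:
        raise ValueError("n_transitions must be a multiple of 16")
    seqs = [
        np.array([[a, b, 0], [a2, b2, a ^ b]])
        for _ in range(n_transitions // 16)
        for a, b, a2, b2 in itertools.product((0, 1), repeat=4)
    ]
    return DiscreteDataset(genes=["A", "B", "C"], arities=[2, 2, 2], sequences=seqs)


def copy_chain_dataset(
    n_genes: int, n_transitions: int, rng: np.random.Generator
) -> DiscreteDataset:
    """Noise-free binary cascade: gene i+1 at t+1 copies gene i at t.

    The root gene is i.i.d. uniform, so each link is an exact copy with all
    configurations observed — the textbook case both learners must recover.
    """
    length = n_transitions + 1
    cols = [rng.integers(0, 2, size=length)]
    for _ in range(1, n_genes):
        prev = cols[-1]
        col = np.empty(length, dtype=np.int64)
        col[0] = rng.integers(0, 2)
        col[1:] = prev[:-1]
        cols.append(col)
    seq = np.stack(cols, axis=1)
    return DiscreteDataset(
        genes=[f"g{i}" for i in range(n_genes)],
        arities=[2] * n_genes,
        sequences=[seq],
    )
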