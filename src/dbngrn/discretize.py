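"""Discretization of continuous expression matrices into level sequences.

Each gene is binned independently, with thresholds computed over that gene's
values pooled across all time points and replicates, so that a gene's level
has the same meaning in every slice.  A cell's level is the number of
thresholds strictly below its value (values equal to a threshold fall in the
lower bin).  Each replicate becomes one complete observation sequence, so a
matrix with R replicates and T time points yields ``N_seq = R`` sequences
and ``N = R * (T - 1)`` pooled transitions.
"""

from __future__ import annotations

import numpy as np

from .core import DiscretizationError, DiscreteDataset, ExpressionMatrix

METHODS = ("quantile", "interval")


def _thresholds(values: np.ndarray, n_levels: int, method: str, gene: str) -> np.ndarray:
    if method == "quantile":
        if np.unique(values).size < n_levels:
            raise DiscretizationError(
                f"gene {gene!r} has fewer than {n_levels} distinct values; "
                "use interval binning or fewer levels"
            )
        qs = np.arange(1, n_levels) / n_levels
        return np.quantile(values, qs)
    lo, hi = float(values.min()), float(values.max())
    return lo + (hi - lo) * np.arange(1, n_levels) / n_levels


def discretize(
    matrix: ExpressionMatrix,
    n_levels: int = 3,
    method: str = "quantile",
) -> DiscreteDataset:
    """Bin an expression matrix into per-gene discrete levels.

    Parameters
    ----------
    matrix
        Complete continuous expression data.
    n_levels
        Number of levels per gene (>= 2).  The default of 3 reads naturally
        as low / medium / high expression.
    method
        ``"quantile"`` places thresholds at equally spaced quantiles of the
        gene's pooled values (balanced bins); ``"interval"`` splits the
        gene's observed range into equal-width bins.
    """
    if n_levels < 2:
        raise DiscretizationError("n_levels must be >= 2")
    if method not in METHODS:
        raise DiscretizationError(f"unknown method {method!r}; expected one of {METHODS}")

    n_genes, n_times, n_reps = matrix.values.shape
    levels = np.empty_like(matrix.values, dtype=np.int64)
    for i, gene in enumerate(matrix.genes):
        pooled = matrix.values[i].reshape(-1)
        th = np.sort(_thresholds(pooled, n_levels, method, gene))
        # level = number of thresholds strictly below the value
        levels[i] = (matrix.values[i][..., None] > th).sum(axis=-1)

    sequences = [levels[:, :, r].T.copy() for r in range(n_reps)]
    return DiscreteDataset(
        genes=list(matrix.genes),
        arities=[n_levels] * n_genes,
        sequences=sequences,
    )
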