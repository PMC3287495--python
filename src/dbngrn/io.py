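"""File I/O for expression tables, networks, discrete datasets and orders.

Formats are plain tab-separated text:

* expression tables: header ``gene`` followed by ``t<i>_r<j>`` columns,
  one row per gene;
* networks: SIF lines ``regulator<TAB>relation<TAB>target`` or two-column
  edge lists;
* discrete datasets: same gene-by-column layout with integer levels and
  column headers ``s<l>_t<i>`` (sequence, slice), plus a small ``key=value``
  sidecar recording arities and sequence lengths.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    DiscreteDataset,
    ExpressionMatrix,
    GeneNetwork,
    ParseError,
)

log = logging.getLogger(__name__)

_HEADER_RE = re.compile(r"^t(\d+)_r(\d+)$")
_SEQ_HEADER_RE = re.compile(r"^s(\d+)_t(\d+)$")


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a gene x (time, replicate) expression table.

    The first column holds the gene identifier; every remaining column header
    must have the form ``t<time>_r<replicate>``.  The (time, replicate) grid
    must be complete and every cell numeric.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a gene column plus data columns")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    dup = pd.Series(genes)[pd.Series(genes).duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate gene id {dup.iloc[0]!r}")

    coords: list[tuple[int, int]] = []
    for col in df.columns[1:]:
        m = _HEADER_RE.match(col)
        if not m:
            raise ParseError(
                f"{path}: unparsable column header {col!r} (expected t<i>_r<j>)"
            )
        coords.append((int(m.group(1)), int(m.group(2))))
    times = sorted({t for t, _ in coords})
    reps = sorted({r for _, r in coords})
    expected = {(t, r) for t in times for r in reps}
    if set(coords) != expected or len(coords) != len(expected):
        raise ParseError(
            f"{path}: columns do not form a complete time x replicate grid"
        )
    if reps != list(range(len(reps))):
        raise ParseError(f"{path}: replicate indices must be 0..R-1, got {reps}")

    values = np.empty((len(genes), len(times), len(reps)), dtype=float)
    t_pos = {t: i for i, t in enumerate(times)}
    for col, (t, r) in zip(df.columns[1:], coords):
        try:
            parsed = df[col].to_numpy(dtype=str).astype(float)
        except ValueError:
            for row, cell in enumerate(df[col]):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric or missing cell for gene "
                        f"{genes[row]!r} in column {col!r} (value {cell!r})"
                    ) from None
            raise
        if np.isnan(parsed).any():
            row = int(np.nonzero(np.isnan(parsed))[0][0])
            raise ParseError(
                f"{path}: non-numeric or missing cell for gene {genes[row]!r} "
                f"in column {col!r} (value {df[col].iloc[row]!r})"
            )
        values[:, t_pos[t], r] = parsed
    return ExpressionMatrix(genes=genes, times=times, values=values)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression table; round-trips to full float precision."""
    path = Path(path)
    cols = [
        f"t{t}_r{r}" for t in matrix.times for r in range(matrix.n_replicates)
    ]
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for i, g in enumerate(matrix.genes):
            row = matrix.values[i].reshape(-1)  # times-major, replicates inner
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_network(
    path: str | Path,
    nodes: Iterable[str] | None = None,
    strict: bool = True,
) -> GeneNetwork:
    """Read a directed network from SIF or two-column edge-list text.

    SIF lines are ``regulator<TAB>relation<TAB>target``; two-column lines are
    ``regulator<TAB>target``.  Self-loop lines raise in strict mode and are
    dropped with a warning otherwise.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen_nodes: list[str] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 2:
            u, v = parts
        elif len(parts) == 3:
            u, _, v = parts
        else:
            raise ParseError(
                f"{path}:{ln}: expected 2 or 3 tab-separated fields, got {len(parts)}"
            )
        if not u or not v:
            raise ParseError(f"{path}:{ln}: empty gene identifier")
        for g in (u, v):
            if g not in seen_nodes:
                seen_nodes.append(g)
        if u == v:
            if strict:
                raise ParseError(f"{path}:{ln}: self-loop on {u!r}")
            log.warning("%s:%d: dropping self-loop on %r", path, ln, u)
            continue
        edges.append((u, v))
    all_nodes = list(nodes) if nodes is not None else seen_nodes
    return GeneNetwork(all_nodes, edges)


def write_network(
    network: GeneNetwork,
    path: str | Path,
    relation: str = "regulates",
    two_column: bool = False,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(network.edges):
            if two_column:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{relation}\t{v}\n")


def write_discrete_dataset(dataset: DiscreteDataset, path: str | Path) -> None:
    """Write integer levels as TSV plus a ``<path>.meta`` sidecar."""
    path = Path(path)
    cols: list[str] = []
    data: list[np.ndarray] = []
    for l, seq in enumerate(dataset.sequences):
        for t in range(seq.shape[0]):
            cols.append(f"s{l}_t{t}")
            data.append(seq[t])
    mat = np.stack(data, axis=1)  # genes x columns
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for i, g in enumerate(dataset.genes):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in mat[i]) + "\n")
    meta = Path(str(path) + ".meta")
    with meta.open("w") as fh:
        fh.write(
            "sequence_lengths="
            + ",".join(str(s.shape[0]) for s in dataset.sequences)
            + "\n"
        )
        for g, r in zip(dataset.genes, dataset.arities):
            fh.write(f"arity.{g}={r}\n")


def read_discrete_dataset(path: str | Path) -> DiscreteDataset:
    path = Path(path)
    meta_path = Path(str(path) + ".meta")
    if not meta_path.exists():
        raise ParseError(f"missing sidecar metadata file {meta_path}")
    lengths: list[int] = []
    arities: dict[str, int] = {}
    for ln, line in enumerate(meta_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        if key == "sequence_lengths":
            lengths = [int(x) for x in val.split(",")]
        elif key.startswith("arity."):
            arities[key[len("arity."):]] = int(val)
        else:
            raise ParseError(f"{meta_path}:{ln}: unknown key {key!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes = df[df.columns[0]].tolist()
    values = df[df.columns[1:]].to_numpy(dtype=np.int64)
    sequences = []
    offset = 0
    for T in lengths:
        sequences.append(values[:, offset:offset + T].T.copy())
        offset += T
    if offset != values.shape[1]:
        raise ParseError(f"{path}: column count does not match sequence lengths")
    return DiscreteDataset(
        genes=genes,
        arities=[arities[g] for g in genes],
        sequences=sequences,
    )


def read_order_file(path: str | Path) -> list[str]:
    """Read one gene identifier per line (a K2 node ordering)."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
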