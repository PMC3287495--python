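"""Synthetic gene regulatory networks and stochastic time-series expression.

A stand-in for external benchmark simulators: random directed regulatory
networks plus a discrete-time dynamical model that generates replicated
expression time courses with Gaussian noise.  Gene ``i`` with parents
``pa(i)`` evolves as

    x_i[t+1] = sigmoid(b_i + sum_{j in pa(i)} w_ij * x_j[t]) + eps,
    eps ~ Normal(0, noise_sd)

with weights drawn once per network from the configured strength range with
random signs (activation / repression) and biases centered so that a gene
responds around the middle of its parents' range.  Replicates are
independent stochastic runs differing only by noise and initial state
(drawn uniform in (0, 1)).  The process is first-order Markov and
stationary — exactly the assumptions of the learners — and fully
reproducible from the configuration seed.

Defaults produce the benchmark data shape used throughout the package:
21 time points and 10 replicates per network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import ExpressionMatrix, GeneNetwork, ValidationError
from .io import write_expression_table, write_network

# sub-stream tags so network topology, parameters and trajectories draw
# from independent generators derived from one seed
_STREAM_GRN = 101
_STREAM_PARAMS = 202
_STREAM_TRAJ = 303


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults give 21 time points x 10 replicates.

    ``avg_in_degree`` is the mean of the (truncated) in-degree
    distribution; ``strength_range`` bounds the absolute interaction
    weights, chosen strong enough that a top-strength edge is detectable
    after 3-level discretization at the default noise level.
    """

    n_genes: int = 10
    avg_in_degree: float = 1.5
    n_times: int = 21
    n_replicates: int = 10
    noise_sd: float = 0.05
    strength_range: tuple[float, float] = (2.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("need at least 2 genes")
        if self.n_times < 2:
            raise ValidationError("need at least 2 time points")
        if self.n_replicates < 1:
            raise ValidationError("need at least 1 replicate")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.strength_range
        if not (0 < lo <= hi):
            raise ValidationError("strength_range must satisfy 0 < lo <= hi")


def gene_names(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n)]


def random_grn(config: SimulationConfig) -> GeneNetwork:
    """Sample a random directed regulatory network.

    Each gene draws an in-degree from a Poisson distribution with the
    configured mean truncated to [0, 3], then picks that many distinct
    parents uniformly (no self-loops).  At least one regulator hub with
    out-degree >= 2 is guaranteed.  Deterministic given the seed.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GRN])
    names = gene_names(config.n_genes)
    lam = config.avg_in_degree
    ks = np.arange(4)
    pmf = np.exp(-lam) * lam**ks / np.array([1, 1, 2, 6])
    pmf = pmf / pmf.sum()
    edges: list[tuple[str, str]] = []
    for i, child in enumerate(names):
        k = int(rng.choice(ks, p=pmf))
        k = min(k, config.n_genes - 1)
        others = [g for g in names if g != child]
        parents = rng.choice(len(others), size=k, replace=False)
        edges.extend((others[j], child) for j in sorted(parents))
    net = GeneNetwork(names, edges)
    # guarantee a hub regulator (out-degree >= 2)
    hub = max(names, key=net.out_degree)
    targets = [g for g in names if g != hub and not net.has_edge(hub, g)]
    while net.out_degree(hub) < 2 and targets:
        j = int(rng.integers(len(targets)))
        net.add_edge(hub, targets.pop(j))
    net.meta["seed"] = config.seed
    return net


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def draw_parameters(
    grn: GeneNetwork, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the network's dynamical parameters ``(W, bias)``.

    ``W[i, j]`` is the signed weight of edge ``nodes[j] -> nodes[i]`` with
    magnitude uniform in ``strength_range`` and random sign (activation or
    repression); biases center each gene's response when its parents sit
    mid-range.  Deterministic given the config seed, and exactly the
    parameters :func:`simulate_timeseries` uses.
    """
    names = list(grn.nodes)
    idx = {g: i for i, g in enumerate(names)}
    rng_p = np.random.default_rng([config.seed, _STREAM_PARAMS])
    lo, hi = config.strength_range
    n = len(names)
    W = np.zeros((n, n))
    for u, v in sorted(grn.edges):
        sign = 1.0 if rng_p.random() < 0.5 else -1.0
        W[idx[v], idx[u]] = sign * rng_p.uniform(lo, hi)
    bias = rng_p.uniform(-0.5, 0.5, size=n) - 0.5 * W.sum(axis=1)
    return W, bias


def simulate_timeseries(grn: GeneNetwork, config: SimulationConfig) -> ExpressionMatrix:
    """Simulate replicated expression trajectories on a network.

    Weights and biases are drawn once per network; each replicate then runs
    the squashed-linear dynamics from its own uniform initial state with
    independent Gaussian noise.  Noise-free runs from a fixed initial state
    are fully deterministic.
    """
    names = list(grn.nodes)
    if len(names) != config.n_genes:
        raise ValidationError(
            f"network has {len(names)} genes but config declares {config.n_genes}"
        )
    W, bias = draw_parameters(grn, config)
    n = len(names)
    rng_t = np.random.default_rng([config.seed, _STREAM_TRAJ])
    values = np.empty((n, config.n_times, config.n_replicates))
    state = rng_t.uniform(0.0, 1.0, size=(n, config.n_replicates))
    values[:, 0, :] = state
    for t in range(1, config.n_times):
        state = _sigmoid(bias[:, None] + W @ state)
        if config.noise_sd > 0:
            state = state + rng_t.normal(0.0, config.noise_sd, size=state.shape)
        values[:, t, :] = state
    return ExpressionMatrix(genes=names, times=list(range(config.n_times)), values=values)


def chain_network(n_genes: int) -> GeneNetwork:
    """A linear regulatory cascade G000 -> G001 -> ... (useful ground truth)."""
    names = gene_names(n_genes)
    return GeneNetwork(names, list(zip(names, names[1:])))


@dataclass(frozen=True)
class BenchmarkCase:
    """One (truth network, simulated expression matrix) benchmark instance."""

    size: int
    seed: int
    config: SimulationConfig
    truth: GeneNetwork
    matrix: ExpressionMatrix
    directory: Path | None = None


def make_benchmark(
    sizes: list[int],
    seeds: list[int],
    outdir: str | Path | None = None,
    base_config: SimulationConfig | None = None,
) -> list[BenchmarkCase]:
    """One case per (size, seed); optionally written to a run directory.

    Each case directory holds ``expression.tsv`` and ``truth.sif``; a
    ``manifest.txt`` at the top level records every configuration as flat
    ``key=value`` lines, so a run can be regenerated byte-identically.
    """
    base = base_config or SimulationConfig()
    cases: list[BenchmarkCase] = []
    manifest: list[str] = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for size in sizes:
        for seed in seeds:
            config = replace(base, n_genes=size, seed=seed)
            truth = random_grn(config)
            matrix = simulate_timeseries(truth, config)
            case_dir = None
            if out is not None:
                case_dir = out / f"n{size}_s{seed}"
                case_dir.mkdir(exist_ok=True)
                write_expression_table(matrix, case_dir / "expression.tsv")
                write_network(truth, case_dir / "truth.sif")
            cases.append(
                BenchmarkCase(
                    size=size,
                    seed=seed,
                    config=config,
                    truth=truth,
                    matrix=matrix,
                    directory=case_dir,
                )
            )
            prefix = f"case.n{size}_s{seed}"
            manifest.append(f"{prefix}.n_genes={size}")
            manifest.append(f"{prefix}.seed={seed}")
            manifest.append(f"{prefix}.n_times={config.n_times}")
            manifest.append(f"{prefix}.n_replicates={config.n_replicates}")
            manifest.append(f"{prefix}.noise_sd={config.noise_sd}")
            manifest.append(f"{prefix}.avg_in_degree={config.avg_in_degree}")
            manifest.append(
                f"{prefix}.strength_range={config.strength_range[0]},{config.strength_range[1]}"
            )
    if out is not None:
        (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return cases
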