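"""Ground-truth time-varying sparse Gaussian graphical models.

The generator produces a precision-matrix trajectory ``Omega(t)`` on a
temporal grid in [0, 1] whose support evolves smoothly: a set of persistent
base edges plus edges whose partial-correlation weight follows a raised-cosine
bump over a sub-interval (zero outside, continuously rising and falling
inside). Positive definiteness is enforced by diagonal dominance so the
intended support is preserved exactly. Observations are i.i.d. draws from
``N_p(0, Omega(t_k)^{-1})`` at each grid point, emulating replicate samples
within an age group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Bump",
    "SmoothGraphTrajectory",
    "SimulatedDataset",
    "generate_graph_trajectory",
    "generate_regime_trajectory",
    "sample_dataset",
    "true_edge_sets",
    "write_dataset_tsv",
]

_SUPPORT_TOL = 1e-12


@dataclass(frozen=True)
class Bump:
    """Smooth bump profile of one edge over the interval [a, b].

    With ``ramp == 0.5 * (b - a)`` this is the classic raised cosine (zero at
    the endpoints, peak at the center). A smaller ``ramp`` yields a plateau:
    the weight rises along a half-cosine over ``[a, a + ramp]``, stays at the
    peak, and falls over ``[b - ramp, b]`` — still continuous in ``t``.
    """

    pair: tuple[int, int]
    a: float
    b: float
    peak: float  # signed peak magnitude
    ramp: float | None = None  # None -> raised cosine over the whole interval

    def weight(self, t: float) -> float:
        if t <= self.a or t >= self.b:
            return 0.0
        ramp = 0.5 * (self.b - self.a) if self.ramp is None else self.ramp
        edge_dist = min(t - self.a, self.b - t)
        if edge_dist >= ramp:
            return self.peak
        return self.peak * 0.5 * (1.0 - np.cos(np.pi * edge_dist / ramp))


@dataclass
class SmoothGraphTrajectory:
    """Time-indexed family of sparse, positive-definite precision matrices."""

    n_vars: int
    grid: np.ndarray
    base_pairs: list[tuple[int, int]]
    base_weights: list[float]
    bumps: list[Bump] = field(default_factory=list)

    def precision(self, t: float) -> np.ndarray:
        """The p x p precision matrix at time ``t`` (diagonally dominant)."""
        p = self.n_vars
        omega = np.zeros((p, p))
        for (u, v), w in zip(self.base_pairs, self.base_weights):
            omega[u, v] = omega[v, u] = w
        for bump in self.bumps:
            u, v = bump.pair
            w = bump.weight(t)
            omega[u, v] += w
            omega[v, u] += w
        np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + 1.0)
        return omega

    def support(self, t: float) -> frozenset[tuple[int, int]]:
        omega = self.precision(t)
        iu = np.triu_indices(self.n_vars, k=1)
        mask = np.abs(omega[iu]) > _SUPPORT_TOL
        return frozenset(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))

    @property
    def true_supports(self) -> list[frozenset[tuple[int, int]]]:
        return [self.support(t) for t in self.grid]


@dataclass
class SimulatedDataset:
    """Observations drawn from a :class:`SmoothGraphTrajectory`."""

    values: np.ndarray  # p x N
    times: np.ndarray  # length N, each equal to a grid coordinate
    group_labels: np.ndarray  # length N, grid-point index of each sample
    trajectory: SmoothGraphTrajectory
    seed: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _default_grid(n_grid: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_grid)


def _sample_pairs(p: int, n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    iu = np.triu_indices(p, k=1)
    all_pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    idx = rng.choice(len(all_pairs), size=n, replace=False)
    return [all_pairs[i] for i in sorted(idx.tolist())]


def generate_graph_trajectory(
    p: int,
    n_grid: int = 9,
    base_edges: int = 0,
    n_changing: int = 0,
    seed: int = 0,
    peak_range: tuple[float, float] = (0.2, 0.4),
) -> SmoothGraphTrajectory:
    """Generate a smooth trajectory with persistent and transient edges.

    ``base_edges`` edges carry a constant weight over the whole grid;
    ``n_changing`` edges follow raised-cosine bumps over random sub-intervals
    aligned to the grid, so each transient edge is active on one contiguous
    run of grid points. Peak magnitudes are drawn uniformly from
    ``peak_range`` with random sign; the diagonal is set to the row-wise
    absolute off-diagonal sum plus one, which guarantees positive
    definiteness without altering the support.
    """
    if p < 2:
        raise ValueError(f"need at least 2 variables, got p={p}")
    if n_grid < 2:
        raise ValueError(f"need at least 2 grid points, got n_grid={n_grid}")
    max_edges = p * (p - 1) // 2
    total = base_edges + n_changing
    if base_edges < 0 or n_changing < 0 or total > max_edges:
        raise ValueError(
            f"requested {base_edges}+{n_changing} edges; feasible range is "
            f"0..{max_edges} for p={p}"
        )
    rng = np.random.default_rng(seed)
    grid = _default_grid(n_grid)
    step = grid[1] - grid[0]
    pairs = _sample_pairs(p, total, rng)
    base_pairs = pairs[:base_edges]
    base_weights = [
        float(rng.uniform(*peak_range) * rng.choice([-1.0, 1.0])) for _ in base_pairs
    ]
    bumps = []
    for pair in pairs[base_edges:]:
        # active run of grid points [i0, i1]; interval extended half a step so
        # endpoints of the run still get positive weight
        i0 = int(rng.integers(0, n_grid - 1))
        i1 = int(rng.integers(i0 + 1, n_grid))
        peak = float(rng.uniform(*peak_range) * rng.choice([-1.0, 1.0]))
        bumps.append(Bump(pair, grid[i0] - 0.5 * step, grid[i1] + 0.5 * step, peak))
    return SmoothGraphTrajectory(p, grid, base_pairs, base_weights, bumps)


def generate_regime_trajectory(
    p: int,
    n_grid: int = 9,
    n_regimes: int = 3,
    edges_per_regime: int = 10,
    seed: int = 0,
    peak_range: tuple[float, float] = (0.25, 0.4),
) -> tuple[SmoothGraphTrajectory, np.ndarray]:
    """Trajectory with ``n_regimes`` planted stages of distinct topology.

    The grid is split into contiguous segments; each segment gets its own
    disjoint set of edges, at full strength on every grid point of the
    segment and ramping smoothly to zero inside the gaps between segments,
    so the topology is constant within a stage and disjoint across stages.
    Returns the trajectory and the planted per-grid-point stage labels.
    """
    if n_regimes < 2 or n_regimes > n_grid:
        raise ValueError("n_regimes must be between 2 and n_grid")
    rng = np.random.default_rng(seed)
    grid = _default_grid(n_grid)
    step = grid[1] - grid[0]
    pairs = _sample_pairs(p, n_regimes * edges_per_regime, rng)
    rng.shuffle(pairs)  # decouple pair ordering from regime assignment
    bounds = np.array_split(np.arange(n_grid), n_regimes)
    labels = np.empty(n_grid, dtype=int)
    bumps = []
    for r, seg in enumerate(bounds):
        labels[seg] = r
        seg_pairs = pairs[r * edges_per_regime : (r + 1) * edges_per_regime]
        # plateau covers the segment's grid points; ramps stay inside the gaps
        ramp = 0.5 * step
        a = grid[seg[0]] - 0.75 * step
        b = grid[seg[-1]] + 0.75 * step
        for pair in seg_pairs:
            peak = float(rng.uniform(*peak_range) * rng.choice([-1.0, 1.0]))
            bumps.append(Bump(tuple(pair), a, b, peak, ramp=ramp))
    traj = SmoothGraphTrajectory(p, grid, [], [], bumps)
    return traj, labels


def sample_dataset(
    traj: SmoothGraphTrajectory,
    replicates: Sequence[int],
    seed: int = 0,
) -> SimulatedDataset:
    """Draw i.i.d. ``N_p(0, Omega(t_k)^{-1})`` replicates at each grid point.

    Per-grid-point child RNGs are derived deterministically from the root
    seed, so the draws at grid point ``k`` do not depend on the replicate
    counts at other grid points.
    """
    replicates = list(replicates)
    if len(replicates) != len(traj.grid):
        raise ValueError(
            f"need one replicate count per grid point "
            f"({len(traj.grid)}), got {len(replicates)}"
        )
    if any(n < 0 for n in replicates):
        raise ValueError("replicate counts must be non-negative")
    blocks, times, labels = [], [], []
    for k, (t, n_k) in enumerate(zip(traj.grid, replicates)):
        if n_k == 0:
            continue
        omega = traj.precision(t)
        try:
            chol_prec = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"precision matrix at grid point {k} is not positive definite"
            ) from exc
        rng = np.random.default_rng([seed, k])
        z = rng.standard_normal((traj.n_vars, n_k))
        # x = L^{-T} z has covariance Omega^{-1} when Omega = L L^T
        x = np.linalg.solve(chol_prec.T, z)
        blocks.append(x)
        times.extend([t] * n_k)
        labels.extend([k] * n_k)
    if blocks:
        values = np.concatenate(blocks, axis=1)
    else:
        values = np.empty((traj.n_vars, 0))
    return SimulatedDataset(
        values=values,
        times=np.asarray(times, dtype=float),
        group_labels=np.asarray(labels, dtype=int),
        trajectory=traj,
        seed=seed,
    )


def true_edge_sets(traj: SmoothGraphTrajectory) -> list[frozenset[tuple[int, int]]]:
    """Ground-truth edge set at every grid point, for recovery metrics."""
    return traj.true_supports


def write_dataset_tsv(
    dataset: SimulatedDataset,
    out_dir: str | Path,
    gene_prefix: str = "G",
) -> tuple[Path, Path]:
    """Write expression + metadata TSVs in the format read by ``preprocess``.

    The expression file is genes x samples with a header of sample ids; the
    metadata file has columns ``sample_id``, ``time`` and ``group``.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p, n = dataset.values.shape
    genes = [f"{gene_prefix}{i:04d}" for i in range(p)]
    samples = [f"S{j:04d}" for j in range(n)]
    expr = pd.DataFrame(dataset.values, index=genes, columns=samples)
    expr.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "time": dataset.times,
            "group": [f"grid{g}" for g in dataset.group_labels],
        }
    )
    expr_path = out_dir / "expression.tsv"
    meta_path = out_dir / "metadata.tsv"
    expr.to_csv(expr_path, sep="\t")
    meta.to_csv(meta_path, sep="\t", index=False)
    return expr_path, meta_path
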