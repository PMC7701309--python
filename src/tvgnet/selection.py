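"""Tuning-parameter selection by K-fold cross-validation with consensus voting.

Grid points are assigned to folds by their index modulo K, which for nine
grid points and K=3 yields the validation sets {1,4,7}, {2,5,8}, {3,6,9}
(1-based). For a candidate (h, d, lambda) the model is fitted on the training
folds, the selected support is refit by constrained MLE, and the refit is
scored against the held-out kernel covariance::

    CV_j(t_k) = tr(Omega_rf^(−j) S_val^(j)(t_k)) − log det Omega_rf^(−j)

summed over folds. The lambda descent within a (h, d) cell stops early once
the fitted edge count exceeds ``early_stop_multiplier * p`` (default 8p).
After selection, cv.vote retains only edges present in at least a threshold
fraction (default 0.8) of the per-fold fitted models, reducing false
discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import KernelSpec, kernel_weights
from .core import (
    NeighborhoodIndex,
    fit_joint,
    fit_pseudo,
    refit_support,
    standardize_covariance,
    support_of,
)

__all__ = [
    "CVConfig",
    "CVResult",
    "early_stop_triggered",
    "make_cv_folds",
    "cv_score",
    "cv_vote",
    "validation_covariance",
    "grid_search",
]


@dataclass
class CVConfig:
    """Search grids and CV structure.

    The default grids span the comparator special cases (d=0 kernel, d=1
    invariant) and bandwidths around the 9-point grid spacing of 0.125.
    """

    n_folds: int = 3
    h_grid: tuple[float, ...] = (0.1, 0.15, 0.2, 0.3)
    d_grid: tuple[float, ...] = (0.0, 0.125, 0.25, 0.5, 1.0)
    lam_grid: tuple[float, ...] = tuple(
        float(x) for x in np.geomspace(0.05, 1.0, 15)
    )
    early_stop_multiplier: float = 8.0
    vote_threshold: float = 0.8
    kernel_family: str = "epanechnikov"
    mode: str = "exact"
    standardize: bool = True  # fit and score on the correlation scale

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("K-fold CV requires at least 2 folds")
        if not 0.0 < self.vote_threshold <= 1.0:
            raise ValueError("vote threshold must lie in (0, 1]")
        if self.early_stop_multiplier <= 0:
            raise ValueError("early-stop multiplier must be positive")


@dataclass
class CVResult:
    """Selected parameters, the searched score table and consensus supports."""

    h: float
    d: np.ndarray  # per grid point
    lam: np.ndarray  # per grid point
    table: pd.DataFrame
    fold_supports: list[list[frozenset[tuple[int, int]]]]  # [grid point][fold]
    consensus: list[frozenset[tuple[int, int]]]
    total_score: float


def early_stop_triggered(n_edges: int, p: int, multiplier: float = 8.0) -> bool:
    """The grid-search stop rule: halt the lambda descent once a fitted
    model's edge count exceeds ``multiplier * p`` (default 8p)."""
    return n_edges > multiplier * p


def make_cv_folds(n_grid: int, K: int) -> np.ndarray:
    """Fold id of each grid point: point j goes to fold j mod K."""
    if K < 2:
        raise ValueError("need at least 2 folds")
    if K > n_grid:
        raise ValueError(f"cannot make {K} folds from {n_grid} grid points")
    return np.arange(n_grid) % K


def cv_score(omega_refit: np.ndarray, sigma_val: np.ndarray) -> float:
    """Validation negative log-likelihood tr(Omega S) - log|Omega|."""
    sign, logdet = np.linalg.slogdet(omega_refit)
    if sign <= 0:
        raise ValueError("refit precision matrix is not positive definite")
    return float(np.trace(omega_refit @ sigma_val) - logdet)


def cv_vote(
    fold_supports: Sequence[frozenset[tuple[int, int]]],
    threshold: float = 0.8,
) -> frozenset[tuple[int, int]]:
    """Edges present in at least ``threshold`` of the per-fold models."""
    if not fold_supports:
        raise ValueError("need at least one fold support")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    n = len(fold_supports)
    counts: dict[tuple[int, int], int] = {}
    for s in fold_supports:
        for e in s:
            counts[e] = counts.get(e, 0) + 1
    return frozenset(e for e, c in counts.items() if c / n >= threshold - 1e-12)


def _masked_covariance(
    values: np.ndarray,
    times: np.ndarray,
    mask: np.ndarray,
    t: float,
    spec: KernelSpec,
) -> np.ndarray:
    """Kernel covariance from a sample subset, with nearest-sample fallback.

    With a compactly supported kernel a subset (training or validation fold)
    can have zero mass at some grid point; the deterministic fallback is a
    uniform average over the subset samples nearest in time.
    """
    sub_vals = values[:, mask]
    sub_times = times[mask]
    if sub_vals.shape[1] == 0:
        raise ValueError("no samples available for covariance estimation")
    try:
        w = kernel_weights(sub_times, t, spec)
    except ValueError:
        dist = np.abs(sub_times - t)
        nearest = dist <= dist.min() + 1e-12
        w = nearest / nearest.sum()
    xw = sub_vals * w
    s = xw @ sub_vals.T
    return 0.5 * (s + s.T)


def validation_covariance(
    values: np.ndarray,
    times: np.ndarray,
    grid: np.ndarray,
    fold_of_point: np.ndarray,
    fold: int,
    t: float,
    spec: KernelSpec,
) -> np.ndarray:
    """Covariance at ``t`` using only the held-out fold's samples."""
    sample_fold = fold_of_point[np.searchsorted(grid, times)]
    return _masked_covariance(values, times, sample_fold == fold, t, spec)


def grid_search(Xc, grid: np.ndarray, config: CVConfig) -> CVResult:
    """Search (h, d_k, lambda_k) by K-fold CV.

    h is shared across the grid (selected by the total score over all grid
    points); (d_k, lambda_k) are selected per grid point. Ties are broken
    toward sparser, smoother fits: larger lambda, then larger d, then larger
    h. Within each (h, d) cell, lambda is searched from largest to smallest
    and the descent stops once any fold's fitted edge count exceeds
    ``early_stop_multiplier * p``.
    """
    values = np.asarray(Xc.values, dtype=float)
    times = np.asarray(Xc.times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n_grid = len(grid)
    p = values.shape[0]
    if not (config.h_grid and config.d_grid and config.lam_grid):
        raise ValueError("all parameter grids must be non-empty")
    folds = make_cv_folds(n_grid, config.n_folds)
    sample_fold = folds[np.searchsorted(grid, times)]
    max_edges = config.early_stop_multiplier * p
    lam_desc = sorted(config.lam_grid, reverse=True)
    rows = []
    best_per_h: dict[float, dict] = {}

    for h in config.h_grid:
        spec = KernelSpec(config.kernel_family, h)
        # per-fold training covariances over the whole grid; validation at each point
        train_covs = {}
        val_covs = {}
        for j in range(config.n_folds):
            train_mask = sample_fold != j
            val_mask = sample_fold == j
            train_covs[j] = [
                _masked_covariance(values, times, train_mask, float(t), spec)
                for t in grid
            ]
            val_covs[j] = [
                _masked_covariance(values, times, val_mask, float(t), spec)
                for t in grid
            ]
            if config.standardize:
                train_covs[j] = [standardize_covariance(s)[0] for s in train_covs[j]]
                val_covs[j] = [standardize_covariance(s)[0] for s in val_covs[j]]
        sel = {
            "d": np.empty(n_grid),
            "lam": np.empty(n_grid),
            "score": np.empty(n_grid),
            "fold_supports": [None] * n_grid,
        }
        for k in range(n_grid):
            best = None  # (score, lam, d, fold_supports)
            any_scored = False
            for d in config.d_grid:
                nbhd = NeighborhoodIndex.build(grid, k, float(d))
                for lam in lam_desc:
                    fold_sup = []
                    scores = []
                    stop = False
                    for j in range(config.n_folds):
                        sub = [train_covs[j][i] for i in nbhd.members]
                        if config.mode == "pseudo":
                            support, omega_rf = fit_pseudo(
                                sub, nbhd.center_pos, float(lam)
                            )
                        else:
                            fitted = fit_joint(sub, float(lam))
                            support = support_of(fitted[nbhd.center_pos])
                            omega_rf = refit_support(train_covs[j][k], support)
                        fold_sup.append(support)
                        scores.append(cv_score(omega_rf, val_covs[j][k]))
                        if early_stop_triggered(len(support), p, config.early_stop_multiplier):
                            stop = True
                    total = float(sum(scores))
                    rows.append(
                        {
                            "h": h,
                            "grid_point": k,
                            "d": d,
                            "lambda": lam,
                            "score": total,
                            "edges": max(len(s) for s in fold_sup),
                            "stopped_early": stop,
                        }
                    )
                    if not stop:
                        any_scored = True
                        cand = (total, -lam, -d)
                        if best is None or cand < best[0]:
                            best = (cand, lam, d, fold_sup, total)
                    if stop:
                        break  # skip denser lambda values in this (h, d) cell
            if not any_scored or best is None:
                raise ValueError(
                    f"every candidate at grid point {k} exceeded "
                    f"{max_edges:.0f} edges; extend the lambda grid upward"
                )
            sel["d"][k] = best[2]
            sel["lam"][k] = best[1]
            sel["score"][k] = best[4]
            sel["fold_supports"][k] = best[3]
        best_per_h[h] = sel

    # shared h minimizing the total score over grid points; ties toward larger h
    totals = {h: float(best_per_h[h]["score"].sum()) for h in config.h_grid}
    h_star = min(config.h_grid, key=lambda h: (totals[h], -h))
    sel = best_per_h[h_star]
    consensus = [
        cv_vote(sel["fold_supports"][k], config.vote_threshold) for k in range(n_grid)
    ]
    return CVResult(
        h=float(h_star),
        d=sel["d"].copy(),
        lam=sel["lam"].copy(),
        table=pd.DataFrame(rows),
        fold_supports=list(sel["fold_supports"]),
        consensus=consensus,
        total_score=totals[h_star],
    )
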