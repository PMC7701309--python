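"""Expression-matrix I/O, feature selection, age grouping and centering.

Samples carry an age on one numeric axis: prenatal ages are stored as
negative years, ``-(40 - gestational_weeks) / 52``, postnatal ages as years.
The nine developmental groups (fetus through 60s) map to nine equally spaced
grid coordinates on [0, 1], and observations are centered by subtracting the
kernel-estimated mean at each sample's own time so downstream covariance
smoothing sees zero-mean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import KernelSpec, kernel_weights

__all__ = [
    "ExpressionMatrix",
    "AgeGroupScheme",
    "DEFAULT_SCHEME",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "select_top_variance_genes",
    "subset_by_gene_list",
    "gestational_weeks_to_age",
    "assign_age_groups",
    "map_groups_to_grid",
    "center_expressions",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample time annotations."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # p x N
    times: np.ndarray | None = None  # per-sample coordinate in [0, 1]
    group_labels: list[str] | None = None
    ages: np.ndarray | None = None  # raw ages (negative = prenatal), if known

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, n = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match value rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match value columns")
        if len(set(self.gene_ids)) != p:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (n,):
                raise ValueError("times length does not match sample count")
            if np.any((self.times < 0) | (self.times > 1)):
                raise ValueError("sample times must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def take_genes(self, index: Sequence[int]) -> "ExpressionMatrix":
        index = list(index)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            values=self.values[index, :],
            times=None if self.times is None else self.times.copy(),
            group_labels=None if self.group_labels is None else list(self.group_labels),
            ages=None if self.ages is None else self.ages.copy(),
        )


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered age groups with half-open intervals on the numeric age axis."""

    names: tuple[str, ...]
    lower: tuple[float, ...]  # inclusive
    upper: tuple[float, ...]  # exclusive (last bin inclusive at its upper end)

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("scheme fields must have equal length")
        for i in range(len(self.names) - 1):
            if self.upper[i] != self.lower[i + 1]:
                raise ValueError("intervals must tile the age axis in order")

    @property
    def n_groups(self) -> int:
        return len(self.names)


# Fetus covers 14-20 gestational weeks encoded as negative years; the verbal
# bins leave 6 months..1 year unnamed, so the child bin starts at 0.5 y to
# keep the intervals a partition.
DEFAULT_SCHEME = AgeGroupScheme(
    names=("fetus", "infant", "child", "10s", "20s", "30s", "40s", "50s", "60s"),
    lower=(-0.5, 0.0, 0.5, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    upper=(0.0, 0.5, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 120.0),
)


def gestational_weeks_to_age(weeks: float) -> float:
    """Encode a prenatal age (gestational weeks) as negative years."""
    return -(40.0 - weeks) / 52.0


def read_expression_matrix(
    matrix_path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample metadata TSV.

    The metadata must contain ``sample_id`` and either ``time`` (coordinate
    in [0,1]) or ``age`` (numeric age, grouped later); an optional ``group``
    column is carried through. Samples are reordered to the matrix columns;
    any column missing from the metadata is a hard error.
    """
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {matrix_path}: {dupes[:5]}")
    non_numeric = expr.columns[
        [not np.issubdtype(dt, np.number) for dt in expr.dtypes]
    ].tolist()
    if non_numeric:
        raise ValueError(
            f"non-numeric expression values in columns {non_numeric[:5]} "
            f"of {matrix_path}"
        )
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata {metadata_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    meta = meta.loc[list(expr.columns)]
    times = meta["time"].to_numpy(dtype=float) if "time" in meta.columns else None
    groups = meta["group"].astype(str).tolist() if "group" in meta.columns else None
    return ExpressionMatrix(
        gene_ids=[str(g) for g in expr.index],
        sample_ids=[str(s) for s in expr.columns],
        values=expr.to_numpy(dtype=float),
        times=times,
        group_labels=groups,
        ages=meta["age"].to_numpy(dtype=float) if "age" in meta.columns else None,
    )


def write_expression_matrix(
    X: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame({"sample_id": X.sample_ids})
    if X.times is not None:
        meta["time"] = X.times
    if X.group_labels is not None:
        meta["group"] = X.group_labels
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; '#' starts a comment."""
    out = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out


def select_top_variance_genes(X: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """The ``k`` genes of largest sample variance, in their original order.

    Ties at the k-th rank are broken by gene-id lexicographic order so the
    selection is deterministic.
    """
    if not 1 <= k <= X.n_genes:
        raise ValueError(f"k must be in [1, {X.n_genes}], got {k}")
    variances = X.values.var(axis=1, ddof=1) if X.n_samples > 1 else np.zeros(X.n_genes)
    order = sorted(range(X.n_genes), key=lambda i: (-variances[i], X.gene_ids[i]))
    selected = sorted(order[:k])  # preserve input gene order among selected
    return X.take_genes(selected)


def subset_by_gene_list(
    X: ExpressionMatrix, gene_list: Sequence[str]
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Genes present in both the matrix and the list (pathway subsetting).

    Returns the subset matrix and a mapping report with the list size
    (duplicates counted once), the number mapped and the number unmapped.
    """
    wanted = list(dict.fromkeys(gene_list))  # dedupe, keep order
    if not wanted:
        raise ValueError("gene list is empty")
    present = set(X.gene_ids)
    mapped = [g for g in wanted if g in present]
    if not mapped:
        raise ValueError("no genes from the list are present in the matrix")
    mapped_set = set(mapped)
    index = [i for i, g in enumerate(X.gene_ids) if g in mapped_set]
    report = {
        "list_size": len(wanted),
        "mapped": len(mapped),
        "unmapped": len(wanted) - len(mapped),
    }
    return X.take_genes(index), report


def assign_age_groups(
    ages: Sequence[float], scheme: AgeGroupScheme = DEFAULT_SCHEME
) -> list[str]:
    """Assign each sample age to exactly one group of the scheme."""
    ages = np.asarray(ages, dtype=float)
    labels = []
    for j, a in enumerate(ages):
        hit = None
        for name, lo, hi in zip(scheme.names, scheme.lower, scheme.upper):
            last = name == scheme.names[-1]
            if lo <= a < hi or (last and a == hi):
                hit = name
                break
        if hit is None:
            raise ValueError(
                f"sample {j} has age {a} outside all intervals "
                f"[{scheme.lower[0]}, {scheme.upper[-1]}]"
            )
        labels.append(hit)
    return labels


def map_groups_to_grid(
    group_labels: Sequence[str], scheme: AgeGroupScheme = DEFAULT_SCHEME
) -> tuple[np.ndarray, np.ndarray]:
    """Map group j of G to coordinate (j-1)/(G-1); returns (times, grid)."""
    n_groups = scheme.n_groups
    grid = np.linspace(0.0, 1.0, n_groups)
    pos = {name: grid[i] for i, name in enumerate(scheme.names)}
    unknown = sorted({g for g in group_labels if g not in pos})
    if unknown:
        raise ValueError(f"labels not in scheme: {unknown}")
    times = np.array([pos[g] for g in group_labels])
    return times, grid


def center_expressions(
    X: ExpressionMatrix,
    spec: KernelSpec,
) -> ExpressionMatrix:
    """Subtract the kernel-estimated mean at each sample's own time.

    Uses the same weights as the covariance smoother, so each centered
    observation is (approximately) a draw from a zero-mean Gaussian. With a
    compactly supported kernel whose bandwidth is below the grid spacing the
    kernel-weighted mean of the centered data vanishes exactly at every grid
    point; wider bandwidths leave residual means of the order of the trend
    curvature over the bandwidth.
    """
    if X.times is None:
        raise ValueError("expression matrix has no sample times")
    values = X.values.copy()
    for t in np.unique(X.times):
        w = kernel_weights(X.times, float(t), spec)
        mu = X.values @ w
        values[:, X.times == t] -= mu[:, None]
    return ExpressionMatrix(
        gene_ids=list(X.gene_ids),
        sample_ids=list(X.sample_ids),
        values=values,
        times=X.times.copy(),
        group_labels=None if X.group_labels is None else list(X.group_labels),
        ages=None if X.ages is None else X.ages.copy(),
    )
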