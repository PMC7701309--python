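"""End-to-end, seeded, logged pipeline: data -> CV -> fit -> networks.

One declarative YAML config drives the run. Exactly one of the ``input``
(expression + metadata paths) or ``simulation`` blocks must be present.
Stages: preprocessing (feature selection, age grouping, grid mapping,
kernel centering), cross-validated parameter selection, series fitting,
cv.vote consensus with constrained-MLE refit, and network analysis. All
artifacts (edge lists, GraphML, similarity matrix, CV table, summary,
run metadata) are written under the output directory; identical config and
seed produce identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import networks as na
from .core import covariance_series, fit_series, refit_support, support_of
from .kernels import KernelSpec
from .preprocess import (
    DEFAULT_SCHEME,
    ExpressionMatrix,
    assign_age_groups,
    center_expressions,
    map_groups_to_grid,
    read_expression_matrix,
    read_gene_list,
    select_top_variance_genes,
    subset_by_gene_list,
)
from .selection import CVConfig, grid_search
from .synthetic import generate_graph_trajectory, sample_dataset

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "ConfigError"]

logger = logging.getLogger("tvgnet")

# The prior-knowledge three-stage partition of the nine age groups:
# fast development | deceleration to stationary | recession.
PRIOR_STAGES = (0, 0, 0, 1, 1, 1, 2, 2, 2)

_KNOWN_TOP = {
    "seed", "out_dir", "input", "simulation", "kernel", "cv", "fixed",
    "method", "mode", "analysis",
}


class ConfigError(ValueError):
    """Raised with every structural problem found in a config, at once."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  - " + "\n  - ".join(errors))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "tvgnet_run"
    input: dict | None = None
    simulation: dict | None = None
    kernel: dict = field(default_factory=lambda: {"family": "epanechnikov", "h": 0.2})
    cv: dict = field(default_factory=dict)
    fixed: dict | None = None  # {"d": ..., "lambda": ...} skips CV
    method: str = "loggle"
    mode: str = "exact"
    analysis: dict = field(
        default_factory=lambda: {
            "hub_k": 3,
            "n_stages": 3,
            "edge_tol": 1e-6,
            "stage_partition": "both",
        }
    )


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config, reporting all errors together."""
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"unreadable YAML: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    for key in raw:
        if key not in _KNOWN_TOP:
            errors.append(f"unknown key: {key!r}")
    has_input = bool(raw.get("input"))
    has_sim = bool(raw.get("simulation"))
    if has_input == has_sim:
        errors.append("exactly one of 'input' and 'simulation' must be present")
    if has_input:
        for k in ("expression", "metadata"):
            if k not in raw["input"]:
                errors.append(f"input block missing {k!r}")
            elif not Path(raw["input"][k]).exists():
                errors.append(f"input file does not exist: {raw['input'][k]}")
        gl = raw["input"].get("gene_list")
        if gl and not Path(gl).exists():
            errors.append(f"gene list does not exist: {gl}")
        k = raw["input"].get("top_variance_k")
        if k is not None and (not isinstance(k, int) or k < 1):
            errors.append("input.top_variance_k must be a positive integer")
        if gl and k:
            errors.append("choose one of top_variance_k and gene_list, not both")
    if has_sim:
        sim = raw["simulation"]
        if not isinstance(sim.get("p", 2), int) or sim.get("p", 2) < 2:
            errors.append("simulation.p must be an integer >= 2")
    if raw.get("method", "loggle") not in ("loggle", "kernel", "invar"):
        errors.append("method must be one of loggle, kernel, invar")
    if raw.get("mode", "exact") not in ("exact", "pseudo"):
        errors.append("mode must be 'exact' or 'pseudo'")
    cv = raw.get("cv", {})
    if isinstance(cv, dict):
        if cv.get("n_folds", 3) == 1:
            errors.append("cv.n_folds=1 is not a valid cross-validation")
        thr = cv.get("vote_threshold", 0.8)
        if not 0.0 < thr <= 1.0:
            errors.append("cv.vote_threshold must lie in (0, 1]")
    else:
        errors.append("cv block must be a mapping")
    if errors:
        raise ConfigError(errors)
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key == "analysis":
            cfg.analysis.update(val)
        elif key == "kernel":
            cfg.kernel.update(val)
        else:
            setattr(cfg, key, val)
    return cfg


def _setup_logging(out_dir: Path, verbose: bool = False) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handlers = [logging.FileHandler(out_dir / "run.log", mode="w")]
    if verbose:
        handlers.append(logging.StreamHandler())
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def _prepare_data(cfg: PipelineConfig) -> tuple[ExpressionMatrix, np.ndarray, list[str]]:
    """Load or simulate expression data; returns (matrix, grid, grid labels)."""
    if cfg.simulation is not None:
        sim = dict(cfg.simulation)
        p = sim.get("p", 20)
        n_grid = sim.get("n_grid", 9)
        reps = sim.get("replicates", 30)
        if isinstance(reps, int):
            reps = [reps] * n_grid
        traj = generate_graph_trajectory(
            p=p,
            n_grid=n_grid,
            base_edges=sim.get("base_edges", p),
            n_changing=sim.get("n_changing", p // 2),
            seed=sim.get("seed", cfg.seed),
        )
        ds = sample_dataset(traj, reps, seed=sim.get("seed", cfg.seed))
        genes = [f"G{i:04d}" for i in range(p)]
        samples = [f"S{j:04d}" for j in range(ds.n_samples)]
        labels = [f"grid{k}" for k in range(n_grid)]
        X = ExpressionMatrix(
            gene_ids=genes,
            sample_ids=samples,
            values=ds.values,
            times=ds.times,
            group_labels=[labels[g] for g in ds.group_labels],
        )
        logger.info("simulated dataset: p=%d, N=%d, %d grid points", p, ds.n_samples, n_grid)
        return X, traj.grid, labels
    inp = cfg.input
    X = read_expression_matrix(inp["expression"], inp["metadata"])
    if X.ages is not None and X.times is None:
        groups = assign_age_groups(X.ages, DEFAULT_SCHEME)
        X.group_labels = groups
        X.times, grid = map_groups_to_grid(groups, DEFAULT_SCHEME)
        labels = list(DEFAULT_SCHEME.names)
    elif X.times is not None:
        grid = np.unique(X.times)
        labels = (
            list(dict.fromkeys(X.group_labels))
            if X.group_labels
            else [f"t{j}" for j in range(len(grid))]
        )
    else:
        raise ValueError("metadata must provide either 'age' or 'time'")
    if inp.get("top_variance_k"):
        X = select_top_variance_genes(X, inp["top_variance_k"])
        logger.info("top-variance selection kept %d genes", X.n_genes)
    elif inp.get("gene_list"):
        gene_list = read_gene_list(inp["gene_list"])
        X, report = subset_by_gene_list(X, gene_list)
        logger.info(
            "gene-list subsetting: %(mapped)d mapped, %(unmapped)d unmapped", report
        )
    return X, np.asarray(grid, dtype=float), labels


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Nested-text (newick) rendering of a scipy linkage matrix."""
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for i, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + i] = f"({nodes[a]}:{la:.4f},{nodes[b]}:{lb:.4f})"
        heights[n + i] = h
    return nodes[n + len(z) - 1] + ";"


def run_pipeline(cfg: PipelineConfig, verbose: bool = False) -> dict[str, Any]:
    """Execute the full analysis and write artifacts to ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    _setup_logging(out_dir, verbose)
    stage = "preprocess"
    try:
        X, grid, grid_labels = _prepare_data(cfg)
        spec = KernelSpec(cfg.kernel.get("family", "epanechnikov"), cfg.kernel.get("h", 0.2))
        Xc = center_expressions(X, spec)
        logger.info("centered %d genes x %d samples", Xc.n_genes, Xc.n_samples)

        stage = "model selection"
        if cfg.fixed is not None:
            h = cfg.kernel.get("h", 0.2)
            d_sel = cfg.fixed.get("d", 0.125)
            lam_sel = cfg.fixed["lambda"]
            cv_result = None
            logger.info("fixed parameters: h=%s d=%s lambda=%s", h, d_sel, lam_sel)
        else:
            cv_cfg = CVConfig(mode=cfg.mode, **cfg.cv)
            if cfg.method == "kernel":
                cv_cfg.d_grid = (0.0,)
            elif cfg.method == "invar":
                cv_cfg.d_grid = (1.0,)
            cv_result = grid_search(Xc, grid, cv_cfg)
            h, d_sel, lam_sel = cv_result.h, cv_result.d, cv_result.lam
            if cfg.method == "invar":
                lam_sel = np.full(len(grid), float(np.median(lam_sel)))
            spec = KernelSpec(cfg.kernel.get("family", "epanechnikov"), h)
            cv_result.table.to_csv(out_dir / "cv_table.tsv", sep="\t", index=False)
            logger.info(
                "CV selected h=%.3g, d=%s, lambda=%s", h,
                np.asarray(d_sel).tolist(), np.round(np.asarray(lam_sel), 4).tolist(),
            )

        stage = "fitting"
        series = fit_series(
            Xc, grid, spec, d=d_sel, lam=lam_sel, method=cfg.method, mode=cfg.mode
        )
        covs = covariance_series(Xc, grid, spec)
        if cv_result is not None:
            # cv.vote consensus, then constrained-MLE refit on the full data
            tol = cfg.analysis.get("edge_tol", 1e-6)
            voted = cv_result.consensus
            matrices = [
                refit_support(covs.matrices[k], voted[k]) for k in range(len(grid))
            ]
            series.matrices = matrices
            series.supports = [support_of(m, tol) for m in matrices]
            logger.info("cv.vote consensus applied at threshold %.2f",
                        cfg.cv.get("vote_threshold", 0.8))

        stage = "network analysis"
        tol = cfg.analysis.get("edge_tol", 1e-6)
        graphs = [
            na.network_from_precision(m, X.gene_ids, tol) for m in series.matrices
        ]
        net_series = na.NetworkSeries(list(grid_labels), graphs, list(X.gene_ids))
        props = pd.DataFrame([na.global_properties(g) for g in graphs])
        props.insert(0, "group", grid_labels)
        excl = na.exclusive_edges(net_series)
        props["exclusive_edges"] = [len(e) for e in excl]
        sim = na.similarity_matrix(net_series)
        n_stages = cfg.analysis.get("n_stages", 3)
        z, stage_labels = na.cluster_networks(sim, n_stages)
        hub_k = cfg.analysis.get("hub_k", 3)
        hubs = {lab: na.identify_hubs(g, hub_k) for lab, g in zip(grid_labels, graphs)}

        stage = "writing artifacts"
        _write_artifacts(
            out_dir, cfg, X, grid, grid_labels, series, props, sim, z,
            stage_labels, hubs, cv_result,
        )
        result = {
            "properties": props,
            "similarity": sim,
            "stages": stage_labels,
            "hubs": hubs,
            "series": series,
            "networks": net_series,
            "cv": cv_result,
            "selected": {"h": float(spec.h), "d": np.asarray(d_sel).tolist()
                         if not np.isscalar(d_sel) else d_sel,
                         "lambda": np.asarray(lam_sel).tolist()
                         if not np.isscalar(lam_sel) else lam_sel},
        }
        logger.info("pipeline complete: %d networks", len(graphs))
        return result
    except Exception:
        logger.exception("pipeline failed during stage: %s", stage)
        raise RuntimeError(f"pipeline failed during stage: {stage}") from None


def _write_artifacts(
    out_dir, cfg, X, grid, grid_labels, series, props, sim, z,
    stage_labels, hubs, cv_result,
) -> None:
    edges_dir = out_dir / "edges"
    edges_dir.mkdir(parents=True, exist_ok=True)
    for k, (label, mat) in enumerate(zip(grid_labels, series.matrices)):
        rows = [
            {
                "time": grid[k],
                "gene_u": X.gene_ids[u],
                "gene_v": X.gene_ids[v],
                "precision_value": mat[u, v],
            }
            for (u, v) in sorted(series.supports[k])
        ]
        pd.DataFrame(
            rows, columns=["time", "gene_u", "gene_v", "precision_value"]
        ).to_csv(edges_dir / f"network_{k}_{label}.tsv", sep="\t", index=False)
        g = na.network_from_precision(mat, X.gene_ids, cfg.analysis.get("edge_tol", 1e-6))
        nx.write_graphml(g, edges_dir / f"network_{k}_{label}.graphml")
    pd.DataFrame(sim, index=grid_labels, columns=grid_labels).to_csv(
        out_dir / "similarity.tsv", sep="\t"
    )
    (out_dir / "dendrogram.nwk").write_text(
        _linkage_to_newick(z, list(grid_labels)) + "\n"
    )
    props_out = props.copy()
    props_out["stage_cluster"] = stage_labels
    partition_mode = cfg.analysis.get("stage_partition", "both")
    if partition_mode in ("prior", "both") and len(grid_labels) == len(PRIOR_STAGES):
        props_out["stage_prior"] = PRIOR_STAGES
    props_out.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    md = ["# Network development summary", "", "```", props_out.to_string(index=False), "```", ""]
    md.append("## Hub genes (by degree)")
    for label, hub in hubs.items():
        md.append(f"- {label}: {', '.join(hub) if hub else '(none)'}")
    (out_dir / "summary.md").write_text("\n".join(md) + "\n")
    meta = {
        "seed": cfg.seed,
        "method": cfg.method,
        "mode": cfg.mode,
        "kernel": cfg.kernel,
        "selected": {
            "h": float(cv_result.h) if cv_result else cfg.kernel.get("h"),
            "d": np.asarray(cv_result.d).tolist() if cv_result else cfg.fixed.get("d"),
            "lambda": np.asarray(cv_result.lam).tolist()
            if cv_result
            else cfg.fixed.get("lambda"),
        },
        "analysis": cfg.analysis,
    }
    (out_dir / "run_meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
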