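"""End-to-end orchestration: the full metacell -> network pipeline and the
simulation studies (bias sweep, type-I error, library-size stabilization,
planted-module recovery) that validate the method on synthetic data."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream
from .bias_eval import empirical_type1_error, evaluate_null_bias
from .coexpression import build_network, detect_modules, module_eigengenes
from .data_io import (
    CellExpressionMatrix,
    attach_annotations,
    filter_genes_by_detection,
    library_sizes,
    log_normalize,
    read_annotations,
    read_count_matrix,
    write_count_matrix,
)
from .metacell import (
    build_metacells,
    build_metacells_by_group,
    build_metacells_primary,
    library_size_cv,
    metacells_to_expression,
)
from .similarity import cell_similarity
from .simulate import (
    NullSimulationConfig,
    make_fixture,
    make_planted_module_model,
    simulate_copula,
    simulate_null,
)

logger = logging.getLogger("lsmetacell")


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    counts_path: str
    out_prefix: str
    format: str = "mtx"
    orientation: str = "genes_by_cells"
    annotations_path: Optional[str] = None
    celltype_col: Optional[str] = "cell_type"
    group_col: Optional[str] = "group"
    n_metacells: int = 50
    seed: int = 0
    scale_factor: float = 10_000.0
    min_detection_fraction: float = 0.10
    min_module_size: int = 30
    cut_height: float = 0.99
    powers: Sequence[int] = tuple(range(1, 21))
    r2_target: float = 0.8
    pooled: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineStageError(RuntimeError):
    """An error wrapped with the name of the failing pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Read counts, build metacells per cell type (and per group when group
    labels exist), run the co-expression network per cell type, and write
    assignments, metacell counts, module labels, eigengenes and a JSON
    report; returns the manifest (also written as ``<prefix>.manifest.json``).
    """
    out_prefix = Path(cfg.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    X = _stage("read_counts")(read_count_matrix)(
        cfg.counts_path, format=cfg.format, orientation=cfg.orientation
    )
    if cfg.annotations_path is not None:
        annot = _stage("read_annotations")(read_annotations)(cfg.annotations_path)
        X = _stage("attach_annotations")(attach_annotations)(
            X, annot, cell_type_col=cfg.celltype_col, group_col=cfg.group_col
        )

    if cfg.pooled or X.cell_type is None:
        celltype_sets = {"all": X}
    else:
        labels = X.cell_type.astype(str).to_numpy()
        celltype_sets = {
            ct: X.subset_cells(labels == ct) for ct in sorted(set(labels))
        }

    assignments = []
    module_rows = []
    eigengene_frames = []
    artifacts: list[str] = []
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_metacells_requested": cfg.n_metacells,
        "cell_types": {},
    }

    for ct, Xct in celltype_sets.items():
        ct_seed = int(substream(cfg.seed, f"celltype:{ct}").integers(0, 2**31 - 1))
        Xf = _stage("filter_genes")(filter_genes_by_detection)(
            Xct, cfg.min_detection_fraction
        )
        if not cfg.pooled and Xf.group is not None and Xf.group.nunique() > 1:
            groups = Xf.split_by_group()
            sims = {
                g: _stage("similarity")(cell_similarity)(
                    log_normalize(Xg, cfg.scale_factor)
                )
                for g, Xg in groups.items()
            }
            result = _stage("build_metacells")(build_metacells_by_group)(
                groups, cfg.n_metacells, sims, seed=ct_seed
            )
        else:
            N = _stage("normalize")(log_normalize)(Xf, cfg.scale_factor)
            P = _stage("similarity")(cell_similarity)(N)
            result = _stage("build_metacells")(build_metacells)(
                Xf, cfg.n_metacells, P, seed=ct_seed, id_prefix=f"{ct}:mc"
            )
        for cell, mc in result.assignment.items():
            assignments.append({"cell_id": cell, "metacell_id": mc, "cell_type": ct})

        Xmc = metacells_to_expression(result)
        counts_path = (
            f"{out_prefix}.counts.mtx"
            if len(celltype_sets) == 1
            else f"{out_prefix}.{ct}.counts.mtx"
        )
        Path(counts_path).parent.mkdir(parents=True, exist_ok=True)
        write_count_matrix(Xmc, counts_path, format="mtx")
        artifacts.append(counts_path)

        Nmc = _stage("normalize_metacells")(log_normalize)(Xmc, cfg.scale_factor)
        net = _stage("network")(build_network)(
            Nmc, powers=cfg.powers, r2_target=cfg.r2_target
        )
        modules = _stage("detect_modules")(detect_modules)(
            net.tom, net.gene_ids, cfg.min_module_size, cfg.cut_height
        )
        if modules.module_names:
            modules = _stage("eigengenes")(module_eigengenes)(Nmc, modules)
            eig = modules.eigengenes.copy()
            eig.columns = [f"{ct}:{m}" for m in eig.columns]
            eigengene_frames.append(eig)
        for gene, mod in modules.labels.items():
            row = {"cell_type": ct, "gene_id": gene, "module": mod}
            if modules.kme is not None and mod in modules.kme.columns:
                row["kME"] = float(modules.kme.loc[gene, mod])
            module_rows.append(row)

        report["cell_types"][ct] = {
            "n_cells": Xct.n_cells,
            "n_genes_after_filter": Xf.n_genes,
            "n_metacells": result.n_metacells,
            "target_mu_L": result.target_mu_L,
            "library_size_cv": (
                library_size_cv(result.metacell_library_sizes)
                if result.n_metacells >= 2
                else None
            ),
            "soft_power": int(net.power),
            "modules": {
                m: int((modules.labels == m).sum()) for m in modules.module_names
            },
        }

    assign_path = f"{out_prefix}.assignments.tsv"
    pd.DataFrame(assignments).sort_values("cell_id").to_csv(
        assign_path, sep="\t", index=False
    )
    artifacts.append(assign_path)

    modules_path = f"{out_prefix}.modules.tsv"
    pd.DataFrame(module_rows).to_csv(modules_path, sep="\t", index=False)
    artifacts.append(modules_path)

    eigengenes_path = f"{out_prefix}.eigengenes.tsv"
    if eigengene_frames:
        pd.concat(eigengene_frames, axis=1).to_csv(eigengenes_path, sep="\t")
    else:
        pd.DataFrame().to_csv(eigengenes_path, sep="\t")
    artifacts.append(eigengenes_path)

    report_path = f"{out_prefix}.report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    artifacts.append(report_path)

    manifest = {
        "artifacts": artifacts,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
    }
    with open(f"{out_prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ------------------------------------------------------------- studies


def default_null_base(
    seed: int = 0, n_cells: int = 2000, n_genes: int = 300
) -> CellExpressionMatrix:
    """The base fixture feeding the null resampler: droplet-like counts
    with log-normal library sizes (sigma 0.8, roughly ten-fold spread)."""
    return make_fixture(
        n_cells=n_cells,
        n_genes=n_genes,
        mean_library_size=2000.0,
        sigma_log=0.8,
        seed=seed,
    )


def run_bias_study(
    vsf_list: Sequence[float],
    seeds: Sequence[int] = (0, 1, 2),
    n_cells: int = 2000,
    n_genes: int = 300,
    alpha: float = 0.05,
    n_pairs: int = 1000,
    base_seed: int = 12345,
) -> pd.DataFrame:
    """Sweep the variance size factor over null data: one row per
    (vsf, seed) with the library-size scale factor, the mean absolute
    correlation bias against truth zero, and the empirical type-I error of
    the Pearson independence test."""
    if len(vsf_list) == 0:
        raise ValueError("vsf_list must be non-empty")
    base = default_null_base(seed=base_seed, n_cells=n_cells, n_genes=n_genes)
    rows = []
    for f in vsf_list:
        for seed in seeds:
            cfg = NullSimulationConfig(variance_size_factor=f, seed=int(seed))
            null = simulate_null(base, cfg)
            rep = evaluate_null_bias(null, variance_size_factor=f)
            t1 = empirical_type1_error(null, alpha=alpha, n_pairs=n_pairs, seed=seed)
            rows.append(
                {
                    "vsf": float(f),
                    "seed": int(seed),
                    "scale_factor": rep.scale_factor,
                    "mean_abs_bias": rep.mean_abs_bias,
                    "type1_rate": t1,
                }
            )
    return pd.DataFrame(rows)


def stabilization_study(
    seeds: Sequence[int] = tuple(range(20)),
    n_cells: int = 500,
    n_metacells: int = 25,
    sigma_log: float = 0.8,
    n_genes: int = 100,
) -> pd.DataFrame:
    """Library-size CV of single cells vs the primary (count-capped) and
    stabilized aggregations, one row per seed."""
    rows = []
    for seed in seeds:
        X = make_fixture(
            n_cells=n_cells,
            n_genes=n_genes,
            mean_library_size=2000.0,
            sigma_log=sigma_log,
            seed=int(seed),
        )
        N = log_normalize(X)
        P = cell_similarity(N)
        ls = build_metacells(X, n_metacells, P, seed=int(seed))
        prim = build_metacells_primary(X, n_metacells, P, seed=int(seed))
        rows.append(
            {
                "seed": int(seed),
                "cv_single": library_size_cv(library_sizes(X)),
                "cv_primary": library_size_cv(prim.metacell_library_sizes),
                "cv_lsmetacell": library_size_cv(ls.metacell_library_sizes),
            }
        )
    return pd.DataFrame(rows)


def module_recovery_study(
    seed: int = 0,
    n_cells: int = 600,
    n_metacells: int = 50,
    n_blocks: int = 3,
    block_size: int = 40,
    rho_within: float = 0.6,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> dict:
    """Planted-block recovery: copula counts with block-structured latent
    correlation -> stabilized metacells -> network -> modules; returns the
    adjusted Rand index against the planted labels plus run details."""
    from sklearn.metrics import adjusted_rand_score

    model, planted = make_planted_module_model(
        n_blocks=n_blocks,
        block_size=block_size,
        rho_within=rho_within,
        size_mean=30.0,
        size_cv=0.5,
        seed=int(seed),
    )
    X, _theta = simulate_copula(model, n_cells)
    s = library_sizes(X)
    if (s == 0).any():
        X = X.subset_cells(s > 0)
    N = log_normalize(X)
    P = cell_similarity(N)
    result = build_metacells(X, n_metacells, P, seed=int(seed))
    Xmc = metacells_to_expression(result)
    Nmc = log_normalize(Xmc)
    net = build_network(Nmc)
    modules = detect_modules(
        net.tom, net.gene_ids, min_module_size=min_module_size, cut_height=cut_height
    )
    found = modules.labels.to_numpy()
    ari = float(adjusted_rand_score(planted, found))
    return {
        "ari": ari,
        "power": int(net.power),
        "n_metacells": result.n_metacells,
        "modules": modules,
        "planted": planted,
        "metacell_normalized": Nmc,
        "network": net,
    }
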