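"""End-to-end analysis driver: one seed, one directory of outputs.

`run_full_pipeline` chains every stage of the single-bud analysis on an
expression table: detection filtering, rescaling to the highest stage
median, per-gene stage contrasts against the reference stage,
transition-stage distribution diagnostics (upper-fence outliers and dip
tests), PCA and hierarchical clustering, the transition-stage network
with and without outliers, the balanced-subsampling correlation matrix,
and the in-silico pooling study.  All randomness descends from the single
configured seed, so a rerun with the same inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import write_expression_table, write_tsv
from .multivariate import cluster_heatmap, pca, standardize_genes
from .quant import filter_undetected_genes, rescale_to_max_stage_median
from .resample import (ResamplingConfig, balanced_correlation_matrix,
                       flag_stage_outliers, pooled_correlation_network,
                       pooled_stage_tests, s3_network)
from .stats import dip_null_table, dip_test, mann_whitney_u
from .table import ExpressionTable

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full pipeline run."""

    seed: int = 0
    reference_stage: str = "S1"
    transition_stage: str = "S3"
    alpha: float = 0.001
    min_detected_fraction: float = 0.5
    outlier_k: float = 3.0
    pca_center: str = "median"
    dip_n_mc: int = 1000
    n_clusters: int | None = None
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(n)]


def run_full_pipeline(
    table: ExpressionTable, out_dir: str | Path, cfg: PipelineConfig
) -> Path:
    """Run every analysis stage and write all outputs plus a manifest.

    Any stage failure aborts with the stage name; a partial manifest
    recording the stages completed so far is still written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    (dip_seed, bal_seed, pool_test_seed, pool_net_seed,
     pool_net_out_seed) = _derived_seeds(seed, 5)
    manifest: dict = {
        "tool": "singlebud",
        "version": __version__,
        "seed": seed,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg))),
        "input": {"n_buds": len(table.bud_ids), "n_genes": len(table.genes)},
        "stages_completed": [],
        "timings_s": {},
        "warnings": [],
    }
    stage_name = "setup"
    t_stage = time.perf_counter()

    def done(name: str) -> None:
        nonlocal stage_name, t_stage
        manifest["stages_completed"].append(name)
        manifest["timings_s"][name] = round(time.perf_counter() - t_stage, 3)
        t_stage = time.perf_counter()

    try:
        # -- filter + rescale ------------------------------------------------
        stage_name = "filter"
        filtered, dropped = filter_undetected_genes(
            table, cfg.min_detected_fraction)
        write_tsv(pd.DataFrame({"dropped_gene": dropped}),
                  out / "dropped_genes.tsv", seed=seed, index=False)
        done("filter")

        stage_name = "rescale"
        rescaled = rescale_to_max_stage_median(filtered)
        write_expression_table(rescaled, out / "expression_rescaled.tsv",
                               seed=seed)
        done("rescale")

        # -- per-gene stage contrasts ---------------------------------------
        stage_name = "stage_tests"
        ref = cfg.reference_stage
        rows = []
        for gene in rescaled.genes:
            x_ref = rescaled.gene_values(gene, ref).dropna().to_numpy()
            for st in rescaled.stage_names:
                if st == ref:
                    continue
                x = rescaled.gene_values(gene, st).dropna().to_numpy()
                res = mann_whitney_u(x, x_ref)
                rows.append((gene, f"{st}_vs_{ref}", res.statistic,
                             res.p_value, res.method_detail,
                             res.p_value < cfg.alpha))
        write_tsv(pd.DataFrame(rows, columns=[
            "gene", "comparison", "U", "p_value", "method", "significant"]),
            out / "stage_tests.tsv", seed=seed, index=False)
        done("stage_tests")

        # -- transition-stage distribution diagnostics -----------------------
        stage_name = "distributions"
        s3 = cfg.transition_stage
        flags = flag_stage_outliers(rescaled, stage=s3, k=cfg.outlier_k)
        flag_rows = [(g, b, float(rescaled.values.at[b, g]))
                     for g, buds in flags.items() for b in buds]
        write_tsv(pd.DataFrame(flag_rows,
                               columns=["gene", "bud_id", "value"]),
                  out / "s3_outliers.tsv", seed=seed, index=False)

        n_s3 = len(rescaled.stage_buds(s3))
        null_tab = dip_null_table(n_s3, cfg.dip_n_mc,
                                  np.random.default_rng(dip_seed))
        dip_rows = []
        for gene in rescaled.genes:
            x = rescaled.gene_values(gene, s3).dropna().to_numpy()
            res = (dip_test(x, null_dips=null_tab) if x.size == n_s3
                   else dip_test(x, n_mc=cfg.dip_n_mc, rng=dip_seed))
            dip_rows.append((gene, res.statistic, res.p_value, x.size))
        write_tsv(pd.DataFrame(dip_rows, columns=["gene", "dip", "p_value", "n"]),
                  out / "s3_dip_tests.tsv", seed=seed, index=False)
        done("distributions")

        # -- multivariate ----------------------------------------------------
        stage_name = "pca"
        std = standardize_genes(rescaled, center=cfg.pca_center)
        pca_res = pca(std, center=cfg.pca_center)
        write_tsv(pca_res.scores, out / "pca_scores.tsv", seed=seed)
        write_tsv(pca_res.loadings, out / "pca_loadings.tsv", seed=seed)
        write_tsv(pca_res.variance_fraction.rename("variance_fraction")
                  .to_frame(), out / "pca_variance.tsv", seed=seed)
        done("pca")

        stage_name = "clustering"
        rep = cluster_heatmap(rescaled, n_clusters=cfg.n_clusters)
        write_tsv(rep.composition, out / "cluster_composition.tsv", seed=seed)
        write_tsv(rep.flat_clusters.to_frame(),
                  out / "cluster_assignments.tsv", seed=seed)
        (out / "cluster_tree.txt").write_text(rep.tree_text() + "\n")
        done("clustering")

        # -- transition-stage networks ---------------------------------------
        stage_name = "s3_network"
        for tag, rm in (("", False), ("_no_outliers", True)):
            edges = s3_network(rescaled, alpha=cfg.alpha, remove_outliers=rm,
                               k=cfg.outlier_k, stage=s3)
            write_tsv(edges.edges, out / f"s3_edges{tag}.tsv", seed=seed,
                      index=False)
        done("s3_network")

        # -- balanced subsampling over all stages ----------------------------
        stage_name = "balanced_matrix"
        bal_cfg = dataclasses.replace(cfg.resampling, seed=bal_seed,
                                      subsampled_stage=s3)
        bal = balanced_correlation_matrix(rescaled, bal_cfg)
        write_tsv(bal.mean_rho, out / "balanced_mean_rho.tsv", seed=seed)
        write_tsv(bal.sig_fraction_observed,
                  out / "balanced_sig_fraction.tsv", seed=seed)
        write_tsv(bal.edge_list().edges, out / "balanced_edges.tsv",
                  seed=seed, index=False)
        done("balanced_matrix")

        # -- in-silico pooling -----------------------------------------------
        stage_name = "pooled_stage_tests"
        pt_cfg = dataclasses.replace(cfg.resampling, seed=pool_test_seed)
        others = tuple(st for st in rescaled.stage_names if st != s3)
        ptests = pooled_stage_tests(rescaled, pt_cfg, stage=s3,
                                    other_stages=others)
        write_tsv(ptests, out / "pooled_stage_tests.tsv", seed=seed,
                  index=False)
        done("pooled_stage_tests")

        stage_name = "pooled_network"
        for tag, rm, s in (("", False, pool_net_seed),
                           ("_no_outliers", True, pool_net_out_seed)):
            pn_cfg = dataclasses.replace(cfg.resampling, seed=s)
            edges, summary = pooled_correlation_network(
                rescaled, pn_cfg, remove_outliers=rm, k=cfg.outlier_k, stage=s3)
            write_tsv(edges.edges, out / f"pooled_edges{tag}.tsv", seed=seed,
                      index=False)
            write_tsv(summary.mean_rho, out / f"pooled_mean_rho{tag}.tsv",
                      seed=seed)
            write_tsv(summary.sig_fraction_observed,
                      out / f"pooled_sig_fraction{tag}.tsv", seed=seed)
        done("pooled_network")
    except Exception as exc:
        manifest["failed_stage"] = stage_name
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage_name!r} failed") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
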