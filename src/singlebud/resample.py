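"""Resampling-stabilized co-expression analysis and in-silico bud pooling.

Three related procedures deal with the severe stage imbalance of the
study design (one stage holds ~7x more buds than the others) and with the
question of what a conventional pooled-RNA experiment would have seen:

* **Balanced subsampling** — correlations over all stages are computed on
  replicates that draw a fixed small number of transition-stage buds (so
  that stage cannot dominate), all other stages entering whole.  A gene
  pair is called significant only when its per-replicate p-value beats
  ``alpha`` in more than ``sig_fraction`` of replicates (the ">80% rule").
* **Transition-stage network** — Spearman correlations among genes over
  the transition-stage buds alone, optionally after removing extreme-high
  buds by the upper Tukey fence (pairwise deletion per gene).
* **In-silico pooling** — artificial multi-bud samples are built by
  averaging the expression of ``pool_size`` randomly drawn transition
  buds; stage tests and correlation networks are then repeated over many
  such simulated pooled experiments with the same >80% aggregation rule.

Every operation is a pure function of its inputs and the configured seed:
replicate r draws from the r-th spawned child of the seed sequence, so
enlarging ``n_reps`` never perturbs earlier replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .stats import (_spearman_p_from_rho, spearman_matrix,
                    tukey_upper_outliers)
from .table import ExpressionTable

logger = logging.getLogger("singlebud")

__all__ = [
    "ResamplingConfig",
    "CorrelationSummary",
    "EdgeList",
    "balanced_correlation_matrix",
    "s3_network",
    "simulate_pooled_s3",
    "pooled_stage_tests",
    "pooled_correlation_network",
    "flag_stage_outliers",
]


@dataclass(frozen=True)
class ResamplingConfig:
    """Knobs of the resampling procedures, with the study's defaults.

    ``n_sub_s3`` transition buds enter each balanced replicate (matching
    the size of the other stages); each artificial pooled sample averages
    ``pool_size`` buds and each simulated experiment holds
    ``n_artificial`` of them (matching the single-bud sample size); the
    whole simulation runs ``n_reps`` times.  A pair or contrast is called
    significant when its per-replicate p-value is below ``alpha`` in
    strictly more than ``sig_fraction`` of replicates.
    """

    n_sub_s3: int = 10
    pool_size: int = 5
    n_artificial: int = 71
    n_reps: int = 1000
    alpha: float = 0.001
    sig_fraction: float = 0.8
    seed: int = 0
    subsampled_stage: str = "S3"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.sig_fraction <= 1.0:
            raise ValueError("sig_fraction must be in (0, 1]")
        for name in ("n_sub_s3", "pool_size", "n_artificial", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def replicate_rngs(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(self.n_reps)
        return [np.random.default_rng(c) for c in children]


@dataclass
class CorrelationSummary:
    """Replicate-aggregated all-pairs correlation evidence.

    ``mean_rho`` averages the Spearman rho over replicates;
    ``sig_fraction_observed`` is the per-pair fraction of replicates with
    p < alpha; ``significant`` applies the strict >threshold rule.  The
    diagonal holds rho 1 but is never flagged significant.
    """

    genes: list[str]
    mean_rho: pd.DataFrame
    sig_fraction_observed: pd.DataFrame
    significant: pd.DataFrame
    n_reps_used: int

    def edge_list(self, **metadata) -> "EdgeList":
        """Significant pairs as an edge list carrying the mean rho."""
        rows = []
        for i, ga in enumerate(self.genes):
            for gb in self.genes[i + 1:]:
                if bool(self.significant.at[ga, gb]):
                    rho = float(self.mean_rho.at[ga, gb])
                    rows.append((ga, gb, rho,
                                 "positive" if rho >= 0 else "negative"))
        return EdgeList(_edge_frame(rows), **metadata)


def _edge_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "sign"])


@dataclass
class EdgeList:
    """Significant gene-pair network in tabular form.

    Negative-correlation edges are retained with ``sign='negative'``; a
    positive-only view (the form usually drawn as a network diagram) is
    available via :meth:`positive_only`.
    """

    edges: pd.DataFrame
    outliers_removed: bool = False
    pooled: bool = False

    def __post_init__(self) -> None:
        pairs = list(map(frozenset, zip(self.edges["gene_a"], self.edges["gene_b"])))
        if any(len(p) != 2 for p in pairs):
            raise ValueError("self-edges are not allowed")
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate unordered gene pairs")

    def pair_set(self) -> frozenset:
        return frozenset(map(frozenset,
                             zip(self.edges["gene_a"], self.edges["gene_b"])))

    def positive_only(self) -> "EdgeList":
        keep = self.edges[self.edges["sign"] == "positive"].reset_index(drop=True)
        return EdgeList(keep, self.outliers_removed, self.pooled)

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# balanced subsampling over all stages
# ---------------------------------------------------------------------------

def _require_complete(values: pd.DataFrame) -> None:
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(
            f"missing values in genes {bad}; filter undetected genes first")


def balanced_correlation_matrix(
    table: ExpressionTable, cfg: ResamplingConfig
) -> CorrelationSummary:
    """All-stage Spearman matrix stabilized by balanced subsampling.

    Each replicate draws ``cfg.n_sub_s3`` buds (without replacement) from
    the over-represented stage and joins them with every bud of the other
    stages; rho and p are computed for all gene pairs and aggregated
    across replicates.
    """
    _require_complete(table.values)
    stage = cfg.subsampled_stage
    if stage not in set(table.stages):
        raise ValueError(f"stage {stage!r} missing from the table")
    s3_ids = table.stage_buds(stage)
    if len(s3_ids) < cfg.n_sub_s3:
        raise ValueError(
            f"{stage} holds {len(s3_ids)} buds < n_sub_s3={cfg.n_sub_s3}")
    other_ids = [b for b in table.bud_ids if table.stages[b] != stage]
    if not other_ids:
        raise ValueError("no buds outside the subsampled stage")

    genes = table.genes
    g = len(genes)
    rho_sum = np.zeros((g, g))
    sig_count = np.zeros((g, g))
    vals = table.values
    for rng in cfg.replicate_rngs():
        chosen = rng.choice(len(s3_ids), size=cfg.n_sub_s3, replace=False)
        rows = other_ids + [s3_ids[i] for i in chosen]
        rho, p = spearman_matrix(vals.loc[rows].to_numpy())
        rho_sum += rho
        sig_count += p < cfg.alpha
    mean_rho = rho_sum / cfg.n_reps
    np.fill_diagonal(mean_rho, 1.0)
    sig_frac = sig_count / cfg.n_reps
    significant = sig_frac > cfg.sig_fraction
    np.fill_diagonal(significant, False)

    def frame(arr):
        return pd.DataFrame(arr, index=genes, columns=genes)

    return CorrelationSummary(genes=list(genes), mean_rho=frame(mean_rho),
                              sig_fraction_observed=frame(sig_frac),
                              significant=frame(significant),
                              n_reps_used=cfg.n_reps)


# ---------------------------------------------------------------------------
# transition-stage network with optional fence-based outlier removal
# ---------------------------------------------------------------------------

def flag_stage_outliers(
    table: ExpressionTable, stage: str = "S3", k: float = 3.0,
    anchor: Literal["q3", "median"] = "q3",
) -> dict[str, list[str]]:
    """Upper-fence outlier buds per gene within one stage."""
    out: dict[str, list[str]] = {}
    buds = table.stage_buds(stage)
    for gene in table.genes:
        x = table.values.loc[buds, gene].dropna()
        rule = tukey_upper_outliers(x.to_numpy(), k=k, anchor=anchor)
        out[gene] = [x.index[i] for i in rule.flagged]
    return out


def s3_network(
    table: ExpressionTable,
    alpha: float = 0.001,
    remove_outliers: bool = False,
    k: float = 3.0,
    stage: str = "S3",
    listwise: bool = False,
    anchor: Literal["q3", "median"] = "q3",
) -> EdgeList:
    """Single-bud co-expression network within the transition stage.

    Spearman correlation over the stage's buds for every gene pair; edges
    where p < alpha.  With ``remove_outliers``, buds flagged by the upper
    Tukey fence for a gene are excluded from every pair involving that
    gene (pairwise deletion; ``listwise=True`` instead drops a flagged
    bud from all pairs).
    """
    buds = table.stage_buds(stage)
    if len(buds) < 4:
        raise ValueError(f"stage {stage!r} needs >= 4 buds")
    vals = table.values.loc[buds]
    _require_complete(vals)
    genes = table.genes

    drop: dict[str, set[str]] = {gene: set() for gene in genes}
    if remove_outliers:
        flags = flag_stage_outliers(table, stage=stage, k=k, anchor=anchor)
        if listwise:
            union = set().union(*flags.values())
            for gene in genes:
                drop[gene] = set(union)
        else:
            drop = {gene: set(f) for gene, f in flags.items()}

    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            keep = [b for b in buds if b not in drop[ga] and b not in drop[gb]]
            if len(keep) < 4:
                logger.warning("pair (%s, %s): only %d buds after outlier "
                               "removal; skipped", ga, gb, len(keep))
                continue
            x = vals.loc[keep, ga].to_numpy()
            y = vals.loc[keep, gb].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("pair (%s, %s): constant values; skipped", ga, gb)
                continue
            from .stats import spearman  # local import keeps module load light
            res = spearman(x, y)
            if res.p_value < alpha:
                rows.append((ga, gb, res.statistic,
                             "positive" if res.statistic >= 0 else "negative"))
    return EdgeList(_edge_frame(rows), outliers_removed=remove_outliers,
                    pooled=False)


# ---------------------------------------------------------------------------
# in-silico multi-bud pooling
# ---------------------------------------------------------------------------

def simulate_pooled_s3(
    table: ExpressionTable,
    cfg: ResamplingConfig,
    rng: np.random.Generator | int | None = None,
    stage: str = "S3",
) -> ExpressionTable:
    """One simulated pooled-RNA experiment on the transition stage.

    Each of ``cfg.n_artificial`` artificial samples is the per-gene mean
    of ``cfg.pool_size`` transition buds drawn without replacement within
    the pool; pools are drawn independently of each other and may
    overlap.  Cells removed upstream (NaN) are skipped by the pool mean.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    buds = table.stage_buds(stage)
    if cfg.pool_size > len(buds):
        raise ValueError(
            f"pool_size={cfg.pool_size} exceeds the {len(buds)} buds of {stage}")
    vals = table.values.loc[buds].to_numpy()
    n = len(buds)
    pooled = np.empty((cfg.n_artificial, vals.shape[1]))
    for j in range(cfg.n_artificial):
        members = rng.choice(n, size=cfg.pool_size, replace=False)
        pooled[j] = np.nanmean(vals[members], axis=0)
    ids = [f"pool_{j + 1:03d}" for j in range(cfg.n_artificial)]
    values = pd.DataFrame(pooled, index=ids, columns=table.genes)
    stages = pd.Series(f"{stage}-pooled", index=ids, name="stage")
    return ExpressionTable(values, stages, rescaled=table.rescaled)


def pooled_stage_tests(
    table: ExpressionTable,
    cfg: ResamplingConfig,
    stage: str = "S3",
    other_stages: tuple[str, ...] = ("S1", "S2", "S4"),
) -> pd.DataFrame:
    """Stage contrasts of simulated pooled samples vs single buds.

    For each repetition an artificial pooled transition-stage table is
    built and every gene is compared (Mann-Whitney, two-sided, normal
    approximation with tie correction) against the single buds of each
    other stage.  Returns a per-(gene, comparison) frame with the
    fraction of repetitions reaching p < alpha and the >sig_fraction
    significance call.
    """
    from scipy.stats import mannwhitneyu

    _require_complete(table.values)
    for s in (stage, *other_stages):
        if s not in set(table.stages):
            raise ValueError(f"stage {s!r} missing from the table")
    genes = table.genes
    buds = table.stage_buds(stage)
    vals = table.values.loc[buds].to_numpy()
    n = len(buds)

    # batch all repetitions' pooled tables into one array
    pooled = np.empty((cfg.n_reps, cfg.n_artificial, len(genes)))
    for r, rng in enumerate(cfg.replicate_rngs()):
        for j in range(cfg.n_artificial):
            members = rng.choice(n, size=cfg.pool_size, replace=False)
            pooled[r, j] = np.nanmean(vals[members], axis=0)

    rows = []
    for gi, gene in enumerate(genes):
        for other in other_stages:
            y = table.values.loc[table.stage_buds(other), gene].to_numpy()
            res = mannwhitneyu(pooled[:, :, gi], y[None, :],
                               alternative="two-sided", method="asymptotic",
                               use_continuity=True, axis=1)
            frac = float(np.mean(res.pvalue < cfg.alpha))
            rows.append((gene, f"{stage}-pooled_vs_{other}", frac,
                         frac > cfg.sig_fraction))
    return pd.DataFrame(rows, columns=["gene", "comparison",
                                       "sig_fraction_observed", "significant"])


def pooled_correlation_network(
    table: ExpressionTable,
    cfg: ResamplingConfig,
    remove_outliers: bool = False,
    k: float = 3.0,
    stage: str = "S3",
    anchor: Literal["q3", "median"] = "q3",
) -> tuple[EdgeList, CorrelationSummary]:
    """Co-expression network of simulated pooled transition samples.

    Per repetition, Spearman correlations are computed among genes over
    the ``cfg.n_artificial`` pooled samples; evidence is aggregated with
    the mean rho and the >sig_fraction rule.  Outlier removal, when
    requested, is applied to the single-bud table before pooling (flagged
    cells become missing and drop out of their pools' means).
    """
    _require_complete(table.values)
    work = table
    if remove_outliers:
        flags = flag_stage_outliers(table, stage=stage, k=k, anchor=anchor)
        vals = table.values.copy()
        for gene, buds in flags.items():
            vals.loc[buds, gene] = np.nan
        work = table.with_values(vals)

    genes = table.genes
    g = len(genes)
    rho_sum = np.zeros((g, g))
    sig_count = np.zeros((g, g))
    for rng in cfg.replicate_rngs():
        art = simulate_pooled_s3(work, cfg, rng=rng, stage=stage)
        rho, p = spearman_matrix(art.values.to_numpy())
        rho_sum += rho
        sig_count += p < cfg.alpha
    mean_rho = rho_sum / cfg.n_reps
    np.fill_diagonal(mean_rho, 1.0)
    sig_frac = sig_count / cfg.n_reps
    significant = sig_frac > cfg.sig_fraction
    np.fill_diagonal(significant, False)

    def frame(arr):
        return pd.DataFrame(arr, index=genes, columns=genes)

    summary = CorrelationSummary(genes=list(genes), mean_rho=frame(mean_rho),
                                 sig_fraction_observed=frame(sig_frac),
                                 significant=frame(significant),
                                 n_reps_used=cfg.n_reps)
    edges = summary.edge_list(outliers_removed=remove_outliers, pooled=True)
    return edges, summary
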