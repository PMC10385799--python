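"""Synthetic single-bud expression datasets with known ground truth.

The generator emulates the statistical structure of a single-bud RT-qPCR
study of dormancy progression: four sampling stages with very unequal bud
counts (the transition stage is deliberately over-sampled), a dozen genes
organized in two co-expression modules (a dormancy-high module and a
release-high module) plus idiosyncratic genes, log-normal biological
noise, rare extreme-high outlier buds, and optionally a two-component
mixture within the transition stage as a positive control for bimodality
screening.

Correlation within a module arises from a single shared latent factor per
module per bud: on the log scale

    y[bud, gene] = stage_mean + sqrt(rho) * s * Z[module, bud]
                   + sqrt(1 - rho) * s * eps[bud, gene]

so every within-module gene pair has Pearson correlation ``rho`` on the
log scale (marginal log-sd ``s`` for every gene), and between-module
pairs are independent.  Expression is ``exp(y)`` with optional
multiplicative outlier spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .table import DEFAULT_STAGES, ExpressionTable

__all__ = [
    "GeneSpec",
    "SyntheticDesign",
    "GroundTruth",
    "study_design",
    "null_design",
    "generate_expression",
    "generate_bimodal_s3",
    "generate_cq",
]


@dataclass(frozen=True)
class GeneSpec:
    """One simulated amplicon: its module membership and stage profile.

    ``stage_means`` are natural-log relative-expression means per stage.
    ``detectable=False`` emulates an amplicon below the detection
    threshold: its measurements are emitted as missing.
    """

    name: str
    module: str | None
    stage_means: Mapping[str, float]
    detectable: bool = True


@dataclass(frozen=True)
class SyntheticDesign:
    """Full parameterization of a simulated single-bud experiment."""

    genes: tuple[GeneSpec, ...]
    stage_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"S1": 10, "S2": 10, "S3": 71, "S4": 10})
    module_rho: Mapping[str, float] = field(
        default_factory=lambda: {"dormancy": 0.75, "release": 0.75})
    log_sd: float = 0.6
    outlier_rate: float = 0.01
    outlier_factor: float = 20.0
    bimodal_s3: tuple[float, float] | None = None  # (mixing fraction, separation / log_sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.stage_sizes.values()):
            raise ValueError("every stage needs at least one bud")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        for mod, rho in self.module_rho.items():
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"module {mod!r}: correlation must be in [0, 1)")
        for g in self.genes:
            if g.detectable:
                missing = set(self.stage_sizes) - set(g.stage_means)
                if missing:
                    raise ValueError(
                        f"gene {g.name!r} lacks stage means for {sorted(missing)}")
            if g.module is not None and g.module not in self.module_rho:
                raise ValueError(f"gene {g.name!r}: unknown module {g.module!r}")
        if self.bimodal_s3 is not None:
            frac, sep = self.bimodal_s3
            if not 0.0 < frac < 1.0:
                raise ValueError("mixing fraction must be in (0, 1)")
            if sep < 0:
                raise ValueError("mode separation must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and downstream analyses try to recover."""

    module_of: Mapping[str, str | None]
    true_edges: frozenset[frozenset]       # within-module detectable pairs
    spiked: tuple[tuple[str, str], ...]    # (bud_id, gene) outlier cells
    s3_component: Mapping[str, int] | None  # bud -> mixture component


# -- design presets ----------------------------------------------------------

#: Qualitative stage profiles (natural-log means) tracing the field's
#: canonical dormancy expression shapes: the dormancy-high module falls
#: from dormant to released stages, the release module peaks after
#: dormancy release, LOX-like carries a secondary early-dormant peak, the
#: FT-like gene peaks in late dormancy.  Illustrative presets, not
#: measured values.
_PROFILES = {
    "dormancy_high": {"S1": 0.0, "S2": -0.2, "S3": -1.5, "S4": -2.5},
    "dormancy_tor": {"S1": 0.0, "S2": -0.5, "S3": -1.2, "S4": -0.8},
    "release_high": {"S1": -2.5, "S2": -2.5, "S3": -1.8, "S4": 0.0},
    "release_lox": {"S1": -0.8, "S2": -2.0, "S3": -1.8, "S4": 0.0},
    "ft_like": {"S1": -0.5, "S2": 0.5, "S3": -0.5, "S4": -0.5},
    "flat": {"S1": 0.0, "S2": 0.0, "S3": 0.0, "S4": 0.0},
}


def study_design(
    module_rho: float = 0.75,
    include_undetectable: bool = True,
    flat_stage_means: bool = False,
    **overrides,
) -> SyntheticDesign:
    """The default 13-gene two-module panel emulating the study layout.

    A 14th, undetectable amplicon (DAM2-like) is included by default so
    the detection filter has something to do.  ``flat_stage_means`` keeps
    the module/noise structure but removes all stage effects (useful when
    only correlation structure should drive an analysis).
    """
    def prof(key):
        return _PROFILES["flat"] if flat_stage_means else _PROFILES[key]

    dormancy = ["DAM1-like", "DAM3-like", "DAM4-like", "DAM5-like", "DAM6-like",
                "SAP1-like"]
    release = ["AOC1-like", "AOC2-like", "LOX-like", "TIP-like", "SWEET15-like"]
    genes = [GeneSpec(g, "dormancy", prof("dormancy_high")) for g in dormancy]
    genes.append(GeneSpec("TOR-like", "dormancy", prof("dormancy_tor")))
    genes += [GeneSpec(g, "release",
                       prof("release_lox") if g == "LOX-like" else prof("release_high"))
              for g in release]
    genes.append(GeneSpec("FT-like", None, prof("ft_like")))
    if include_undetectable:
        genes.append(GeneSpec("DAM2-like", None, {}, detectable=False))
    return SyntheticDesign(
        genes=tuple(genes),
        module_rho={"dormancy": module_rho, "release": module_rho},
        **overrides,
    )


def null_design(n_genes: int = 12, **overrides) -> SyntheticDesign:
    """Mutually independent genes with no stage effects (null control)."""
    genes = tuple(GeneSpec(f"G{i + 1:02d}", None, _PROFILES["flat"])
                  for i in range(n_genes))
    return SyntheticDesign(genes=genes, module_rho={}, **overrides)


# -- generation --------------------------------------------------------------

def _bud_ids(design: SyntheticDesign) -> tuple[list[str], pd.Series]:
    ids, stages = [], []
    for stage, size in design.stage_sizes.items():
        for i in range(size):
            ids.append(f"{stage}_b{i + 1:02d}")
            stages.append(stage)
    return ids, pd.Series(stages, index=ids, name="stage")


def generate_expression(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[ExpressionTable, GroundTruth]:
    """Draw one synthetic experiment from the design.

    Fully deterministic given ``design`` (and its seed, unless overridden
    by ``seed``).  Returns the expression table (undetectable genes as
    all-missing columns) and the ground-truth record scoring downstream
    stages: module membership (hence the true co-expression edge set),
    spiked outlier cells, and — when the design requests a bimodal
    transition stage — the mixture component of every S3 bud.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    ids, stages = _bud_ids(design)
    n = len(ids)
    modules = sorted({g.module for g in design.genes if g.module is not None})
    latent = {m: rng.standard_normal(n) for m in modules}

    # the component-assignment uniforms are always consumed so that a
    # mixture with separation 0 is bit-identical to the unimodal generator
    s3_mask = (stages == "S3").to_numpy()
    comp_u = rng.random(int(s3_mask.sum()))
    s3_component: dict[str, int] | None = None
    comp_shift = np.zeros(n)
    if design.bimodal_s3 is not None:
        frac, sep = design.bimodal_s3
        comp = np.zeros(n, dtype=int)
        comp[s3_mask] = comp_u < frac
        # components sit sep log-sd apart, centred on the stage mean
        comp_shift[s3_mask] = (comp[s3_mask] - frac) * sep * design.log_sd
        s3_component = {bud: int(c) for bud, c in zip(ids, comp) if stages[bud] == "S3"}

    cols = {}
    spiked: list[tuple[str, str]] = []
    for g in design.genes:
        if not g.detectable:
            cols[g.name] = np.full(n, np.nan)
            continue
        mean = stages.map(g.stage_means).to_numpy(dtype=float)
        if g.module is None:
            y = mean + design.log_sd * rng.standard_normal(n)
        else:
            rho = design.module_rho[g.module]
            y = (mean
                 + np.sqrt(rho) * design.log_sd * latent[g.module]
                 + np.sqrt(1.0 - rho) * design.log_sd * rng.standard_normal(n))
        y = y + comp_shift
        vals = np.exp(y)
        if design.outlier_rate > 0:
            spikes = rng.random(n) < design.outlier_rate
            vals[spikes] *= design.outlier_factor
            spiked += [(ids[i], g.name) for i in np.nonzero(spikes)[0]]
        cols[g.name] = vals

    values = pd.DataFrame(cols, index=ids)
    table = ExpressionTable(values, stages)
    module_of = {g.name: g.module for g in design.genes}
    edges = frozenset(
        frozenset((a.name, b.name))
        for i, a in enumerate(design.genes) for b in design.genes[i + 1:]
        if a.module is not None and a.module == b.module
        and a.detectable and b.detectable
    )
    truth = GroundTruth(module_of=module_of, true_edges=edges,
                        spiked=tuple(spiked), s3_component=s3_component)
    return table, truth


def generate_bimodal_s3(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[ExpressionTable, GroundTruth]:
    """Expression table whose transition stage is a two-component mixture.

    Requires ``design.bimodal_s3 = (mixing_fraction, separation)`` with
    the separation expressed in units of the log-scale noise sd; at
    separation 0 this reduces to the unimodal generator.
    """
    if design.bimodal_s3 is None:
        raise ValueError("design.bimodal_s3 is not set")
    return generate_expression(design, seed=seed)


def generate_cq(
    design: SyntheticDesign,
    seed: int | None = None,
    curves: Mapping[str, "StandardCurve"] | None = None,
    cq_noise_sd: float = 0.1,
    n_replicates: int = 3,
    reference_gene: str = "SAND-like",
    reference_quantity: float = 10.0,
) -> tuple[list, pd.DataFrame, dict, ExpressionTable]:
    """Round-trip test bed: synthesize raw Cq data from known expression.

    The ground-truth relative expression is drawn from ``design`` (without
    outlier spikes, which live on the expression scale); each gene's true
    template quantity is expression x the (near-constant) reference
    quantity, inverted through that gene's standard curve to a Cq, with
    Gaussian replicate noise added.  Returns ``(cq_records,
    dilution_series, curves, truth_table)`` where the dilution series is
    the five-point ten-fold series the curves would be refit from.
    """
    from .quant import CqRecord, StandardCurve  # deferred: avoid cycle

    rng = np.random.default_rng(design.seed if seed is None else seed)
    clean = replace(design, outlier_rate=0.0)
    table, _ = generate_expression(clean, seed=int(rng.integers(2**31)))

    detectable = [g.name for g in design.genes if g.detectable]
    gene_names = detectable + [reference_gene]
    all_names = [g.name for g in design.genes] + [reference_gene]
    if curves is None:
        curves = {}
        for i, g in enumerate(all_names):
            slope = -3.1 - 0.5 * rng.random()
            curves[g] = StandardCurve(gene=g, slope=float(slope),
                                      intercept=float(34.0 + rng.normal(0, 1)),
                                      r_squared=1.0)

    # five ten-fold dilutions, log10 quantity 0..4
    dil_rows = []
    for g in all_names:
        for lq in range(5):
            cq = curves[g].intercept + curves[g].slope * lq
            cq += rng.normal(0.0, cq_noise_sd)
            dil_rows.append((g, float(lq), float(cq)))
    dilutions = pd.DataFrame(dil_rows, columns=["gene", "log10_quantity", "cq"])

    records: list[CqRecord] = []
    for bud in table.bud_ids:
        stage = table.stages[bud]
        for g in gene_names:
            if g == reference_gene:
                qty = reference_quantity
            else:
                qty = float(table.values.at[bud, g]) * reference_quantity
            true_cq = curves[g].intercept + curves[g].slope * np.log10(qty)
            for rep in range(1, n_replicates + 1):
                cq = float(true_cq + rng.normal(0.0, cq_noise_sd)) if cq_noise_sd > 0 \
                    else float(true_cq)
                records.append(CqRecord(bud_id=bud, stage=stage, gene=g,
                                        replicate=rep, cq=cq))
    for g in design.genes:
        if not g.detectable:
            for bud in table.bud_ids:
                records.append(CqRecord(bud_id=bud, stage=table.stages[bud],
                                        gene=g.name, replicate=1, cq=None))
    return records, dilutions, dict(curves), table
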