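"""Relative quantification of RT-qPCR data by the standard-curve method.

A per-gene dilution series gives a linear fit of Cq on log10 template
quantity; sample Cq values are inverted through that fit to (arbitrary
unit) quantities, normalized to a reference gene measured in the same
bud, and finally rescaled gene-wise so the highest per-stage median is 1.
Undetected reactions are carried as missing values throughout, never as
zero expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .table import ExpressionTable

__all__ = [
    "CqRecord",
    "StandardCurve",
    "InsufficientDilutionError",
    "DegenerateCurveError",
    "ZeroMedianError",
    "fit_standard_curve",
    "cq_to_quantity",
    "collapse_replicates",
    "relative_expression",
    "rescale_to_max_stage_median",
    "filter_undetected_genes",
    "quantify_cq_table",
]

#: Technical replicates whose Cq range exceeds this many cycles are
#: flagged (never dropped) as high-spread; ~0.5 cycles corresponds to a
#: ~40% quantity discrepancy at perfect efficiency.
REPLICATE_SPREAD_CYCLES = 0.5


class InsufficientDilutionError(ValueError):
    """Fewer than three distinct dilution points."""


class DegenerateCurveError(ValueError):
    """Standard-curve slope is not negative (no amplification signal)."""


class ZeroMedianError(ValueError):
    """A gene's highest stage median is zero; rescaling is undefined."""


@dataclass(frozen=True)
class CqRecord:
    """One technical-replicate quantification cycle for a bud x gene."""

    bud_id: str
    stage: str
    gene: str
    replicate: int
    cq: float | None  # None = undetected

    def __post_init__(self) -> None:
        if self.cq is not None and not self.cq > 0:
            raise ValueError(f"Cq must be positive, got {self.cq}")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Cq on log10 quantity for one amplicon.

    ``slope`` is the Cq change per decade of template (negative);
    ``efficiency`` is the per-cycle amplification gain
    ``E = 10^(-1/slope) - 1`` (1.0 = perfect doubling).
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise DegenerateCurveError(
                f"{self.gene}: slope {self.slope} is not negative")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    points: Sequence[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Ordinary least squares of mean Cq on log10 quantity.

    ``points`` are (log10_quantity, mean_cq) pairs from the dilution
    series; at least three distinct dilutions are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (log10_quantity, cq) pairs")
    if np.unique(pts[:, 0]).size < 3:
        raise InsufficientDilutionError(
            f"{gene or 'curve'}: need >= 3 distinct dilution points, "
            f"got {np.unique(pts[:, 0]).size}")
    fit = sps.linregress(pts[:, 0], pts[:, 1])
    r2 = float(fit.rvalue**2)
    return StandardCurve(gene=gene, slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=min(r2, 1.0))


def cq_to_quantity(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10^((cq - intercept)/slope)."""
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def collapse_replicates(cqs: Sequence[float]) -> tuple[float, bool]:
    """Average 1-3 technical replicate Cq values.

    Returns ``(mean_cq, high_spread)``; an empty replicate set yields
    ``(nan, False)`` — a missing value, not an error.  The spread flag is
    raised when max - min exceeds :data:`REPLICATE_SPREAD_CYCLES`.
    """
    vals = [c for c in cqs if c is not None and not math.isnan(c)]
    if not vals:
        return float("nan"), False
    if len(vals) > 3:
        raise ValueError(f"at most 3 technical replicates expected, got {len(vals)}")
    return float(np.mean(vals)), (max(vals) - min(vals)) > REPLICATE_SPREAD_CYCLES


def relative_expression(target_qty: float, reference_qty: float) -> float:
    """Target quantity normalized to the reference gene of the same bud."""
    if math.isnan(target_qty) or math.isnan(reference_qty) or reference_qty <= 0:
        return float("nan")
    return target_qty / reference_qty


def rescale_to_max_stage_median(table: ExpressionTable) -> ExpressionTable:
    """Divide each gene by its highest per-stage median.

    After rescaling, every gene's maximum stage median is exactly 1, which
    puts genes with very different absolute abundances on a comparable
    scale.  Idempotent and invariant to a global positive rescaling of the
    input.
    """
    scaled = table.values.copy()
    for gene in table.genes:
        med = table.stage_medians(gene)
        top = med.max()
        if not top > 0:
            raise ZeroMedianError(
                f"gene {gene!r}: highest stage median is {top}; cannot rescale")
        scaled[gene] = table.values[gene] / top
    return table.with_values(scaled, rescaled=True)


def filter_undetected_genes(
    table: ExpressionTable, min_detected_fraction: float
) -> tuple[ExpressionTable, list[str]]:
    """Drop genes detected in too small a fraction of buds.

    Emulates the exclusion of amplicons whose signal sits below the
    detection threshold in most reactions.  Returns the filtered table
    and the list of dropped genes.
    """
    if not 0.0 < min_detected_fraction <= 1.0:
        raise ValueError("min_detected_fraction must be in (0, 1]")
    frac = table.detected_fraction()
    dropped = [g for g in table.genes if frac[g] < min_detected_fraction]
    kept = [g for g in table.genes if g not in set(dropped)]
    if not kept:
        raise ValueError("all genes fall below the detection threshold")
    return table.subset(genes=kept), dropped


def quantify_cq_table(
    cq_records: Iterable[CqRecord],
    curves: Mapping[str, StandardCurve],
    reference_gene: str,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Full Cq -> relative-expression pass for a single-bud experiment.

    Replicates are averaged per bud x gene, inverted through each gene's
    standard curve and normalized to the reference gene within the same
    bud.  Returns the (unrescaled) expression table, reference gene
    excluded, plus a QC frame with per-(bud, gene) mean Cq and spread
    flags.
    """
    df = pd.DataFrame(
        [(r.bud_id, r.stage, r.gene, r.cq) for r in cq_records],
        columns=["bud_id", "stage", "gene", "cq"],
    )
    if df.empty:
        raise ValueError("no Cq records")
    unknown = sorted(set(df["gene"]) - set(curves))
    if unknown:
        raise ValueError(f"no standard curve for genes: {unknown}")
    if reference_gene not in set(df["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from records")

    rows = []
    for (bud, stage, gene), grp in df.groupby(
            ["bud_id", "stage", "gene"], sort=False):
        mean_cq, spread = collapse_replicates(grp["cq"].tolist())
        qty = (cq_to_quantity(mean_cq, curves[gene])
               if not math.isnan(mean_cq) else float("nan"))
        rows.append((bud, stage, gene, mean_cq, spread, qty))
    qc = pd.DataFrame(rows, columns=[
        "bud_id", "stage", "gene", "mean_cq", "high_spread", "quantity"])

    qty_wide = qc.pivot(index="bud_id", columns="gene", values="quantity")
    ref = qty_wide[reference_gene]
    rel = qty_wide.drop(columns=[reference_gene]).div(ref, axis=0)
    rel[ref.isna() | (ref <= 0)] = float("nan")
    # preserve input bud order (pivot sorts lexically)
    bud_order = df["bud_id"].drop_duplicates().tolist()
    gene_order = [g for g in df["gene"].drop_duplicates() if g != reference_gene]
    rel = rel.loc[bud_order, gene_order]
    rel.columns.name = None
    stages = df.drop_duplicates("bud_id").set_index("bud_id")["stage"]
    return ExpressionTable(rel, stages), qc
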