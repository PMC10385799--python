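"""The bud x gene relative-expression table shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Stage labels of the study design: early dormant, late dormant,
#: dormancy transition, dormancy released.  The container accepts any
#: label set; these are the defaults used throughout.
DEFAULT_STAGES = ("S1", "S2", "S3", "S4")


@dataclass
class ExpressionTable:
    """Relative expression of genes across individually sampled buds.

    ``values`` is a bud x gene matrix of nonnegative, reference-normalized
    relative expression (dimensionless); missing measurements (e.g. an
    undetected target or reference) are NaN.  ``stages`` maps every bud to
    its sampling stage.  ``rescaled`` records whether the per-gene
    "divide by the highest stage median" normalization has been applied.
    """

    values: pd.DataFrame
    stages: pd.Series
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.stages = self.stages.astype(str)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate bud ids: {dupes}")
        missing_stage = self.values.index.difference(self.stages.index)
        if len(missing_stage):
            raise ValueError(f"buds without a stage label: {list(missing_stage)}")
        self.stages = self.stages.loc[self.values.index]
        self.values.index.name = "bud_id"
        self.values.columns.name = None
        self.stages.index.name = "bud_id"
        self.stages.name = "stage"
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("negative expression values are not allowed")

    # -- basic views --------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def bud_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stages:
            seen.setdefault(s, None)
        return list(seen)

    def stage_buds(self, stage: str) -> list[str]:
        if stage not in set(self.stages):
            raise ValueError(f"stage {stage!r} not present "
                             f"(stages: {self.stage_names})")
        return list(self.stages.index[self.stages == stage])

    def stage_matrix(self, stage: str) -> pd.DataFrame:
        """bud x gene values restricted to one stage."""
        return self.values.loc[self.stage_buds(stage)]

    def gene_values(self, gene: str, stage: str | None = None) -> pd.Series:
        col = self.values[gene]
        if stage is not None:
            col = col.loc[self.stage_buds(stage)]
        return col

    # -- derived tables ------------------------------------------------------

    def subset(self, buds: Sequence[str] | None = None,
               genes: Sequence[str] | None = None) -> "ExpressionTable":
        vals = self.values
        if buds is not None:
            vals = vals.loc[list(buds)]
        if genes is not None:
            vals = vals[list(genes)]
        return ExpressionTable(vals.copy(), self.stages.loc[vals.index].copy(),
                               rescaled=self.rescaled)

    def with_values(self, values: pd.DataFrame, **changes) -> "ExpressionTable":
        out = replace(self, values=values)
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    def stage_medians(self, gene: str) -> pd.Series:
        """Per-stage median expression of one gene (NaN-skipping)."""
        return (self.values[gene]
                .groupby(self.stages, sort=False)
                .median())

    def detected_fraction(self) -> pd.Series:
        """Per-gene fraction of buds with a non-missing measurement."""
        return self.values.notna().mean(axis=0)


def from_records(
    records: Iterable[tuple[str, str, str, float]],
    stage_order: Sequence[str] = DEFAULT_STAGES,
) -> ExpressionTable:
    """Build a table from (bud_id, stage, gene, value) tuples."""
    df = pd.DataFrame(records, columns=["bud_id", "stage", "gene", "value"])
    values = df.pivot(index="bud_id", columns="gene", values="value")
    stages = df.drop_duplicates("bud_id").set_index("bud_id")["stage"]
    order = [b for s in stage_order for b in stages.index[stages == s]]
    extra = [b for b in stages.index if b not in set(order)]
    values = values.loc[order + extra]
    values.columns.name = None
    return ExpressionTable(values, stages)
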