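"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are TSV with an optional leading comment block (lines starting
with ``#``) carrying the package version and the run seed, so outputs are
diff-able across runs.  Cq input is long format (one technical replicate
per line, the natural export shape of qPCR instruments); expression
matrices are wide (buds x genes with a stage column), the shape
correlation and ordination consume.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .quant import CqRecord
from .table import DEFAULT_STAGES, ExpressionTable

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_cq_records",
    "read_dilution_series",
    "write_tsv",
]


def _header_lines(seed: int | None) -> str:
    lines = [f"# singlebud v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None = None,
              index: bool = True) -> Path:
    """Write any frame as TSV with the standard comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed))
        df.to_csv(fh, sep="\t", index=index)
    return path


def write_expression_table(table: ExpressionTable, path: str | Path,
                           seed: int | None = None) -> Path:
    """Serialize an expression table (stage column first, genes after)."""
    df = pd.concat([table.stages.rename("stage"), table.values], axis=1)
    df.index.name = "bud_id"
    return write_tsv(df, path, seed=seed)


def read_expression_table(
    path: str | Path,
    stage_labels: Sequence[str] | None = DEFAULT_STAGES,
) -> ExpressionTable:
    """Read a wide expression TSV back into an :class:`ExpressionTable`.

    Validates the stage column against ``stage_labels`` (pass ``None`` to
    accept any label set), rejects duplicate bud ids, reports the exact
    cell on non-numeric expression values and preserves empty cells as
    missing.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "bud_id" or "stage" not in df.columns[:2]:
        raise ValueError(f"{path}: expected 'bud_id' and 'stage' as the "
                         "first two columns")
    if df["bud_id"].duplicated().any():
        dupes = df.loc[df["bud_id"].duplicated(), "bud_id"].tolist()
        raise ValueError(f"{path}: duplicate bud ids {dupes}")
    df = df.set_index("bud_id")
    stages = df.pop("stage")
    if stage_labels is not None:
        bad = sorted(set(stages) - set(stage_labels))
        if bad:
            raise ValueError(f"{path}: unknown stage labels {bad} "
                             f"(expected one of {list(stage_labels)})")
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[parsed.isna() & df[col].notna()
                            & (df[col].str.strip() != "")]
        if len(bad_rows):
            raise ValueError(
                f"{path}: non-numeric expression value at bud "
                f"{bad_rows[0]!r}, gene {col!r}: {df.at[bad_rows[0], col]!r}")
        values[col] = parsed
    return ExpressionTable(values, stages)


def read_cq_records(path: str | Path) -> list[CqRecord]:
    """Read long-format Cq data: bud_id, stage, gene, replicate, cq.

    An empty ``cq`` field means the reaction did not cross threshold
    (undetected) and is carried as a missing value.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["bud_id", "stage", "gene", "replicate", "cq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        cq = None if (row.cq is None or (isinstance(row.cq, float)
                                         and math.isnan(row.cq))) else float(row.cq)
        records.append(CqRecord(bud_id=str(row.bud_id), stage=str(row.stage),
                                gene=str(row.gene), replicate=int(row.replicate),
                                cq=cq))
    return records


def read_dilution_series(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read a dilution-series TSV (gene, log10_quantity, cq) per gene."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene", "log10_quantity", "cq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene), []).append(
            (float(row.log10_quantity), float(row.cq)))
    return out
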