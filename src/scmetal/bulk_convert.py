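"""Bulk-ICP-MS digest arithmetic: µg/L to pg per million cells and fg per cell.

A digest of a counted cell pellet is split into technical replicates; the
instrument reports an analyte concentration in µg/L per replicate.  With the
replicate volume and the number of cells it contains, the chain is

    total_pg      = concentration(µg/L) * volume(L) * 1e6
    pg/10^6 cells = total_pg / (cells / 1e6)
    fg/cell       = pg/10^6 cells / 1000        (1 pg = 1000 fg)

Replicates below the limit of quantification (BLQ) are excluded from the
triplicate mean rather than zero-imputed; a sample whose replicates are all
BLQ is itself reported BLQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "BulkSample",
    "PerCellResult",
    "BulkSummary",
    "bulk_to_per_cell",
    "average_replicates",
    "read_bulk_table",
    "write_bulk_summary",
    "split_replicates",
]


@dataclass(frozen=True)
class BulkSample:
    """One technical replicate of a bulk digest measurement."""

    sample_id: str
    element: str
    concentration: float  # µg/L as reported by the instrument
    replicate_volume: float  # litres in this replicate tube
    cells_in_replicate: float  # cells contributing to this replicate
    blq: bool = False

    def __post_init__(self) -> None:
        if not self.blq and self.concentration < 0:
            raise ValidationError(f"{self.sample_id}: concentration must be >= 0")
        if self.replicate_volume <= 0:
            raise ValidationError(f"{self.sample_id}: replicate_volume must be > 0")
        if self.cells_in_replicate <= 0:
            raise ValidationError(f"{self.sample_id}: cells_in_replicate must be > 0")


@dataclass(frozen=True)
class PerCellResult:
    """Converted replicate: pg per 10^6 cells and fg per single cell."""

    sample_id: str
    element: str
    pg_per_million_cells: float | None
    fg_per_cell: float | None
    blq: bool


@dataclass(frozen=True)
class BulkSummary:
    """Replicate-averaged per-cell content for one sample/element."""

    sample_id: str
    element: str
    mean_fg_per_cell: float | None
    sd_fg_per_cell: float | None
    mean_pg_per_million: float | None
    n_used: int
    n_blq: int

    @property
    def blq(self) -> bool:
        return self.n_used == 0


def bulk_to_per_cell(sample: BulkSample) -> PerCellResult:
    """Convert one replicate's µg/L reading to per-cell content.

    BLQ replicates return a BLQ marker with no numbers; they are excluded
    from downstream means.
    """
    if sample.blq:
        return PerCellResult(sample.sample_id, sample.element, None, None, True)
    total_pg = sample.concentration * sample.replicate_volume * 1e6
    pg_per_million = total_pg / (sample.cells_in_replicate / 1e6)
    fg_per_cell = pg_per_million / 1000.0  # 1000 pg/10^6 cells == 1 fg/cell
    return PerCellResult(
        sample.sample_id, sample.element, pg_per_million, fg_per_cell, False
    )


def average_replicates(results: Sequence[PerCellResult]) -> BulkSummary:
    """Mean/SD over non-BLQ replicates; all-BLQ propagates a BLQ summary."""
    if len(results) == 0:
        raise ValidationError("need at least one replicate")
    ids = {r.sample_id for r in results}
    elements = {r.element for r in results}
    if len(ids) != 1 or len(elements) != 1:
        raise ValidationError("replicates must share sample_id and element")
    used = [r for r in results if not r.blq]
    n_blq = len(results) - len(used)
    if not used:
        return BulkSummary(results[0].sample_id, results[0].element, None, None, None, 0, n_blq)
    fg = np.array([r.fg_per_cell for r in used], dtype=float)
    pg = np.array([r.pg_per_million_cells for r in used], dtype=float)
    sd = float(fg.std(ddof=1)) if len(fg) > 1 else 0.0
    return BulkSummary(
        sample_id=results[0].sample_id,
        element=results[0].element,
        mean_fg_per_cell=float(fg.mean()),
        sd_fg_per_cell=sd,
        mean_pg_per_million=float(pg.mean()),
        n_used=len(used),
        n_blq=n_blq,
    )


def split_replicates(total_cells: float, n_replicates: int = 3) -> float:
    """Cells per replicate when a counted pellet is divided evenly."""
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    return total_cells / n_replicates


# ---------------------------------------------------------------------------
# on-disk tables


def read_bulk_table(path: str | Path) -> list[BulkSample]:
    """Read ``sample_id,element,concentration_ug_L,volume_mL,cells_in_replicate,blq``."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {
        "sample_id",
        "element",
        "concentration_ug_L",
        "volume_mL",
        "cells_in_replicate",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        blq = bool(getattr(row, "blq", False))
        conc = row.concentration_ug_L
        if isinstance(conc, float) and math.isnan(conc):
            if not blq:
                raise ValidationError(
                    f"{path}: {row.sample_id} has no concentration and is not BLQ"
                )
            conc = 0.0
        out.append(
            BulkSample(
                sample_id=str(row.sample_id),
                element=str(row.element),
                concentration=float(conc),
                replicate_volume=float(row.volume_mL) * 1e-3,
                cells_in_replicate=float(row.cells_in_replicate),
                blq=blq,
            )
        )
    return out


def write_bulk_summary(summaries: Iterable[BulkSummary], path: str | Path) -> None:
    """Per-sample summary table (pg/10^6 cells and fg/cell, BLQ-aware)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "sample_id": s.sample_id,
                "element": s.element,
                "mean_pg_per_million_cells": "BLQ" if s.blq else repr(s.mean_pg_per_million),
                "mean_fg_per_cell": "BLQ" if s.blq else repr(s.mean_fg_per_cell),
                "sd_fg_per_cell": "BLQ" if s.blq else repr(s.sd_fg_per_cell),
                "n_used": s.n_used,
                "n_blq": s.n_blq,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "element",
            "mean_pg_per_million_cells",
            "mean_fg_per_cell",
            "sd_fg_per_cell",
            "n_used",
            "n_blq",
        ],
    ).to_csv(path, index=False)
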