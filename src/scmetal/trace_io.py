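"""Reading and writing on-disk artifacts: traces, event logs, configs, results.

File dialects
-------------
Trace CSV
    Header ``time_s,<analyte>_cps`` (one analyte per column), e.g.
    ``time_s,56Fe_cps``.  Times are seconds, intensities counts per second.
Events CSV
    ``spot_id,kind,t_start,t_end,nominal_mass_fg,group`` with kind one of
    ``cell``/``blank``/``standard``; ``nominal_mass_fg`` is required for
    standards and empty otherwise.  Windows are half-open ``[t_start, t_end)``:
    sample *i* belongs to a window iff ``t_start <= times[i] < t_end``, so a
    boundary sample is never assigned twice.
Results CSV
    ``spot_id,group,integrated_response,mass_fg,flags`` with flags as
    semicolon-joined tokens (``EDGE_TRUNCATED``, ``BELOW_LOD``, ``BELOW_LOQ``,
    ``MERGED_SUSPECT``), rows sorted by spot_id.
Run config
    Flat ``key: value`` text (YAML-compatible subset).  Unknown keys are an
    error, not a warning.

All indices are 0-based; masses are femtograms; intensities are CPS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "TimeTrace",
    "SpotEvent",
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_results",
    "write_results",
    "read_config",
    "write_config",
]

#: Recognised QC flag tokens, in canonical output order.
FLAG_TOKENS = ("EDGE_TRUNCATED", "BELOW_LOD", "BELOW_LOQ", "MERGED_SUSPECT")

_KINDS = ("cell", "blank", "standard")


@dataclass(frozen=True)
class TimeTrace:
    """Uniformly sampled intensity series for one analyte channel.

    Parameters
    ----------
    acquisition_id
        Identifier of the acquisition (usually the source file stem).
    analyte
        Isotope label, e.g. ``"56Fe"``.
    times
        Sample timestamps in seconds, strictly increasing, uniformly spaced.
    intensities
        Detector intensity in counts per second (CPS), non-negative.
    dwell_time
        Integration interval of one detector reading, in seconds.  Must match
        the median sample spacing within 1%.
    """

    acquisition_id: str
    analyte: str
    times: np.ndarray
    intensities: np.ndarray
    dwell_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValidationError("times and intensities must be 1-D and equal length")
        if len(t) < 2:
            raise ValidationError("a trace needs at least 2 samples")
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"times not strictly increasing at row {int(bad[0]) + 1}"
            )
        med = float(np.median(dt))
        if not np.allclose(dt, med, rtol=1e-6, atol=0.0):
            raise ValidationError("sample spacing is not uniform (rtol 1e-6)")
        if np.any(y < 0):
            raise ValidationError("negative intensity encountered")
        if not (self.dwell_time > 0):
            raise ValidationError("dwell_time must be positive")
        if not math.isclose(self.dwell_time, med, rel_tol=0.01):
            raise ValidationError(
                f"dwell_time {self.dwell_time} disagrees with median spacing {med}"
            )

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Index slice of samples with ``t_start <= t < t_end`` (half-open)."""
        i0 = int(np.searchsorted(self.times, t_start, side="left"))
        i1 = int(np.searchsorted(self.times, t_end, side="left"))
        return slice(i0, i1)

    def segment(self, t_start: float, t_end: float) -> np.ndarray:
        """Intensities of the half-open window ``[t_start, t_end)``."""
        return self.intensities[self.window_slice(t_start, t_end)]

    def __eq__(self, other: object) -> bool:
        # data equality; acquisition_id is provenance (file stem) and ignored
        if not isinstance(other, TimeTrace):
            return NotImplemented
        return (
            self.analyte == other.analyte
            and self.dwell_time == other.dwell_time
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class SpotEvent:
    """A labeled trace segment: one cell, blank, or standard ablation."""

    spot_id: str
    kind: str
    t_start: float
    t_end: float
    nominal_mass: float | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r} for {self.spot_id}")
        if not self.t_start < self.t_end:
            raise ValidationError(f"{self.spot_id}: t_start must be < t_end")
        if self.kind == "standard":
            if self.nominal_mass is None:
                raise ValidationError(
                    f"{self.spot_id}: standard events require nominal_mass_fg"
                )
            if self.nominal_mass < 0:
                raise ValidationError(f"{self.spot_id}: nominal_mass must be >= 0")

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


_THRESHOLD_METHODS = ("blank_mean", "blank_mean_plus_k_sigma")
_BOUNDARY_RULES = ("local_min_at_or_below", "first_at_or_below")
_DRIFT_MODES = ("none", "piecewise_linear")
_INTEGRATION_UNITS = ("summed_cps", "counts")


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings for one quantification run.

    Defaults reproduce the reference workflow: the background threshold is the
    mean of the blank means, peak boundaries are the nearest sub-threshold
    local minima on either side of the apex, responses are summed CPS, and
    LOD/LOQ use the 3-sigma/10-sigma convention.
    """

    threshold_method: str = "blank_mean"
    k_sigma: float = 0.0
    boundary_rule: str = "local_min_at_or_below"
    drift_correction: str = "none"
    integration_units: str = "summed_cps"
    lod_k: float = 3.0
    loq_k: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_method not in _THRESHOLD_METHODS:
            raise ValidationError(f"unknown threshold_method {self.threshold_method!r}")
        if self.boundary_rule not in _BOUNDARY_RULES:
            raise ValidationError(f"unknown boundary_rule {self.boundary_rule!r}")
        if self.drift_correction not in _DRIFT_MODES:
            raise ValidationError(f"unknown drift_correction {self.drift_correction!r}")
        if self.integration_units not in _INTEGRATION_UNITS:
            raise ValidationError(
                f"unknown integration_units {self.integration_units!r}"
            )
        if self.k_sigma < 0:
            raise ValidationError("k_sigma must be >= 0")
        if not self.lod_k < self.loq_k:
            raise ValidationError("lod_k must be < loq_k")


# ---------------------------------------------------------------------------
# traces


def read_trace(path: str | Path, analyte: str) -> TimeTrace:
    """Read a trace CSV; dwell time is inferred from the median spacing.

    Raises :class:`FormatError` if the time or analyte column is missing and
    :class:`ValidationError` (with the first offending row) on non-monotone
    time or other invariant violations.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    time_col = _find_time_column(df, path)
    analyte_col = _find_analyte_column(df, analyte, path)
    t = df[time_col].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: time not strictly increasing at row {int(bad[0]) + 1}"
        )
    # snap to 6 significant digits: dwell settings are round numbers and the
    # spacing-uniformity tolerance is 1e-6 anyway
    dwell = float(f"{np.median(dt):.6g}")
    return TimeTrace(
        acquisition_id=path.stem,
        analyte=analyte,
        times=t,
        intensities=df[analyte_col].to_numpy(dtype=float),
        dwell_time=dwell,
    )


def _find_time_column(df: pd.DataFrame, path: Path) -> str:
    for col in df.columns:
        if col == "time_s" or col.lower().startswith("time"):
            return col
    raise FormatError(f"{path}: no time column (expected 'time_s')")


def _find_analyte_column(df: pd.DataFrame, analyte: str, path: Path) -> str:
    for cand in (f"{analyte}_cps", analyte):
        if cand in df.columns:
            return cand
    raise FormatError(f"{path}: missing analyte column '{analyte}_cps'")


def write_trace(trace: TimeTrace, path: str | Path) -> None:
    """Write a trace in the canonical ``time_s,<analyte>_cps`` dialect."""
    df = pd.DataFrame(
        {"time_s": trace.times, f"{trace.analyte}_cps": trace.intensities}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event logs


def read_events(path: str | Path) -> list[SpotEvent]:
    """Read the event log; returns events ordered by t_start.

    Overlapping windows produce a warning naming both spot_ids (post-hoc
    review decides whether a merge is real); unknown kinds and standards
    without a nominal mass are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"spot_id", "kind", "t_start", "t_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        mass = getattr(row, "nominal_mass_fg", None)
        if mass is not None and (isinstance(mass, float) and math.isnan(mass)):
            mass = None
        events.append(
            SpotEvent(
                spot_id=str(row.spot_id),
                kind=str(row.kind),
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                nominal_mass=None if mass is None else float(mass),
                group="" if _isna(getattr(row, "group", "")) else str(getattr(row, "group", "")),
            )
        )
    events.sort(key=lambda e: (e.t_start, e.spot_id))
    for prev, cur in zip(events, events[1:]):
        if cur.t_start < prev.t_end:
            warnings.warn(
                f"overlapping event windows: {prev.spot_id} and {cur.spot_id}",
                stacklevel=2,
            )
    return events


def _isna(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def write_events(events: Iterable[SpotEvent], path: str | Path) -> None:
    rows = [
        {
            "spot_id": e.spot_id,
            "kind": e.kind,
            "t_start": e.t_start,
            "t_end": e.t_end,
            "nominal_mass_fg": e.nominal_mass,
            "group": e.group,
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=["spot_id", "kind", "t_start", "t_end", "nominal_mass_fg", "group"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def write_results(measurements: Sequence, path: str | Path) -> None:
    """Write per-cell results, one row per cell, sorted by spot_id.

    ``measurements`` are :class:`scmetal.event_quant.CellMeasurement`; an
    empty list produces a header-only file.
    """
    rows = [
        {
            "spot_id": m.spot_id,
            "group": m.group,
            "integrated_response": repr(float(m.integrated_response)),
            "mass_fg": "" if m.mass_fg is None else repr(float(m.mass_fg)),
            "flags": ";".join(tok for tok in FLAG_TOKENS if tok in m.flags),
        }
        for m in sorted(measurements, key=lambda m: m.spot_id)
    ]
    pd.DataFrame(
        rows, columns=["spot_id", "group", "integrated_response", "mass_fg", "flags"]
    ).to_csv(path, index=False)


def read_results(path: str | Path) -> list:
    """Read a results CSV back into :class:`CellMeasurement` objects."""
    from .event_quant import CellMeasurement  # local import: avoid cycle

    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        mass = None if row.mass_fg == "" else float(row.mass_fg)
        flags = frozenset(t for t in str(row.flags).split(";") if t)
        out.append(
            CellMeasurement(
                spot_id=str(row.spot_id),
                group=str(row.group),
                integrated_response=float(row.integrated_response),
                mass_fg=mass,
                flags=flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# run config


def read_config(path: str | Path) -> RunConfig:
    """Read a flat key:value run configuration; unknown keys are an error."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat key:value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fields(RunConfig):
            fh.write(f"{f.name}: {getattr(config, f.name)}\n")


# re-export the bulk table readers so every on-disk artifact has a home here
from .bulk_convert import read_bulk_table, write_bulk_summary  # noqa: E402,F401
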