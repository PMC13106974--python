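"""Blank-derived background threshold, peak boundary detection, integration.

The background threshold is the unweighted average of per-blank mean CPS
values.  For each ablation event, the peak is the maximal contiguous run of
samples above the threshold containing the segment maximum, extended on each
side to the "first downward peak at or below the threshold": by default the
nearest sub-threshold local minimum (``local_min_at_or_below``), or simply the
nearest sub-threshold sample (``first_at_or_below``).  Everything between the
two boundaries is summed — no per-sample baseline subtraction; the calibration
intercept (the 0 fg standard is part of the fit) absorbs the baseline
contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .trace_io import RunConfig, SpotEvent, TimeTrace

__all__ = [
    "Threshold",
    "Peak",
    "CellMeasurement",
    "compute_blank_threshold",
    "detect_peak",
    "integrate_events",
    "quantify_events",
    "blank_window_responses",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Threshold:
    """Background threshold in CPS, derived from blank ablations.

    ``blank_mean`` is the mean of per-blank mean CPS values; ``blank_sd`` is
    the standard deviation of those per-blank means (0 for a single blank).
    With method ``blank_mean`` the threshold value equals ``blank_mean``;
    with ``blank_mean_plus_k_sigma`` it is ``blank_mean + k_sigma*blank_sd``.
    """

    value: float
    method: str
    n_blanks: int
    blank_mean: float
    blank_sd: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("threshold value must be >= 0")


@dataclass(frozen=True)
class Peak:
    """One integrated ablation pulse within an event segment.

    Indices are 0-based and inclusive, relative to the segment passed to
    :func:`detect_peak`.  ``integrated_response`` is summed CPS between the
    boundaries (times the dwell time in ``counts`` mode).  ``merged_suspect``
    marks a second super-threshold run outside the integrated window.
    """

    spot_id: str
    i_left: int
    i_right: int
    i_apex: int
    integrated_response: float
    edge_truncated: bool
    merged_suspect: bool = False

    def __post_init__(self) -> None:
        if not (self.i_left <= self.i_apex <= self.i_right):
            raise ValidationError("peak indices must satisfy i_left <= i_apex <= i_right")

    @property
    def width(self) -> int:
        return self.i_right - self.i_left + 1


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell integrated response, optional derived mass, and QC flags."""

    spot_id: str
    group: str
    integrated_response: float
    mass_fg: float | None = None
    flags: frozenset[str] = frozenset()

    def with_mass(self, mass_fg: float, extra_flags: frozenset[str] = frozenset()) -> "CellMeasurement":
        return CellMeasurement(
            spot_id=self.spot_id,
            group=self.group,
            integrated_response=self.integrated_response,
            mass_fg=mass_fg,
            flags=self.flags | extra_flags,
        )


def compute_blank_threshold(
    blank_segments: list[np.ndarray], config: RunConfig
) -> Threshold:
    """Average per-blank mean CPS values into the background threshold.

    Each blank segment is averaged on its own, then the per-blank means are
    averaged together (unweighted).  ``blank_sd`` is the SD (ddof=1) of the
    per-blank means, 0 when only one blank was collected.
    """
    if len(blank_segments) == 0:
        raise ValidationError("no blank measurements")
    means = []
    for i, seg in enumerate(blank_segments):
        seg = np.asarray(seg, dtype=float)
        if seg.size == 0:
            raise ValidationError(f"blank segment {i} is empty")
        means.append(float(seg.mean()))
    means = np.asarray(means)
    blank_mean = float(means.mean())
    blank_sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    if blank_mean == 0.0 and np.all(means == 0):
        log.warning("all blank segments are zero; threshold set to 0 CPS")
    if config.threshold_method == "blank_mean":
        value = blank_mean
    else:
        value = blank_mean + config.k_sigma * blank_sd
    return Threshold(
        value=value,
        method=config.threshold_method,
        n_blanks=len(means),
        blank_mean=blank_mean,
        blank_sd=blank_sd,
    )


def _runs_above(y: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Maximal contiguous runs (inclusive index pairs) with y > thr."""
    above = y > thr
    runs: list[tuple[int, int]] = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(y) - 1))
    return runs


def _is_local_min(y: np.ndarray, i: int) -> bool:
    """Value <= both neighbors; segment edges count as local minima."""
    left_ok = i == 0 or y[i] <= y[i - 1]
    right_ok = i == len(y) - 1 or y[i] <= y[i + 1]
    return left_ok and right_ok


def detect_peak(
    segment: np.ndarray,
    threshold: Threshold | float,
    config: RunConfig,
    spot_id: str = "",
    dwell_time: float = 1.0,
) -> Peak | None:
    """Locate and integrate the ablation pulse in one event segment.

    Returns ``None`` when no sample exceeds the threshold.  The core region is
    the contiguous super-threshold run containing the global maximum (earliest
    index on ties); boundaries extend outward per ``config.boundary_rule``.
    Hitting the segment edge before a boundary sets ``edge_truncated``.
    Super-threshold runs inside the window are absorbed; one outside it sets
    ``merged_suspect``.
    """
    y = np.asarray(segment, dtype=float)
    if y.size == 0:
        raise ValidationError(f"empty segment for {spot_id or 'event'}")
    thr = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    if not np.any(y > thr):
        return None
    i_apex = int(np.argmax(y))  # earliest index on ties
    runs = _runs_above(y, thr)
    core_start, core_end = next(r for r in runs if r[0] <= i_apex <= r[1])

    local_min_rule = config.boundary_rule == "local_min_at_or_below"

    def boundary_ok(j: int) -> bool:
        if y[j] > thr:
            return False
        return _is_local_min(y, j) if local_min_rule else True

    edge_truncated = False
    i_left = None
    for j in range(core_start - 1, -1, -1):
        if boundary_ok(j):
            i_left = j
            break
    if i_left is None:
        i_left = 0
        edge_truncated = True
    i_right = None
    for j in range(core_end + 1, len(y)):
        if boundary_ok(j):
            i_right = j
            break
    if i_right is None:
        i_right = len(y) - 1
        edge_truncated = True

    response = float(y[i_left : i_right + 1].sum())
    if config.integration_units == "counts":
        response *= dwell_time
    merged = any(r0 < i_left or r0 > i_right for r0, _ in runs)
    return Peak(
        spot_id=spot_id,
        i_left=i_left,
        i_right=i_right,
        i_apex=i_apex,
        integrated_response=response,
        edge_truncated=edge_truncated,
        merged_suspect=merged,
    )


def integrate_events(
    trace: TimeTrace,
    events: list[SpotEvent],
    threshold: Threshold,
    config: RunConfig,
    kinds: tuple[str, ...] = ("cell",),
) -> list[tuple[SpotEvent, Peak | None]]:
    """Run :func:`detect_peak` over the events of the requested kinds."""
    out = []
    t0, t1 = float(trace.times[0]), float(trace.times[-1])
    for ev in events:
        if ev.kind not in kinds:
            continue
        if ev.t_end <= t0 or ev.t_start > t1:
            raise ValidationError(f"event window outside trace for {ev.spot_id}")
        seg = trace.segment(ev.t_start, ev.t_end)
        if seg.size == 0:
            raise ValidationError(f"event window outside trace for {ev.spot_id}")
        peak = detect_peak(
            seg, threshold, config, spot_id=ev.spot_id, dwell_time=trace.dwell_time
        )
        out.append((ev, peak))
    return out


def quantify_events(
    trace: TimeTrace,
    events: list[SpotEvent],
    threshold: Threshold,
    config: RunConfig,
) -> list[CellMeasurement]:
    """One measurement per cell event, in event order.

    Cells with no super-threshold sample are reported with response 0 and
    flag ``BELOW_LOD`` rather than dropped.  Standards are handled by the
    calibration module; blanks are excluded.
    """
    measurements = []
    for ev, peak in integrate_events(trace, events, threshold, config, kinds=("cell",)):
        if peak is None:
            measurements.append(
                CellMeasurement(
                    spot_id=ev.spot_id,
                    group=ev.group,
                    integrated_response=0.0,
                    flags=frozenset({"BELOW_LOD"}),
                )
            )
            continue
        flags = set()
        if peak.edge_truncated:
            flags.add("EDGE_TRUNCATED")
        if peak.merged_suspect:
            flags.add("MERGED_SUSPECT")
        measurements.append(
            CellMeasurement(
                spot_id=ev.spot_id,
                group=ev.group,
                integrated_response=peak.integrated_response,
                flags=frozenset(flags),
            )
        )
    return measurements


def blank_window_responses(
    trace: TimeTrace, events: list[SpotEvent], config: RunConfig
) -> np.ndarray:
    """Integrated whole-window responses of the blank events (for LOD/LOQ)."""
    responses = []
    for ev in events:
        if ev.kind != "blank":
            continue
        seg = trace.segment(ev.t_start, ev.t_end)
        if seg.size == 0:
            raise ValidationError(f"event window outside trace for {ev.spot_id}")
        r = float(seg.sum())
        if config.integration_units == "counts":
            r *= trace.dwell_time
        responses.append(r)
    return np.asarray(responses, dtype=float)
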