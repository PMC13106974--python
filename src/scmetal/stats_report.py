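"""Group summaries, Mann-Whitney comparisons, and run reports.

Group comparisons follow the reference workflow: an unadjusted two-sided
Mann-Whitney U test per pair (exact p when the smaller group has at most 8
values and there are no ties, normal approximation with tie correction
otherwise), with fold change computed on group means.  Holm adjustment across
a batch of comparisons is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve
from .errors import ValidationError
from .event_quant import CellMeasurement, Threshold

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize_group",
    "summarize_by_group",
    "compare_groups",
    "holm_adjust",
    "render_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD/median per-cell mass for one sample or condition."""

    group: str
    n_cells: int
    mean_fg: float
    sd_fg: float
    median_fg: float


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided Mann-Whitney U comparison between two groups."""

    group_a: str
    group_b: str
    U: float
    p_value: float
    fold_change_of_means: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value outside [0, 1]")


def summarize_group(
    measurements: Sequence[CellMeasurement],
    include_below_lod: bool = True,
    group: str | None = None,
) -> GroupSummary:
    """Arithmetic mean, SD (ddof=1), and median of per-cell masses.

    ``include_below_lod=False`` drops cells flagged BELOW_LOD before
    summarizing (the reference workflow's treatment of undetected cells is
    unstated, so both behaviors are exposed).
    """
    used = [
        m
        for m in measurements
        if include_below_lod or "BELOW_LOD" not in m.flags
    ]
    if not used:
        raise ValidationError("no measurements left after filtering")
    masses = np.array(
        [m.mass_fg if m.mass_fg is not None else 0.0 for m in used], dtype=float
    )
    if group is None:
        groups = {m.group for m in used}
        group = groups.pop() if len(groups) == 1 else "all"
    sd = float(masses.std(ddof=1)) if len(masses) > 1 else 0.0
    return GroupSummary(
        group=group,
        n_cells=len(masses),
        mean_fg=float(masses.mean()),
        sd_fg=sd,
        median_fg=float(np.median(masses)),
    )


def summarize_by_group(
    measurements: Sequence[CellMeasurement], include_below_lod: bool = True
) -> list[GroupSummary]:
    """One summary per group label, sorted by group name."""
    by_group: dict[str, list[CellMeasurement]] = {}
    for m in measurements:
        by_group.setdefault(m.group, []).append(m)
    return [
        summarize_group(ms, include_below_lod=include_below_lod, group=g)
        for g, ms in sorted(by_group.items())
    ]


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test with fold change of means (b over a).

    The exact null distribution is used when ``min(n_a, n_b) <= 8`` and there
    are no ties across the pooled sample; otherwise the normal approximation
    with tie-corrected variance (and no continuity correction, so identical
    groups give p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    mean_a = float(a.mean())
    fold = float(b.mean()) / mean_a if mean_a != 0 else float("inf")
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        U=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        fold_change_of_means=fold,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def render_report(
    path: str | Path,
    threshold: Threshold,
    curve: CalibrationCurve | None,
    lod: float | None,
    loq: float | None,
    measurements: Sequence[CellMeasurement],
    comparisons: Sequence[ComparisonResult] = (),
    include_below_lod: bool = True,
    blank_strata: Sequence[tuple[str, float]] = (),
) -> str:
    """Write the per-run QC/summary report; returns the report text.

    Content is deterministic given the same inputs: threshold provenance,
    calibration diagnostics, LOD/LOQ, per-group summaries, comparisons, and
    the per-cell table sorted by spot_id.
    """
    lines: list[str] = []
    lines.append("# scmetal run report")
    lines.append("")
    lines.append("## Background threshold")
    lines.append(f"value_cps: {threshold.value!r}")
    lines.append(f"method: {threshold.method}")
    lines.append(f"n_blanks: {threshold.n_blanks}")
    lines.append(f"blank_mean_cps: {threshold.blank_mean!r}")
    lines.append(f"blank_sd_cps: {threshold.blank_sd!r}")
    if blank_strata:
        lines.append("per_blank_means_by_time:")
        for spot_id, mean in blank_strata:
            lines.append(f"  {spot_id}: {mean!r}")
    lines.append("")
    if curve is not None:
        lines.append("## Calibration")
        lines.append(f"slope_response_per_fg: {curve.slope!r}")
        lines.append(f"intercept_response: {curve.intercept!r}")
        lines.append(f"r_squared: {curve.r_squared!r}")
        lines.append(f"residual_sd: {curve.residual_sd!r}")
        lines.append(f"n_points: {curve.n_points}")
        if lod is not None:
            lines.append(f"lod_fg: {lod!r}")
        if loq is not None:
            lines.append(f"loq_fg: {loq!r}")
        lines.append("")
    lines.append("## Group summaries")
    lines.append("group,n_cells,mean_fg,sd_fg,median_fg")
    for s in summarize_by_group(measurements, include_below_lod=include_below_lod):
        lines.append(
            f"{s.group},{s.n_cells},{s.mean_fg!r},{s.sd_fg!r},{s.median_fg!r}"
        )
    lines.append("")
    if comparisons:
        lines.append("## Comparisons (Mann-Whitney, two-sided)")
        lines.append("group_a,group_b,U,p_value,fold_change_of_means")
        for c in comparisons:
            lines.append(
                f"{c.group_a},{c.group_b},{c.U!r},{c.p_value!r},"
                f"{c.fold_change_of_means!r}"
            )
        lines.append("")
    lines.append("## Per-cell measurements")
    lines.append("spot_id,group,integrated_response,mass_fg,flags")
    from .trace_io import FLAG_TOKENS

    for m in sorted(measurements, key=lambda m: m.spot_id):
        mass = "" if m.mass_fg is None else repr(float(m.mass_fg))
        flags = ";".join(t for t in FLAG_TOKENS if t in m.flags)
        lines.append(
            f"{m.spot_id},{m.group},{float(m.integrated_response)!r},{mass},{flags}"
        )
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
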