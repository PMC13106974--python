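"""Seeded generator of synthetic LA-ICP-MS runs with ground truth.

The simulator emulates a single-analyte, time-resolved acquisition over a
chamber slide: a flat Poisson baseline, short super-threshold ablation pulses
whose total counts are proportional to per-cell analyte mass, cell-free blank
windows, standard-droplet pulses at the calibration ladder masses, and a slow
multiplicative sensitivity drift.  Counting noise is Poisson on counts per
dwell interval, then converted to CPS — physically faithful for pulse-counting
detectors and variance-predictable in tests.

Spots are laid out sequentially: the calibration ladder is ablated in
``standard_replicates`` blocks spread through the run (so repeated standards
double as drift anchors), with cells and evenly interspersed blanks between
the blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationStandard
from .errors import FormatError, ValidationError
from .trace_io import SpotEvent, TimeTrace, write_events, write_trace

__all__ = ["SimParams", "SimTruth", "simulate_run", "simulate_calibration", "write_run"]

#: Nominal masses (fg) of the gelatin micro-droplet calibration ladder.
STANDARD_LADDER = (0.0, 173.0, 351.0, 684.0, 1821.0, 3455.0)

_DISTRIBUTIONS = ("normal_truncated_at_zero", "lognormal")
_PULSE_SHAPES = ("gaussian", "exp_modified_gaussian")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic run.

    Defaults describe a resting-T-cell iron measurement: per-cell masses from
    a zero-truncated normal with mean 1.83 fg and SD 0.27 fg, a sensitivity of
    10,000 counts per fg, a baseline of 100 counts per dwell interval, 20
    blank windows, and the six-mass standard ladder ablated in six blocks
    spread through the run (one per ~20 cells, doubling as drift anchors).  The
    ablation pulse defaults to a 1 s FWHM Gaussian sampled at a 0.2 s dwell
    (about five readings per pulse) inside a 6 s spot window.
    """

    n_cells: int = 100
    mass_mean: float = 1.83  # fg
    mass_sd: float = 0.27  # fg
    mass_distribution: str = "normal_truncated_at_zero"
    sensitivity: float = 10_000.0  # counts per fg
    baseline_rate: float = 100.0  # counts per dwell interval
    dwell_time: float = 0.2  # s
    pulse_shape: str = "gaussian"
    pulse_width: float = 1.0  # FWHM, s
    drift_slope: float = 0.0  # fractional sensitivity change per s
    n_blanks: int = 20
    standard_masses: tuple[float, ...] = STANDARD_LADDER
    standard_replicates: int = 6
    seed: int = 0
    poisson_noise: bool = True
    spot_duration: float = 6.0  # s per ablation window
    group: str = "sim"

    def __post_init__(self) -> None:
        if self.mass_distribution not in _DISTRIBUTIONS:
            raise ValidationError(f"unknown mass_distribution {self.mass_distribution!r}")
        if self.pulse_shape not in _PULSE_SHAPES:
            raise ValidationError(f"unknown pulse_shape {self.pulse_shape!r}")
        for name in ("sensitivity", "dwell_time", "pulse_width", "spot_duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.mass_sd < 0 or self.baseline_rate < 0:
            raise ValidationError("mass_sd and baseline_rate must be >= 0")
        if self.n_cells < 0 or self.n_blanks < 0 or self.standard_replicates < 0:
            raise ValidationError("counts must be >= 0")
        if self.spot_duration < 3.0 * self.pulse_width:
            raise ValidationError(
                "pulse wider than its event window: spot_duration must be >= 3*pulse_width"
            )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated cell or standard ablation."""

    spot_id: str
    true_mass: float  # fg
    emitted_counts: float  # expected total pulse counts (exact when noiseless)
    window: tuple[float, float]
    drift_factor_at_event: float

    def __post_init__(self) -> None:
        if self.emitted_counts < 0:
            raise ValidationError("emitted_counts must be >= 0")


def _draw_masses(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_cells
    if params.mass_sd == 0:
        return np.full(n, params.mass_mean)
    if params.mass_distribution == "normal_truncated_at_zero":
        out = np.empty(n)
        filled = 0
        while filled < n:  # rejection sampling; acceptance ~1 for mean >> sd
            draw = rng.normal(params.mass_mean, params.mass_sd, size=n - filled)
            keep = draw[draw >= 0]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out
    cv2 = (params.mass_sd / params.mass_mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(params.mass_mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=n)


def _pulse_weights(t: np.ndarray, center: float, params: SimParams) -> np.ndarray:
    """Discrete pulse profile over one spot window, normalized to sum to 1."""
    sigma = params.pulse_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if params.pulse_shape == "gaussian":
        w = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    else:  # exponentially modified Gaussian: Gaussian onset, exponential tail
        from scipy.stats import exponnorm

        tau = params.pulse_width / 2.0
        w = exponnorm.pdf(t, K=tau / sigma, loc=center - tau, scale=sigma)
    total = w.sum()
    if total <= 0:
        raise ValidationError("pulse profile has no support inside the window")
    return w / total


def _spot_plan(params: SimParams) -> list[tuple[str, str, float, str]]:
    """Ordered (spot_id, kind, mass, group) plan for the whole run."""
    def ladder_block(b: int, descending: bool) -> list[tuple[str, str, float, str]]:
        masses = sorted(params.standard_masses, reverse=descending)
        return [
            (f"std_b{b}_m{int(round(m))}", "standard", float(m), "cal")
            for m in masses
        ]
    middle: list[tuple[str, str, float, str]] = []
    blank_every = (
        max(1, round(params.n_cells / params.n_blanks)) if params.n_blanks else 0
    )
    b_used = 0
    for c in range(params.n_cells):
        middle.append((f"cell_{c:03d}", "cell", np.nan, params.group))
        if params.n_blanks and (c + 1) % blank_every == 0 and b_used < params.n_blanks:
            middle.append((f"blank_{b_used:03d}", "blank", 0.0, "blank"))
            b_used += 1
    while b_used < params.n_blanks:
        middle.append((f"blank_{b_used:03d}", "blank", 0.0, "blank"))
        b_used += 1

    # Bracket the run with the drift monitor: the first block leads with the
    # highest (reference) mass and the last block ends with it, so every cell
    # lies inside the anchored span and no clamped extrapolation is needed.
    nb = params.standard_replicates
    if nb == 0:
        return middle
    if nb == 1:
        return ladder_block(0, descending=True) + middle
    plan: list[tuple[str, str, float, str]] = []
    cut_points = [round(i * len(middle) / (nb - 1)) for i in range(nb)]
    prev = 0
    for b, cut in enumerate(cut_points):
        plan.extend(middle[prev:cut])
        plan.extend(ladder_block(b, descending=(b == 0)))
        prev = cut
    plan.extend(middle[prev:])
    return plan


def simulate_run(
    params: SimParams,
) -> tuple[TimeTrace, list[SpotEvent], list[SimTruth]]:
    """Generate one synthetic acquisition: trace, event log, and ground truth.

    Each spot occupies a half-open window of ``spot_duration`` seconds with
    its pulse centered; per-sample counts are Poisson around
    ``baseline_rate + total_counts * weight`` where ``total_counts`` is
    ``true_mass * sensitivity * drift_factor`` at the event center.  The same
    seed reproduces the run byte-for-byte.
    """
    rng = np.random.default_rng(params.seed)
    plan = _spot_plan(params)
    masses = iter(_draw_masses(params, rng))
    n_per_spot = int(round(params.spot_duration / params.dwell_time))
    total_samples = n_per_spot * len(plan)
    times = np.arange(total_samples) * params.dwell_time
    run_duration = total_samples * params.dwell_time
    if params.drift_slope != 0.0 and 1.0 + params.drift_slope * run_duration <= 0:
        raise ValidationError("drift_slope drives sensitivity non-positive within the run")

    expected = np.full(total_samples, float(params.baseline_rate))
    events: list[SpotEvent] = []
    truths: list[SimTruth] = []
    for k, (spot_id, kind, mass, group) in enumerate(plan):
        sl = slice(k * n_per_spot, (k + 1) * n_per_spot)
        t_start = times[sl][0]
        t_end = t_start + params.spot_duration
        center = t_start + 0.5 * params.spot_duration
        drift = 1.0 + params.drift_slope * center
        true_mass = float(next(masses)) if kind == "cell" else float(mass)
        if kind != "blank":
            total_counts = true_mass * params.sensitivity * drift
            if total_counts > 0:
                expected[sl] += total_counts * _pulse_weights(times[sl], center, params)
            truths.append(
                SimTruth(
                    spot_id=spot_id,
                    true_mass=true_mass,
                    emitted_counts=total_counts,
                    window=(float(t_start), float(t_end)),
                    drift_factor_at_event=drift,
                )
            )
        events.append(
            SpotEvent(
                spot_id=spot_id,
                kind=kind,
                t_start=float(t_start),
                t_end=float(t_end),
                nominal_mass=float(mass) if kind == "standard" else None,
                group=group,
            )
        )

    counts = rng.poisson(expected).astype(float) if params.poisson_noise else expected
    trace = TimeTrace(
        acquisition_id=f"sim_seed{params.seed}",
        analyte="56Fe",
        times=times,
        intensities=counts / params.dwell_time,
        dwell_time=params.dwell_time,
    )
    return trace, events, truths


def simulate_calibration(
    params: SimParams, multiplicative_cv: float | None = None
) -> list[CalibrationStandard]:
    """Standalone integrated ladder responses (counts), noise per ``params``.

    With ``multiplicative_cv`` the Poisson model is replaced by multiplicative
    Gaussian noise of that coefficient of variation, useful for linearity
    studies at a fixed relative error.
    """
    if len(set(params.standard_masses)) < 2:
        raise ValidationError("need at least 2 distinct standard masses")
    rng = np.random.default_rng(params.seed)
    out: list[CalibrationStandard] = []
    t = 0.0
    for rep in range(max(1, params.standard_replicates)):
        for m in params.standard_masses:
            true = m * params.sensitivity
            if multiplicative_cv is not None:
                resp = true * (1.0 + multiplicative_cv * rng.standard_normal())
            elif params.poisson_noise:
                resp = float(rng.poisson(true))
            else:
                resp = true
            out.append(
                CalibrationStandard(
                    spot_id=f"std_r{rep}_m{int(round(m))}",
                    nominal_mass=float(m),
                    integrated_response=float(resp),
                    t_mid=t + 0.5 * params.spot_duration,
                )
            )
            t += params.spot_duration
    return out


def write_run(
    trace: TimeTrace,
    events: Sequence[SpotEvent],
    truths: Sequence[SimTruth],
    out_dir: str | Path,
) -> None:
    """Write trace.csv / events.csv / truth.csv in the canonical dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_trace(trace, out_dir / "trace.csv")
    write_events(events, out_dir / "events.csv")
    pd.DataFrame(
        [
            {
                "spot_id": tr.spot_id,
                "true_mass_fg": tr.true_mass,
                "emitted_counts": tr.emitted_counts,
                "t_start": tr.window[0],
                "t_end": tr.window[1],
                "drift_factor": tr.drift_factor_at_event,
            }
            for tr in truths
        ]
    ).to_csv(out_dir / "truth.csv", index=False)


def read_sim_params(path: str | Path) -> SimParams:
    """Read simulator parameters from a flat YAML mapping; unknown keys error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(SimParams)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown simulator key(s) {sorted(unknown)}")
    if "standard_masses" in raw:
        raw["standard_masses"] = tuple(float(m) for m in raw["standard_masses"])
    return SimParams(**raw)
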