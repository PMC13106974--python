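"""End-to-end quantification: trace + event log + config -> per-cell masses.

Order of operations: blank threshold, standard integration, optional drift
model (anchored to the highest standard mass), drift correction of standard
and cell responses, calibration fit, LOD/LOQ from integrated blank windows,
then conversion of each cell's integrated response to femtograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    CalibrationCurve,
    CalibrationStandard,
    DriftModel,
    build_drift_model,
    correct_drift,
    fit_calibration,
    identity_drift_model,
    lod_loq,
    response_to_mass,
)
from .errors import ValidationError
from .event_quant import (
    CellMeasurement,
    Threshold,
    blank_window_responses,
    compute_blank_threshold,
    integrate_events,
    quantify_events,
)
from .trace_io import RunConfig, SpotEvent, TimeTrace

__all__ = ["RunResult", "quantify_run", "extract_standards"]


@dataclass(frozen=True)
class RunResult:
    """Everything one quantification run produces."""

    threshold: Threshold
    standards: list[CalibrationStandard]
    curve: CalibrationCurve
    drift_model: DriftModel
    lod: float
    loq: float
    measurements: list[CellMeasurement]
    blank_strata: list[tuple[str, float]]


def extract_standards(
    trace: TimeTrace,
    events: list[SpotEvent],
    threshold: Threshold,
    config: RunConfig,
) -> list[CalibrationStandard]:
    """Integrate standard events with the identical peak rule used for cells.

    A standard with no super-threshold sample (typical for the 0 fg droplet
    when the threshold sits at the blank mean and noise is low) contributes a
    response of 0.
    """
    out = []
    for ev, peak in integrate_events(trace, events, threshold, config, kinds=("standard",)):
        out.append(
            CalibrationStandard(
                spot_id=ev.spot_id,
                nominal_mass=float(ev.nominal_mass),
                integrated_response=0.0 if peak is None else peak.integrated_response,
                t_mid=ev.t_mid,
            )
        )
    return out


def quantify_run(
    trace: TimeTrace,
    events: list[SpotEvent],
    config: RunConfig,
    use_intercept: bool = True,
    allow_negative: bool = False,
) -> RunResult:
    """Run the full quantification workflow on one acquisition."""
    blanks = [ev for ev in events if ev.kind == "blank"]
    if not blanks:
        raise ValidationError("no blank measurements in the event log")
    blank_segments = [trace.segment(ev.t_start, ev.t_end) for ev in blanks]
    threshold = compute_blank_threshold(blank_segments, config)
    blank_strata = [
        (ev.spot_id, float(seg.mean()))
        for ev, seg in zip(blanks, blank_segments)
    ]

    standards = extract_standards(trace, events, threshold, config)
    if len(standards) < 2:
        raise ValidationError("need at least 2 standards to calibrate")

    if config.drift_correction == "piecewise_linear":
        reference_mass = max(s.nominal_mass for s in standards)
        drift_model = build_drift_model(standards, reference_mass)
    else:
        drift_model = identity_drift_model()
    corrected_standards = [
        CalibrationStandard(
            spot_id=s.spot_id,
            nominal_mass=s.nominal_mass,
            integrated_response=correct_drift(s.integrated_response, s.t_mid, drift_model),
            t_mid=s.t_mid,
        )
        for s in standards
    ]
    curve = fit_calibration(corrected_standards)

    blank_resp = blank_window_responses(trace, events, config)
    blank_sd_resp = float(blank_resp.std(ddof=1)) if blank_resp.size > 1 else 0.0
    lod, loq = lod_loq(blank_sd_resp, curve, config)

    raw = quantify_events(trace, events, threshold, config)
    cell_mid = {ev.spot_id: ev.t_mid for ev in events if ev.kind == "cell"}
    measurements = []
    for m in raw:
        resp = correct_drift(m.integrated_response, cell_mid[m.spot_id], drift_model)
        mass, flags = response_to_mass(
            resp,
            curve,
            config,
            lod=lod,
            loq=loq,
            use_intercept=use_intercept,
            allow_negative=allow_negative,
        )
        measurements.append(
            CellMeasurement(
                spot_id=m.spot_id,
                group=m.group,
                integrated_response=resp,
                mass_fg=mass,
                flags=m.flags | flags,
            )
        )
    return RunResult(
        threshold=threshold,
        standards=corrected_standards,
        curve=curve,
        drift_model=drift_model,
        lod=lod,
        loq=loq,
        measurements=measurements,
        blank_strata=blank_strata,
    )
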