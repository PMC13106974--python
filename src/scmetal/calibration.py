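"""External calibration with micro-droplet standards, drift correction, LOD/LOQ.

Gelatin micro-droplets doped with known analyte masses (fg) are fully ablated
and integrated with the same peak rule as cells.  An ordinary least-squares
line of integrated response on nominal mass converts cell responses to
femtograms; because the 0 fg droplet is part of the fit, the intercept
estimates the blank contribution to an integrated window and is subtracted by
default (a slope-only mode is available).  Slow multiplicative sensitivity
drift is corrected by anchoring repeated standards of one reference mass and
interpolating a relative-sensitivity factor piecewise linearly over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .trace_io import RunConfig

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "DriftModel",
    "fit_calibration",
    "build_drift_model",
    "correct_drift",
    "response_to_mass",
    "lod_loq",
    "write_curve",
    "read_curve",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationStandard:
    """One integrated standard-droplet ablation."""

    spot_id: str
    nominal_mass: float  # fg
    integrated_response: float
    t_mid: float = 0.0  # seconds; used for drift anchoring

    def __post_init__(self) -> None:
        if self.nominal_mass < 0:
            raise ValidationError(f"{self.spot_id}: nominal_mass must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line response = slope*mass + intercept with fit diagnostics."""

    slope: float  # response units per fg
    intercept: float  # response units
    r_squared: float
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("inverted calibration: slope must be > 0")
        if self.n_points < 2:
            raise ValidationError("calibration needs at least 2 points")


@dataclass(frozen=True)
class DriftModel:
    """Piecewise-linear relative sensitivity over the run.

    ``anchor_factors[i]`` is the sensitivity at ``anchor_times[i]`` relative to
    the first anchor (which is 1 by construction).  Outside the anchored span
    the factor is clamped to the nearest anchor.
    """

    anchor_times: np.ndarray
    anchor_factors: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.anchor_times, dtype=float)
        f = np.asarray(self.anchor_factors, dtype=float)
        object.__setattr__(self, "anchor_times", t)
        object.__setattr__(self, "anchor_factors", f)
        if t.shape != f.shape or t.ndim != 1 or t.size == 0:
            raise ValidationError("drift anchors must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("anchor_times must be strictly increasing")
        if np.any(f <= 0):
            raise ValidationError("drift factors must be > 0")

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.anchor_factors == 1.0))

    def factor(self, t: float | np.ndarray) -> float | np.ndarray:
        """Interpolated relative sensitivity at time ``t`` (clamped outside)."""
        out = np.interp(t, self.anchor_times, self.anchor_factors)
        return float(out) if np.isscalar(t) else out


def identity_drift_model() -> DriftModel:
    return DriftModel(anchor_times=np.array([0.0]), anchor_factors=np.array([1.0]))


def fit_calibration(standards: list[CalibrationStandard]) -> CalibrationCurve:
    """Ordinary least-squares line of integrated response on nominal mass.

    Replicate standards all enter individually (no pre-averaging), preserving
    residual degrees of freedom.  r^2 is the squared Pearson correlation.
    """
    if len(standards) < 2:
        raise ValidationError("calibration needs at least 2 standards")
    x = np.array([s.nominal_mass for s in standards], dtype=float)
    y = np.array([s.integrated_response for s in standards], dtype=float)
    if np.all(x == x[0]):
        raise ValidationError("all standard masses identical; cannot fit a line")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise ValidationError("inverted calibration: fitted slope <= 0")
    resid = y - (slope * x + intercept)
    dof = len(x) - 2
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rvalue**2),
        residual_sd=residual_sd,
        n_points=len(x),
    )


def build_drift_model(
    standards: list[CalibrationStandard], reference_mass: float
) -> DriftModel:
    """Anchor relative sensitivity to repeated standards of one mass.

    Needs >= 2 standards of ``reference_mass`` at distinct times; otherwise an
    identity model is returned with a warning.  Factors are responses divided
    by the earliest anchor's response.
    """
    anchors = sorted(
        (s for s in standards if s.nominal_mass == reference_mass),
        key=lambda s: s.t_mid,
    )
    times = np.array([s.t_mid for s in anchors], dtype=float)
    if len(anchors) < 2 or np.unique(times).size < 2:
        log.warning(
            "need >=2 standards of mass %g fg at distinct times for drift "
            "anchoring; using identity model",
            reference_mass,
        )
        return identity_drift_model()
    responses = np.array([s.integrated_response for s in anchors], dtype=float)
    if np.any(responses == 0):
        raise ValidationError("zero response at a drift anchor")
    return DriftModel(anchor_times=times, anchor_factors=responses / responses[0])


def correct_drift(
    measurement_response: float, t_mid: float, model: DriftModel
) -> float:
    """Divide a raw response by the interpolated sensitivity factor at t_mid."""
    return float(measurement_response) / model.factor(t_mid)


def response_to_mass(
    response: float,
    curve: CalibrationCurve,
    config: RunConfig,
    lod: float | None = None,
    loq: float | None = None,
    use_intercept: bool = True,
    allow_negative: bool = False,
) -> tuple[float, frozenset[str]]:
    """Invert the calibration line: mass = (response - intercept) / slope.

    ``use_intercept=False`` gives the strict slope-only conversion.  Negative
    masses are clamped to 0 and flagged ``BELOW_LOD`` unless
    ``allow_negative``.  When LOD/LOQ are supplied, masses below them are
    flagged ``BELOW_LOD`` / ``BELOW_LOQ``.
    """
    intercept = curve.intercept if use_intercept else 0.0
    mass = (float(response) - intercept) / curve.slope
    flags: set[str] = set()
    if mass <= 0 and not allow_negative:
        mass = max(mass, 0.0)
        flags.add("BELOW_LOD")
    if lod is not None and mass < lod:
        flags.add("BELOW_LOD")
    if loq is not None and mass < loq:
        flags.add("BELOW_LOQ")
    return mass, frozenset(flags)


def lod_loq(
    blank_sd_response: float, curve: CalibrationCurve, config: RunConfig
) -> tuple[float, float]:
    """3-sigma / 10-sigma detection and quantification limits in fg.

    ``blank_sd_response`` is the SD of integrated blank-window responses in
    the same response units as the curve.  A zero SD yields LOD = LOQ = 0
    with a warning (flags then never fire).
    """
    if curve.slope <= 0:
        raise ValidationError("LOD/LOQ undefined for non-positive slope")
    if blank_sd_response == 0:
        log.warning("blank response SD is 0; LOD/LOQ set to 0 fg")
    lod = config.lod_k * blank_sd_response / curve.slope
    loq = config.loq_k * blank_sd_response / curve.slope
    return float(lod), float(loq)


# ---------------------------------------------------------------------------
# persistence (flat key:value, reusable across chambers)

_CURVE_FIELDS = ("slope", "intercept", "r_squared", "residual_sd", "n_points")


def write_curve(curve: CalibrationCurve, path) -> None:
    with open(path, "w") as fh:
        for name in _CURVE_FIELDS:
            fh.write(f"{name}: {getattr(curve, name)!r}\n")


def read_curve(path) -> CalibrationCurve:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CalibrationCurve(
        slope=float(raw["slope"]),
        intercept=float(raw["intercept"]),
        r_squared=float(raw["r_squared"]),
        residual_sd=float(raw["residual_sd"]),
        n_points=int(raw["n_points"]),
    )
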