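# Methods

This note documents the models, numerical choices, and limitations behind
`scmetal`. It is the design record a maintainer should read before changing
defaults.

## Signal model

A pulse-counting ICP-MS detector reports, per dwell interval `τ`, a count
drawn from a Poisson distribution whose rate is baseline plus any ablation
pulse passing through the plasma; intensities are reported as CPS =
counts/τ. The simulator follows this model literally: for sample `i` at time
`t_i` inside a spot window,

    counts_i ~ Poisson( B + M·S·f(t_c)·w_i )

where `B` is the baseline rate (counts per dwell), `M` the true analyte mass
(fg), `S` the sensitivity (counts per fg), `f(t_c)` the relative sensitivity
(drift) at the event center, and `w_i` a discrete pulse profile normalized to
sum to 1 over the window, so the *expected total pulse counts are exactly
M·S·f*. This normalization is what makes the noiseless conservation tests
exact, and Poisson-on-counts is what makes variance predictions testable.
In noiseless mode the expectation is emitted directly (non-integer counts are
deliberate there).

## Background threshold

Blank ablations (cell-free spots) are each averaged; the threshold is the
unweighted mean of the per-blank means. `blank_sd` is the SD *of the
per-blank means* (0 for one blank), which is what the optional
`blank_mean + k·σ` method uses. Note this is the between-blank spread, not
the per-sample counting noise: with a Poisson baseline the per-sample spread
is much larger, so even `k = 5` on between-blank σ does not suppress
single-sample noise excursions. The per-run report stratifies blank means by
collection time so a drifting background is visible regardless of whether
blanks were collected independently or interleaved (the two collection
schemes are aggregated identically).

## Peak boundaries and integration

The integration window is the contiguous super-threshold run containing the
segment maximum (earliest index on ties), extended outward to the "first
downward peak at or below the threshold". Two formalizations are offered:

- `local_min_at_or_below` (default): the nearest sub-threshold sample that is
  also a local minimum (≤ both neighbors; segment edges qualify). This
  captures the pulse tail without truncating at the first noise dip.
- `first_at_or_below`: the nearest sub-threshold sample.

If the search reaches the segment edge, the edge is used and the measurement
is flagged `EDGE_TRUNCATED`. Super-threshold runs that fall inside the chosen
window are absorbed; any run outside it flags `MERGED_SUSPECT`. With the
default threshold at the blank *mean*, roughly half of all baseline samples
lie above threshold, so isolated noise excursions raise this flag on most
windows; it becomes a genuine merged-event indicator only under a stricter
`k·σ` threshold. Overlapping events are flagged, never deconvolved.

The integrated response is the plain sum of CPS between the boundaries
(inclusive); `counts` mode multiplies by the dwell time. No per-sample
baseline is subtracted inside the window: standards are integrated with the
identical rule, so the calibration intercept absorbs the baseline
contribution (see below). The implementation is verified property-wise
against an exhaustive enumeration of all candidate boundary pairs.

## Calibration, intercept, and extrapolation error

Responses of the gelatin micro-droplet ladder (defaults 0, 173, 351, 684,
1821, 3455 fg; replicates enter individually) are fitted by unweighted OLS of
response on mass. Per-cell mass is `(R − intercept)/slope` by default. The
intercept is retained because the integration window of a real cell contains
a baseline contribution (≈ window-width × baseline CPS) that the 0 fg
standard anchors; slope-only conversion (`use_intercept=False`, provided for
strict replication of slope-only workflows) leaves that contribution in the
mass and biases small cells high by several percent under the default
simulation conditions.

Two error sources matter when converting ~2 fg cells from a ladder that
starts at 173 fg (a 100-fold extrapolation below the calibration range):

- *Intercept noise.* Counting noise on the high-mass standards propagates
  into the intercept through leverage; with six ladder blocks the intercept's
  standard error corresponds to roughly 2–3% of a 1.8 fg cell and is
  common-mode across all cells in a run. More ladder blocks shrink it as
  1/√blocks.
- *Window-width mismatch.* Cell windows and standard windows contain slightly
  different numbers of baseline samples, so the fitted intercept compensates
  the cell baseline only approximately.

Both effects are visible in the pipeline tests; the default of six ladder
blocks per ~100 cells keeps the combined mean-recovery error within ±5% for
typical seeds.

r² is reported as the squared Pearson correlation; `residual_sd` uses
n − 2 degrees of freedom. A non-positive fitted slope is rejected as an
inverted calibration. Weighted or robust regression is deliberately out of
scope.

## Drift correction

Instrument sensitivity drifts slowly over a run. Repeated standards of one
reference mass (the highest, by default) anchor relative factors
`f_k = R(t_k)/R(t_1)`; between anchors the factor is interpolated linearly,
outside the anchored span it is clamped to the nearest anchor. Responses are
divided by `f(t_mid)` before calibration and conversion. Single-mass
anchoring needs the fewest standards; refitting full curves per block is a
configuration away (run the ladder more often) but not required.

The simulator lays standards out in blocks spread through the run and
*brackets* it: the first block leads with the reference mass and the last
block ends with it, so every cell lies inside the anchored span and the
clamp never extrapolates. On noiseless linear drift the correction is exact
(piecewise-linear interpolation of a linear factor), which the tests assert
at 1e-9; with counting noise the corrected masses match a no-drift run
within the counting-noise error of the mean.

## LOD / LOQ

`LOD = k_lod·σ_blank / slope` and `LOQ = k_loq·σ_blank / slope` with the
3σ/10σ convention, where `σ_blank` is the SD of *integrated whole-window*
blank responses, i.e. the noise of an integration that found no peak. Masses
below the limits are flagged (`BELOW_LOD`, `BELOW_LOQ`), never censored;
negative fitted masses are clamped to 0 and flagged unless raw negatives are
requested. Zero blank spread yields zero limits with a logged warning.

## Bulk conversion

`total_pg = c(µg/L)·V(L)·10⁶`; `pg/10⁶ cells = total_pg/(cells/10⁶)`;
`fg/cell = pg/10⁶ cells ÷ 1000`. Replicates below the limit of
quantification are excluded from the replicate mean (not zero-imputed); a
sample is BLQ only if all its replicates are. When only a pre-split cell
count is known, `split_replicates` divides it evenly (default triplicate).

## Simulator defaults and what they emulate

| parameter | default | why |
|---|---|---|
| mass_mean, mass_sd | 1.83, 0.27 fg | resting-T-cell iron summary the toolkit targets |
| mass_distribution | zero-truncated normal | tight homeostatic spread; lognormal offered for heterogeneous activated cells |
| sensitivity | 10,000 counts/fg | gives ≥10⁴ counts for a ~2 fg cell, comfortably above counting noise |
| baseline_rate | 100 counts/dwell | low but non-negligible background after blank subtraction is impossible |
| dwell_time | 0.2 s | ≈5 readings per pulse |
| pulse_width | 1.0 s FWHM | configurable placeholder for a slow-washout ablation cell |
| spot_duration | 6 s | comfortably holds a 1 s FWHM pulse; pulses wider than a third of the window are rejected |
| n_blanks | 20 | one blank per ~5 cells |
| standard_replicates | 6 ladder blocks | "a series of standards throughout the run": one block per ~20 cells, doubling as drift anchors and controlling intercept noise |

The simulator does **not** model aerosol transport/washout physics, spot
geometry, polyatomic interferences (assumed removed upstream by the
collision/reaction cell), detector dead time, or flicker noise; sensitivity
is a single scalar. Passing tests therefore demonstrate the *data analysis*
is correct and self-consistent under Poisson statistics — not that any
particular instrument matches these conditions.

## Numerical conventions

- Event windows are half-open `[t_start, t_end)`; indices 0-based; apex ties
  resolve to the earliest index; masses always fg; intensities always CPS.
- Trace readers require strictly increasing, uniform (rtol 1e-6) time stamps
  and infer the dwell time from the median spacing, snapped to 6 significant
  digits; a declared dwell must agree within 1%.
- CSV writers emit shortest round-trip float representations and readers
  parse with round-trip precision, so write→read is bit-exact.
- Mann-Whitney: exact null when min(n) ≤ 8 with no ties, else normal
  approximation with tie-corrected variance and no continuity correction
  (identical groups then give p = 1 exactly). No multiplicity adjustment by
  default; Holm step-down available by flag. Fold changes use means.
- Group summaries include BELOW_LOD cells (at their clamped mass) by
  default; `include_below_lod=False` excludes them.

## Known limitations

- The intercept-based conversion extrapolates far below the smallest nonzero
  standard; sub-femtogram accuracy is limited by intercept noise as analyzed
  above. A ladder with sub-100 fg points would remove most of this error.
- The `MERGED_SUSPECT` flag is oversensitive at the default threshold (see
  above).
- Blank windows are assumed to share the cell-window geometry; strongly
  differing blank durations would distort the LOD estimate.
- The exact Mann-Whitney path enumerates via the standard distribution and is
  restricted to small groups; large-sample comparisons rely on the
  tie-corrected normal approximation.
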