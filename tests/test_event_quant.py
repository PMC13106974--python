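import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmetal.errors import ValidationError
from scmetal.event_quant import (
    Threshold,
    blank_window_responses,
    compute_blank_threshold,
    detect_peak,
    quantify_events,
)
from scmetal.trace_io import RunConfig, SpotEvent, TimeTrace

from conftest import brute_force_peak

TOY = np.array([5, 4, 6, 50, 200, 120, 30, 4, 5], dtype=float)


class TestBlankThreshold:
    def test_mean_of_per_blank_means(self, config):
        segs = [np.full(4, 100.0), np.full(7, 120.0), np.full(3, 110.0)]
        thr = compute_blank_threshold(segs, config)
        assert thr.value == pytest.approx(110.0)
        assert thr.value == thr.blank_mean  # blank_mean method contract
        assert thr.n_blanks == 3

    def test_single_blank_sd_degenerates_to_zero(self):
        cfg = RunConfig(threshold_method="blank_mean_plus_k_sigma", k_sigma=3.0)
        thr = compute_blank_threshold([np.full(5, 50.0)], cfg)
        assert thr.value == pytest.approx(50.0)
        assert thr.blank_sd == 0.0

    def test_zero_blanks_is_error(self, config):
        with pytest.raises(ValidationError, match="no blank"):
            compute_blank_threshold([], config)

    def test_all_zero_blanks_give_zero_threshold(self, config):
        thr = compute_blank_threshold([np.zeros(5), np.zeros(5)], config)
        assert thr.value == 0.0

    def test_poisson_blanks_recover_baseline_mean(self, config):
        rng = np.random.default_rng(3)
        lam, dwell, n = 100.0, 0.2, 40
        segs = [rng.poisson(lam, 30) / dwell for _ in range(20)]
        thr = compute_blank_threshold(segs, config)
        se = (lam / dwell**2 / 30 / 20) ** 0.5  # SE of grand mean in CPS
        assert abs(thr.value - lam / dwell) < 3 * se


class TestDetectPeak:
    def test_toy_segment_local_min_rule(self, config):
        p = detect_peak(TOY, 10.0, config)
        assert (p.i_left, p.i_right, p.i_apex) == (1, 7, 4)
        assert p.integrated_response == pytest.approx(414.0)
        assert not p.edge_truncated

    def test_all_sub_threshold_returns_none(self, config):
        assert detect_peak(np.array([1.0, 2.0, 1.0]), 10.0, config) is None

    def test_edge_truncation_flagged(self, config):
        p = detect_peak(np.array([200.0, 120.0, 5.0]), 10.0, config)
        assert p.i_left == 0 and p.edge_truncated

    def test_first_at_or_below_rule_stops_earlier(self):
        cfg = RunConfig(boundary_rule="first_at_or_below")
        p = detect_peak(TOY, 10.0, cfg)
        # index 2 (value 6) is sub-threshold but not a local minimum
        assert (p.i_left, p.i_right) == (2, 7)
        assert p.integrated_response == pytest.approx(410.0)

    def test_counts_mode_scales_by_dwell(self):
        cfg = RunConfig(integration_units="counts")
        p = detect_peak(TOY, 10.0, cfg, dwell_time=0.25)
        assert p.integrated_response == pytest.approx(414.0 * 0.25)

    def test_empty_segment_is_error(self, config):
        with pytest.raises(ValidationError):
            detect_peak(np.array([]), 10.0, config)

    def test_apex_tie_resolves_to_earliest(self, config):
        y = np.array([0.0, 50.0, 20.0, 50.0, 0.0])
        p = detect_peak(y, 10.0, config)
        assert p.i_apex == 1

    def test_merged_suspect_on_second_run_outside_window(self, config):
        y = np.array([0.0, 50.0, 0.0, 0.0, 0.0, 0.0, 80.0, 0.0])
        p = detect_peak(y, 10.0, config)
        assert p.i_apex == 6 and p.merged_suspect

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 100_000),
        n=st.integers(3, 200),
        lam=st.floats(1.0, 200.0),
        rule=st.sampled_from(["local_min_at_or_below", "first_at_or_below"]),
    )
    def test_matches_brute_force_boundary_enumeration(self, seed, n, lam, rule):
        """Window and integral equal the exhaustive boundary-pair oracle."""
        rng = np.random.default_rng(seed)
        y = rng.poisson(lam, n).astype(float)
        thr = lam
        cfg = RunConfig(boundary_rule=rule)
        got = detect_peak(y, thr, cfg)
        want = brute_force_peak(y, thr, rule)
        if want is None:
            assert got is None
        else:
            assert (got.i_left, got.i_right, got.i_apex) == want[:3]
            assert got.integrated_response == want[3]
            assert got.edge_truncated == want[4]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.floats(0.1, 50.0))
    def test_threshold_invariance_under_scaling(self, seed, k):
        """Scaling intensities and threshold together scales the integral by k."""
        cfg = RunConfig()
        rng = np.random.default_rng(seed)
        y = rng.poisson(60, 80).astype(float)
        p1 = detect_peak(y, 60.0, cfg)
        p2 = detect_peak(y * k, 60.0 * k, cfg)
        if p1 is None:
            assert p2 is None
        else:
            assert (p2.i_left, p2.i_right) == (p1.i_left, p1.i_right)
            assert p2.integrated_response == pytest.approx(
                k * p1.integrated_response, rel=1e-12
            )

    def test_in_window_offset_adds_c_times_width(self, config):
        """The response is the plain sum over the window: adding c to every
        in-window sample raises the integral by exactly c * width."""
        p = detect_peak(TOY, 10.0, config)
        c = 2.5
        shifted = TOY.copy()
        shifted[p.i_left : p.i_right + 1] += c
        assert shifted[p.i_left : p.i_right + 1].sum() == pytest.approx(
            p.integrated_response + c * p.width
        )


def _trace_with_toy_cells(n_cells):
    block = np.concatenate([TOY, np.zeros(3)])  # 12 samples per spot
    y = np.tile(block, n_cells)
    t = np.arange(y.size) * 0.1
    trace = TimeTrace("t", "56Fe", t, y, 0.1)
    events = [
        SpotEvent(f"cell_{i:03d}", "cell", i * 1.2, i * 1.2 + 0.9, group="g")
        for i in range(n_cells)
    ]
    return trace, events


class TestQuantifyEvents:
    def test_repeated_toy_peaks_all_integrate_identically(self, config):
        trace, events = _trace_with_toy_cells(3)
        thr = Threshold(10.0, "blank_mean", 1, 10.0, 0.0)
        ms = quantify_events(trace, events, thr, config)
        assert [m.integrated_response for m in ms] == [414.0, 414.0, 414.0]

    def test_flat_subthreshold_cell_flagged_below_lod(self, config):
        trace = TimeTrace("t", "56Fe", np.arange(10) * 0.1, np.full(10, 5.0), 0.1)
        events = [SpotEvent("c", "cell", 0.0, 1.0)]
        thr = Threshold(10.0, "blank_mean", 1, 10.0, 0.0)
        (m,) = quantify_events(trace, events, thr, config)
        assert m.integrated_response == 0.0 and "BELOW_LOD" in m.flags

    def test_count_conservation_and_ids(self, config, default_run):
        _, trace, events, truths = default_run
        thr = Threshold(600.0, "blank_mean", 1, 600.0, 0.0)
        ms = quantify_events(trace, events, thr, config)
        cells = [e for e in events if e.kind == "cell"]
        assert len(ms) == len(cells)
        assert [m.spot_id for m in ms] == [e.spot_id for e in cells]

    def test_window_outside_trace_names_spot(self, config):
        trace, _ = _trace_with_toy_cells(1)
        bad = [SpotEvent("ghost", "cell", 900.0, 901.0)]
        thr = Threshold(10.0, "blank_mean", 1, 10.0, 0.0)
        with pytest.raises(ValidationError, match="ghost"):
            quantify_events(trace, bad, thr, config)


def test_blank_window_responses_sum_whole_window(config):
    trace = TimeTrace("t", "56Fe", np.arange(6) * 0.1, np.full(6, 7.0), 0.1)
    events = [SpotEvent("b0", "blank", 0.0, 0.3), SpotEvent("b1", "blank", 0.3, 0.6)]
    r = blank_window_responses(trace, events, config)
    assert np.array_equal(r, [21.0, 21.0])
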