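import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmetal.errors import FormatError, ValidationError
from scmetal.event_quant import CellMeasurement
from scmetal.trace_io import (
    RunConfig,
    SpotEvent,
    TimeTrace,
    read_config,
    read_events,
    read_results,
    read_trace,
    write_config,
    write_events,
    write_results,
    write_trace,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTrace:
    def test_three_row_file_infers_dwell(self, tmp_path):
        p = _write(tmp_path, "t.csv", "time_s,56Fe_cps\n0.0,10\n0.01,20\n0.02,30\n")
        tr = read_trace(p, "56Fe")
        assert tr.dwell_time == pytest.approx(0.01)
        assert np.array_equal(tr.intensities, [10.0, 20.0, 30.0])
        assert tr.analyte == "56Fe"

    def test_duplicated_timestamp_rejected_with_row(self, tmp_path):
        p = _write(tmp_path, "t.csv", "time_s,56Fe_cps\n0.0,10\n0.01,20\n0.01,30\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_trace(p, "56Fe")

    def test_missing_analyte_column_named_in_error(self, tmp_path):
        p = _write(tmp_path, "t.csv", "time_s,66Zn_cps\n0.0,1\n0.01,2\n")
        with pytest.raises(FormatError, match="56Fe_cps"):
            read_trace(p, "56Fe")

    def test_missing_time_column(self, tmp_path):
        p = _write(tmp_path, "t.csv", "sample,56Fe_cps\n0,1\n1,2\n")
        with pytest.raises(FormatError, match="time"):
            read_trace(p, "56Fe")

    def test_simulator_roundtrip_identity(self, tmp_path, default_run):
        _, trace, _, _ = default_run
        write_trace(trace, tmp_path / "trace.csv")
        back = read_trace(tmp_path / "trace.csv", trace.analyte)
        assert back == trace


class TestTimeTraceInvariants:
    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            TimeTrace("a", "56Fe", [0.0, 0.1, 0.2], [1.0, -1.0, 1.0], 0.1)

    def test_dwell_must_match_spacing(self):
        with pytest.raises(ValidationError):
            TimeTrace("a", "56Fe", [0.0, 0.1, 0.2], [1.0, 1.0, 1.0], 0.2)

    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValidationError):
            TimeTrace("a", "56Fe", [0.0, 0.1, 0.35], [1.0, 1.0, 1.0], 0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        kind=st.sampled_from(["dup_time", "negative", "shuffled"]),
        n=st.integers(5, 30),
        seed=st.integers(0, 10_000),
    )
    def test_corrupted_traces_always_rejected(self, kind, n, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * 0.1
        y = rng.poisson(50, n).astype(float)
        if kind == "dup_time":
            t[n // 2] = t[n // 2 - 1]
        elif kind == "negative":
            y[n // 2] = -1.0
        else:
            t[n // 2], t[n // 2 - 1] = t[n // 2 - 1], t[n // 2]
        with pytest.raises(ValidationError):
            TimeTrace("a", "56Fe", t, y, 0.1)

    def test_half_open_window_membership(self):
        tr = TimeTrace("a", "56Fe", np.arange(10) * 0.1, np.arange(10.0), 0.1)
        seg = tr.segment(0.2, 0.5)  # samples at 0.2, 0.3, 0.4 but not 0.5
        assert np.array_equal(seg, [2.0, 3.0, 4.0])


class TestEvents:
    def test_cell_row(self, tmp_path):
        p = _write(
            tmp_path,
            "e.csv",
            "spot_id,kind,t_start,t_end,nominal_mass_fg,group\n"
            "cell_001,cell,12.0,15.5,,donor1\n",
        )
        (ev,) = read_events(p)
        assert ev.kind == "cell" and ev.group == "donor1" and ev.nominal_mass is None

    def test_standard_row_with_ladder_mass(self, tmp_path):
        p = _write(
            tmp_path,
            "e.csv",
            "spot_id,kind,t_start,t_end,nominal_mass_fg,group\n"
            "std_2,standard,40.0,43.0,173,cal\n",
        )
        (ev,) = read_events(p)
        assert ev.kind == "standard" and ev.nominal_mass == 173.0

    def test_standard_without_mass_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "e.csv",
            "spot_id,kind,t_start,t_end,nominal_mass_fg,group\n"
            "std_2,standard,40.0,43.0,,cal\n",
        )
        with pytest.raises(ValidationError, match="std_2"):
            read_events(p)

    def test_unknown_kind_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "e.csv",
            "spot_id,kind,t_start,t_end,nominal_mass_fg,group\n"
            "x,droplet,0.0,1.0,,\n",
        )
        with pytest.raises(ValidationError, match="droplet"):
            read_events(p)

    def test_overlap_warns_with_both_ids(self, tmp_path):
        p = _write(
            tmp_path,
            "e.csv",
            "spot_id,kind,t_start,t_end,nominal_mass_fg,group\n"
            "a,cell,0.0,2.0,,\nb,cell,1.5,3.0,,\n",
        )
        with pytest.warns(UserWarning, match="a and b"):
            read_events(p)

    def test_events_roundtrip_ordered_by_start(self, tmp_path, default_run):
        _, _, events, _ = default_run
        write_events(events, tmp_path / "e.csv")
        back = read_events(tmp_path / "e.csv")
        assert back == sorted(events, key=lambda e: (e.t_start, e.spot_id))


class TestResults:
    def test_empty_list_header_only(self, tmp_path):
        write_results([], tmp_path / "r.csv")
        lines = (tmp_path / "r.csv").read_text().splitlines()
        assert lines == ["spot_id,group,integrated_response,mass_fg,flags"]

    def test_two_measurements_three_lines(self, tmp_path):
        ms = [
            CellMeasurement("c2", "g", 2.0, 0.5, frozenset({"BELOW_LOQ"})),
            CellMeasurement("c1", "g", 1.0, 0.25),
        ]
        write_results(ms, tmp_path / "r.csv")
        lines = (tmp_path / "r.csv").read_text().splitlines()
        assert len(lines) == 3
        assert lines[1].startswith("c1,")  # sorted by spot_id

    def test_roundtrip_full_precision(self, tmp_path):
        ms = [
            CellMeasurement("c1", "g", 1.234567890123456e5, 1.8300000000000001),
            CellMeasurement("c2", "g", 0.1 + 0.2, None, frozenset({"BELOW_LOD"})),
        ]
        write_results(ms, tmp_path / "r.csv")
        back = read_results(tmp_path / "r.csv")
        assert back == sorted(ms, key=lambda m: m.spot_id)


class TestRunConfig:
    def test_defaults_roundtrip(self, tmp_path):
        cfg = RunConfig(k_sigma=2.5, threshold_method="blank_mean_plus_k_sigma")
        write_config(cfg, tmp_path / "c.yaml")
        assert read_config(tmp_path / "c.yaml") == cfg

    def test_unknown_key_is_error(self, tmp_path):
        p = _write(tmp_path, "c.yaml", "threshold_method: blank_mean\nsigma: 3\n")
        with pytest.raises(FormatError, match="sigma"):
            read_config(p)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_sigma": -1.0},
            {"lod_k": 10.0, "loq_k": 3.0},
            {"threshold_method": "median"},
            {"boundary_rule": "zero_crossing"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            RunConfig(**kwargs)


class TestSpotEvent:
    def test_inverted_window_rejected(self):
        with pytest.raises(ValidationError):
            SpotEvent("x", "cell", 5.0, 4.0)

    def test_negative_standard_mass_rejected(self):
        with pytest.raises(ValidationError):
            SpotEvent("x", "standard", 0.0, 1.0, nominal_mass=-5.0)
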