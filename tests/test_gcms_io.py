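"""mzML reading, trace extraction, apex integration, and EI peak tables."""

import numpy as np
import pandas as pd
import pytest

from aspenrich.fragments import FragmentSpec
from aspenrich.gcms_io import (
    MIDMeasurement,
    ScanSeries,
    Traces,
    extract_traces,
    load_mzml,
    mid_apci,
    mid_ei,
)
from aspenrich.isotopes import parse_formula
from aspenrich.simulate import simulate_mid, write_mzml


@pytest.fixture(scope="module")
def m232(registry):
    from aspenrich.fragments import lookup

    return lookup(registry, "aspartic acid 3TMS", 232)


@pytest.fixture()
def fixture_mzml(tmp_path, m232):
    mid = simulate_mid(m232, {2: 0.4, 3: 0.1, 4: 0.7}, 2e5)
    path = write_mzml([mid], tmp_path / "one_fragment.mzml")
    return path, mid


class TestScanSeries:
    def test_requires_increasing_retention_times(self):
        with pytest.raises(ValueError):
            ScanSeries([(1.0, np.array([100.0]), np.array([1.0])),
                        (1.0, np.array([100.0]), np.array([1.0]))])

    def test_requires_matching_array_lengths(self):
        with pytest.raises(ValueError):
            ScanSeries([(1.0, np.array([100.0, 101.0]), np.array([1.0]))])


class TestLoadMzml:
    def test_round_trip_scan_count_and_rt_order(self, fixture_mzml):
        series = load_mzml(fixture_mzml[0])
        assert len(series) == 120
        assert np.all(np.diff(series.retention_times) > 0)

    def test_rt_range_filter(self, fixture_mzml):
        series = load_mzml(fixture_mzml[0], rt_range=(305.0, 310.0))
        rts = series.retention_times
        assert rts.min() >= 305.0 and rts.max() <= 310.0
        assert len(series) < 120

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            load_mzml(tmp_path / "nope.mzml")

    def test_malformed_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.mzml"
        bad.write_text("<mzML>not really")
        with pytest.raises(ValueError):
            load_mzml(bad)

    def test_profile_mode_rejected(self, fixture_mzml, tmp_path):
        text = fixture_mzml[0].read_text()
        text = text.replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        path = tmp_path / "profile.mzml"
        path.write_text(text)
        with pytest.raises(ValueError, match="profile"):
            load_mzml(path)


class TestExtractTraces:
    def test_recovers_injected_fractions(self, fixture_mzml, m232):
        path, mid = fixture_mzml
        traces = extract_traces(load_mzml(path), m232, (302.0, 328.0))
        areas = np.array(
            [np.trapezoid(tr, traces.retention_times) for tr in traces.intensities]
        )
        np.testing.assert_allclose(
            areas / areas.sum(), mid.abundances / mid.abundances.sum(), rtol=1e-3
        )

    def test_mass_displaced_peak_outside_window_gives_zero_traces(
        self, fixture_mzml, m232
    ):
        displaced = FragmentSpec(
            m232.analyte, m232.ion_label, m232.exact_mz + 0.02,
            None, m232.backbone_positions,
        )
        traces = extract_traces(load_mzml(fixture_mzml[0]), displaced, (302.0, 328.0))
        assert traces.intensities.sum() == 0.0

    def test_two_to_one_area_ratio_preserved(self, tmp_path, m232):
        mid = MIDMeasurement(m232, "s", np.array([2.0e5, 1.0e5, 0, 0, 0, 0, 0]))
        path = write_mzml([mid], tmp_path / "ratio.mzml")
        traces = extract_traces(load_mzml(path), m232, (302.0, 328.0))
        a0 = np.trapezoid(traces.intensities[0], traces.retention_times)
        a1 = np.trapezoid(traces.intensities[1], traces.retention_times)
        assert a0 / a1 == pytest.approx(2.0, abs=1e-6)

    def test_window_outside_data_rejected(self, fixture_mzml, m232):
        with pytest.raises(ValueError):
            extract_traces(load_mzml(fixture_mzml[0]), m232, (0.0, 10.0))

    def test_wider_tolerance_collects_more_of_a_spread_peak(self, m232):
        # centroids jittered around the theoretical m/z by a few mDa, as on
        # a real high-resolution instrument
        rng = np.random.default_rng(0)
        scans = []
        for k in range(21):
            mz = m232.exact_mz + rng.normal(0.0, 0.003, size=5)
            inten = np.full(5, 100.0) * np.exp(-0.5 * ((k - 10) / 3) ** 2)
            scans.append((float(k), mz, inten))
        series = ScanSeries(scans)
        areas = [
            extract_traces(series, m232, (0.0, 20.0), tol=tol).intensities.sum()
            for tol in (0.001, 0.002, 0.005, 0.01)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(areas, areas[1:]))
        assert areas[0] < areas[-1]


class TestMidApci:
    def test_flat_zero_traces_signal_missing_measurement(self, m232):
        traces = Traces(m232, np.arange(50.0), np.zeros((7, 50)))
        assert mid_apci(traces, "s") is None

    def test_triangular_peak_area_closed_form(self, m232):
        rts = np.arange(50.0)
        trace = np.zeros((7, 50))
        trace[0, 23:28] = [0.0, 1.0, 2.0, 1.0, 0.0]  # triangle, trapezoid area 4
        mid = mid_apci(Traces(m232, rts, trace), "s")
        assert mid.abundances[0] == pytest.approx(4.0)
        assert mid.apex_rt == 25.0

    def test_integration_bounds_are_apex_plus_minus_ten_scans(self, m232):
        rts = np.arange(300.0)
        trace = np.zeros((7, 300))
        trace[0, :] = 1.0  # constant background on M0
        trace[0, 100] = 100.0  # apex at scan 100
        mid = mid_apci(Traces(m232, rts, trace), "s")
        # trapezoid over scans 90..110: 20 unit intervals + apex spike
        assert mid.abundances[0] == pytest.approx(20.0 + 99.0)

    def test_round_trip_recovers_simulated_mid(self, fixture_mzml, m232):
        path, mid = fixture_mzml
        recovered = mid_apci(
            extract_traces(load_mzml(path), m232, (302.0, 328.0)), "s"
        )
        np.testing.assert_allclose(
            recovered.abundances / recovered.abundances.sum(),
            mid.abundances / mid.abundances.sum(),
            rtol=1e-3,
        )


class TestMidEi:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "ion_label", "isotopologue", "abundance"]
        )

    def test_four_rows_build_vector(self, m232):
        table = self._table([("s1", 232, i, h) for i, h in
                             enumerate([100.0, 1.0, 0.0, 0.0])])
        mid = mid_ei(table, m232, "s1")
        assert len(mid.abundances) == 4
        assert mid.quant_mode == "apex_height"

    def test_duplicate_rows_rejected(self, m232):
        table = self._table(
            [("s1", 232, 0, 1.0), ("s1", 232, 0, 2.0), ("s1", 232, 1, 1.0),
             ("s1", 232, 2, 1.0), ("s1", 232, 3, 1.0)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            mid_ei(table, m232, "s1")

    def test_too_few_isotopologues_rejected(self, m232):
        table = self._table([("s1", 232, i, 1.0) for i in range(3)])
        with pytest.raises(ValueError):
            mid_ei(table, m232, "s1")

    def test_missing_sample_rejected(self, m232):
        table = self._table([("s1", 232, i, 1.0) for i in range(4)])
        with pytest.raises(ValueError):
            mid_ei(table, m232, "other")
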