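"""Forward simulation: envelopes, noise, panels, time courses, mzML."""

import numpy as np
import pytest

from aspenrich.correction import build_matrix, correct
from aspenrich.gcms_io import extract_traces, load_mzml
from aspenrich.isotopes import NATURAL_13C, natural_pattern
from aspenrich.simulate import (
    NOISE_FREE,
    NoiseModel,
    _soft_saturate,
    dark_scenario,
    light_scenario,
    simulate_mid,
    simulate_mixture_panel,
    simulate_timecourse,
    write_mzml,
)
from aspenrich.validation import table_s1_designs


class TestSimulateMid:
    def test_natural_noise_free_equals_nia_pattern_times_scale(self, frag_by_label):
        frag = frag_by_label(232)
        mid = simulate_mid(frag, {}, scale=1e6)
        expected = natural_pattern(frag.ion_formula)[: len(mid.abundances)] * 1e6
        # tiny slack: pattern pruning renormalizes the two routes differently
        np.testing.assert_allclose(mid.abundances, expected, rtol=1e-6)

    def test_full_labelling_shifts_envelope_by_tracer_count(self, frag_by_label):
        frag = frag_by_label(232)
        labelled = simulate_mid(frag, {2: 1.0, 3: 1.0, 4: 1.0}, 1.0, n_extra=3)
        rest = frag.ion_formula.without("C", 3)
        shifted = natural_pattern(rest)[: len(labelled.abundances) - 3]
        np.testing.assert_allclose(labelled.abundances[3:], shifted, rtol=1e-9)
        np.testing.assert_allclose(labelled.abundances[:3], 0.0, atol=1e-12)

    def test_fixed_seed_is_bitwise_reproducible(self, frag_by_label):
        frag = frag_by_label(349)
        noise = NoiseModel(cv_multiplicative=0.05, baseline_sd=10.0, seed=123)
        a = simulate_mid(frag, {1: 0.5}, 1e5, noise)
        b = simulate_mid(frag, {1: 0.5}, 1e5, noise)
        assert np.array_equal(a.abundances, b.abundances)

    def test_atom_fraction_outside_unit_interval_rejected(self, frag_by_label):
        with pytest.raises(ValueError):
            simulate_mid(frag_by_label(232), {2: 1.2}, 1e5)


class TestSoftSaturation:
    def test_linear_well_below_threshold(self):
        noise = NoiseModel()
        v = np.array([1e4, 1e5, 1e6])
        np.testing.assert_allclose(_soft_saturate(v, noise), v, rtol=5e-3)

    def test_compresses_and_caps_above_threshold(self):
        noise = NoiseModel()
        out = _soft_saturate(np.array([2e7, 1e8]), noise)
        assert np.all(out < noise.saturation_threshold * 1.001)
        assert out[1] > out[0]  # still monotone


class TestMixturePanel:
    def test_panel_size_144_measurements_per_fragment(self):
        designs = table_s1_designs()
        panel = simulate_mixture_panel(designs, [25.0], 4, NOISE_FREE, seed=0)
        per_fragment = {}
        for pm in panel:
            per_fragment.setdefault(pm.mid.fragment.ion_label, 0)
            per_fragment[pm.mid.fragment.ion_label] += 1
        assert all(count == 144 for count in per_fragment.values())

    def test_zero_replicates_empty_dataset(self):
        assert simulate_mixture_panel(table_s1_designs()[:2], [25.0], 0) == []

    def test_abundance_linear_in_injection_before_saturation(self):
        designs = table_s1_designs()[:1]
        unsaturated = NoiseModel(cv_multiplicative=0.0, saturation_threshold=1e15)
        low = simulate_mixture_panel(designs, [12.5], 1, unsaturated, seed=0)
        high = simulate_mixture_panel(designs, [25.0], 1, unsaturated, seed=0)
        for a, b in zip(low, high):
            assert b.mid.total_abundance == pytest.approx(
                2 * a.mid.total_abundance, rel=1e-9
            )


class TestTimecourse:
    def test_dark_scenario_labels_only_position_four_with_late_onset(self):
        scenario = dark_scenario()
        early = scenario.enrichment(10.0)
        assert all(early[p] == 0.0 for p in (1, 2, 3))
        assert early[4] < 0.01 * scenario.trajectories[4].y_max
        later = scenario.enrichment(15.0)
        assert later[4] >= 0.01 * scenario.trajectories[4].y_max

    def test_light_scenario_first_detectable_at_ten_minutes(self):
        scenario = light_scenario()
        y_max = scenario.trajectories[1].y_max
        assert scenario.enrichment(5.0)[1] < 0.01 * y_max
        assert scenario.enrichment(10.0)[1] >= 0.01 * y_max

    def test_noise_free_pipeline_recovers_trajectories(self, positional_fragments):
        from aspenrich.positional import FragmentEnrichment, positional_e13c

        scenario = light_scenario(replicates=1)
        dataset = simulate_timecourse(scenario, NOISE_FREE, seed=0)
        matrices = {}
        for sample in dataset.samples:
            truth = scenario.enrichment(sample.time_min)
            e13cs = {}
            for mid in sample.mids:
                key = mid.fragment.ion_label
                if key not in matrices:
                    matrices[key] = build_matrix(mid.fragment, len(mid.abundances))
                e13cs[key] = correct(mid, matrices[key]).e13c
            enr = {
                name: FragmentEnrichment(frag.backbone_positions, e13cs[frag.ion_label])
                for name, frag in positional_fragments.items()
            }
            pos = positional_e13c(enr["E1234"], enr["E234"], enr["E23"], enr["E34"])
            np.testing.assert_allclose(
                pos.e, [truth[p] for p in range(1, 5)], atol=1e-4
            )

    def test_samples_cover_timepoints_and_replicates(self):
        dataset = simulate_timecourse(dark_scenario(replicates=2), NOISE_FREE, seed=1)
        assert len(dataset.samples) == 2 * 7
        assert len(dataset.calibration_levels) >= 3


class TestWriteMzml:
    def test_single_isotopologue_peak_recovers_known_area(self, tmp_path,
                                                          frag_by_label):
        frag = frag_by_label(232)
        mid = simulate_mid(frag, {2: 1.0, 3: 1.0, 4: 1.0}, 5e4)
        path = write_mzml([mid], tmp_path / "single.mzml")
        traces = extract_traces(load_mzml(path), frag, (302.0, 328.0))
        area = np.trapezoid(traces.intensities[3], traces.retention_times)
        assert area == pytest.approx(mid.abundances[3], rel=1e-3)

    def test_coeluting_fragments_give_independent_eics(self, tmp_path,
                                                       frag_by_label):
        # m/z 232 and 216 are far apart; windows must not cross-collect
        f232, f216 = frag_by_label(232), frag_by_label(216)
        mids = [simulate_mid(f232, {}, 1e5), simulate_mid(f216, {}, 3e4)]
        path = write_mzml(mids, tmp_path / "two.mzml")
        series = load_mzml(path)
        t232 = extract_traces(series, f232, (302.0, 328.0))
        t216 = extract_traces(series, f216, (302.0, 328.0))
        a232 = np.trapezoid(t232.intensities.sum(0), t232.retention_times)
        a216 = np.trapezoid(t216.intensities.sum(0), t216.retention_times)
        assert a232 == pytest.approx(1e5, rel=1e-3)
        assert a216 == pytest.approx(3e4, rel=1e-3)
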