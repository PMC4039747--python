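"""Marker-ratio banding, depth-based duplication test, spectrum, exclusion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balscan.callset_io import DepthTrack, VariantCall
from balscan.errors import InsufficientDataError, ValidationError
from balscan.genome_model import BalancerConfig, MarkerLocus
from balscan.strain_qc import (
    MARKER_STATES,
    classify_marker,
    detect_duplication,
    ems_spectrum,
    expected_allelic_ratio,
    qc_strain,
    ratio_band,
)


class TestExpectedRatio:
    @pytest.mark.parametrize(
        "mut,total,expected",
        [(2, 3, 2 / 3), (2, 2, 1.0), (1, 3, 1 / 3), (0, 2, 0.0)],
    )
    def test_copy_arithmetic(self, mut, total, expected):
        assert expected_allelic_ratio(mut, total) == pytest.approx(expected)

    def test_invalid_copies_rejected(self):
        with pytest.raises(ValidationError):
            expected_allelic_ratio(1, 0)
        with pytest.raises(ValidationError):
            expected_allelic_ratio(3, 2)


MARKER_IN = MarkerLocus("m_in", "chrI", 100, "G", "A", 2, 3)
MARKER_OUT = MarkerLocus("m_out", "chrI", 900, "C", "T", 2, 2)


def _call(ratio_alt, ratio_ref, marker=MARKER_IN):
    return VariantCall(marker.chromosome, marker.position, marker.ref, marker.alt,
                       ratio_ref, ratio_alt)


class TestMarkerClassification:
    def test_all_reference_reads_means_marker_absent(self):
        state = classify_marker(_call(0, 30), MARKER_IN)
        assert state.state == "absent"
        assert not state.ok

    def test_one_of_three_copies_reads_as_single_copy(self):
        state = classify_marker(_call(10, 20), MARKER_IN)  # ratio 0.33 vs expected 0.667
        assert state.state == "single_copy"
        assert not state.ok

    def test_balanced_ratio_passes(self):
        state = classify_marker(_call(20, 10), MARKER_IN)  # 0.667
        assert state.state == "balanced" and state.ok

    def test_homozygous_marker_outside_duplication_passes(self):
        state = classify_marker(_call(29, 1, MARKER_OUT), MARKER_OUT)
        assert state.state == "homozygous" and state.ok

    def test_missing_record_means_absent(self):
        state = classify_marker(None, MARKER_IN)
        assert state.state == "absent" and state.observed_ratio == 0.0

    def test_zero_depth_is_anomalous(self):
        state = classify_marker(_call(0, 0), MARKER_IN)
        assert state.state == "anomalous" and state.observed_ratio is None

    @settings(derandomize=True, max_examples=200)
    @given(ratio=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_banding_is_total_over_the_unit_interval(self, ratio):
        assert ratio_band(ratio) in MARKER_STATES


def _track(inside_depth, outside_depth, n_in=10, n_out=10, width=10_000):
    windows = [("chrI", i * width, (i + 1) * width, inside_depth) for i in range(n_in)]
    windows += [
        ("chrI", (n_in + i) * width, (n_in + i + 1) * width, outside_depth)
        for i in range(n_out)
    ]
    return DepthTrack(windows)


CONFIG = BalancerConfig("chrI", (0, 100_000))


class TestDuplicationDetection:
    def test_three_to_two_depth_gives_one_third_statistic(self):
        present, d = detect_duplication(_track(45.0, 30.0), CONFIG)
        assert present
        assert d == pytest.approx(1 / 3)

    def test_flat_track_is_negative(self):
        present, d = detect_duplication(_track(30.0, 30.0), CONFIG)
        assert not present
        assert d == pytest.approx(0.0)

    def test_mild_excess_below_threshold_is_negative(self):
        present, d = detect_duplication(_track(33.0, 30.0), CONFIG)
        assert not present
        assert d == pytest.approx(1 - 30 / 33)

    def test_too_few_windows_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_duplication(_track(45.0, 30.0, n_in=2, n_out=2), CONFIG)


class TestSpectrum:
    def test_transition_fraction_arithmetic(self):
        calls = [
            VariantCall("chrI", i, ref, alt, 10, 10)
            for i, (ref, alt) in enumerate([("G", "A"), ("C", "T"), ("G", "A"), ("A", "C")])
        ]
        spectrum = ems_spectrum(calls)
        assert spectrum.transition_fraction == pytest.approx(0.75)
        assert spectrum.counts == {"G>A": 2, "C>T": 1, "A>C": 1}

    def test_indels_are_ignored(self):
        calls = [VariantCall("chrI", 1, "AT", "A", 5, 5)]
        assert ems_spectrum(calls).n_snvs == 0

    def test_empty_input_reports_missing_fraction(self):
        assert ems_spectrum([]).transition_fraction is None


class TestQCReport:
    def _config_with_markers(self):
        return BalancerConfig("chrI", (0, 100_000), [MARKER_IN], [])

    def test_conforming_strain_passes(self):
        config = self._config_with_markers()
        calls = [_call(20, 10)]
        report = qc_strain("s1", calls, _track(45.0, 30.0), config)
        assert not report.exclude
        assert report.marker_states["m_in"].ok
        assert report.duplication_present

    def test_duplication_loss_is_excluded_with_reason(self):
        config = self._config_with_markers()
        calls = [_call(30, 0)]  # marker homozygous: duplication gone
        report = qc_strain("s2", calls, _track(30.0, 30.0), config)
        assert report.exclude
        assert any("duplication absent" in r for r in report.reasons)
        assert any("m_in" in r for r in report.reasons)

    def test_spectrum_is_summarised_over_strain_private_calls(self):
        config = self._config_with_markers()
        background = [VariantCall("chrI", p, "A", "C", 10, 20) for p in range(200, 240)]
        private = [VariantCall("chrI", p, "G", "A", 10, 20) for p in range(300, 320)]
        report = qc_strain(
            "s3", [_call(20, 10)] + background + private, _track(45.0, 30.0), config,
            background=background,
        )
        assert report.ems_transition_fraction == pytest.approx(1.0)

    def test_cohort_excludes_exactly_the_planted_anomalies(self, tmp_path):
        from balscan.pipeline import load_cohort, run_cohort, simulate_cohort
        from balscan.strain_simulator import SimulationParams

        params = SimulationParams(seed=99)
        simulate_cohort(params, n_strains=4, outdir=tmp_path, n_unbalanced=3)
        summary = run_cohort(load_cohort(tmp_path))
        assert int(summary["excluded"].sum()) == 3
        excluded_ids = set(summary.loc[summary["excluded"], "strain_id"])
        assert excluded_ids == {"strain_005", "strain_006", "strain_007"}
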