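import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventzone import aggregation, zones
from ventzone.io import PatientManifest

from conftest import make_frame

H = 3600.0


@pytest.fixture
def manifest():
    # 3 h phases, 30 min washout, automated first
    return PatientManifest("P1", "automated", 0.0, 3 * H, 3.5 * H, 6.5 * H)


class TestSegmentPhases:
    def test_three_windows_get_their_labels(self, manifest):
        times = [0.0, 1 * H, 3.2 * H, 4.0 * H, 6.0 * H]
        segments, dropped = aggregation.segment_phases(make_frame(times), manifest)
        assert [s.phase_label for s in segments] == \
            ["automated", "washout", "conventional"]
        assert [len(s.frame) for s in segments] == [2, 1, 2]
        assert dropped == 0

    def test_boundary_record_goes_to_washout(self, manifest):
        segments, _ = aggregation.segment_phases(
            make_frame([3 * H]), manifest)  # exactly phase1_end
        by_label = {s.phase_label: len(s.frame) for s in segments}
        assert by_label["washout"] == 1 and by_label["automated"] == 0

    def test_empty_log(self, manifest):
        segments, dropped = aggregation.segment_phases(make_frame([]), manifest)
        assert all(s.frame.empty for s in segments) and dropped == 0

    def test_records_outside_all_windows_are_counted(self, manifest):
        segments, dropped = aggregation.segment_phases(
            make_frame([1.0, 7 * H]), manifest)
        assert dropped == 1
        assert sum(len(s.frame) for s in segments) == 1


class TestPercentBreaths:
    def test_eq1_arithmetic(self):
        labels = ["optimal"] * 50 + ["critical"] * 150
        assert aggregation.percent_breaths_in_zone(labels, "optimal") == 25.0

    def test_saturation(self):
        assert aggregation.percent_breaths_in_zone(["optimal"] * 7, "optimal") == 100.0

    def test_zero_classified_is_missing_not_zero(self):
        assert np.isnan(
            aggregation.percent_breaths_in_zone(["unclassified"] * 3, "optimal"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(list(zones.ZONES) + ["unclassified"]),
                    min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    def test_invariant_under_reordering(self, labels, rnd):
        shuffled = list(labels)
        rnd.shuffle(shuffled)
        for zone in zones.ZONES:
            a = aggregation.percent_breaths_in_zone(labels, zone)
            b = aggregation.percent_breaths_in_zone(shuffled, zone)
            assert (np.isnan(a) and np.isnan(b)) or a == b

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(list(zones.ZONES)), min_size=1, max_size=60))
    def test_classified_percentages_sum_to_100(self, labels):
        total = sum(aggregation.percent_breaths_in_zone(labels, z)
                    for z in zones.ZONES)
        assert total == pytest.approx(100.0, abs=1e-9)


class TestPercentTime:
    def test_equals_breath_fraction_under_uniform_durations(self):
        times = np.arange(200.0) * 4.0
        labels = ["optimal"] * 50 + ["critical"] * 150
        assert aggregation.percent_time_in_zone(times, labels, "optimal") == \
            pytest.approx(25.0)

    def test_unequal_durations_weight_the_zones(self):
        # classified durations 1 s (optimal) and 3 s (critical); the trailing
        # unclassified breath inherits the median duration but is excluded
        times = [0.0, 1.0, 4.0]
        labels = ["optimal", "critical", "unclassified"]
        assert aggregation.percent_time_in_zone(times, labels, "optimal") == \
            pytest.approx(25.0)
        assert aggregation.percent_time_in_zone(times, labels, "critical") == \
            pytest.approx(75.0)

    def test_long_gap_capped(self):
        durations = aggregation.breath_durations(np.array([0.0, 60.0, 63.0]))
        assert durations.tolist() == [15.0, 3.0, 9.0]  # last = median(15, 3)

    def test_single_breath_is_missing_with_warning(self):
        with pytest.warns(UserWarning):
            out = aggregation.percent_time_in_zone([0.0], ["optimal"], "optimal")
        assert np.isnan(out)


class TestSummarizePatient:
    def test_single_zone_log_is_100_0_0(self, manifest, default_table):
        # spo2 94 / peep 5 / fio2 30 classifies optimal in every view
        frame = make_frame(np.arange(0.0, 6.5 * H, 600.0), spo2=94.0)
        segments, _ = aggregation.segment_phases(frame, manifest)
        summary = aggregation.summarize_patient(segments, default_table)
        for arm in ("automated", "conventional"):
            for view in aggregation.VIEWS:
                pct = summary.phases[arm].pct_breaths[view]
                assert pct["optimal"] == 100.0
                assert pct["acceptable"] == 0.0 and pct["critical"] == 0.0

    def test_washout_only_log_has_empty_phases(self, manifest, default_table):
        frame = make_frame([3.1 * H, 3.2 * H, 3.3 * H])
        segments, _ = aggregation.segment_phases(frame, manifest)
        summary = aggregation.summarize_patient(segments, default_table)
        for arm in ("automated", "conventional"):
            assert summary.phases[arm].n_breaths == 0
            assert np.isnan(summary.phases[arm].pct_breaths["combined"]["optimal"])

    def test_zone_conservation_per_segment(self, small_cohort, default_table):
        for pid, frame in small_cohort.frames.items():
            labels = zones.classify_breaths(frame, default_table)
            counts = {z: (labels == z).sum() for z in
                      list(zones.ZONES) + ["unclassified"]}
            assert sum(counts.values()) == len(frame)

    def test_generator_occupancy_recovered(self, default_table):
        # i.i.d. zone draws, ~10,800 breaths/phase: estimate within 2 points
        from ventzone import synthetic
        config = synthetic.SyntheticConfig(
            n_patients=1, phase_minutes=600.0, washout_minutes=5.0,
            dwell_mean_s=0.0, seed=202,
            zone_occupancy={"automated": (0.60, 0.25, 0.15),
                            "conventional": (0.60, 0.25, 0.15)})
        frame, manifest, _ = synthetic.generate_patient(config, 0)
        segments, _ = aggregation.segment_phases(frame, manifest)
        summary = aggregation.summarize_patient(segments, default_table)
        for arm in ("automated", "conventional"):
            pct = summary.phases[arm].pct_breaths["combined"]
            assert pct["optimal"] == pytest.approx(60.0, abs=2.0)
            assert pct["acceptable"] == pytest.approx(25.0, abs=2.0)
            assert pct["critical"] == pytest.approx(15.0, abs=2.0)

    def test_tidy_frame_shape(self, small_cohort, default_table):
        frame = small_cohort.frames["P001"]
        manifest = small_cohort.manifests[0]
        segments, _ = aggregation.segment_phases(frame, manifest)
        summary = aggregation.summarize_patient(segments, default_table)
        tidy = aggregation.summaries_to_frame([summary])
        # 2 phases x 3 views x 2 metrics x 3 zones
        assert len(tidy) == 36
        assert set(tidy["metric"]) == {"breaths", "time"}
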