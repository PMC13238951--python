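import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ysa.event_detection import (
    Baseline,
    DetectionConfig,
    classify_event,
    detect_channel_events,
    detect_discharge_points,
    events_dataframe,
    find_baseline,
    group_into_events,
)

FS = 100.0


def bursty_signal(rng, duration=600.0, quiet=(240.0, 360.0), burst_amp=10.0):
    """Unit noise with large oscillatory bursts everywhere except ``quiet``."""
    n = int(duration * FS)
    t = np.arange(n) / FS
    x = rng.normal(0, 1, n)
    osc = burst_amp * np.sin(2 * np.pi * 7 * t)
    mask = (t < quiet[0]) | (t >= quiet[1])
    x[mask] += osc[mask]
    return x


class TestFindBaseline:
    def test_finds_planted_quiet_region(self, rng):
        x = bursty_signal(rng)
        bl = find_baseline(x, FS)
        assert 240.0 <= bl.start and bl.end <= 360.0

    def test_exact_window_length_signal(self, rng):
        x = rng.normal(0, 1, int(120 * FS))
        bl = find_baseline(x, FS)
        assert (bl.start, bl.end) == (0.0, 120.0)

    def test_short_recording_falls_back_with_warning(self, rng):
        x = rng.normal(0, 1, int(90 * FS))
        with pytest.warns(UserWarning, match="baseline"):
            bl = find_baseline(x, FS)
        assert bl.whole_record and bl.end == pytest.approx(90.0)

    def test_constant_signal_is_degenerate(self):
        bl = find_baseline(np.zeros(int(150 * FS)), FS)
        assert bl.degenerate


class TestDetectDischargePoints:
    def test_planted_burst_is_confirmed(self, rng):
        n = int(300 * FS)
        t = np.arange(n) / FS
        x = rng.normal(0, 1, n)
        burst = (t >= 200.0) & (t < 203.0)
        x[burst] += 10 * np.sin(2 * np.pi * 8 * t[burst])
        bl = find_baseline(x, FS)
        pts = detect_discharge_points(x, FS, bl)
        exceeding = np.abs(x - bl.mean) > 3 * bl.sd
        n_burst_exceeding = np.count_nonzero(exceeding & burst)
        n_confirmed_in_burst = np.count_nonzero((pts >= 200.0) & (pts < 203.0))
        assert n_confirmed_in_burst >= 0.9 * n_burst_exceeding
        # at most a few isolated noise confirmations outside the burst;
        # grouping + classification discards such singletons downstream
        outside = (pts < 199.0) | (pts > 204.0)
        assert np.count_nonzero(outside) <= 3

    def test_matches_naive_rule_evaluation(self, rng):
        """The vectorized detector equals a sample-by-sample evaluation of
        the voltage-outlier + variance-confirmation rule."""
        n = int(150 * FS)
        x = rng.normal(0, 1, n)
        x[int(130 * FS):int(131 * FS)] += 7.0
        bl = find_baseline(x, FS)
        cfg = DetectionConfig()
        w = int(round(cfg.variance_window * FS))
        half = w // 2
        expected = []
        for i in range(n):
            if abs(x[i] - bl.mean) <= cfg.k_v * bl.sd:
                continue
            lo, hi = max(0, i - half), min(n, i - half + w)
            if np.var(x[lo:hi]) > bl.var_mean + cfg.k_var * bl.var_sd:
                expected.append(i / FS)
        np.testing.assert_allclose(detect_discharge_points(x, FS, bl, cfg), expected)

    def test_two_sd_deviations_are_ignored(self):
        bl = Baseline(0, 0.0, 120.0, mean=0.0, sd=1.0, var_mean=1.0, var_sd=0.1)
        x = np.full(1000, 2.0)  # 2 SD everywhere, below the 3-SD threshold
        assert detect_discharge_points(x, FS, bl).size == 0

    def test_degenerate_baseline_yields_nothing(self):
        bl = Baseline(0, 0.0, 120.0, mean=0.0, sd=0.0, var_mean=0.0, var_sd=0.0)
        assert detect_discharge_points(np.zeros(1000), FS, bl).size == 0

    def test_shift_equivariance(self, rng):
        n = int(300 * FS)
        t = np.arange(n) / FS
        x = rng.normal(0, 1, n)
        burst = (t >= 100.0) & (t < 103.0)
        x[burst] += 12 * np.sin(2 * np.pi * 8 * t[burst])
        bl = find_baseline(x, FS)
        shift = int(50 * FS)
        pts = detect_discharge_points(x, FS, bl)
        pts_shifted = detect_discharge_points(np.roll(x, shift), FS, bl)
        keep = (pts > 5.0) & (pts < 250.0 - 5.0)
        np.testing.assert_allclose(np.sort(pts_shifted), np.sort(pts[keep] + 50.0), atol=1e-9)

    def test_raising_threshold_never_adds_points(self, rng):
        n = int(200 * FS)
        x = rng.normal(0, 1, n)
        x[int(150 * FS):int(151 * FS)] += 8.0
        bl = find_baseline(x, FS)
        loose = set(detect_discharge_points(x, FS, bl, DetectionConfig(k_v=3.0)))
        strict = set(detect_discharge_points(x, FS, bl, DetectionConfig(k_v=4.0)))
        assert strict <= loose


class TestGrouping:
    def test_gap_splits_events(self):
        events = group_into_events(np.array([0.0, 1.5, 3.0, 8.0]), gap=2.0)
        assert [(e[0], e[1], len(e[2])) for e in events] == [(0.0, 3.0, 3), (8.0, 8.0, 1)]

    def test_empty_input(self):
        assert group_into_events(np.array([])) == []

    def test_boundary_gap_is_inclusive(self):
        events = group_into_events(np.array([0.0, 2.0, 4.0]), gap=2.0)
        assert len(events) == 1 and events[0][:2] == (0.0, 4.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            group_into_events(np.array([1.0, 0.5]))

    @given(
        st.lists(st.floats(0, 1000, allow_nan=False), min_size=0, max_size=50),
        st.floats(0.1, 10),
    )
    def test_grouping_is_a_partition(self, times, gap):
        pts = np.sort(np.asarray(times))
        events = group_into_events(pts, gap)
        members = np.concatenate([e[2] for e in events]) if events else np.array([])
        np.testing.assert_array_equal(members, pts)  # every point in exactly one event
        for (_, off_a, _), (on_b, _, _) in zip(events, events[1:]):
            assert on_b - off_a > gap  # events disjoint, time-ordered


class TestClassification:
    @pytest.mark.parametrize(
        "duration,label",
        [(5.0, "discarded"), (10.0, "discarded"), (12.0, "SLSLE"),
         (300.0, "SLSLE"), (360.0, "SE")],
    )
    def test_duration_boundaries(self, duration, label):
        assert classify_event(duration) == label

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_event(-1.0)

    @given(st.floats(0, 1e4, allow_nan=False))
    def test_classification_total_and_exclusive(self, duration):
        assert classify_event(duration) in {"SE", "SLSLE", "discarded"}


class TestDetectChannelEvents:
    def test_planted_events_recovered_per_channel(self, standard_run):
        events = standard_run["events"]
        truth = standard_run["truth"].events
        kept = events[events["label"].isin(["SLSLE", "SE"])]
        matched = 0
        for row in truth.itertuples(index=False):
            ch = kept[kept["channel_id"] == row.channel_id]
            hit = ch[
                (ch["onset_s"] < row.offset_s)
                & (ch["offset_s"] > row.onset_s)
                & (ch["label"] == row.label)
            ]
            matched += int(len(hit) > 0)
        assert matched >= 0.9 * len(truth)

    def test_pure_noise_channels_stay_silent(self, standard_run):
        events = standard_run["events"]
        truth_channels = set(standard_run["truth"].events["channel_id"])
        kept = events[events["label"].isin(["SLSLE", "SE"])]
        noise_channels = [
            int(c) for c in standard_run["recording"].channel_ids
            if int(c) not in truth_channels
        ]
        silent = sum(
            1 for c in noise_channels if (kept["channel_id"] == c).sum() == 0
        )
        assert silent >= 0.95 * len(noise_channels)

    def test_short_burst_discarded(self, rng):
        from ysa.mea_io import Recording

        n = int(200 * FS)
        data = rng.normal(0, 1, (1, n))
        t = np.arange(n) / FS
        burst = (t >= 150.0) & (t < 154.0)
        data[0, burst] += 10.0
        rec = Recording(data, FS, [(0, 0)])
        evset = detect_channel_events(rec)
        assert evset.kept() == [] and len(evset.events) > 0
        frame = events_dataframe(evset)
        assert (frame["label"] == "discarded").all()
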