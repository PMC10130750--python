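"""3D track quantification: lengths, censoring, phases, event statistics."""

import numpy as np
import pytest

from kip2traffic.mt_dynamics import (
    DETECTION_LIMIT_NM,
    FRAME_INTERVAL_S,
    EndTrackSeries,
    Phase,
    censor_below_limit,
    count_events,
    event_frequencies,
    interpolate_gaps,
    length_series,
    max_length_and_lifetime,
    read_track_csv,
    segment_phases,
    spindle_filter,
    summarize_cohort,
    summarize_track,
)
from kip2traffic.synthetic_data import TrackGeneratorConfig, generate_tracks


def make_track(lengths_um, spindle_um=1.5, axis=(1.0, 0.0, 0.0)):
    n = len(lengths_um)
    times = np.arange(n) * FRAME_INTERVAL_S
    spbp = np.zeros((n, 3))
    spbd = np.tile(np.array([0.0, 0.0, 1e3 * spindle_um]), (n, 1))
    u = np.asarray(axis) / np.linalg.norm(axis)
    plus = 1e3 * np.outer(np.asarray(lengths_um), u)
    return EndTrackSeries(
        times_s=times, plus_end_nm=plus, spb_proximal_nm=spbp, spb_distal_nm=spbd
    )


class TestLengthSeries:
    def test_coincident_ends_zero(self):
        t = make_track([0.0, 0.0, 0.0])
        assert np.allclose(length_series(t), 0.0)

    def test_three_four_five(self):
        t = make_track([1.0, 1.0])
        t.plus_end_nm = np.tile(np.array([300.0, 400.0, 0.0]), (2, 1))
        assert np.allclose(length_series(t), 0.5)

    def test_matches_bruteforce_on_random_coordinates(self, rng):
        n = 40
        t = make_track(np.ones(n))
        t.plus_end_nm = rng.uniform(-5e3, 5e3, (n, 3))
        t.spb_proximal_nm = rng.uniform(-5e3, 5e3, (n, 3))
        expected = np.array(
            [
                np.sqrt(sum((a - b) ** 2 for a, b in zip(p, s))) / 1000.0
                for p, s in zip(t.plus_end_nm, t.spb_proximal_nm)
            ]
        )
        assert np.allclose(length_series(t), expected, atol=0)


class TestSpindleFilter:
    @pytest.mark.parametrize(
        "spindle_um, keep", [(1.5, True), (2.0, True), (2.5, False)]
    )
    def test_threshold_is_strict(self, spindle_um, keep):
        assert spindle_filter(make_track([1.0] * 5, spindle_um=spindle_um)) is keep

    def test_single_long_frame_drops_cell(self):
        t = make_track([1.0] * 5, spindle_um=1.5)
        t.spb_distal_nm[2] = np.array([0.0, 0.0, 2500.0])
        assert spindle_filter(t) is False


class TestCensoring:
    def test_all_below_limit_reports_zero(self):
        censored, det = censor_below_limit(np.full(10, 0.5))
        assert not det.any()
        assert max_length_and_lifetime(censored, det) == (0.0, 0.0)

    def test_single_frame_above_is_detectable(self):
        lengths = np.full(10, 0.5)
        lengths[4] = 0.7
        _, det = censor_below_limit(lengths)
        assert det[4] and det.sum() == 1

    def test_limit_consistent_with_five_pixels(self):
        # 5 pixels x 133.35 nm = 666.75 nm ~ the documented 666.7-nm limit
        assert 5 * 133.35 == pytest.approx(DETECTION_LIMIT_NM, abs=0.1)

    def test_monotone_in_limit(self, rng):
        lengths = rng.uniform(0.0, 2.5, 80)
        prev_max, prev_life = np.inf, np.inf
        for limit in (400.0, 666.7, 900.0, 1400.0):
            censored, det = censor_below_limit(lengths, limit)
            m, life = max_length_and_lifetime(censored, det)
            assert m <= prev_max + 1e-12
            assert life <= prev_life + 1e-12
            prev_max, prev_life = m, life


class TestMaxLengthAndLifetime:
    def test_full_window_lifetime(self):
        lengths = np.full(80, 1.5)
        censored, det = censor_below_limit(lengths)
        m, life = max_length_and_lifetime(censored, det)
        assert life == pytest.approx(85.6)
        assert m == pytest.approx(1.5)

    def test_longest_contiguous_span_convention(self):
        lengths = np.concatenate([np.full(10, 1.0), np.zeros(5), np.full(20, 0.9)])
        censored, det = censor_below_limit(lengths)
        m, life = max_length_and_lifetime(censored, det)
        assert life == pytest.approx(20 * FRAME_INTERVAL_S)
        assert m == pytest.approx(1.0)  # max over all spans, not just longest

    def test_isolated_single_detection_ignored(self):
        lengths = np.zeros(30)
        lengths[7] = 1.2
        censored, det = censor_below_limit(lengths)
        assert max_length_and_lifetime(censored, det) == (0.0, 0.0)


class TestSegmentation:
    def test_monotone_ramp_single_growth_phase(self):
        t = np.arange(57) * FRAME_INTERVAL_S
        y = 0.8 + 1.2 / 60.0 * t  # 1.2 um/min over ~60 s
        phases = segment_phases(y, t)
        assert len(phases) == 1
        assert phases[0].kind == "growth"
        assert phases[0].speed_um_per_min == pytest.approx(1.2, rel=1e-9)

    def test_triangle_wave_one_catastrophe(self):
        t = np.arange(60) * FRAME_INTERVAL_S
        y = np.where(t <= t[30], 0.8 + 0.025 * t, 0.8 + 0.025 * t[30] - 0.04 * (t - t[30]))
        phases = segment_phases(y, t)
        kinds = [p.kind for p in phases]
        assert kinds == ["growth", "shrinkage"]
        n_cat, n_res = count_events(phases)
        assert (n_cat, n_res) == (1, 0)

    def test_too_few_frames_warns_and_returns_empty(self):
        with pytest.warns(RuntimeWarning):
            assert segment_phases(np.array([1.0, 1.1])) == []

    def test_phase_speed_consistency(self):
        """Growth minus shrinkage displacement equals the net length change."""
        cfg = TrackGeneratorConfig(n_tracks=10, noise_sigma_nm=0.0, seed=5,
                                   initial_length_um=1.5)
        tracks, _ = generate_tracks(cfg)
        for tr in tracks:
            y = tr.true_lengths_um
            phases = segment_phases(y, tr.times_s)
            if not phases:
                continue
            net = sum(p.delta_um for p in phases)
            i0 = phases[0].i_start
            i1 = phases[-1].i_end
            assert net == pytest.approx(y[i1] - y[i0], abs=1e-9)


class TestEventFrequencies:
    def test_one_catastrophe_per_growth_minute(self):
        phases = [
            Phase("growth", 0.0, 60.0, 0, 55, 1.0, 1.0),
            Phase("shrinkage", 60.0, 70.0, 56, 65, 2.0, -0.4),
        ]
        f_cat, f_res = event_frequencies(phases)
        assert f_cat == pytest.approx(1.0)
        assert f_res == 0.0  # shrink time observed, no rescue
        phases.append(Phase("growth", 70.0, 80.0, 66, 74, 1.0, 0.2))
        f_cat, f_res = event_frequencies(phases)
        assert f_res == pytest.approx(6.0)  # 1 rescue / 10 s of shrinkage

    def test_no_catastrophes_zero_frequency(self):
        phases = [Phase("growth", 0.0, 30.0, 0, 27, 1.0, 0.5)]
        f_cat, f_res = event_frequencies(phases)
        assert f_cat == 0.0
        assert f_res is None  # no shrinkage time at all: reported as absent

    def test_pooled_rate_recovers_generator_poisson_rate(self):
        cfg = TrackGeneratorConfig(
            n_tracks=150,
            noise_sigma_nm=0.0,
            seed=9,
            initial_length_um=2.0,
            catastrophe_rate_per_min=0.8,
            rescue_rate_per_min=2.0,
            shrink_speed_um_min=1.5,
        )
        tracks, _ = generate_tracks(cfg)
        n_cat = sum(1 for tr in tracks for k in tr.switch_kinds if k == "catastrophe")
        growth_min = (
            sum(
                (b - a)
                for tr in tracks
                for a, b, st in _phase_bounds(tr)
                if st == "growth"
            )
            / 60.0
        )
        rate = n_cat / growth_min
        se = np.sqrt(n_cat) / growth_min
        assert abs(rate - 0.8) < 2 * se


def _phase_bounds(tr):
    T = tr.times_s[-1]
    bounds = [0.0] + list(tr.switch_times_s) + [T]
    return [
        (a, b, st) for a, b, st in zip(bounds[:-1], bounds[1:], tr.states)
    ]


class TestSummarizeTrack:
    def test_oracle_recomputation_matches(self, rng):
        """All summary statistics match an independent brute-force pass."""
        cfg = TrackGeneratorConfig(n_tracks=5, noise_sigma_nm=10.0, seed=3)
        tracks, _ = generate_tracks(cfg)
        for tr in tracks:
            et = EndTrackSeries(
                times_s=tr.times_s,
                plus_end_nm=tr.plus_end_nm,
                spb_proximal_nm=tr.spb_proximal_nm,
                spb_distal_nm=tr.spb_distal_nm,
            )
            s = summarize_track(et)
            # brute force: per-frame distances, censoring, spans
            d = tr.plus_end_nm - tr.spb_proximal_nm
            lengths = np.sqrt((d**2).sum(axis=1)) / 1000.0
            det = lengths > DETECTION_LIMIT_NM / 1000.0
            runs, cur = [], 0
            for flag in det:
                cur = cur + 1 if flag else 0
                runs.append(cur)
            best = max(runs)
            if best >= 2:
                assert s.lifetime_s == pytest.approx(best * FRAME_INTERVAL_S)
            else:
                assert s.lifetime_s == 0.0

    def test_counts_match_frequencies(self):
        cfg = TrackGeneratorConfig(n_tracks=20, noise_sigma_nm=20.0, seed=12,
                                   initial_length_um=1.6)
        tracks, _ = generate_tracks(cfg)
        for tr in tracks:
            et = EndTrackSeries(
                times_s=tr.times_s,
                plus_end_nm=tr.plus_end_nm,
                spb_proximal_nm=tr.spb_proximal_nm,
                spb_distal_nm=tr.spb_distal_nm,
            )
            s = summarize_track(et)
            if s.catastrophe_frequency_per_min is not None and s.growth_time_s > 0:
                assert s.catastrophe_frequency_per_min == pytest.approx(
                    s.n_catastrophes / s.growth_time_s * 60.0
                )


def test_cohort_summary_shapes():
    cfg = TrackGeneratorConfig(n_tracks=30, seed=2)
    tracks, _ = generate_tracks(cfg)
    summaries = []
    for tr in tracks:
        et = EndTrackSeries(
            times_s=tr.times_s,
            plus_end_nm=tr.plus_end_nm,
            spb_proximal_nm=tr.spb_proximal_nm,
            spb_distal_nm=tr.spb_distal_nm,
        )
        summaries.append(summarize_track(et))
    cohort = summarize_cohort(summaries)
    assert cohort["n_tracks"] == 30
    assert 0.0 <= cohort["detectable_fraction"] <= 1.0
    assert len(cohort["lifetime_cdf"]["lifetime_s"]) == 30
    assert sum(cohort["max_length_histogram"]["counts"]) == 30


class TestTrackIO:
    def test_round_trip(self, tmp_path):
        cfg = TrackGeneratorConfig(n_tracks=2, seed=4)
        tracks, _ = generate_tracks(cfg, out_dir=tmp_path)
        t = read_track_csv(tmp_path / "track0000.csv")
        assert t.n_frames == cfg.n_frames
        assert np.allclose(t.plus_end_nm, tracks[0].plus_end_nm)

    def test_duplicate_frames_rejected(self, tmp_path):
        cfg = TrackGeneratorConfig(n_tracks=1, n_frames=5, seed=4)
        generate_tracks(cfg, out_dir=tmp_path)
        path = tmp_path / "track0000.csv"
        lines = path.read_text().splitlines()
        lines.append(lines[-1])  # duplicate the last frame row
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="duplicate frame"):
            read_track_csv(path)

    def test_missing_column_cited(self, tmp_path):
        (tmp_path / "bad.csv").write_text("frame,time_s\n0,0.0\n")
        with pytest.raises(ValueError, match="plus_x_nm"):
            read_track_csv(tmp_path / "bad.csv")


class TestGapHandling:
    def test_short_gap_interpolated(self):
        t = make_track(np.linspace(1.0, 2.0, 20))
        t.plus_end_nm[5] = np.nan
        with pytest.warns(RuntimeWarning):
            pieces = interpolate_gaps(t)
        assert len(pieces) == 1
        assert np.all(np.isfinite(pieces[0].plus_end_nm))
        # linear interpolation between neighbours
        expected = 0.5 * (t.plus_end_nm[4] + t.plus_end_nm[6])
        assert np.allclose(pieces[0].plus_end_nm[5], expected)

    def test_long_gap_splits_track(self):
        t = make_track(np.linspace(1.0, 2.0, 20))
        t.plus_end_nm[8:12] = np.nan
        pieces = interpolate_gaps(t)
        assert len(pieces) == 2
        assert pieces[0].n_frames == 8
        assert pieces[1].n_frames == 8
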