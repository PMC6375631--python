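"""Event idealization: efficiencies, threshold-run detection, dwell samples."""

import numpy as np
import pytest

from polvmut import (FretSimParams, FretTrajectory, ThresholdEventDetector,
                     detect_events, dwell_times, efficiency_histogram,
                     fret_efficiency, gen_fret_trajectories, rebind_times)


def make_traj(bound_mask, frame_dt=0.3, e_bound=0.7, i_total=300.0,
              traj_id="t0"):
    """Noiseless trajectory with the given per-frame bound mask."""
    n = len(bound_mask)
    mask = np.asarray(bound_mask, dtype=bool)
    times = np.arange(n) * frame_dt
    i_a = np.where(mask, i_total * e_bound, 0.0)
    i_d = np.where(mask, i_total * (1 - e_bound), i_total)
    return FretTrajectory(traj_id, times, i_d, i_a)


class TestFretEfficiency:
    @pytest.mark.parametrize("i_d,i_a,expected", [
        (500.0, 500.0, 0.5),
        (300 * 0.3, 300 * 0.7, 0.7),
        (100.0, 0.0, 0.0),
    ])
    def test_scalar_values(self, i_d, i_a, expected):
        assert fret_efficiency(i_d, i_a) == pytest.approx(expected)

    def test_nonpositive_total_invalid(self):
        with pytest.raises(ValueError):
            fret_efficiency(0.0, 0.0)
        e = fret_efficiency(np.array([-5.0, 100.0]), np.array([5.0, 100.0]))
        assert np.isnan(e[0]) and e[1] == 0.5

    def test_clipped_to_unit_interval(self):
        e = fret_efficiency(np.array([-50.0]), np.array([100.0]))
        assert e[0] == 1.0  # negative donor clipped


class TestDetectEvents:
    def test_single_block_dwell(self):
        mask = np.zeros(60, dtype=bool)
        mask[10:30] = True  # frames 10..29 bound
        es = detect_events(make_traj(mask), threshold=0.2, min_frames=2)
        assert len(es) == 1
        ev = es.events[0]
        assert ev.dwell_s == pytest.approx(6.0)
        assert not ev.censored
        assert ev.mean_E == pytest.approx(0.7)

    def test_all_unbound_gives_empty_set(self):
        es = detect_events(make_traj(np.zeros(50, dtype=bool)))
        assert len(es) == 0

    def test_runs_touching_edges_are_censored(self):
        mask = np.zeros(40, dtype=bool)
        mask[:5] = True
        mask[-4:] = True
        es = detect_events(make_traj(mask))
        assert [e.left_censored for e in es.events] == [True, False]
        assert [e.right_censored for e in es.events] == [False, True]

    def test_short_runs_below_min_frames_dropped(self):
        mask = np.zeros(30, dtype=bool)
        mask[10] = True  # single frame
        assert len(detect_events(make_traj(mask), min_frames=2)) == 0
        assert len(detect_events(make_traj(mask), min_frames=1)) == 1

    def test_threshold_monotone_in_bound_frames(self, noisy_fret_params):
        trajs, _ = gen_fret_trajectories(noisy_fret_params)
        frames_at = []
        for thr in (0.2, 0.4, 0.6):
            det = ThresholdEventDetector(threshold=thr, min_frames=1)
            es = det.transform(trajs)
            frames_at.append(sum(e.n_frames for e in es.events))
        assert frames_at[0] >= frames_at[1] >= frames_at[2]

    def test_detection_idempotent(self, noisy_fret_params):
        trajs, _ = gen_fret_trajectories(noisy_fret_params)
        det = ThresholdEventDetector()
        a = det.transform(trajs)
        b = det.transform(trajs)
        assert [(e.start_s, e.end_s) for e in a.events] == \
               [(e.start_s, e.end_s) for e in b.events]

    def test_conservation_of_trajectory_time(self, noisy_fret_params):
        # dwells + gaps + unbound head/tail spans tile the whole record,
        # within one frame per event boundary
        trajs, _ = gen_fret_trajectories(noisy_fret_params)
        det = ThresholdEventDetector(min_frames=1)
        for tr in trajs[:10]:
            es = det.detect(tr)
            evs = es.events
            if not evs:
                continue
            total = sum(e.dwell_s for e in evs) + sum(rebind_times(es))
            head = evs[0].start_s - tr.times[0]
            tail = (tr.times[-1] + tr.frame_dt) - evs[-1].end_s
            total += head + tail
            n_boundaries = 2 * len(evs)
            assert abs(total - tr.duration) <= n_boundaries * tr.frame_dt + 1e-9

    def test_noiseless_events_match_ground_truth(self):
        params = FretSimParams(tau_bound=6.1, tau_unbound=17.0, noise_sd=0.0,
                               duration=180.0, frame_dt=0.3, n_traj=40, seed=21)
        trajs, truth = gen_fret_trajectories(params)
        det = ThresholdEventDetector(threshold=0.2, min_frames=2,
                                     subtract_background=False)
        dt = params.frame_dt
        for tr in trajs:
            detected = det.detect(tr).events
            path = [e for e in truth if e.traj_id == tr.traj_id]
            # ground-truth bound events long enough to register on >= 2 frame
            # centers and flanked by unbound dwells wide enough (> one frame)
            # that detection cannot merge them with a neighbor
            resolvable = []
            for j, e in enumerate(path):
                if e.state != "bound" or e.dwell_s < 2 * dt or e.end_s > tr.times[-1]:
                    continue
                before = path[j - 1] if j > 0 else None
                after = path[j + 1] if j + 1 < len(path) else None
                if before is not None and before.dwell_s < 1.5 * dt:
                    continue
                if after is not None and after.dwell_s < 1.5 * dt:
                    continue
                resolvable.append(e)
            for ev in resolvable:
                match = [d for d in detected
                         if abs(d.start_s - ev.start_s) <= 1.5 * dt
                         and abs(d.end_s - ev.end_s) <= 1.5 * dt]
                assert match, f"unmatched true event {ev}"

    def test_recovery_rate_on_noisy_ensemble(self):
        # >= 90% of true dwells spanning >= 2 frames recovered with boundary
        # error <= 1 frame under 10% intensity noise
        params = FretSimParams(tau_bound=6.1, tau_unbound=17.0, noise_sd=30.0,
                               I_total=300.0, duration=180.0, frame_dt=0.3,
                               n_traj=100, seed=22)
        trajs, truth = gen_fret_trajectories(params)
        det = ThresholdEventDetector(threshold=0.2, min_frames=2)
        dt = params.frame_dt
        n_ok = n_tot = 0
        by_id = {tr.traj_id: det.detect(tr).events for tr in trajs}
        for ev in truth:
            if ev.state != "bound" or ev.dwell_s < 2 * dt:
                continue
            if ev.end_s > params.duration - dt or ev.start_s < dt:
                continue  # censored at record edges
            n_tot += 1
            detected = by_id.get(ev.traj_id, [])
            if any(abs(d.start_s - ev.start_s) <= 1.5 * dt
                   and abs(d.end_s - ev.end_s) <= 1.5 * dt for d in detected):
                n_ok += 1
        assert n_tot > 200
        assert n_ok / n_tot >= 0.90


class TestDwellAndRebindSamples:
    def test_dwell_sample_excludes_censored_by_default(self):
        mask = np.zeros(50, dtype=bool)
        mask[:5] = True     # left-censored
        mask[10:20] = True  # clean
        mask[30:40] = True  # clean
        es = detect_events(make_traj(mask))
        assert sorted(dwell_times(es)) == pytest.approx([3.0, 3.0])
        assert dwell_times(es, include_censored=True).size == 3

    def test_rebind_gaps(self):
        mask = np.zeros(60, dtype=bool)
        mask[5:10] = True
        mask[30:35] = True
        es = detect_events(make_traj(mask))
        gaps = rebind_times(es)
        assert gaps == pytest.approx([20 * 0.3])

    def test_single_event_has_no_gap(self):
        mask = np.zeros(30, dtype=bool)
        mask[10:15] = True
        assert rebind_times(detect_events(make_traj(mask))).size == 0

    def test_rebind_sample_mean_matches_generator(self):
        params = FretSimParams(tau_bound=6.1, tau_unbound=17.0, noise_sd=0.0,
                               duration=600.0, frame_dt=0.3, n_traj=150, seed=23)
        trajs, _ = gen_fret_trajectories(params)
        det = ThresholdEventDetector(min_frames=1)
        gaps = np.concatenate([rebind_times(det.detect(tr)) for tr in trajs])
        se = 17.0 / np.sqrt(gaps.size)
        assert abs(gaps.mean() - 17.0) < 2 * se + 0.3  # frame quantization


class TestEfficiencyHistogram:
    def test_constant_efficiency_occupies_single_bin(self):
        mask = np.zeros(40, dtype=bool)
        mask[10:30] = True
        es = detect_events(make_traj(mask, e_bound=0.7))
        centers, counts, mode = efficiency_histogram(es, bin_width=0.05)
        assert mode == pytest.approx(0.70)
        assert (counts > 0).sum() == 1

    def test_uniform_efficiencies_fill_bins_flat(self):
        rng = np.random.default_rng(0)
        n = 20000
        e_vals = rng.uniform(0, 1, n)
        i_total = 300.0
        tr = FretTrajectory("u", np.arange(n) * 0.3,
                            i_total * (1 - e_vals), i_total * e_vals)
        es = detect_events(tr, threshold=0.0, min_frames=1,
                           subtract_background=False)
        centers, counts, _ = efficiency_histogram(es, bin_width=0.05)
        interior = counts[1:-1]  # edge bins cover half-width
        assert interior.std() / interior.mean() < 0.1

    def test_empty_event_set_rejected(self):
        es = detect_events(make_traj(np.zeros(30, dtype=bool)))
        with pytest.raises(ValueError):
            efficiency_histogram(es)
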