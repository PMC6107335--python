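"""Purkinje-cell rate estimation, unit verification, grouping, alignment."""

import numpy as np
import pytest

from crchain import (
    CREvent,
    RateSeries,
    SequenceOutcome,
    SpikeTrain,
    align_to_cr_onset,
    average_with_ci,
    ci_separation,
    group_trials,
    instantaneous_rate,
    normalize,
    verify_eyelid_pc,
)


def regular_train(rate_hz, t_start=-1500.0, t_stop=2300.0):
    step = 1000.0 / rate_hz
    return SpikeTrain("u", np.arange(t_start, t_stop, step), np.array([]))


class TestInstantaneousRate:
    def test_regular_50hz_recovered_away_from_edges(self):
        r = instantaneous_rate(regular_train(50.0))
        interior = r.rate[200:-200]
        assert np.max(np.abs(interior - 50.0)) < 0.5

    def test_single_spike_flagged_zero(self):
        r = instantaneous_rate(SpikeTrain("u", np.array([100.0]), np.array([])))
        assert r.flagged
        assert np.all(r.rate == 0.0)

    def test_alternating_isis_give_100_50_segments(self):
        # ISIs 10 ms then 20 ms alternating: pre-smoothing rate is 100 Hz
        # on the 10 ms segments and 50 Hz on the 20 ms segments
        times = [0.0]
        for k in range(60):
            times.append(times[-1] + (10.0 if k % 2 == 0 else 20.0))
        tr = SpikeTrain("u", np.array(times), np.array([]))
        r = instantaneous_rate(tr, t_start=0.0, t_stop=times[-1], kernel_sd=0)
        assert r.rate[5] == pytest.approx(100.0)
        assert r.rate[15] == pytest.approx(50.0)
        assert r.rate[35] == pytest.approx(100.0)

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain("u", np.array([10.0, 0.0]), np.array([]))
        tr = SpikeTrain("u", np.array([0.0, 10.0]), np.array([]))
        tr.simple_spikes = np.array([10.0, 0.0])  # bypass constructor check
        with pytest.raises(ValueError):
            instantaneous_rate(tr)


class TestNormalize:
    def test_constant_rate_normalizes_to_one(self):
        r = instantaneous_rate(regular_train(80.0))
        n = normalize(r)
        assert np.allclose(n.rate[200:-200], 1.0, atol=0.02)

    def test_dip_ratio(self):
        t = np.arange(-1500.0, 2300.0)
        rate = np.full(t.size, 80.0)
        rate[(t >= 300) & (t < 600)] = 40.0
        n = normalize(RateSeries(t=t, rate=rate))
        assert n.rate[np.searchsorted(t, 450.0)] == pytest.approx(0.5)

    def test_zero_baseline_flagged(self):
        t = np.arange(-1500.0, 2300.0)
        rate = np.zeros(t.size)
        rate[t >= 0] = 50.0
        n = normalize(RateSeries(t=t, rate=rate))
        assert n.flagged and np.isnan(n.rate).all()

    def test_poisson_baseline_mean_near_one(self):
        # 50 Bernoulli-per-ms trains at 70 Hz; averaged baseline within 3%
        rng = np.random.default_rng(0)
        t = np.arange(-1500.0, 2300.0)
        means = []
        for _ in range(50):
            spikes = t[rng.random(t.size) < 0.07]
            r = normalize(instantaneous_rate(SpikeTrain("u", spikes,
                                                        np.array([]))))
            means.append(r.rate[(r.t >= -1500) & (r.t < 0)].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.03)


class TestVerifyEyelidPC:
    @staticmethod
    def _unit(us_locked, with_pause, n_trials=30, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(-1500.0, 2300.0)
        trains, us_times = [], []
        for k in range(n_trials):
            us = [500.0]
            simple = t[rng.random(t.size) < 0.07]
            if us_locked:
                cs = np.array([503.0])
            else:
                cs = np.round(rng.uniform(-1400, 2200, 1))
            if with_pause:
                for c in cs:
                    simple = simple[(simple <= c) | (simple > c + 15.0)]
            trains.append(SpikeTrain("u", simple, cs, k))
            us_times.append(us)
        return trains, us_times

    def test_us_locked_complex_spikes_with_pause(self):
        trains, us = self._unit(us_locked=True, with_pause=True)
        assert verify_eyelid_pc(trains, us) == "eyelid_pc"

    def test_unlocked_complex_spikes(self):
        trains, us = self._unit(us_locked=False, with_pause=True)
        assert verify_eyelid_pc(trains, us) == "non_eyelid_pc"

    def test_no_complex_spikes_not_pc(self):
        trains, us = self._unit(us_locked=True, with_pause=True)
        empty = [SpikeTrain(t.unit_id, t.simple_spikes, np.array([]),
                            t.trial_id) for t in trains]
        assert verify_eyelid_pc(empty, us) == "not_pc"

    def test_no_pause_not_pc(self):
        trains, us = self._unit(us_locked=True, with_pause=False)
        assert verify_eyelid_pc(trains, us) == "not_pc"


def _outcome(i, first=None, second=None):
    o = SequenceOutcome(trial_id=i, trial_type="cs_alone",
                        protocol="ipsilateral")
    if first is not None:
        o.events.append(CREvent(1, first[0], first[0] + 10, first[1],
                                first[0] + 150))
    if second is not None:
        o.events.append(CREvent(2, second[0], second[0] + 10, second[1],
                                second[0] + 150))
    return o


class TestGroupTrials:
    def test_nine_trials_split_three_ways(self):
        outs = [_outcome(i, first=(100.0 + i, 3.0)) for i in range(9)]
        g = group_trials(outs, key="first_onset")
        assert [sorted(grp) for grp in g["groups"]] == [[0, 1, 2], [3, 4, 5],
                                                        [6, 7, 8]]

    def test_remainder_to_earliest_groups(self):
        outs = [_outcome(i, first=(100.0 + i, 3.0)) for i in range(10)]
        g = group_trials(outs, key="first_onset")
        assert [len(grp) for grp in g["groups"]] == [4, 3, 3]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        outs = [_outcome(i, first=(float(rng.uniform(100, 400)), 4.0),
                         second=(900.0, 2.0) if rng.random() < 0.6 else None)
                for i in range(40)]
        g = group_trials(outs, key="second_onset")
        all_idx = g["non_cr"] + [i for grp in g["groups"] for i in grp]
        eligible = [i for i, o in enumerate(outs) if o.first_amp > 3.0]
        assert sorted(all_idx) == eligible

    def test_second_key_gated_on_first_amplitude(self):
        outs = [_outcome(i, first=(200.0, 2.0), second=(900.0, 2.0))
                for i in range(9)]
        with pytest.raises(ValueError):  # no eligible trials at all
            group_trials(outs, key="second_onset")

    def test_too_few_cr_trials_rejected(self):
        outs = [_outcome(i, first=(200.0, 3.5)) for i in range(2)]
        with pytest.raises(ValueError):
            group_trials(outs, key="first_onset")


class TestAverageWithCI:
    @staticmethod
    def _series(rate, t=None):
        t = np.arange(0.0, 100.0) if t is None else t
        return RateSeries(t=t, rate=np.full(t.size, rate), normalized=True)

    def test_identical_series_zero_width_ci(self):
        avg = average_with_ci([self._series(0.8)] * 5)
        np.testing.assert_allclose(avg.rate, 0.8)
        np.testing.assert_allclose(avg.ci_high - avg.ci_low, 0.0)

    def test_disjoint_groups_separate_everywhere(self):
        a = average_with_ci([self._series(0.4)] * 4)
        b = average_with_ci([self._series(1.0)] * 4)
        assert ci_separation(a, b).all()

    def test_null_groups_rarely_separate(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 200.0)
        spurious = 0
        reps = 100
        for _ in range(reps):
            g1 = [RateSeries(t=t, rate=1 + 0.3 * rng.standard_normal(t.size))
                  for _ in range(20)]
            g2 = [RateSeries(t=t, rate=1 + 0.3 * rng.standard_normal(t.size))
                  for _ in range(20)]
            sep = ci_separation(average_with_ci(g1), average_with_ci(g2))
            spurious += bool(sep[100])  # fixed time point
        assert spurious / reps <= 0.08


class TestAlignToOnset:
    @staticmethod
    def _dipped_series(onset, lead=50.0, depth=0.4):
        t = np.arange(-1500.0, 2300.0)
        rate = np.ones(t.size)
        dip = (t >= onset - lead) & (t < onset - lead + 300)
        rate[dip] -= depth
        return RateSeries(t=t, rate=rate, normalized=True)

    def test_equal_onsets_is_constant_shift(self):
        series = [self._dipped_series(400.0) for _ in range(5)]
        res = align_to_cr_onset(series, [400.0] * 5, seed=0)
        tau = res["tau"]
        # dip starts at aligned time -lead
        dip_start = tau[np.argmax(res["cr"].rate < 0.99)]
        assert dip_start == pytest.approx(-50.0, abs=1.0)

    def test_dip_leading_onset_appears_before_zero(self):
        rng = np.random.default_rng(2)
        onsets = rng.uniform(250, 450, 30)
        series = [self._dipped_series(o) for o in onsets]
        labels = list(onsets) + [np.nan] * 10
        series += [RateSeries(t=np.arange(-1500.0, 2300.0),
                              rate=np.ones(3800), normalized=True)
                   for _ in range(10)]
        res = align_to_cr_onset(series, labels, seed=0)
        tau = res["tau"]
        pre = (tau < 0) & (tau >= -40)
        assert res["cr"].rate[pre].mean() < 0.7
        assert abs(res["non_cr"].rate[pre].mean() - 1.0) < 0.05

    def test_metric_recovers_planted_rate_at_onset(self):
        series = [self._dipped_series(300.0, depth=0.25) for _ in range(8)]
        res = align_to_cr_onset(series, [300.0] * 8, seed=0)
        assert res["rate_at_onset"] == pytest.approx(0.75)

    def test_no_onsets_rejected(self):
        with pytest.raises(ValueError):
            align_to_cr_onset([], [], seed=0)
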