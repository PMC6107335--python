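"""Sequence statistics: probabilities, curves, resampling, CS2 transfer."""

import numpy as np
import pytest
from scipy import stats as sps

from crchain import (
    CREvent,
    GenParams,
    ProtocolConfig,
    SequenceOutcome,
    conditional_probability,
    cs2_transfer,
    extinction_curve,
    fraction_times,
    generate_session,
    session_summary,
    shuffle_null,
    timing_covariation,
)
from crchain.pipeline import decompose_session

from conftest import make_trace, ramp_trace


def outcome(i, first_amp=None, second_amp=None, trial_type="cs_alone",
            t1=(300.0, 310.0), t2=(900.0, 910.0)):
    o = SequenceOutcome(trial_id=i, trial_type=trial_type,
                        protocol="ipsilateral")
    if first_amp is not None:
        o.events.append(CREvent(1, t1[0], t1[0] + 10, first_amp, t1[1]))
    if second_amp is not None:
        o.events.append(CREvent(2, t2[0], t2[0] + 10, second_amp, t2[1]))
    return o


class TestSessionSummary:
    def test_direct_counting(self):
        outs = [outcome(i, first_amp=2.0,
                        second_amp=2.0 if i < 4 else None) for i in range(8)]
        outs += [outcome(8 + i) for i in range(2)]
        s = session_summary(outs)
        assert s.p_first == pytest.approx(0.8)
        assert s.p_second == pytest.approx(0.5)

    def test_no_first_crs_leaves_p_second_undefined(self):
        s = session_summary([outcome(i) for i in range(5)])
        assert np.isnan(s.p_second)
        assert not s.p_second_defined

    def test_binomial_recovery_on_generated_session(self):
        # truth: p_first = 0.9; estimates within exact binomial 95% CI
        outs = []
        for seed in range(4):
            s = generate_session(ProtocolConfig(), GenParams(), seed=seed)
            outs.extend(decompose_session(s))
        summ = session_summary(outs)
        lo, hi = sps.binom.interval(0.95, summ.n_trials, 0.9)
        assert lo / summ.n_trials <= summ.p_first <= hi / summ.n_trials


class TestExtinctionCurve:
    def test_exact_division(self):
        outs = [outcome(i, first_amp=2.0) for i in range(96)]
        curve = extinction_curve(outs)
        assert [c.n_trials for _, c in curve] == [12] * 8

    def test_remainder_to_earliest_portions(self):
        outs = [outcome(i, first_amp=2.0) for i in range(100)]
        curve = extinction_curve(outs)
        assert [c.n_trials for _, c in curve] == [13, 13, 13, 13, 12, 12, 12, 12]

    def test_partition_is_exact(self):
        outs = [outcome(i, first_amp=2.0) for i in range(101)]
        curve = extinction_curve(outs, n_portions=7)
        assert sum(c.n_trials for _, c in curve) == 101

    def test_fewer_trials_than_portions_rejected(self):
        with pytest.raises(ValueError):
            extinction_curve([outcome(0)], n_portions=8)

    def test_decaying_schedule_monotone_within_noise(self):
        # planted linear decay of p_second 0.8 -> 0 across the session
        rng = np.random.default_rng(5)
        n = 400
        outs = []
        for i in range(n):
            p = 0.8 * (1 - i / n)
            outs.append(outcome(i, first_amp=3.0,
                                second_amp=2.0 if rng.random() < p else None))
        ps = [c.p_second for _, c in extinction_curve(outs)]
        # allow binomial noise: each portion has 50 trials, sd ~0.07
        assert ps[0] > ps[-1] + 0.3
        assert all(ps[k] >= ps[k + 2] - 0.2 for k in range(len(ps) - 2))


class TestConditionalProbability:
    def test_degenerate_bin_has_unit_probability_and_ci(self):
        outs = [outcome(i, first_amp=3.5, second_amp=2.0) for i in range(30)]
        tab = conditional_probability(outs, seed=0)
        b = np.digitize(3.5, tab.bin_edges) - 1
        assert tab.p_second[b] == 1.0
        assert tab.ci_low[b] == 1.0 and tab.ci_high[b] == 1.0

    def test_half_split_bin_ci_matches_binomial_oracle(self):
        outs = [outcome(i, first_amp=3.5,
                        second_amp=2.0 if i < 25 else None) for i in range(50)]
        tab = conditional_probability(outs, seed=1)
        b = np.digitize(3.5, tab.bin_edges) - 1
        assert tab.p_second[b] == pytest.approx(0.5)
        assert 0.35 <= tab.ci_low[b] <= tab.p_second[b]
        assert tab.p_second[b] <= tab.ci_high[b] <= 0.65

    def test_chi_square_null_uniform_rejection_rate(self):
        # second CR independent of first amplitude: ~5% rejections at alpha=.05
        rej = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            outs = [outcome(i, first_amp=float(rng.uniform(0.4, 5.9)),
                            second_amp=2.0 if rng.random() < 0.5 else None)
                    for i in range(200)]
            tab = conditional_probability(outs, n_boot=10,
                                          seed=int(rng.integers(2**31)))
            rej += tab.chi2_p < 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_df_reduced_for_empty_bins(self):
        outs = [outcome(i, first_amp=3.5, second_amp=2.0) for i in range(20)]
        outs += [outcome(100 + i, first_amp=1.5) for i in range(20)]
        tab = conditional_probability(outs, seed=0)
        assert tab.df == 1  # only two occupied bins
        assert np.isnan(tab.p_second[tab.n_per_bin == 0]).all()

    def test_invariant_ci_brackets_estimate(self, chained_outcomes):
        tab = conditional_probability(chained_outcomes, seed=3)
        ok = tab.n_per_bin > 0
        assert np.all(tab.ci_low[ok] <= tab.p_second[ok])
        assert np.all(tab.p_second[ok] <= tab.ci_high[ok])
        assert tab.n_per_bin.sum() == tab.n_total


class TestFractionTimes:
    def test_linear_ramp_inverts_analytically(self):
        tr = ramp_trace(t_start=300, t_stop=500, peak=2.0)
        ev = CREvent(1, onset=300.0, latency_to_criterion=330.0,
                     amplitude=2.0, peak_time=500.0)
        ft = fraction_times(ev, tr, step=0.005)
        for f, t in ft.items():
            assert t == pytest.approx(300.0 + 200.0 * f, abs=1.0)

    def test_full_fraction_maps_to_peak(self):
        tr = ramp_trace(peak=3.0)
        ev = CREvent(1, 300.0, 330.0, 3.0, 500.0)
        ft = fraction_times(ev, tr)
        assert ft[1.0] == pytest.approx(500.0, abs=1e-9)

    def test_coarse_step_yields_few_levels(self):
        tr = ramp_trace(peak=3.0)
        ev = CREvent(1, 300.0, 330.0, 3.0, 500.0)
        ft = fraction_times(ev, tr, step=0.5)
        assert 2 <= len(ft) <= 3


class TestTimingCovariation:
    def test_perfect_linear_dependence(self):
        outs = [outcome(i, 3.0, 3.0, t1=(300.0 + 10 * i, 400.0 + 10 * i),
                        t2=(900.0 + 10 * i, 1000.0 + 10 * i))
                for i in range(10)]
        tp = timing_covariation(outs, measure_first="onset",
                                measure_second="onset")
        assert tp.r == pytest.approx(1.0)
        assert np.allclose(tp.intervals, 600.0)

    def test_subthreshold_amplitudes_excluded(self):
        outs = [outcome(i, 1.5, 1.5) for i in range(10)]
        tp = timing_covariation(outs, amp_threshold=2.0)
        assert len(tp.pairs) == 0 and np.isnan(tp.r)

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(0)
        outs = []
        for i in range(40):
            t1 = 300.0 + rng.normal(0, 20)
            t2 = t1 + 600 + rng.normal(0, 15)
            outs.append(outcome(i, 3.0, 3.0, t1=(t1, t1 + 100),
                                t2=(t2, t2 + 100)))
        # one pair planted 10 SD out in the second coordinate
        outs.append(outcome(99, 3.0, 3.0, t1=(300.0, 400.0),
                            t2=(2100.0, 2200.0)))
        tp = timing_covariation(outs, measure_first="onset",
                                measure_second="onset")
        assert tp.n_outliers_removed == 1
        assert len(tp.pairs) == 40

    def test_independent_generator_near_zero_r(self):
        rng = np.random.default_rng(1)
        outs = [outcome(i, 3.0, 3.0,
                        t1=(300 + rng.normal(0, 50), 400),
                        t2=(900 + rng.normal(0, 50), 1000))
                for i in range(500)]
        tp = timing_covariation(outs, measure_first="onset",
                                measure_second="onset")
        assert abs(tp.r) < 0.1


class TestShuffleNull:
    def test_identical_trials_degenerate(self):
        pairs = np.tile([300.0, 900.0], (10, 1))
        sn = shuffle_null(pairs, n_perm=100, seed=0)
        assert sn.ks_stat == 0.0
        assert sn.p == 1.0

    def test_pool_size(self):
        rng = np.random.default_rng(2)
        pairs = np.column_stack([rng.normal(300, 50, 30),
                                 rng.normal(900, 50, 30)])
        sn = shuffle_null(pairs, n_perm=500, seed=0)
        assert sn.shuffled_intervals.size == 500 * 30

    def test_chained_intervals_detected(self):
        rng = np.random.default_rng(3)
        t1 = rng.normal(300, 55, 100)
        pairs = np.column_stack([t1, t1 + 600 + rng.normal(0, 20, 100)])
        sn = shuffle_null(pairs, seed=0)
        assert sn.p < 0.05

    def test_type_i_error_calibrated(self):
        # independent timings: rejection rate ~alpha (light version; the
        # full 200-replicate calibration runs in the acceptance suite)
        rng = np.random.default_rng(4)
        rej = 0
        for rep in range(60):
            pairs = np.column_stack([rng.normal(300, 55, 100),
                                     rng.normal(900, 60, 100)])
            sn = shuffle_null(pairs, n_perm=500,
                              seed=int(rng.integers(2**31)))
            rej += sn.p < 0.05
        assert rej / 60 <= 0.15


class TestCS2Transfer:
    def test_direct_counting_single_session(self):
        outs = []
        i = 0
        for _ in range(18):  # CS1 with first CR > 3 mm: 18 trials, 16 seconds
            outs.append(outcome(i, 4.0, 2.0 if i < 16 else None,
                                trial_type="cs_alone"))
            i += 1
        for k in range(10):  # CS2-alone with first: 9 of 10 seconds
            outs.append(outcome(i, 4.0, 2.0 if k < 9 else None,
                                trial_type="cs2_alone"))
            i += 1
        for _ in range(12):  # CS2-alone without first CR
            outs.append(outcome(i, trial_type="cs2_alone"))
            i += 1
        res = cs2_transfer([outs])
        sess = res.per_session[0]
        assert sess["cs1"] == pytest.approx(16 / 18)
        assert sess["cs2_alone"] == pytest.approx(0.9)
        assert sess["cs2_alone_no_first"] == 0.0

    def test_feedback_vs_cs_bound_generators_discriminated(self):
        def sessions(driver, n=4):
            return [decompose_session(generate_session(
                ProtocolConfig(protocol="cs2_test"),
                GenParams(second_cr_driver=driver), seed=50 + k))
                for k in range(n)]
        fb = cs2_transfer(sessions("feedback"))
        cb = cs2_transfer(sessions("cs1"))
        assert abs(fb.mean_cs1 - fb.mean_cs2_alone) < 0.25
        assert cb.mean_cs2_alone < 0.1
        assert fb.mean_cs2_alone - cb.mean_cs2_alone > 0.5
        assert fb.mean_no_first < 0.1
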