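"""Conditioned-response detection and sequence decomposition.

An eyelid deflection counts as a CR when its amplitude reaches the 0.3 mm
criterion (5% of full closure).  CR onset is found with a two-step
algorithm: step 1 locates the initial deflection away from the pre-CS
baseline, step 2 back-projects linearly onto the baseline level to obtain
the exact onset time.  Multi-CR ipsilateral trials are decomposed by peak
prominence; contralateral right-eye amplitudes are corrected for
sympathetic co-movement during the CS.

Tie-breaks everywhere: the earliest qualifying sample wins.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .types import (
    CR_CRITERION_MM,
    CREvent,
    EyelidTrace,
    SequenceOutcome,
    TrialRecord,
)
from .traces import velocity as _velocity

__all__ = [
    "detect_cr",
    "cr_onset",
    "timing_measures",
    "decompose_ipsilateral",
    "decompose_contralateral",
    "decompose_trial",
    "right_eye_amplitude",
    "MIN_PEAK_PROMINENCE_MM",
]

#: Minimum peak prominence (mm) for a local maximum to count as a distinct CR.
MIN_PEAK_PROMINENCE_MM = 0.5


def detect_cr(
    trace: EyelidTrace,
    criterion: float = CR_CRITERION_MM,
    t_start: float = 0.0,
    t_stop: Optional[float] = None,
) -> tuple[bool, float]:
    """Is a CR present in ``[t_start, t_stop)``, and when does it reach criterion?

    Returns ``(present, latency_to_criterion_ms)``; the latency is the first
    time point at which position deviates to at least ``criterion`` above
    baseline, or NaN when no CR is present.
    """
    if t_stop is None:
        t_stop = trace.t0 + trace.n
    seg = trace.window(t_start, t_stop)
    idx = np.flatnonzero(seg >= criterion)
    if idx.size == 0:
        return False, np.nan
    i0 = max(0, int(np.ceil(t_start - trace.t0)))
    return True, trace.t0 + i0 + float(idx[0])


def _pre_cs_noise_sd(trace: EyelidTrace, cs_on: float = 0.0) -> float:
    pre = trace.window(trace.t0, cs_on)
    return float(np.std(pre)) if pre.size else 0.0


def cr_onset(
    trace: EyelidTrace,
    crossing_time: float,
    cs_on: float = 0.0,
    noise_mult: float = 2.0,
    sustain_ms: int = 5,
    min_departure: float = 0.01,
    baseline: float = 0.0,
) -> tuple[float, bool]:
    """Two-step CR onset estimate.

    Step 1 scans backward from the criterion crossing for the departure
    point: the first sample at which position falls below
    ``baseline + max(noise_mult * pre-CS noise SD, min_departure)`` and
    stays below for at least ``sustain_ms`` ms.  Step 2 back-projects the
    line through the departure point and the criterion crossing down to the
    baseline level and returns the interpolated crossing time.

    Returns ``(onset_ms, fallback)``; ``fallback`` is True when no departure
    precedes the crossing and the onset fell back to the crossing time.
    """
    thresh = baseline + max(noise_mult * _pre_cs_noise_sd(trace, cs_on),
                            min_departure)
    i_cross = trace.index_of(crossing_time)
    y = trace.samples
    below = y < thresh
    dep = None
    for i in range(i_cross - 1, -1, -1):
        if below[i] and np.all(below[max(0, i - sustain_ms + 1): i + 1]):
            dep = i
            break
    if dep is None:
        return crossing_time, True
    t_dep = trace.t0 + dep
    y_dep = float(y[dep])
    y_cross = float(y[i_cross])
    if y_cross <= y_dep:
        return t_dep, False
    slope = (y_cross - y_dep) / (crossing_time - t_dep)
    onset = t_dep - (y_dep - baseline) / slope
    return min(float(onset), crossing_time), False


def timing_measures(
    trace: EyelidTrace,
    event: CREvent,
    vel: Optional[np.ndarray] = None,
) -> CREvent:
    """Fill the timing measures of a detected CR in place.

    Within the event window ``[onset, peak_time]``: time to half of peak,
    time to 90% of peak (first qualifying sample each), and time of peak
    velocity.  Amplitudes are relative to the pre-CS baseline (0 mm).
    """
    i0 = trace.index_of(max(event.onset, trace.t0))
    i1 = trace.index_of(event.peak_time)
    if i1 < i0:
        raise ValueError("peak_time precedes onset")
    seg = trace.samples[i0: i1 + 1]
    amp = event.amplitude

    def first_at(level: float) -> float:
        idx = np.flatnonzero(seg >= level)
        return trace.t0 + i0 + float(idx[0]) if idx.size else event.peak_time

    event.t_half_peak = first_at(amp / 2.0)
    event.t_90_peak = first_at(0.9 * amp)
    v = vel if vel is not None else _velocity(trace)
    event.t_peak_velocity = trace.t0 + i0 + float(np.argmax(v[i0: i1 + 1]))
    return event


def right_eye_amplitude(
    right_trace: EyelidTrace,
    cs_on: float = 0.0,
    cs_off: float = 500.0,
    t_stop: Optional[float] = None,
) -> float:
    """Corrected right-eye CR amplitude for the contralateral protocol.

    The maximum of right eyelid position during the CS (when the left-eye
    CR occurs and sympathetic co-movement can appear) is subtracted from
    the overall maximum over the analysis window, suppressing false right
    CRs caused by co-movement.  Never exceeds the raw maximum deviation.
    """
    if t_stop is None:
        t_stop = right_trace.t0 + right_trace.n
    overall = right_trace.window(cs_on, t_stop)
    during_cs = right_trace.window(cs_on, cs_off)
    if overall.size == 0:
        return 0.0
    correction = float(during_cs.max()) if during_cs.size else 0.0
    return max(float(overall.max()) - max(correction, 0.0), 0.0)


# ---------------------------------------------------------------------------
# sequence decomposition


def _squint_gate(trace: EyelidTrace, us2_time: float) -> bool:
    """Range gate qualifying a trial for second-CR analysis.

    The difference between the position maximum over [400, us2) ms and the
    minimum over [us2-300, us2) ms must be at least 1 mm; a sustained
    squint after the first CR makes the two comparable and fails the gate.
    """
    hi = trace.window(400.0, us2_time)
    lo = trace.window(us2_time - 300.0, us2_time)
    if hi.size == 0 or lo.size == 0:
        return True
    return float(hi.max() - lo.min()) >= 1.0


def _make_event(
    trace: EyelidTrace,
    index: int,
    onset: float,
    latency: float,
    peak_time: float,
    amplitude: float,
    vel: np.ndarray,
    fallback: bool = False,
) -> CREvent:
    onset = min(onset, latency)
    ev = CREvent(index_in_sequence=index, onset=onset,
                 latency_to_criterion=max(latency, onset),
                 amplitude=amplitude, peak_time=peak_time,
                 eye=trace.eye, onset_fallback=fallback)
    return timing_measures(trace, ev, vel)


def _first_cr_event(
    trace: EyelidTrace,
    vel: np.ndarray,
    peak_time: float,
    amplitude: float,
    criterion: float,
    cs_on: float,
) -> CREvent:
    _, latency = detect_cr(trace, criterion, cs_on, peak_time + 1.0)
    if not np.isfinite(latency):
        latency = peak_time
    onset, fb = cr_onset(trace, latency, cs_on)
    return _make_event(trace, 1, onset, latency, peak_time, amplitude, vel,
                       fallback=fb)


def _later_cr_event(
    trace: EyelidTrace,
    vel: np.ndarray,
    index: int,
    prev_peak_time: float,
    peak_time: float,
    amplitude: float,
    criterion: float,
) -> CREvent:
    # onset of CR k >= 2: time of the position minimum between the peaks
    seg = trace.window(prev_peak_time, peak_time)
    onset = prev_peak_time + float(np.argmin(seg)) if seg.size else prev_peak_time
    between = trace.window(onset, peak_time + 1.0)
    idx = np.flatnonzero(between >= criterion)
    latency = onset + float(idx[0]) if idx.size else peak_time
    return _make_event(trace, index, onset, latency, peak_time, amplitude, vel)


def decompose_ipsilateral(
    trial: TrialRecord,
    trace: Optional[EyelidTrace] = None,
    criterion: float = CR_CRITERION_MM,
    prominence: float = MIN_PEAK_PROMINENCE_MM,
    gap_interval: float = 600.0,
    vel: Optional[np.ndarray] = None,
) -> SequenceOutcome:
    """Decompose an ipsilateral trial into its sequence of CRs.

    CS-alone trials are searched over the full record; paired trials are
    truncated at the delivered US onset, with the second-CR peak
    constrained to within 100 ms of the scheduled US₂ time.  Local maxima
    with prominence >= 0.5 mm define CR candidates; trials whose first-CR
    onset falls after CS offset are handled with the windowed
    delayed/absent rule.  No second CR is ever reported without a first.
    """
    if trace is None:
        trace = trial.traces["left"]
    if vel is None:
        vel = _velocity(trace)
    cs_on, cs_off = trial.cs_on, trial.cs_off
    us2_sched = cs_off + gap_interval
    us_time = trial.first_us_time
    t_stop = us_time if us_time is not None else trace.t0 + trace.n

    out = SequenceOutcome(trial_id=trial.trial_id, trial_type=trial.trial_type,
                          protocol="ipsilateral",
                          us_labels=tuple(u.label for u in trial.us_delivered))

    # candidate peaks on the (possibly truncated) analysis window
    i0 = trace.index_of(cs_on)
    i1 = max(0, int(np.ceil(t_stop - trace.t0)))
    seg = trace.samples[i0:i1]
    pk_idx, _ = find_peaks(seg, prominence=prominence)
    peak_times = cs_on + pk_idx.astype(float)
    peak_amps = seg[pk_idx]
    # discard sub-criterion ripples
    keep = peak_amps >= criterion
    peak_times, peak_amps = peak_times[keep], peak_amps[keep]

    present, latency = detect_cr(trace, criterion, cs_on, t_stop)
    if not present:
        return out

    first_onset, _ = cr_onset(trace, latency, cs_on)

    if peak_times.size >= 1 and first_onset < cs_off:
        events = [_first_cr_event(trace, vel, peak_times[0], float(peak_amps[0]),
                                  criterion, cs_on)]
        out.squint_gate_passed = _squint_gate(trace, min(us2_sched, t_stop))
        if out.squint_gate_passed:
            if trial.is_paired:
                # second CR peak assumed within 100 ms of US2
                in_win = (peak_times[1:] >= us2_sched - 100.0) & (
                    peak_times[1:] <= us2_sched + 100.0)
                cand_t = peak_times[1:][in_win]
                cand_a = peak_amps[1:][in_win]
                if cand_t.size:
                    events.append(_later_cr_event(
                        trace, vel, 2, events[0].peak_time,
                        float(cand_t[0]), float(cand_a[0]), criterion))
                else:
                    # truncation at the US can clip the peak's prominence;
                    # fall back to the windowed maximum, requiring a
                    # criterion-sized re-rise above the inter-CR minimum so
                    # the first CR's decay tail is not double-counted
                    lo = us2_sched - 100.0
                    seg2 = trace.window(lo, t_stop)
                    if seg2.size:
                        pk2_t = lo + float(np.argmax(seg2))
                        amp2 = float(seg2.max())
                        valley = trace.window(events[0].peak_time, pk2_t)
                        rise = amp2 - float(valley.min()) if valley.size else 0.0
                        if amp2 >= criterion and rise >= criterion:
                            events.append(_later_cr_event(
                                trace, vel, 2, events[0].peak_time,
                                pk2_t, amp2, criterion))
            elif peak_times.size >= 2:
                for k in range(1, peak_times.size):
                    events.append(_later_cr_event(
                        trace, vel, k + 1, float(peak_times[k - 1]),
                        float(peak_times[k]), float(peak_amps[k]), criterion))
            else:
                # single prominent peak: search the 200-800 ms post-offset
                # window for a distinct smaller rebound (flagged decision)
                lo, hi = cs_off + 200.0, min(cs_off + 800.0, t_stop)
                j0 = trace.index_of(lo)
                j1 = max(j0, int(np.ceil(hi - trace.t0)))
                sub = trace.samples[j0:j1]
                sidx, _ = find_peaks(sub, prominence=criterion)
                sidx = sidx[(sub[sidx] >= criterion)
                            & (lo + sidx > events[0].peak_time)]
                if sidx.size:
                    out.flagged = True
                    events.append(_later_cr_event(
                        trace, vel, 2, events[0].peak_time,
                        lo + float(sidx[0]), float(sub[sidx[0]]), criterion))
        out.events = events
        return out

    # delayed-or-absent first CR (onset at/after CS offset, or no prominent peak)
    first_win_amp = float(np.max(trace.window(cs_on, min(cs_off + 200.0, t_stop)),
                                 initial=0.0))
    out.delayed_first = first_onset >= cs_off
    if first_win_amp < criterion:
        # no first CR: later activity cannot be attributed to a sequence
        out.flagged = bool(peak_times.size)
        return out
    win_end = min(cs_off + 200.0, t_stop)
    seg1 = trace.window(cs_on, win_end)
    pk1_t = cs_on + float(np.argmax(seg1))
    ev1 = _first_cr_event(trace, vel, pk1_t, first_win_amp, criterion, cs_on)
    out.events = [ev1]
    out.squint_gate_passed = _squint_gate(trace, min(us2_sched, t_stop))
    if out.squint_gate_passed:
        lo, hi = cs_off + 200.0, min(cs_off + 800.0, t_stop)
        if hi > lo:
            seg2 = trace.window(lo, hi)
            amp2 = float(seg2.max())
            if amp2 >= criterion and seg2.size:
                pk2_t = lo + float(np.argmax(seg2))
                out.events.append(_later_cr_event(trace, vel, 2, pk1_t,
                                                  pk2_t, amp2, criterion))
    return out


def decompose_contralateral(
    trial: TrialRecord,
    criterion: float = CR_CRITERION_MM,
    gap_interval: float = 400.0,
    vel_left: Optional[np.ndarray] = None,
    vel_right: Optional[np.ndarray] = None,
) -> SequenceOutcome:
    """Decompose a contralateral trial: left-eye first CR, right-eye second.

    The right-eye amplitude is corrected by subtracting its maximum during
    the CS from its overall maximum (sympathetic co-movement correction);
    the corrected amplitude must reach the 0.3 mm criterion for a right CR.
    """
    left = trial.traces["left"]
    right = trial.traces.get("right")
    cs_on, cs_off = trial.cs_on, trial.cs_off
    us_time = trial.first_us_time
    t_stop = us_time if us_time is not None else left.t0 + left.n

    out = SequenceOutcome(trial_id=trial.trial_id, trial_type=trial.trial_type,
                          protocol="contralateral",
                          us_labels=tuple(u.label for u in trial.us_delivered))
    if vel_left is None:
        vel_left = _velocity(left)

    present, latency = detect_cr(left, criterion, cs_on, t_stop)
    if not present:
        return out
    seg = left.window(cs_on, min(cs_off + 200.0, t_stop))
    amp1 = float(seg.max())
    pk1_t = cs_on + float(np.argmax(seg))
    events = [_first_cr_event(left, vel_left, pk1_t, amp1, criterion, cs_on)]

    if right is not None:
        if vel_right is None:
            vel_right = _velocity(right)
        corrected = right_eye_amplitude(right, cs_on, cs_off, t_stop)
        if corrected >= criterion:
            seg_r = right.window(cs_off, t_stop)
            if seg_r.size:
                pk2_t = cs_off + float(np.argmax(seg_r))
                _, lat2 = detect_cr(right, criterion, cs_off, pk2_t + 1.0)
                if not np.isfinite(lat2):
                    lat2 = pk2_t
                onset2, fb2 = cr_onset(right, lat2, cs_on)
                ev2 = _make_event(right, 2, onset2, lat2, pk2_t, corrected,
                                  vel_right, fallback=fb2)
                events.append(ev2)
    out.events = events
    return out


def decompose_trial(trial: TrialRecord, gap_interval: float = 600.0,
                    **kwargs) -> SequenceOutcome:
    """Protocol dispatcher for sequence decomposition."""
    if trial.protocol == "contralateral":
        return decompose_contralateral(trial, gap_interval=gap_interval, **kwargs)
    return decompose_ipsilateral(trial, gap_interval=gap_interval, **kwargs)
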