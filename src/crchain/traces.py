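"""Calibration, smoothing, differentiation, and screening of eyelid traces.

Raw eyelid-position readouts are scaled so that a test-US full closure reads
6.0 mm and the pre-CS baseline mean is zero.  Position is low-pass filtered
with a Savitzky-Golay filter; velocity uses a second-order-accurate
difference scheme followed by the same filter.  Trials with movement
artifacts are dropped whole, never repaired.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .types import (
    CR_CRITERION_MM,
    FULL_CLOSURE_MM,
    EyelidTrace,
    ExclusionReport,
    TrialRecord,
)

__all__ = ["calibrate", "smooth", "velocity", "screen_trial", "screen_session"]

#: Default Savitzky-Golay window (samples = ms) and polynomial order.  A
#: 21 ms cubic window suppresses sensor noise while leaving CR rise times
#: (~50-150 ms) essentially untouched.
DEFAULT_SG_WINDOW = 21
DEFAULT_SG_ORDER = 3


def calibrate(
    raw: np.ndarray,
    full_closure_reading: float,
    t0: float = -200.0,
    eye: str = "left",
    pre_cs_ms: float = 200.0,
) -> EyelidTrace:
    """Scale a raw readout to millimeters and zero the pre-CS baseline.

    ``full_closure_reading`` is the raw value of the test-US full closure;
    after calibration it maps to 6.0 mm.  The mean of the pre-CS window is
    subtracted so the baseline reads 0 mm.
    """
    if full_closure_reading <= 0:
        raise ValueError("full-closure calibration reading must be positive")
    raw = np.asarray(raw, dtype=float)
    scale = FULL_CLOSURE_MM / full_closure_reading
    mm = raw * scale
    n_pre = int(round(-t0)) if t0 < 0 else 0
    if n_pre > 0:
        mm = mm - mm[:n_pre].mean()
    return EyelidTrace(samples=mm, t0=t0, eye=eye, calibration=scale)


def smooth(
    trace: EyelidTrace,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_ORDER,
) -> EyelidTrace:
    """Savitzky-Golay low-pass filtering of eyelid position.

    Local least-squares polynomial smoothing: any polynomial of degree
    <= ``polyorder`` passes through unchanged and the DC gain is 1.
    """
    if window % 2 == 0 or window < polyorder + 2:
        raise ValueError("window must be odd and >= polyorder + 2")
    return trace.copy_with(savgol_filter(trace.samples, window, polyorder))


def velocity(
    trace: EyelidTrace,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_ORDER,
    smoothed: bool = True,
) -> np.ndarray:
    """Eyelid velocity in mm/ms.

    Central differences in the interior with one-sided second-order
    schemes at the endpoints, then the same Savitzky-Golay filter as
    :func:`smooth` (disable with ``smoothed=False``).
    """
    if trace.n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    v = np.gradient(trace.samples, 1.0, edge_order=2)
    if smoothed:
        v = savgol_filter(v, window, polyorder)
    return v


def _first_exceeding(x: np.ndarray, t0: float, thresh: float) -> float:
    idx = np.flatnonzero(x > thresh)
    return t0 + float(idx[0]) if idx.size else np.nan


def screen_trial(
    trial: TrialRecord,
    cr_criterion: float = CR_CRITERION_MM,
    negative_limit: float = 0.5,
) -> ExclusionReport:
    """Apply the trial-exclusion rules to one trial.

    A trial is discarded if (1) an upward eyelid movement exceeds the
    0.3 mm CR criterion during the 200 ms before CS onset or the first
    100 ms from CS onset, or (2) the eyelid position deviates below
    -0.5 mm at any time before US onset on paired trials, or from trial
    start to 500 ms after CS offset on CS-alone trials.  On contralateral
    trials both eyes are screened and either can trigger exclusion.
    Both windows are half-open; "exceeding" is a strict inequality
    relative to the pre-CS baseline (already zeroed by calibration).
    """
    if trial.is_paired and trial.first_us_time is None:
        raise ValueError(f"paired trial {trial.trial_id} has no US time")
    neg_end = (trial.first_us_time if trial.is_paired
               else trial.cs_off + 500.0)

    for eye in sorted(trial.traces):
        tr = trial.traces[eye]
        pre = tr.window(tr.t0, trial.cs_on)
        t = _first_exceeding(pre, tr.t0, cr_criterion)
        if np.isfinite(t):
            return ExclusionReport(trial.trial_id, False, "pre_cs_upward", t)
        early = tr.window(trial.cs_on, trial.cs_on + 100.0)
        t = _first_exceeding(early, trial.cs_on, cr_criterion)
        if np.isfinite(t):
            return ExclusionReport(trial.trial_id, False, "early_cs_upward", t)
        seg = tr.window(tr.t0, neg_end)
        t = _first_exceeding(-seg, tr.t0, negative_limit)
        if np.isfinite(t):
            return ExclusionReport(trial.trial_id, False, "negative_deviation", t)
    return ExclusionReport(trial.trial_id, True, "none")


def screen_session(trials: list[TrialRecord], **kwargs) -> list[ExclusionReport]:
    """Screen every trial, marking excluded trials in place."""
    reports = []
    for trial in trials:
        rep = screen_trial(trial, **kwargs)
        trial.excluded = not rep.kept
        trial.exclusion_reason = rep.reason
        reports.append(rep)
    return reports


def exclusion_rate(n_excluded: int, n_total: int) -> float:
    """Percentage of trials discarded, e.g. 242/17574 -> 1.4 (%)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_excluded / n_total


def criterion_as_percent(criterion: float = CR_CRITERION_MM,
                         full_closure: float = FULL_CLOSURE_MM) -> float:
    """The CR criterion expressed as a percentage of full closure (5%)."""
    return 100.0 * criterion / full_closure
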