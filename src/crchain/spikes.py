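"""Purkinje-cell firing-rate estimation and its relation to CR kinematics.

The instantaneous simple-spike rate is estimated per trial as the inverse
inter-spike interval (piecewise constant between spikes) convolved with a
20 ms SD Gaussian kernel, then normalized by the mean rate over 1500 ms of
pre-CS baseline.  Units are screened for Purkinje-cell identity (complex
spikes with a post-complex-spike simple-spike pause) and for eyelid-PC
identity (US-evoked complex spikes).  Trial-averaged rates carry pointwise
95% confidence intervals; non-overlap of the intervals between trial
groups is the criterion for reliable separation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import RateSeries, SequenceOutcome, SpikeTrain

__all__ = [
    "instantaneous_rate",
    "normalize",
    "verify_eyelid_pc",
    "group_trials",
    "average_with_ci",
    "ci_separation",
    "align_to_cr_onset",
    "SPIKE_WINDOW_MS",
]

#: Spike-trial clock relative to CS onset: [-1500, 2300) ms.
SPIKE_WINDOW_MS = (-1500.0, 2300.0)
KERNEL_SD_MS = 20.0


def _gauss_kernel(sd: float, truncate: float = 4.0) -> np.ndarray:
    half = int(np.ceil(truncate * sd))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def _edge_normalized_smooth(y: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian smoothing with the kernel mass renormalized inside the window."""
    k = _gauss_kernel(sd)
    num = np.convolve(y, k, mode="same")
    den = np.convolve(np.ones_like(y), k, mode="same")
    return num / den


def instantaneous_rate(
    train: SpikeTrain,
    t_start: float = SPIKE_WINDOW_MS[0],
    t_stop: float = SPIKE_WINDOW_MS[1],
    kernel_sd: float = KERNEL_SD_MS,
) -> RateSeries:
    """Inverse-ISI firing-rate estimate on the 1 kHz trial grid (raw Hz).

    Between consecutive simple spikes the rate is 1/ISI (in Hz); before
    the first and after the last spike the rate is zero.  The piecewise-
    constant series is then convolved with a unit-area Gaussian kernel
    (SD ``kernel_sd`` ms), renormalized at the window edges.  Trains with
    fewer than two simple spikes yield a flagged all-zero series.
    """
    t = np.arange(t_start, t_stop)
    s = train.simple_spikes
    if s.size and np.any(np.diff(s) < 0):
        raise ValueError("spike times must be sorted")
    s = np.unique(s)  # 1 ms rounding can merge spikes; refractoriness implies one
    if s.size < 2:
        return RateSeries(t=t, rate=np.zeros_like(t), flagged=True)
    rate = np.zeros_like(t)
    isi = np.diff(s)
    if np.any(isi <= 0):
        isi = np.maximum(isi, 1.0)  # coincident rounded spikes
    idx = np.clip(np.searchsorted(s, t, side="right") - 1, -1, s.size - 1)
    inside = (idx >= 0) & (idx < s.size - 1)
    rate[inside] = 1000.0 / isi[idx[inside]]
    if kernel_sd > 0:  # kernel_sd=0 exposes the raw piecewise-constant rate
        rate = _edge_normalized_smooth(rate, kernel_sd)
    return RateSeries(t=t, rate=rate)


def normalize(
    rate: RateSeries,
    baseline: tuple[float, float] = (-1500.0, 0.0),
) -> RateSeries:
    """Divide by the mean rate over the pre-CS baseline window.

    The baseline window is half-open ``[a, b)`` on the rate's own grid.  A
    zero baseline mean leaves the series undefined (NaN) and flagged.
    """
    mask = (rate.t >= baseline[0]) & (rate.t < baseline[1])
    if not mask.any():
        raise ValueError("baseline window outside the recorded span")
    base = float(rate.rate[mask].mean())
    if base == 0.0:
        return RateSeries(t=rate.t, rate=np.full_like(rate.rate, np.nan),
                          normalized=True, flagged=True)
    return RateSeries(t=rate.t, rate=rate.rate / base, normalized=True,
                      n_trials=rate.n_trials, flagged=rate.flagged)


def verify_eyelid_pc(
    trains: Sequence[SpikeTrain],
    us_times: Sequence[Sequence[float]],
    cs_latency_window: float = 10.0,
    us_locked_fraction: float = 0.5,
    pause_ratio: float = 0.5,
    pause_min_ms: int = 8,
    pause_search_ms: int = 20,
) -> str:
    """Classify a unit as ``eyelid_pc``, ``non_eyelid_pc`` or ``not_pc``.

    PC identity requires complex spikes plus a post-complex-spike pause in
    the complex-spike-triggered simple-spike average (rate below
    ``pause_ratio`` of the pre-event rate for at least ``pause_min_ms``
    consecutive ms within ``pause_search_ms``).  An eyelid PC additionally
    shows a complex spike within ``cs_latency_window`` ms after at least
    ``us_locked_fraction`` of US deliveries.  With no US trials in the
    session the eyelid check is undefined and the unit is reported
    ``non_eyelid_pc`` at best.
    """
    all_complex = np.concatenate([tr.complex_spikes for tr in trains]) \
        if trains else np.array([])
    if all_complex.size == 0:
        return "not_pc"

    # complex-spike-triggered average of simple spikes, 1 ms bins
    pre, post = pause_search_ms, pause_search_ms
    counts = np.zeros(pre + post)
    n_events = 0
    for tr in trains:
        for c in tr.complex_spikes:
            rel = tr.simple_spikes - c
            sel = rel[(rel >= -pre) & (rel < post)]
            counts += np.histogram(sel, bins=np.arange(-pre, post + 1))[0]
            n_events += 1
    if n_events == 0:
        return "not_pc"
    sta = counts / n_events  # spikes per ms per event
    pre_rate = sta[:pre].mean()
    if pre_rate <= 0:
        return "not_pc"
    below = sta[pre:] < pause_ratio * pre_rate
    run, best = 0, 0
    for b in below:
        run = run + 1 if b else 0
        best = max(best, run)
    if best < pause_min_ms:
        return "not_pc"

    n_us, n_locked = 0, 0
    for tr, times in zip(trains, us_times):
        for t_us in times:
            n_us += 1
            d = tr.complex_spikes - t_us
            if np.any((d > 0) & (d <= cs_latency_window)):
                n_locked += 1
    if n_us == 0 or n_locked / n_us < us_locked_fraction:
        return "non_eyelid_pc"
    return "eyelid_pc"


def group_trials(
    outcomes: Sequence[SequenceOutcome],
    key: str = "first_onset",
    n_groups: int = 3,
    first_amp_gate: float = 3.0,
) -> dict:
    """Split trials into a non-CR group plus ``n_groups`` ordered CR groups.

    ``key`` is one of ``first_onset``, ``first_amp``, ``second_onset``,
    ``second_amp``.  CR trials are sorted by the key and split into
    near-equal ordered groups (remainder to the earliest groups).  For
    second-CR keys, only trials with a first CR larger than 3 mm are
    eligible; the non-CR group is then the eligible trials lacking a
    second CR.  Returns positional indices into ``outcomes``.
    """
    which, attr = key.split("_", 1)
    k = {"first": 1, "second": 2}[which]
    attr = {"onset": "onset", "amp": "amplitude"}[attr]
    if k == 2:
        eligible = [i for i, o in enumerate(outcomes)
                    if o.event(1) is not None and o.first_amp > first_amp_gate]
    else:
        eligible = list(range(len(outcomes)))
    cr = [(getattr(outcomes[i].event(k), attr), i) for i in eligible
          if outcomes[i].event(k) is not None]
    non_cr = [i for i in eligible if outcomes[i].event(k) is None]
    if len(cr) < n_groups:
        raise ValueError(f"only {len(cr)} CR trials for {n_groups} groups")
    cr.sort()
    sizes, groups, start = [], [], 0
    base, rem = divmod(len(cr), n_groups)
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        groups.append([i for _, i in cr[start: start + size]])
        start += size
    return {"non_cr": non_cr, "groups": groups, "key": key}


def average_with_ci(series: Sequence[RateSeries]) -> RateSeries:
    """Pointwise trial average with a 95% CI (mean +/- 1.96 SEM).

    NaN samples (outside an aligned trial's span, or truncated at the US)
    are ignored pointwise.  A single-trial group has no defined CI.
    """
    if len(series) == 0:
        raise ValueError("empty group")
    t = series[0].t
    for s in series[1:]:
        if s.t.shape != t.shape or not np.allclose(s.t, t):
            raise ValueError("rate series must share a time grid")
    mat = np.vstack([s.rate for s in series])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    if len(series) < 2:
        return RateSeries(t=t, rate=mean, normalized=series[0].normalized,
                          n_trials=1)
    n_eff = np.sum(np.isfinite(mat), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    half = 1.96 * sem
    return RateSeries(t=t, rate=mean, normalized=series[0].normalized,
                      ci_low=mean - half, ci_high=mean + half,
                      n_trials=len(series))


def ci_separation(a: RateSeries, b: RateSeries) -> np.ndarray:
    """Pointwise boolean non-overlap of two groups' 95% CIs."""
    if a.ci_low is None or b.ci_low is None:
        raise ValueError("both series need CI bands")
    return (a.ci_high < b.ci_low) | (b.ci_high < a.ci_low)


def truncate_at(series: RateSeries, t_trunc: Optional[float]) -> RateSeries:
    """NaN out the series at and after ``t_trunc`` (e.g. the delivered US)."""
    if t_trunc is None:
        return series
    rate = series.rate.copy()
    rate[series.t >= t_trunc] = np.nan
    return RateSeries(t=series.t, rate=rate, normalized=series.normalized,
                      n_trials=series.n_trials, flagged=series.flagged)


def align_to_cr_onset(
    series: Sequence[RateSeries],
    onsets: Sequence[float],
    seed: Optional[int] = None,
    t_window: tuple[float, float] = (-750.0, 750.0),
) -> dict:
    """Average rates aligned to CR onset, with pseudo-aligned non-CR trials.

    ``onsets`` holds the CR onset per trial (NaN for non-CR trials).  Each
    CR trial's series is shifted so its onset maps to time 0; each non-CR
    trial is assigned a pseudo-onset drawn (seeded) from the empirical
    distribution of CR onsets.  Returns the aligned group averages and the
    pre-onset decrease metric: the mean normalized rate of CR trials at
    aligned time 0.
    """
    onsets = np.asarray(onsets, dtype=float)
    cr_onsets = onsets[np.isfinite(onsets)]
    if cr_onsets.size == 0:
        raise ValueError("no CR onsets to align to")
    rng = np.random.default_rng(seed)
    tau = np.arange(t_window[0], t_window[1])

    def shift(s: RateSeries, onset: float) -> RateSeries:
        idx = np.round(tau + onset - s.t[0]).astype(int)
        ok = (idx >= 0) & (idx < s.t.size)
        out = np.full(tau.size, np.nan)
        out[ok] = s.rate[idx[ok]]
        return RateSeries(t=tau, rate=out, normalized=s.normalized)

    cr_aligned, non_aligned = [], []
    for s, onset in zip(series, onsets):
        if np.isfinite(onset):
            cr_aligned.append(shift(s, onset))
        else:
            non_aligned.append(shift(s, float(rng.choice(cr_onsets))))
    cr_avg = average_with_ci(cr_aligned) if cr_aligned else None
    non_avg = average_with_ci(non_aligned) if non_aligned else None
    metric = float(cr_avg.rate[np.argmin(np.abs(tau))]) if cr_avg else np.nan
    return {"cr": cr_avg, "non_cr": non_avg, "tau": tau,
            "rate_at_onset": metric}
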