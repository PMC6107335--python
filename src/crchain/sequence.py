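"""Session- and trial-level statistics of CR sequences.

Covers response probabilities and acquisition/extinction curves, the
conditional probability of a second CR given first-CR amplitude (with
percentile-bootstrap confidence intervals and a chi-square test across
amplitude bins), trial-by-trial timing co-variation of successive CRs with
a permutation shuffle null on inter-CR intervals, and the CS2-transfer
analysis that discriminates feedback-driven from cue-bound second CRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import CR_CRITERION_MM, CREvent, EyelidTrace, SequenceOutcome

__all__ = [
    "SessionSummary",
    "ConditionalProbTable",
    "TimingPair",
    "ShuffleNull",
    "session_summary",
    "extinction_curve",
    "conditional_probability",
    "fraction_times",
    "timing_covariation",
    "shuffle_null",
    "cs2_transfer",
    "DEFAULT_AMP_BIN_EDGES",
]

#: First-CR amplitude bin edges (mm).  The first bin (< 0.3 mm) is the
#: non-CR bin; seven bins in total.
DEFAULT_AMP_BIN_EDGES = (0.0, CR_CRITERION_MM, 1.0, 2.0, 3.0, 4.0, 5.0, np.inf)


@dataclass
class SessionSummary:
    """Per-session (or per-portion) probabilities and mean amplitudes.

    ``p_second`` is the fraction of first-CR trials on which a second CR
    was present too.  Undefined quantities (zero denominator) are NaN and
    flagged, never reported as 0.
    """

    n_trials: int
    n_first: int
    n_second: int
    p_first: float
    p_second: float
    mean_first_amp: float
    mean_second_amp: float
    p_first_defined: bool = True
    p_second_defined: bool = True


def session_summary(outcomes: Sequence[SequenceOutcome]) -> SessionSummary:
    """Response probabilities and mean amplitudes over decomposed trials."""
    n = len(outcomes)
    firsts = [o for o in outcomes if o.event(1) is not None]
    seconds = [o for o in firsts if o.event(2) is not None]
    p_first = len(firsts) / n if n else np.nan
    p_second = len(seconds) / len(firsts) if firsts else np.nan
    return SessionSummary(
        n_trials=n, n_first=len(firsts), n_second=len(seconds),
        p_first=p_first, p_second=p_second,
        mean_first_amp=float(np.mean([o.first_amp for o in firsts]))
        if firsts else np.nan,
        mean_second_amp=float(np.mean([o.second_amp for o in seconds]))
        if seconds else np.nan,
        p_first_defined=n > 0, p_second_defined=len(firsts) > 0,
    )


def _portion_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + 1 if i < rem else base for i in range(k)]


def extinction_curve(
    outcomes: Sequence[SequenceOutcome], n_portions: int = 8
) -> list[tuple[int, SessionSummary]]:
    """Break a chronologically ordered session into equal portions.

    The trials are split into ``n_portions`` contiguous near-equal groups
    (any remainder spread over the earliest groups) and summarized per
    portion, to evaluate the time course of within-session extinction.
    """
    if len(outcomes) < n_portions:
        raise ValueError("fewer trials than portions")
    sizes = _portion_sizes(len(outcomes), n_portions)
    curve, start = [], 0
    for i, size in enumerate(sizes):
        curve.append((i, session_summary(outcomes[start: start + size])))
        start += size
    return curve


@dataclass
class ConditionalProbTable:
    """Second-CR probability conditioned on first-CR amplitude bin."""

    bin_edges: tuple[float, ...]
    p_second: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_per_bin: np.ndarray
    n_second_per_bin: np.ndarray
    chi2: float
    chi2_p: float
    df: int
    n_total: int
    seed: Optional[int] = None


def conditional_probability(
    outcomes: Sequence[SequenceOutcome],
    bin_edges: Sequence[float] = DEFAULT_AMP_BIN_EDGES,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    criterion: float = CR_CRITERION_MM,
) -> ConditionalProbTable:
    """Probability of a second CR as a function of first-CR amplitude.

    Trials are binned by first-CR amplitude (the first bin collects
    non-CR trials below the 0.3 mm criterion).  Per bin, ``p_second`` is
    the fraction of trials whose second-CR amplitude reaches the
    criterion; 95% confidence intervals come from a percentile bootstrap
    (``n_boot`` resamples of the trials within the bin).  A chi-square
    test of homogeneity is computed on the per-bin present/absent table;
    empty bins are excluded with the degrees of freedom reduced.
    """
    edges = np.asarray(bin_edges, dtype=float)
    first = np.array([o.first_amp for o in outcomes])
    second = np.array([o.second_amp >= criterion and o.event(2) is not None
                       for o in outcomes])
    which = np.clip(np.searchsorted(edges, first, side="right") - 1,
                    0, len(edges) - 2)
    k = len(edges) - 1
    n_per_bin = np.array([(which == b).sum() for b in range(k)])
    n_second = np.array([second[which == b].sum() for b in range(k)])
    with np.errstate(invalid="ignore"):
        p = np.where(n_per_bin > 0, n_second / np.maximum(n_per_bin, 1), np.nan)

    rng = np.random.default_rng(seed)
    ci_low = np.full(k, np.nan)
    ci_high = np.full(k, np.nan)
    for b in range(k):
        if n_per_bin[b] == 0:
            continue
        # resampling trials within a bin with replacement is a binomial draw
        boot = rng.binomial(n_per_bin[b], p[b], size=n_boot) / n_per_bin[b]
        ci_low[b], ci_high[b] = np.percentile(boot, [2.5, 97.5])

    occupied = n_per_bin > 0
    table = np.vstack([n_second[occupied],
                       (n_per_bin - n_second)[occupied]])
    df = int(occupied.sum()) - 1
    if df >= 1 and table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
        chi2, chi2_p, df, _ = sps.chi2_contingency(table, correction=False)
    else:
        chi2, chi2_p = np.nan, np.nan
    return ConditionalProbTable(
        bin_edges=tuple(edges), p_second=p, ci_low=ci_low, ci_high=ci_high,
        n_per_bin=n_per_bin, n_second_per_bin=n_second,
        chi2=float(chi2), chi2_p=float(chi2_p), df=df,
        n_total=int(n_per_bin.sum()), seed=seed,
    )


def fraction_times(
    event: CREvent,
    trace: EyelidTrace,
    step: float = 0.005,
) -> dict[float, float]:
    """Times at which the normalized CR profile first reaches each fraction.

    The profile between CR onset and peak is normalized by its peak value;
    for every fraction level from the onset fraction up to 1.0 in ``step``
    increments, the first time the normalized position reaches the level is
    found, interpolating linearly between samples.  Multiple crossings of a
    level map to the first.
    """
    if not event.onset < event.peak_time:
        raise ValueError("event must have onset < peak_time")
    i0 = trace.index_of(event.onset)
    i1 = trace.index_of(event.peak_time)
    seg = trace.samples[i0: i1 + 1]
    peak = seg[-1]
    if peak <= 0:
        raise ValueError("non-positive peak value")
    norm = seg / peak
    t = trace.t0 + i0 + np.arange(seg.size, dtype=float)
    start = float(np.ceil(max(norm[0], 0.0) / step) * step)
    levels = np.round(np.arange(start, 1.0 + step / 2, step), 10)
    out: dict[float, float] = {}
    running_max = np.maximum.accumulate(norm)
    for f in levels:
        idx = np.flatnonzero(running_max >= f)
        if idx.size == 0:
            out[float(f)] = float(t[-1])
            continue
        j = idx[0]
        if j == 0 or norm[j] == norm[j - 1]:
            out[float(f)] = float(t[j])
        else:
            out[float(f)] = float(t[j - 1] + (f - norm[j - 1])
                                  / (norm[j] - norm[j - 1]))
    return out


@dataclass
class TimingPair:
    """Paired timing measures of successive CRs over qualifying trials."""

    measure_first: str
    measure_second: str
    pairs: np.ndarray  # shape (n, 2): (t_first, t_second) ms
    r: float
    p: float
    n_outliers_removed: int = 0

    @property
    def intervals(self) -> np.ndarray:
        return self.pairs[:, 1] - self.pairs[:, 0]


def timing_covariation(
    outcomes: Sequence[SequenceOutcome],
    measure_first: str = "latency_to_criterion",
    measure_second: str = "latency_to_criterion",
    indices: tuple[int, int] = (1, 2),
    amp_threshold: float = 2.0,
    outlier_sd: float = 3.0,
) -> TimingPair:
    """Trial-by-trial co-variation of timing measures of CRs in sequence.

    Pairs are collected from trials where both CR amplitudes exceed
    ``amp_threshold`` (2 mm default; 3 mm per the normalized-profile
    procedure is available via the argument).  Outliers farther than
    ``outlier_sd`` standard deviations from the mean in either coordinate
    are discarded before computing the Pearson correlation.
    """
    k1, k2 = indices
    raw = []
    for o in outcomes:
        e1, e2 = o.event(k1), o.event(k2)
        if e1 is None or e2 is None:
            continue
        if e1.amplitude > amp_threshold and e2.amplitude > amp_threshold:
            raw.append((getattr(e1, measure_first), getattr(e2, measure_second)))
    pairs = np.array(raw, dtype=float).reshape(-1, 2)
    n0 = pairs.shape[0]
    if n0 >= 3 and outlier_sd > 0:
        mu = pairs.mean(axis=0)
        sd = pairs.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        keep = np.all(np.abs(pairs - mu) <= outlier_sd * sd, axis=1)
        pairs = pairs[keep]
    if pairs.shape[0] < 3 or np.any(pairs.std(axis=0) == 0):
        r, p = np.nan, np.nan
        if pairs.shape[0] >= 3:
            r, p = sps.pearsonr(pairs[:, 0], pairs[:, 1])
    else:
        r, p = sps.pearsonr(pairs[:, 0], pairs[:, 1])
    return TimingPair(measure_first=measure_first, measure_second=measure_second,
                      pairs=pairs, r=float(r), p=float(p),
                      n_outliers_removed=n0 - pairs.shape[0])


@dataclass
class ShuffleNull:
    """Permutation null for inter-CR intervals."""

    true_intervals: np.ndarray
    shuffled_intervals: np.ndarray
    n_perm: int
    ks_stat: float
    p: float
    seed: Optional[int] = None


def _ks_vs_pool(samples: np.ndarray, pool_sorted: np.ndarray) -> np.ndarray:
    """KS statistic of each row of ``samples`` against a sorted pool."""
    samples = np.sort(samples, axis=-1)
    n = samples.shape[-1]
    m = pool_sorted.size
    f_right = np.searchsorted(pool_sorted, samples, side="right") / m
    f_left = np.searchsorted(pool_sorted, samples, side="left") / m
    grid = np.arange(1, n + 1) / n
    d_plus = np.max(grid - f_right, axis=-1)
    d_minus = np.max(f_left - (grid - 1.0 / n), axis=-1)
    return np.maximum(np.maximum(d_plus, d_minus), 0.0)


def shuffle_null(
    pairs: np.ndarray,
    n_perm: int = 2000,
    seed: Optional[int] = None,
) -> ShuffleNull:
    """Shuffle test of the dependence between successive CR times.

    The first-CR timings are randomly permuted across trials ``n_perm``
    times; each permutation yields a new distribution of inter-CR
    intervals, pooled into the shuffled distribution.  If second-CR timing
    is independent of first-CR timing the two distributions coincide; the
    two-sample Kolmogorov-Smirnov statistic between the true intervals and
    the pooled shuffle quantifies the difference.

    Because the true sample is itself one permutation (and is embedded in
    the pool), the asymptotic two-sample p-value is badly conservative;
    the reported ``p`` is therefore permutation-calibrated — the rank of
    the true KS statistic among the per-permutation statistics — which is
    exact under the independence null by exchangeability.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    rng = np.random.default_rng(seed)
    t1, t2 = pairs[:, 0], pairs[:, 1]
    true_iv = t2 - t1
    n = t1.size
    perms = np.empty((n_perm, n), dtype=float)
    for i in range(n_perm):
        perms[i] = t1[rng.permutation(n)]
    perm_iv = t2[None, :] - perms
    shuffled = perm_iv.ravel()
    pool = np.sort(shuffled)
    ks = float(_ks_vs_pool(true_iv[None, :], pool)[0])
    ks_perm = _ks_vs_pool(perm_iv, pool)
    p = (1.0 + np.sum(ks_perm >= ks - 1e-12)) / (n_perm + 1.0)
    return ShuffleNull(true_intervals=true_iv, shuffled_intervals=shuffled,
                       n_perm=n_perm, ks_stat=ks, p=float(p), seed=seed)


@dataclass
class CS2Transfer:
    """Second-CR probabilities per trial group and their session coupling."""

    per_session: list[dict]  # keys: cs1, cs2_alone, cs2_alone_no_first
    mean_cs1: float
    mean_cs2_alone: float
    mean_no_first: float
    r: float
    r_p: float


def _group_p(outcomes: Sequence[SequenceOutcome]) -> float:
    summ = session_summary(outcomes)
    return summ.p_second if summ.p_second_defined else np.nan


def cs2_transfer(
    sessions: Sequence[Sequence[SequenceOutcome]],
    amp_gate: float = 3.0,
) -> CS2Transfer:
    """Second-CR probability by cue type across CS2 test sessions.

    Per session: second-CR probability on CS1 trials with first CR larger
    than the 3 mm gate, on CS2-alone trials with first CR larger than the
    gate, and on CS2-alone trials without a first CR (where the fraction
    of trials with a second CR is reported directly).  The across-session
    Pearson correlation between the CS1 and CS2-alone group probabilities
    tests whether sequence expression transfers with the first response
    rather than with the training cue.
    """
    per_session = []
    for outcomes in sessions:
        # US1-truncated trials cannot express a second CR (the analysis
        # truncates at the US); the online contingency keeps them out of
        # the >gate group in the experiment, so they are excluded here too
        cs1 = [o for o in outcomes
               if o.trial_type in ("paired", "cs_alone")
               and o.event(1) is not None and o.first_amp > amp_gate
               and not any(lbl in ("US1", "USL") for lbl in o.us_labels)]
        cs2a = [o for o in outcomes if o.trial_type == "cs2_alone"
                and o.event(1) is not None and o.first_amp > amp_gate]
        cs2_none = [o for o in outcomes if o.trial_type == "cs2_alone"
                    and o.event(1) is None]
        n_second_nf = sum(o.event(2) is not None for o in cs2_none)
        per_session.append({
            "cs1": _group_p(cs1),
            "cs2_alone": _group_p(cs2a),
            "cs2_alone_no_first": (n_second_nf / len(cs2_none)
                                   if cs2_none else np.nan),
            "n_cs1": len(cs1), "n_cs2_alone": len(cs2a),
            "n_no_first": len(cs2_none),
        })
    a = np.array([s["cs1"] for s in per_session])
    b = np.array([s["cs2_alone"] for s in per_session])
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() >= 3 and a[ok].std() > 0 and b[ok].std() > 0:
        r, r_p = sps.pearsonr(a[ok], b[ok])
    else:
        r, r_p = np.nan, np.nan
    c = np.array([s["cs2_alone_no_first"] for s in per_session])
    return CS2Transfer(
        per_session=per_session,
        mean_cs1=float(np.nanmean(a)) if np.any(np.isfinite(a)) else np.nan,
        mean_cs2_alone=float(np.nanmean(b)) if np.any(np.isfinite(b)) else np.nan,
        mean_no_first=float(np.nanmean(c)) if np.any(np.isfinite(c)) else np.nan,
        r=float(r), r_p=float(r_p),
    )
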