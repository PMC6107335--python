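"""Synthetic closed-loop conditioning sessions.

This module emulates the amplitude-contingent sequence-training protocols:
a 500 ms CS, a first conditioned response (CR) whose amplitude at the
scheduled US₁ time decides whether US₁ (at CS offset) or US₂ (gap_interval
after CS offset) is delivered, and chained second/third CRs whose presence
and timing depend on the preceding CR.  Two generative modes are provided:

* ``chained`` — the second CR's onset is a linear function of the first CR's
  onset plus jitter, and its probability ramps with first-CR amplitude
  (the feedback-signal structure the analysis is designed to detect);
* ``independent`` — second-CR presence and timing are drawn without
  reference to the first CR (the null used to calibrate the resampling
  statistics).

An optional Purkinje-cell model produces simple-spike trains with
CR-locked rate decreases that lead CR onset, and US-evoked complex spikes.

The default parameter values are placeholders chosen to be physiologically
plausible for rabbit eyelid conditioning; the source experiments report no
numerical onset/amplitude distributions to copy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .types import (
    CR_CRITERION_MM,
    FULL_CLOSURE_MM,
    EyelidTrace,
    PlantedCR,
    Session,
    SpikeTrain,
    TrialRecord,
    USDelivery,
)

__all__ = [
    "ProtocolConfig",
    "GenParams",
    "PCGenParams",
    "USSchedule",
    "cr_waveform",
    "simulate_contingency",
    "generate_session",
    "generate_spike_train",
]

PRE_CS_MS = 200.0
POST_CS_MS = 2300.0
SPIKE_PRE_CS_MS = 1500.0  # spike records carry a longer pre-CS baseline

_VALID_GAPS = (300.0, 400.0, 500.0, 600.0)


@dataclass
class ProtocolConfig:
    """Session-level protocol parameters.

    A standard training session is 12 blocks of 9 trials (1 CS-alone +
    8 paired).  A CS2 test session is 108 trials mixed as 60% CS1-paired,
    25% CS2-paired, 15% CS2-alone.
    """

    protocol: str = "ipsilateral"  # ipsilateral | contralateral | cs2_test
    cs_duration: float = 500.0  # ms
    isi: float = 500.0  # ms, CS onset to US1 onset
    gap_interval: float = 600.0  # ms, CS offset to US2
    target_amplitude: float = 3.0  # mm, half of full closure
    full_closure: float = FULL_CLOSURE_MM
    n_blocks: int = 12
    trials_per_block: int = 9
    cs_alone_per_block: int = 1
    cs2_mix: tuple[float, float, float] = (0.60, 0.25, 0.15)
    n_trials_cs2: int = 108

    def __post_init__(self) -> None:
        if self.protocol not in ("ipsilateral", "contralateral", "cs2_test"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if float(self.gap_interval) not in _VALID_GAPS:
            raise ValueError(
                f"gap_interval must be one of {_VALID_GAPS}, got {self.gap_interval}"
            )
        if abs(sum(self.cs2_mix) - 1.0) > 1e-9:
            raise ValueError("cs2_mix fractions must sum to 1")
        if not 0 < self.cs_alone_per_block <= self.trials_per_block:
            raise ValueError("cs_alone_per_block must be in (0, trials_per_block]")

    @property
    def us1_time(self) -> float:
        return self.isi

    @property
    def us2_time(self) -> float:
        return self.cs_duration + self.gap_interval


@dataclass
class GenParams:
    """Behavioral generator parameters (see module docstring)."""

    p_first_cr: float = 0.9
    first_onset_mean: float = 300.0  # ms from CS onset
    first_onset_sd: float = 55.0
    first_amp_mean: float = 3.5  # mm
    first_amp_sd: float = 1.2
    chain_mode: str = "chained"  # chained | independent
    chain_gain: float = 1.0  # slope of second-CR onset on first-CR onset
    #: onset-to-onset spacing of successive CRs; None adapts to the
    #: protocol so the next CR peaks at the trained US2/USR time
    inter_cr_interval: Optional[float] = None
    interval_jitter_sd: float = 30.0
    p_second_given_gate: float = 0.85
    amp_decay: float = 0.7  # ratio of successive CR amplitudes
    amp_jitter_sd: float = 0.15  # multiplicative, successive CRs
    rise_time: float = 190.0  # ms, onset to peak (CRs peak near the US)
    decay_time: float = 250.0  # ms, exponential return toward baseline
    noise_sd: float = 0.05  # mm additive trace noise (detector ~ +/-0.1 mm)
    second_cr_driver: str = "feedback"  # feedback | cs1
    co_movement_gain: float = 0.05  # right-eye leak of left CR (contralateral)
    p_pre_cs_artifact: float = 0.0  # planted screening violations
    p_negative_artifact: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_first_cr", "p_second_given_gate",
                     "p_pre_cs_artifact", "p_negative_artifact"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.chain_mode not in ("chained", "independent"):
            raise ValueError(f"unknown chain_mode {self.chain_mode!r}")
        if self.second_cr_driver not in ("feedback", "cs1"):
            raise ValueError(f"unknown second_cr_driver {self.second_cr_driver!r}")


@dataclass
class PCGenParams:
    """Purkinje-cell spike generator parameters."""

    baseline_rate: float = 70.0  # Hz
    dip_depth: float = 0.15  # fraction of baseline per mm of CR profile
    dip_lead: float = 50.0  # ms by which the rate decrease precedes the CR
    complex_spike_latency: float = 3.0  # ms after US
    post_cs_pause: float = 15.0  # ms simple-spike pause after a complex spike
    n_units: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.post_cs_pause <= 0:
            raise ValueError("post_cs_pause must be positive")
        if not 0.0 <= self.dip_depth * FULL_CLOSURE_MM <= 1.0 + 1e-9:
            raise ValueError("dip_depth * full closure must lie in [0, 1]")


@dataclass(frozen=True)
class USSchedule:
    """Outcome of the amplitude contingency for one paired trial."""

    deliveries: tuple[USDelivery, ...]

    @property
    def us2_delivered(self) -> bool:
        return any(d.label in ("US2", "USR") for d in self.deliveries)


def cr_waveform(
    onset: float,
    amplitude: float,
    rise_time: float,
    decay_time: float,
    grid: np.ndarray,
) -> np.ndarray:
    """A single smooth CR bump evaluated on ``grid`` (ms).

    The rise is a quarter-sine from 0 to ``amplitude`` over ``rise_time``
    (``A sin(pi u / 2)`` with ``u = (t - onset)/rise_time``): the movement
    starts with a definite, nonzero velocity — eyelid closures are
    ballistic — and flattens smoothly into the peak.  After the peak the
    position decays exponentially toward baseline with time constant
    ``decay_time``.  The peak equals ``amplitude`` exactly at
    ``onset + rise_time``.  Bumps are additive, so overlapping responses
    superpose.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if rise_time <= 0 or decay_time <= 0:
        raise ValueError("rise_time and decay_time must be positive")
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    if amplitude == 0:
        return y
    u = (grid - onset) / rise_time
    rising = (u > 0) & (u < 1)
    y[rising] = amplitude * np.sin(0.5 * np.pi * u[rising])
    after = u >= 1
    y[after] = amplitude * np.exp(-(grid[after] - onset - rise_time) / decay_time)
    return y


def simulate_contingency(
    first_cr_amplitude_at_us1: float, cfg: ProtocolConfig
) -> USSchedule:
    """Apply the closed-loop US rule to one paired trial.

    If the eyelid position at the scheduled US₁ time is below the target
    amplitude, US₁ is delivered at CS offset; at or above the target, US₁
    is omitted and US₂ is delivered ``gap_interval`` after CS offset.  The
    contralateral protocol uses the same rule with US_L/US_R and the second
    US delivered to the right eye.
    """
    if first_cr_amplitude_at_us1 < 0:
        raise ValueError("amplitude must be non-negative")
    contra = cfg.protocol == "contralateral"
    if first_cr_amplitude_at_us1 >= cfg.target_amplitude:
        label = "USR" if contra else "US2"
        eye = "right" if contra else "left"
        return USSchedule((USDelivery(label, cfg.us2_time, eye),))
    label = "USL" if contra else "US1"
    return USSchedule((USDelivery(label, cfg.us1_time, "left"),))


# ---------------------------------------------------------------------------
# session generation


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Draw from a normal truncated to [lo, hi] by rejection."""
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _trial_type_sequence(cfg: ProtocolConfig, rng: np.random.Generator) -> list[str]:
    """The chronological list of trial types for one session."""
    if cfg.protocol == "cs2_test":
        n = cfg.n_trials_cs2
        # largest-remainder apportionment of the mix fractions
        raw = np.array(cfg.cs2_mix) * n
        counts = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
            counts[i] += 1
        types = (["paired"] * counts[0] + ["cs2_paired"] * counts[1]
                 + ["cs2_alone"] * counts[2])
        rng.shuffle(types)
        return types
    types: list[str] = []
    for _ in range(cfg.n_blocks):
        block = ["paired"] * (cfg.trials_per_block - cfg.cs_alone_per_block)
        block += ["cs_alone"] * cfg.cs_alone_per_block
        rng.shuffle(block)
        types.extend(block)
    return types


def _p_next_cr(prev_amp: float, cfg: ProtocolConfig, gen: GenParams) -> float:
    """Probability that the next CR in the chain is expressed."""
    if gen.chain_mode == "independent":
        return gen.p_second_given_gate
    ramp = min(max(prev_amp, 0.0) / cfg.target_amplitude, 1.0)
    return gen.p_second_given_gate * ramp


def _plan_chain(
    cfg: ProtocolConfig,
    gen: GenParams,
    rng: np.random.Generator,
    cue: str,
) -> list[tuple[float, float]]:
    """Plan the (onset, amplitude) list of CRs for one trial, pre-contingency.

    Returns the full chain as it would unfold with no US truncation; the
    caller trims it against the delivered US schedule.
    """
    if rng.random() >= gen.p_first_cr:
        return []
    onset1 = _truncnorm(rng, gen.first_onset_mean, gen.first_onset_sd,
                        10.0, cfg.cs_duration - 50.0)
    amp1 = _truncnorm(rng, gen.first_amp_mean, gen.first_amp_sd,
                      0.0, cfg.full_closure)
    chain = [(onset1, amp1)]
    if gen.second_cr_driver == "cs1" and cue != "cs1":
        return chain  # later CRs bound to the CS1 cue, absent otherwise
    window_end = POST_CS_MS
    interval = gen.inter_cr_interval
    if interval is None:
        # train-time US2/USR timing: the next CR peaks at the second US
        interval = (cfg.cs_duration + cfg.gap_interval
                    - gen.rise_time - gen.first_onset_mean)
    prev_onset, prev_amp = onset1, amp1
    while True:
        if rng.random() >= _p_next_cr(prev_amp, cfg, gen):
            break
        jitter = rng.normal(0.0, gen.interval_jitter_sd)
        if gen.chain_mode == "chained":
            onset = gen.chain_gain * prev_onset + interval + jitter
        else:
            ref = _truncnorm(rng, gen.first_onset_mean, gen.first_onset_sd,
                             10.0, cfg.cs_duration - 50.0)
            onset = ref + len(chain) * interval + jitter
        amp = prev_amp * gen.amp_decay * max(rng.normal(1.0, gen.amp_jitter_sd), 0.0)
        amp = min(amp, cfg.full_closure)
        # stop when the next response would be unresolvable as a distinct
        # CR: peak too close to the record edge, or amplitude below the
        # 0.5 mm peak-prominence resolution given the preceding CR's tail
        if onset + gen.rise_time >= window_end - 300.0:
            break
        if amp < 0.6 + 0.2 * prev_amp:
            break
        chain.append((onset, amp))
        prev_onset, prev_amp = onset, amp
    return chain


def _realized_peaks(clean: np.ndarray, t0: float,
                    chain: list[tuple[float, float]],
                    rise_time: float) -> list[tuple[float, float]]:
    """Realized (peak_time, peak_amp) of each bump on the summed clean trace."""
    out = []
    for onset, amp in chain:
        nominal = onset + rise_time
        i0 = max(0, int(nominal - t0) - 60)
        i1 = min(clean.size, int(nominal - t0) + 60)
        seg = clean[i0:i1]
        k = int(np.argmax(seg))
        out.append((t0 + i0 + k, float(seg[k])))
    return out


def generate_spike_train(
    trial: TrialRecord,
    pc: PCGenParams,
    seed: int | np.random.SeedSequence,
    unit_id: str = "pc0",
    cr_profile: Optional[np.ndarray] = None,
) -> SpikeTrain:
    """Simulate one eyelid-PC spike train for a trial.

    Simple spikes follow an inhomogeneous Poisson process (1 ms bins) with
    rate ``baseline * (1 - dip_depth * profile(t + dip_lead))`` clipped at
    zero, where ``profile`` is the clean CR-only eyelid profile in mm.  One
    complex spike follows each delivered US at ``complex_spike_latency``,
    and simple spikes within ``post_cs_pause`` after a complex spike are
    suppressed.  The spike clock spans [-1500, 2300) ms around CS onset.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(-SPIKE_PRE_CS_MS, POST_CS_MS)
    if cr_profile is None:
        eye = "left" if "left" in trial.traces else next(iter(trial.traces), "left")
        profile = np.zeros_like(t)
        if eye in trial.traces:
            tr = trial.traces[eye]
            idx = np.searchsorted(t, tr.t0)
            profile[idx: idx + tr.n] = tr.samples
    else:
        profile = np.zeros_like(t)
        n0 = int(SPIKE_PRE_CS_MS - PRE_CS_MS)
        profile[n0: n0 + cr_profile.size] = cr_profile
    # shift the dip earlier than the behavior by dip_lead
    lead = int(round(pc.dip_lead))
    shifted = np.concatenate([profile[lead:], np.zeros(lead)]) if lead > 0 else profile
    rate = pc.baseline_rate * np.clip(1.0 - pc.dip_depth * shifted, 0.0, None)
    simple = t[rng.random(t.size) < rate / 1000.0]
    complex_spikes = np.array(
        [us.time_ms + pc.complex_spike_latency for us in trial.us_delivered]
    )
    complex_spikes = np.round(np.sort(complex_spikes))
    for cs_time in complex_spikes:
        simple = simple[(simple <= cs_time) | (simple > cs_time + pc.post_cs_pause)]
    return SpikeTrain(unit_id=unit_id, simple_spikes=np.round(simple),
                      complex_spikes=complex_spikes, trial_id=trial.trial_id)


def generate_session(
    cfg: ProtocolConfig,
    gen: GenParams,
    pc: Optional[PCGenParams] = None,
    seed: Optional[int] = None,
    session_id: str = "synthetic",
) -> Session:
    """Generate a full closed-loop session.

    Traces are built from :func:`cr_waveform`, US schedules from
    :func:`simulate_contingency` evaluated on the clean first-CR profile at
    the scheduled US₁ time, and second/third CRs follow ``gen.chain_mode``.
    Third and later CRs appear only on trials where no US truncates the
    sequence (CS-alone trials).  Identical inputs produce identical output.
    """
    if seed is None:
        seed = gen.seed
    root = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    types = _trial_type_sequence(cfg, order_rng)
    trial_seeds = root.spawn(len(types))

    grid = np.arange(-PRE_CS_MS, POST_CS_MS)
    trials: list[TrialRecord] = []
    for tid, (ttype, tseed) in enumerate(zip(types, trial_seeds)):
        rng = np.random.default_rng(tseed)
        cue = "cs2" if ttype.startswith("cs2") else "cs1"
        chain = _plan_chain(cfg, gen, rng, cue)

        contra = cfg.protocol == "contralateral"
        # eye of each CR in the chain: ipsilateral all left, contralateral
        # alternation stops at the second (right-eye) CR
        if contra:
            chain = chain[:2]
            eyes = ["left", "right"][: len(chain)]
        else:
            eyes = ["left"] * len(chain)

        # clean first-CR-only trace to evaluate the contingency
        first_clean = np.zeros_like(grid)
        if chain:
            first_clean = cr_waveform(chain[0][0], chain[0][1],
                                      gen.rise_time, gen.decay_time, grid)
        amp_at_us1 = float(first_clean[int(cfg.us1_time + PRE_CS_MS)])

        deliveries: list[USDelivery] = []
        if ttype == "paired":
            deliveries = list(simulate_contingency(amp_at_us1, cfg).deliveries)
        elif ttype == "cs2_paired":
            deliveries = [USDelivery("US1", cfg.us1_time, "left")]
        us2_given = any(d.label in ("US2", "USR") for d in deliveries)
        first_us = min((d.time_ms for d in deliveries), default=None)

        # trim the chain against the delivered US schedule
        if deliveries:
            if us2_given:
                chain, eyes = chain[:2], eyes[:2]
            else:
                chain, eyes = chain[:1], eyes[:1]

        # build per-eye clean traces
        clean = {"left": np.zeros_like(grid)}
        if contra:
            clean["right"] = np.zeros_like(grid)
        for (onset, amp), eye in zip(chain, eyes):
            clean[eye] = clean[eye] + cr_waveform(onset, amp, gen.rise_time,
                                                  gen.decay_time, grid)
        if contra and gen.co_movement_gain > 0:
            clean["right"] = clean["right"] + gen.co_movement_gain * clean["left"]

        planted: list[PlantedCR] = []
        for k, ((onset, amp), eye) in enumerate(zip(chain, eyes), start=1):
            # realized peak on the full summed trace for that eye
            pk_t, pk_a = _realized_peaks(clean[eye], -PRE_CS_MS,
                                         [(onset, amp)], gen.rise_time)[0]
            planted.append(PlantedCR(index=k, eye=eye, onset=onset,
                                     amplitude=amp, peak_time=pk_t, peak_amp=pk_a))

        # keep a copy of the CR-only left profile for the PC model
        cr_profile = clean["left"].copy()

        # US-evoked unconditioned response: fast full closure after the US
        for d in deliveries:
            ur_amp = max(cfg.full_closure - float(
                clean[d.eye][int(d.time_ms + PRE_CS_MS)]), 0.0)
            clean[d.eye] = clean[d.eye] + cr_waveform(
                d.time_ms + 10.0, ur_amp, 40.0, 300.0, grid)

        # planted screening violations
        if rng.random() < gen.p_pre_cs_artifact:
            clean["left"] = clean["left"] + cr_waveform(-120.0, 0.5, 30.0, 60.0, grid)
        if rng.random() < gen.p_negative_artifact:
            clean["left"] = clean["left"] - cr_waveform(250.0, 0.8, 40.0, 80.0, grid)

        traces = {}
        for eye, y in clean.items():
            noisy = y + rng.normal(0.0, gen.noise_sd, y.size) if gen.noise_sd > 0 else y
            traces[eye] = EyelidTrace(samples=noisy, t0=-PRE_CS_MS, eye=eye)

        trial = TrialRecord(
            trial_id=tid, trial_type=ttype, protocol=cfg.protocol,
            cs_on=0.0, cs_off=cfg.cs_duration, traces=traces,
            us_delivered=deliveries, planted=planted, amp_at_us1=amp_at_us1,
        )
        if pc is not None:
            unit_seeds = np.random.SeedSequence((seed, tid, 7)).spawn(pc.n_units)
            for u in range(pc.n_units):
                trial.spikes.append(generate_spike_train(
                    trial, pc, unit_seeds[u], unit_id=f"pc{u}",
                    cr_profile=cr_profile))
        trials.append(trial)

    prov = {"generator": "crchain.synthetic", "seed": seed,
            "gen": asdict(gen), "cfg": asdict(cfg),
            "pc": asdict(pc) if pc is not None else None}
    return Session(session_id=session_id, protocol=cfg.protocol,
                   trials=trials, config=asdict(cfg), provenance=prov)
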