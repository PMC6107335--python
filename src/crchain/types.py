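"""Core data containers for eyelid-conditioning sequence analysis.

Conventions used throughout the package:

* time is in milliseconds with t = 0 at CS onset;
* sampling is uniform at 1 kHz (1 ms per sample), samples indexed 0-based;
* eyelid position is in millimeters, upward (closure) positive, with full
  closure calibrated to 6.0 mm and the pre-CS baseline at 0 mm;
* windows are half-open ``[a, b)`` unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "EyelidTrace",
    "USDelivery",
    "PlantedCR",
    "TrialRecord",
    "SpikeTrain",
    "CREvent",
    "SequenceOutcome",
    "ExclusionReport",
    "RateSeries",
    "Session",
    "FULL_CLOSURE_MM",
    "CR_CRITERION_MM",
]

#: Full eyelid closure in millimeters (calibration target).
FULL_CLOSURE_MM = 6.0

#: Minimum amplitude for an eyelid deflection to count as a CR.
CR_CRITERION_MM = 0.3


@dataclass
class EyelidTrace:
    """Calibrated 1 kHz eyelid-position series for one eye on one trial.

    Parameters
    ----------
    samples
        Position in mm at 1 ms spacing.
    t0
        Time of the first sample in ms relative to CS onset (default -200).
    eye
        ``"left"`` or ``"right"``.
    calibration
        mm-per-unit scale that was applied to the raw readout.
    """

    samples: np.ndarray
    t0: float = -200.0
    eye: str = "left"
    calibration: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.eye not in ("left", "right"):
            raise ValueError(f"unknown eye {self.eye!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to CS onset."""
        return self.t0 + np.arange(self.n, dtype=float)

    def index_of(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (nearest sample)."""
        idx = int(round(t_ms - self.t0))
        if idx < 0 or idx >= self.n:
            raise ValueError(f"time {t_ms} ms outside trace window")
        return idx

    def value_at(self, t_ms: float) -> float:
        return float(self.samples[self.index_of(t_ms)])

    def window(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples in the half-open window ``[t_start, t_stop)`` ms."""
        i0 = max(0, int(np.ceil(t_start - self.t0)))
        i1 = min(self.n, int(np.ceil(t_stop - self.t0)))
        return self.samples[i0:i1]

    def copy_with(self, samples: np.ndarray) -> "EyelidTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class USDelivery:
    """One delivered unconditioned stimulus."""

    label: str  # "US1", "US2", "USL", "USR"
    time_ms: float
    eye: str  # eye receiving the stimulation


@dataclass(frozen=True)
class PlantedCR:
    """Generator ground truth for one planted conditioned response.

    ``peak_time``/``peak_amp`` are the realized local maximum of the clean
    (noise-free) summed trace, which can differ from the nominal amplitude by
    the tail of the preceding response.
    """

    index: int  # 1-based position in the sequence
    eye: str
    onset: float  # ms, start of the rise
    amplitude: float  # nominal bump amplitude, mm
    peak_time: float  # realized, ms
    peak_amp: float  # realized, mm


@dataclass
class SpikeTrain:
    """Labeled spike times (ms, trial clock, 1 ms resolution) for one unit."""

    unit_id: str
    simple_spikes: np.ndarray
    complex_spikes: np.ndarray
    trial_id: int = -1

    def __post_init__(self) -> None:
        self.simple_spikes = np.asarray(self.simple_spikes, dtype=float)
        self.complex_spikes = np.asarray(self.complex_spikes, dtype=float)
        for arr in (self.simple_spikes, self.complex_spikes):
            if arr.size and np.any(np.diff(arr) < 0):
                raise ValueError("spike times must be sorted")


@dataclass
class TrialRecord:
    """One trial: traces, protocol metadata, delivered US schedule."""

    trial_id: int
    trial_type: str  # "paired" | "cs_alone" | "cs2_paired" | "cs2_alone"
    protocol: str  # "ipsilateral" | "contralateral" | "cs2_test"
    cs_on: float = 0.0
    cs_off: float = 500.0
    traces: dict[str, EyelidTrace] = field(default_factory=dict)
    us_delivered: list[USDelivery] = field(default_factory=list)
    spikes: list[SpikeTrain] = field(default_factory=list)
    # generator ground truth (absent for imported data)
    planted: list[PlantedCR] = field(default_factory=list)
    amp_at_us1: Optional[float] = None
    excluded: bool = False
    exclusion_reason: str = "none"

    @property
    def cue(self) -> str:
        """Which CS started the trial ('cs1' unless a CS2-type trial)."""
        return "cs2" if self.trial_type.startswith("cs2") else "cs1"

    @property
    def is_paired(self) -> bool:
        return self.trial_type in ("paired", "cs2_paired")

    def us_time(self, label: str) -> Optional[float]:
        for us in self.us_delivered:
            if us.label == label:
                return us.time_ms
        return None

    @property
    def first_us_time(self) -> Optional[float]:
        if not self.us_delivered:
            return None
        return min(us.time_ms for us in self.us_delivered)


@dataclass
class CREvent:
    """One detected conditioned response with its timing measures.

    All times in ms from CS onset; amplitude in mm relative to the pre-CS
    baseline.
    """

    index_in_sequence: int
    onset: float
    latency_to_criterion: float
    amplitude: float
    peak_time: float
    t_peak_velocity: float = np.nan
    t_half_peak: float = np.nan
    t_90_peak: float = np.nan
    eye: str = "left"
    onset_fallback: bool = False  # onset fell back to latency-to-criterion


@dataclass
class SequenceOutcome:
    """Per-trial decomposition of the CR sequence."""

    trial_id: int
    trial_type: str
    protocol: str
    squint_gate_passed: bool = True
    events: list[CREvent] = field(default_factory=list)
    delayed_first: bool = False
    flagged: bool = False  # ambiguous single-peak second-CR search etc.
    us_labels: tuple[str, ...] = ()  # labels of the USs actually delivered

    def event(self, k: int) -> Optional[CREvent]:
        """The k-th (1-based) CR in the sequence, or None."""
        for ev in self.events:
            if ev.index_in_sequence == k:
                return ev
        return None

    @property
    def first_amp(self) -> float:
        ev = self.event(1)
        return ev.amplitude if ev is not None else 0.0

    @property
    def second_amp(self) -> float:
        ev = self.event(2)
        return ev.amplitude if ev is not None else 0.0

    @property
    def third_present(self) -> bool:
        return self.event(3) is not None


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of the trial-screening rules for one trial."""

    trial_id: int
    kept: bool
    reason: str  # none | pre_cs_upward | early_cs_upward | negative_deviation
    offending_time_ms: float = np.nan

    def __post_init__(self) -> None:
        if self.kept != (self.reason == "none"):
            raise ValueError("kept must be equivalent to reason == 'none'")


@dataclass
class RateSeries:
    """Firing rate on the trial time grid (1 kHz).

    ``rate`` is raw Hz or baseline-normalized (dimensionless); CI bands are
    present only for trial averages.
    """

    t: np.ndarray
    rate: np.ndarray
    normalized: bool = False
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    n_trials: int = 1
    flagged: bool = False  # e.g. < 2 spikes on the trial

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.t.shape != self.rate.shape:
            raise ValueError("t and rate must have identical shape")


@dataclass
class Session:
    """An ordered collection of trials plus provenance."""

    session_id: str
    protocol: str
    trials: list[TrialRecord]
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    format_version: str = "1"

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("trial ids must be unique")
        if ids != sorted(ids):
            raise ValueError("trials must be ordered by trial id")

    def __len__(self) -> int:
        return len(self.trials)

    def kept_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if not t.excluded]
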