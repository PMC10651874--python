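"""Core in-memory containers shared across analysis stages.

Times are in seconds, depths in micrometres below the cortical surface,
firing rates in Hz.  Behavioral/stimulus events are stored as parallel
numpy arrays sorted by time; sorted spike-time arrays live on
:class:`UnitRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Recognised behavioral / stimulus event types.
EVENT_TYPES = ("press", "release", "sound_self", "sound_random", "light_on", "reward")

#: Ordering applied to simultaneous events so logs are byte-stable.
_EVENT_PRIORITY = {t: i for i, t in enumerate(EVENT_TYPES)}


@dataclass
class EventLog:
    """Time-stamped behavioral and stimulus events for one session."""

    times: np.ndarray
    types: np.ndarray
    durations: np.ndarray
    session_duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.types = np.asarray(self.types, dtype="U12")
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.times) == len(self.types) == len(self.durations)):
            raise ValueError("times, types and durations must have equal length")
        if np.any(np.diff(self.times) < 0):
            first = int(np.flatnonzero(np.diff(self.times) < 0)[0]) + 1
            raise ValueError(f"event times must be non-decreasing (row {first})")
        if np.any(self.durations < 0):
            raise ValueError("event durations must be non-negative")
        unknown = set(self.types) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.times)

    def of_type(self, *types: str) -> np.ndarray:
        """Times of all events whose type is in ``types``."""
        mask = np.isin(self.types, types)
        return self.times[mask]

    def sounds(self) -> tuple[np.ndarray, np.ndarray]:
        """All sound onsets with a boolean self-generated flag, time order."""
        mask = np.isin(self.types, ("sound_self", "sound_random"))
        return self.times[mask], self.types[mask] == "sound_self"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "event_type": self.types, "duration_s": self.durations}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, session_duration: Optional[float] = None) -> "EventLog":
        required = {"time_s", "event_type", "duration_s"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        if session_duration is None:
            session_duration = float(frame["time_s"].max()) if len(frame) else 0.0
        return cls(
            times=frame["time_s"].to_numpy(dtype=float),
            types=frame["event_type"].to_numpy(dtype="U12"),
            durations=frame["duration_s"].to_numpy(dtype=float),
            session_duration=session_duration,
        )

    @classmethod
    def empty(cls, session_duration: float = 0.0) -> "EventLog":
        return cls(np.empty(0), np.empty(0, dtype="U12"), np.empty(0), session_duration)


def sort_events(times, types, durations):
    """Stable event ordering: by time, ties broken by fixed type priority."""
    times = np.asarray(times, dtype=float)
    types = np.asarray(types, dtype="U12")
    durations = np.asarray(durations, dtype=float)
    prio = np.array([_EVENT_PRIORITY[t] for t in types])
    order = np.lexsort((prio, times))
    return times[order], types[order], durations[order]


@dataclass
class UnitRecord:
    """One sorted unit: identity, anatomy and spike train."""

    unit_id: str
    animal_id: str
    genotype: str
    depth_um: float
    spike_times: np.ndarray
    waveform: Optional[np.ndarray] = None
    fs: float = 30000.0
    #: Generator ground truth (empty for real recordings); never used by analyses.
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError(f"spike times of unit {self.unit_id} are not sorted")


@dataclass
class Psth:
    """Event-aligned trial-by-bin spike counts and the derived rate."""

    bin_edges: np.ndarray  # seconds relative to the event, uniform bins
    counts: np.ndarray  # (n_trials, n_bins) spike counts

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("PSTH bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def rate(self) -> np.ndarray:
        """Trial-averaged firing rate per bin, Hz."""
        return self.counts.mean(axis=0) / self.bin_width


@dataclass
class ResponseProfile:
    """Baseline statistics and evoked amplitudes for one unit."""

    unit_id: str
    baseline_mean: float  # Hz, 0-200 ms pre-event, pooled over both sound classes
    baseline_sd: float  # Hz, SD of 5 ms-binned baseline rate
    amp_random: float  # Hz
    amp_self: float  # Hz
    z_random: float
    z_self: float
    is_responsive: bool
    per_trial_amp_random: np.ndarray
    per_trial_amp_self: np.ndarray
    n_trials_random: int
    n_trials_self: int
    #: fraction of trials (either class) with >=1 spike in the response window;
    #: drives the silent-baseline responsiveness convention.
    frac_trials_with_spike: float = 0.0


@dataclass
class ModulationResult:
    unit_id: str
    mi: float  # (S - R) / (S + R); NaN when undefined
    sig_class: str  # attenuated | enhanced | ns
    mi_early: Optional[float] = None
    mi_late: Optional[float] = None
    depth_bin: Optional[str] = None
    flagged: bool = False  # negative amplitude pushed MI outside [-1, 1]


@dataclass
class OptoResponse:
    """Light-evoked response of one unit against the surrogate-PSTH null."""

    unit_id: str
    delta_fr: np.ndarray  # Hz per 5 ms bin, 0-100 ms post light
    p_per_bin: np.ndarray
    spikes_per_bin: np.ndarray  # total spike counts per response bin across trials
    n_baseline_spikes: int
    latency_ms: Optional[float]  # end time of first p<0.001 excited bin
    label: str  # excitatory_short_latency | inhibitory | none
    mode: str  # terminal | soma


@dataclass
class BootstrapResult:
    p: float
    n_reps: int
    boot_means_a: np.ndarray
    boot_means_b: np.ndarray
    observed_difference: float
    flagged: bool = False  # single-animal group: comparison underpowered
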