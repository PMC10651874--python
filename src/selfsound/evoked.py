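"""Event-aligned PSTHs, evoked amplitudes, responsiveness, preparatory
activity and paired-pulse adaptation.

The evoked amplitude of a unit is its mean firing rate 10-50 ms after
stimulus onset minus its baseline rate 0-200 ms before onset.  A unit is
auditory responsive when that amplitude, for either stimulus class, is at
least twice the standard deviation of the 5 ms-binned baseline rate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import Psth, ResponseProfile

RESPONSE_WINDOW = (0.010, 0.050)  # s relative to stimulus onset
BASELINE_WINDOW = (-0.200, 0.0)
BASELINE_BIN = 0.005  # s


def compute_psth(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float] = (-0.2, 0.1),
    bin_width: float = 0.005,
) -> Psth:
    """Trial-by-bin spike counts aligned to ``event_times``.

    Bins are half-open ``[lo, hi)``; a spike at time ``t`` lands in the bin
    containing ``t - event_time``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    event_times = np.asarray(event_times, dtype=float)
    if len(event_times) == 0:
        raise ValueError("cannot compute a PSTH from zero events")
    lo, hi = window
    n_bins = (hi - lo) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window must span an integer number of bins")
    edges = lo + bin_width * np.arange(round(n_bins) + 1)
    spike_times = np.asarray(spike_times, dtype=float)
    idx = np.searchsorted(spike_times, event_times[:, None] + edges[None, :], side="left")
    counts = np.diff(idx, axis=1)
    return Psth(bin_edges=edges, counts=counts)


def _window_counts(spike_times: np.ndarray, event_times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Spike counts per event in the half-open window ``[t+lo, t+hi)``."""
    event_times = np.asarray(event_times, dtype=float)
    a = np.searchsorted(spike_times, event_times + lo, side="left")
    b = np.searchsorted(spike_times, event_times + hi, side="left")
    return b - a


def _mean_rate(psth: Psth, lo: float, hi: float) -> float:
    centers = psth.bin_edges[:-1]
    mask = (centers >= lo - 1e-12) & (centers < hi - 1e-12)
    return float(psth.rate[mask].mean())


def response_amplitude(psth: Psth) -> float:
    """Mean rate over [10, 50) ms minus mean rate over [-200, 0) ms, Hz."""
    if psth.bin_edges[0] > BASELINE_WINDOW[0] or psth.bin_edges[-1] < RESPONSE_WINDOW[1]:
        raise ValueError("PSTH must cover -200 ms to at least +50 ms")
    return _mean_rate(psth, *RESPONSE_WINDOW) - _mean_rate(psth, *BASELINE_WINDOW)


def per_event_amplitudes(spike_times: np.ndarray, event_times: np.ndarray) -> np.ndarray:
    """One evoked amplitude per event, each trial referenced to its own
    0-200 ms baseline."""
    event_times = np.asarray(event_times, dtype=float)
    resp = _window_counts(spike_times, event_times, *RESPONSE_WINDOW)
    base = _window_counts(spike_times, event_times, *BASELINE_WINDOW)
    resp_len = RESPONSE_WINDOW[1] - RESPONSE_WINDOW[0]
    base_len = BASELINE_WINDOW[1] - BASELINE_WINDOW[0]
    return resp / resp_len - base / base_len


def baseline_statistics(spike_times: np.ndarray, event_times: np.ndarray) -> tuple[float, float]:
    """(mean, SD) of the trial-averaged baseline rate in 5 ms bins, Hz."""
    psth = compute_psth(spike_times, event_times, window=(BASELINE_WINDOW[0], 0.0), bin_width=BASELINE_BIN)
    rates = psth.rate
    return float(rates.mean()), float(rates.std(ddof=0))


def compute_profile(
    unit_id: str,
    spike_times: np.ndarray,
    self_times: np.ndarray,
    random_times: np.ndarray,
) -> ResponseProfile:
    """Evoked-response profile of one unit from its retained sounds.

    Baseline statistics pool both sound classes; z-scores divide each
    class's amplitude by the pooled 5 ms-binned baseline SD.  When the
    baseline is completely silent (SD 0) the unit counts as responsive iff
    its amplitude is positive and at least 25% of trials carry a response
    spike — an artifact convention avoiding division by zero.
    """
    self_times = np.asarray(self_times, dtype=float)
    random_times = np.asarray(random_times, dtype=float)
    pooled = np.sort(np.concatenate([self_times, random_times]))
    if len(pooled) == 0:
        raise ValueError(f"unit {unit_id}: no retained sounds")

    base_mean, base_sd = baseline_statistics(spike_times, pooled)
    amps_self = per_event_amplitudes(spike_times, self_times) if len(self_times) else np.empty(0)
    amps_random = per_event_amplitudes(spike_times, random_times) if len(random_times) else np.empty(0)
    amp_self = float(amps_self.mean()) if len(amps_self) else np.nan
    amp_random = float(amps_random.mean()) if len(amps_random) else np.nan

    resp_counts = _window_counts(spike_times, pooled, *RESPONSE_WINDOW)
    frac_spiking = float((resp_counts > 0).mean())

    if base_sd > 0:
        z_self = amp_self / base_sd if np.isfinite(amp_self) else np.nan
        z_random = amp_random / base_sd if np.isfinite(amp_random) else np.nan
        zs = [z for z in (z_self, z_random) if np.isfinite(z)]
        responsive = bool(zs and max(zs) >= 2.0)
    else:
        z_self = z_random = np.nan
        amps = [a for a in (amp_self, amp_random) if np.isfinite(a)]
        responsive = bool(amps and max(amps) > 0 and frac_spiking >= 0.25)

    return ResponseProfile(
        unit_id=unit_id,
        baseline_mean=base_mean,
        baseline_sd=base_sd,
        amp_random=amp_random,
        amp_self=amp_self,
        z_random=z_random,
        z_self=z_self,
        is_responsive=responsive,
        per_trial_amp_random=amps_random,
        per_trial_amp_self=amps_self,
        n_trials_random=len(random_times),
        n_trials_self=len(self_times),
        frac_trials_with_spike=frac_spiking,
    )


def classify_responsive(profile: ResponseProfile) -> bool:
    """Auditory-responsiveness gate: max z >= 2, with the silent-baseline
    convention documented on :func:`compute_profile`."""
    if profile.baseline_sd > 0:
        zs = [z for z in (profile.z_random, profile.z_self) if np.isfinite(z)]
        return bool(zs and max(zs) >= 2.0)
    amps = [a for a in (profile.amp_random, profile.amp_self) if np.isfinite(a)]
    return bool(amps and max(amps) > 0 and profile.frac_trials_with_spike >= 0.25)


def preparatory_activity(
    spike_times: np.ndarray,
    press_times: np.ndarray,
    window: tuple[float, float] = (-1.0, 0.0),
    bin_width: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Firing-rate change before lever presses.

    Returns (per-bin delta rate over ``window``, mean delta over the last
    200 ms).  Deltas are referenced to the first bin (-1000 to -900 ms by
    default), which is therefore identically zero.
    """
    psth = compute_psth(spike_times, press_times, window=window, bin_width=bin_width)
    rates = psth.rate
    delta = rates - rates[0]
    centers = psth.bin_edges[:-1]
    summary = float(delta[centers >= -0.2 - 1e-12].mean())
    return delta, summary


def paired_pulse_ratio(
    spike_times: np.ndarray,
    first_times: np.ndarray,
    ipis: np.ndarray,
    exclude_ipis: Sequence[float] = (0.1,),
) -> dict[float, float]:
    """Adaptation ratio per inter-pulse interval.

    The ratio is the mean response to the second sound of each pair divided
    by the mean response to the first (both as 10-50 ms rates minus the
    pair's pre-first baseline).  Intervals listed in ``exclude_ipis``
    (100 ms by default, where responses to the first sound overlap the
    second) are dropped from the summary.  A non-positive first-sound
    response makes the ratio undefined (NaN) for that interval.
    """
    first_times = np.asarray(first_times, dtype=float)
    ipis = np.asarray(ipis, dtype=float)
    if len(first_times) != len(ipis):
        raise ValueError("one IPI label per pair required")
    second_times = first_times + ipis
    base = _window_counts(spike_times, first_times, *BASELINE_WINDOW) / (
        BASELINE_WINDOW[1] - BASELINE_WINDOW[0]
    )
    resp_len = RESPONSE_WINDOW[1] - RESPONSE_WINDOW[0]
    r1 = _window_counts(spike_times, first_times, *RESPONSE_WINDOW) / resp_len - base
    r2 = _window_counts(spike_times, second_times, *RESPONSE_WINDOW) / resp_len - base

    out: dict[float, float] = {}
    for ipi in np.unique(ipis):
        if any(np.isclose(ipi, ex) for ex in exclude_ipis):
            continue
        mask = np.isclose(ipis, ipi)
        m1 = float(r1[mask].mean())
        m2 = float(r2[mask].mean())
        out[float(ipi)] = m2 / m1 if m1 > 0 else np.nan
    return out
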