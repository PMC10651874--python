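"""Classification of light-evoked responses via a surrogate-PSTH null.

For each unit the PSTH around light onset (100 ms before to 100 ms after,
5 ms bins) yields a per-bin firing-rate change dFR relative to the 100 ms
pre-light baseline.  A chance distribution of dFR is built by cutting
200 ms segments at random out of the baseline periods (away from any
post-light epoch), treating the first half of each segment as baseline
and the second half as response.  Each of 1000 surrogates contributes its
20 response-bin dFR values to one pooled null (20,000 values), against
which each observed bin's one-tailed p is computed on the side matching
its sign.

Excitatory label: first bin with positive dFR and p < 0.001 ends at
<= 10 ms (terminal stimulation) or <= 15 ms (soma), with >= 10 spikes in
that bin across trials.  Inhibitory label: >= 3 consecutive bins with
negative dFR and p < 0.05 within the first 50 ms, with >= 20 baseline
spikes.  The excitatory label takes precedence.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import OptoResponse, UnitRecord

BIN = 0.005  # s
N_BINS = 20  # response bins, 0-100 ms
BASELINE = 0.1  # s pre-light
LAYER_BOUNDARY_UM = 600.0


class InsufficientBaselineError(ValueError):
    pass


def _psth_counts(spike_times: np.ndarray, light_onsets: np.ndarray) -> np.ndarray:
    """(n_trials, 40) counts in 5 ms bins from -100 to +100 ms."""
    edges = -BASELINE + BIN * np.arange(2 * N_BINS + 1)
    idx = np.searchsorted(spike_times, light_onsets[:, None] + edges[None, :], side="left")
    return np.diff(idx, axis=1)


def delta_fr(spike_times: np.ndarray, light_onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """(dFR per response bin, spike counts per response bin, baseline spikes).

    dFR is the trial-averaged rate in each 5 ms bin 0-100 ms after light
    onset minus the mean baseline rate (-100-0 ms), Hz.
    """
    light_onsets = np.asarray(light_onsets, dtype=float)
    if len(light_onsets) == 0:
        raise ValueError("no light onsets")
    counts = _psth_counts(np.asarray(spike_times, dtype=float), light_onsets)
    n = len(light_onsets)
    base_counts = counts[:, :N_BINS].sum()
    resp_counts = counts[:, N_BINS:].sum(axis=0)
    base_rate = base_counts / (n * BASELINE)
    resp_rate = resp_counts / (n * BIN)
    return resp_rate - base_rate, resp_counts, int(base_counts)


def _valid_segment_starts(duration: float, light_onsets: np.ndarray) -> np.ndarray:
    """Start bins (on the 5 ms grid) of 200 ms segments that avoid every
    100 ms post-light epoch."""
    n_grid = int(np.floor(duration / BIN))
    bad = np.zeros(n_grid, dtype=bool)
    for L in light_onsets:
        lo = int(np.floor(L / BIN))
        hi = int(np.ceil((L + BASELINE) / BIN))
        bad[max(lo, 0) : min(hi, n_grid)] = True
    window = 2 * N_BINS
    if n_grid < window:
        return np.empty(0, dtype=int)
    csum = np.concatenate(([0], np.cumsum(bad)))
    n_bad = csum[window:] - csum[:-window]  # bad bins in [s, s+window)
    return np.flatnonzero(n_bad == 0)


def surrogate_null(
    spike_times: np.ndarray,
    light_onsets: np.ndarray,
    duration: Optional[float] = None,
    n_surrogates: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled null dFR distribution and per-bin p-values.

    Each surrogate draws as many 200 ms baseline segments as there are
    light presentations (with replacement, aligned to the 5 ms grid),
    builds a pseudo-PSTH and contributes 20 dFR values; the p-value of an
    observed bin is the fraction of pooled null values at least as extreme
    on the side of the observed sign (ties count as extreme).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    spike_times = np.asarray(spike_times, dtype=float)
    light_onsets = np.asarray(light_onsets, dtype=float)
    if duration is None:
        last_spike = spike_times[-1] if len(spike_times) else 0.0
        last_light = light_onsets[-1] + BASELINE if len(light_onsets) else 0.0
        duration = max(last_spike, last_light)

    starts = _valid_segment_starts(duration, light_onsets)
    if len(starts) == 0:
        raise InsufficientBaselineError(
            f"need at least {2 * N_BINS * BIN:.1f} s of contiguous baseline clear of "
            "post-light epochs to draw surrogate segments"
        )

    n_grid = int(np.floor(duration / BIN))
    grid = np.bincount(
        np.clip((spike_times[spike_times < n_grid * BIN] / BIN).astype(int), 0, n_grid - 1),
        minlength=n_grid,
    )

    n_lights = len(light_onsets)
    pick = rng.choice(starts, size=(n_surrogates, n_lights), replace=True)
    seg = grid[pick[:, :, None] + np.arange(2 * N_BINS)[None, None, :]]
    summed = seg.sum(axis=1)  # (n_surrogates, 40)
    base = summed[:, :N_BINS].sum(axis=1) / (n_lights * BASELINE)
    resp = summed[:, N_BINS:] / (n_lights * BIN)
    null = (resp - base[:, None]).ravel()

    observed, _, _ = delta_fr(spike_times, light_onsets)
    p = np.ones(N_BINS)
    pos = observed > 0
    neg = observed < 0
    if pos.any():
        p[pos] = (null[None, :] >= observed[pos, None]).mean(axis=1)
    if neg.any():
        p[neg] = (null[None, :] <= observed[neg, None]).mean(axis=1)
    return null, p


def classify_opto(
    delta: np.ndarray,
    p_per_bin: np.ndarray,
    spikes_per_bin: np.ndarray,
    n_baseline_spikes: int,
    mode: str = "terminal",
) -> tuple[str, Optional[float]]:
    """Apply the excitatory/inhibitory criteria; returns (label, latency_ms).

    Latency is the *end* time of the first bin with positive dFR and
    p < 0.001 (bin [0,5) -> 5 ms), so the 10 ms cutoff admits exactly the
    first two bins.
    """
    if mode not in ("terminal", "soma"):
        raise ValueError("mode must be 'terminal' or 'soma'")
    max_latency = 10.0 if mode == "terminal" else 15.0

    sig_exc = (delta > 0) & (p_per_bin < 0.001)
    latency = None
    if sig_exc.any():
        first = int(np.flatnonzero(sig_exc)[0])
        latency = (first + 1) * BIN * 1000.0
        if latency <= max_latency and spikes_per_bin[first] >= 10:
            return "excitatory_short_latency", latency

    first_50ms = slice(0, 10)
    sig_inh = (delta[first_50ms] < 0) & (p_per_bin[first_50ms] < 0.05)
    run = 0
    longest = 0
    for s in sig_inh:
        run = run + 1 if s else 0
        longest = max(longest, run)
    if longest >= 3 and n_baseline_spikes >= 20:
        return "inhibitory", latency
    return "none", latency


def analyze_opto_unit(
    unit: UnitRecord,
    light_onsets: np.ndarray,
    duration: Optional[float] = None,
    mode: str = "terminal",
    n_surrogates: int = 1000,
    seed: int = 0,
) -> OptoResponse:
    """Full per-unit opto classification against the surrogate null."""
    delta, counts, n_base = delta_fr(unit.spike_times, light_onsets)
    _, p = surrogate_null(
        unit.spike_times, light_onsets, duration=duration, n_surrogates=n_surrogates, seed=seed
    )
    label, latency = classify_opto(delta, p, counts, n_base, mode=mode)
    return OptoResponse(
        unit_id=unit.unit_id,
        delta_fr=delta,
        p_per_bin=p,
        spikes_per_bin=counts,
        n_baseline_spikes=n_base,
        latency_ms=latency if label == "excitatory_short_latency" else None,
        label=label,
        mode=mode,
    )


def analyze_opto_session(
    units: Sequence[UnitRecord],
    light_onsets: np.ndarray,
    duration: Optional[float] = None,
    mode: str = "terminal",
    n_surrogates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-unit opto table (unit_id, depth_um, label, latency_ms, p_min)."""
    rows = []
    for i, u in enumerate(units):
        r = analyze_opto_unit(
            u, light_onsets, duration=duration, mode=mode, n_surrogates=n_surrogates, seed=seed + i
        )
        rows.append(
            {
                "unit_id": u.unit_id,
                "depth_um": u.depth_um,
                "label": r.label,
                "latency_ms": r.latency_ms,
                "p_min": float(r.p_per_bin.min()),
            }
        )
    return pd.DataFrame(rows)


def population_fractions(
    labels: Sequence[str], depths: Sequence[float], boundary_um: float = LAYER_BOUNDARY_UM
) -> dict:
    """Fractions of each response label among upper (< boundary) and lower
    (> boundary) layer units, relative to the unit count in each layer."""
    labels = np.asarray(labels)
    depths = np.asarray(depths, dtype=float)
    out = {}
    for layer, mask in (("upper", depths < boundary_um), ("lower", depths > boundary_um)):
        n = int(mask.sum())
        layer_out = {"n": n}
        for lab in ("excitatory_short_latency", "inhibitory"):
            k = int(((labels == lab) & mask).sum())
            layer_out[lab] = {
                "count": k,
                "percent": round(100.0 * k / n, 2) if n else 0.0,
            }
        out[layer] = layer_out
    return out
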