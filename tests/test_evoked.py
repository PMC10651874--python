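"""PSTHs, evoked amplitudes, responsiveness, preparatory activity and
paired-pulse adaptation."""

import numpy as np
import pytest

import selfsound as ss
from selfsound import evoked
from selfsound.evoked import (
    compute_profile,
    compute_psth,
    paired_pulse_ratio,
    per_event_amplitudes,
    preparatory_activity,
    response_amplitude,
)


def test_psth_basic_binning():
    psth = compute_psth(np.array([10.0]), np.array([10.0]), window=(0.0, 0.1), bin_width=0.005)
    assert psth.counts[0, 0] == 1
    assert psth.counts.sum() == 1


def test_psth_rate_scaling():
    events = np.arange(100, dtype=float) * 10.0
    spikes = np.sort(events + 0.020)
    psth = compute_psth(spikes, events, window=(-0.2, 0.1), bin_width=0.005)
    rates = psth.rate
    centers = psth.bin_edges[:-1]
    hot = np.isclose(centers, 0.020)
    assert rates[hot] == pytest.approx(200.0)
    assert rates[~hot].sum() == 0.0


def test_psth_requires_events_and_valid_bins():
    with pytest.raises(ValueError):
        compute_psth(np.array([1.0]), np.array([]))
    with pytest.raises(ValueError):
        compute_psth(np.array([1.0]), np.array([1.0]), bin_width=-1.0)


def test_psth_count_conservation(rng):
    """Total PSTH counts equal the number of spikes inside trial windows."""
    spikes = np.sort(rng.uniform(0, 1000, 5000))
    events = np.sort(rng.uniform(5, 995, 50))
    psth = compute_psth(spikes, events, window=(-0.2, 0.1), bin_width=0.005)
    expected = sum(
        ((spikes >= t - 0.2) & (spikes < t + 0.1)).sum() for t in events
    )
    assert psth.counts.sum() == expected


def test_response_amplitude_examples():
    events = np.arange(100, dtype=float) * 10.0
    # 1 spike per trial in [10, 50) ms, silent baseline -> 25 Hz
    spikes = np.sort(events + 0.030)
    psth = compute_psth(spikes, events, window=(-0.2, 0.1), bin_width=0.005)
    assert response_amplitude(psth) == pytest.approx(25.0)
    # stationary regular spiking -> amplitude 0 (rate identical in both windows)
    grid = np.concatenate([events + off for off in np.arange(-0.2, 0.1, 0.005)])
    psth2 = compute_psth(np.sort(grid), events, window=(-0.2, 0.1), bin_width=0.005)
    assert response_amplitude(psth2) == pytest.approx(0.0)


def test_response_amplitude_requires_full_window():
    psth = compute_psth(np.array([0.5]), np.array([1.0]), window=(0.0, 0.1), bin_width=0.005)
    with pytest.raises(ValueError):
        response_amplitude(psth)


def test_per_event_amplitudes_deterministic():
    events = np.array([10.0, 20.0, 30.0])
    spikes = np.sort(events + 0.020)
    amps = per_event_amplitudes(spikes, events)
    assert np.allclose(amps, 25.0)
    # zero-spike trial with silent baseline -> 0
    assert per_event_amplitudes(np.array([]), np.array([5.0]))[0] == 0.0


def test_amplitude_invariant_to_constant_rate_offset():
    """Adding the same rate to baseline and response windows leaves the
    evoked amplitude unchanged."""
    events = np.arange(50, dtype=float) * 10.0
    signal = np.sort(events + 0.030)
    offset = np.sort(np.concatenate([events + off for off in np.arange(-0.2, 0.05, 0.005)]))
    amp_signal = per_event_amplitudes(signal, events).mean()
    amp_both = per_event_amplitudes(np.sort(np.concatenate([signal, offset])), events).mean()
    assert amp_both == pytest.approx(amp_signal)


def test_responsiveness_thresholds():
    """z >= 2 is inclusive; silent units are not responsive."""
    events = np.arange(200, dtype=float) * 10.0
    # silent unit
    prof = compute_profile("u", np.array([]), events[:100], events[100:])
    assert not prof.is_responsive
    # strong responder: 6 locked spikes per trial against a sparse baseline
    baseline = np.concatenate([events + off for off in (-0.15, -0.05)])
    resp = np.concatenate([events + off for off in (0.012, 0.018, 0.024, 0.030, 0.036, 0.042)])
    spikes = np.sort(np.concatenate([baseline, resp]))
    prof2 = compute_profile("u", spikes, events[:100], events[100:])
    assert prof2.is_responsive
    assert evoked.classify_responsive(prof2)


def test_responsiveness_power_and_false_positives():
    """Units with true z >= 4 are detected >= 95% of the time; null units
    are flagged at close to the nominal ~5% rate."""
    cfg = ss.SimConfig.high_snr(seed=21, attenuation=1.0, session_duration=3600.0, n_units_per_animal=60)
    log = ss.generate_behavior(cfg)
    self_t, rand_t = ss.select_sounds(log, ss.SelectionConfig())

    units = ss.generate_spikes(cfg, log, rng=np.random.default_rng(22))
    hits = [
        compute_profile(u.unit_id, u.spike_times, self_t, rand_t).is_responsive for u in units
    ]
    assert np.mean(hits) >= 0.95

    null_cfg = ss.SimConfig(
        seed=23, session_duration=3600.0, n_units_per_animal=60,
        evoked_amp_random=0.0, ramp_amplitude=0.0,
    )
    null_units = ss.generate_spikes(null_cfg, log, rng=np.random.default_rng(24))
    fps = [
        compute_profile(u.unit_id, u.spike_times, self_t, rand_t).is_responsive
        for u in null_units
    ]
    assert np.mean(fps) <= 0.15  # ~5% nominal + binomial tolerance at n=60


def test_preparatory_ramp_closed_form():
    """A linear ramp reaching +3 Hz at press with 600 ms onset averages
    +2.5 Hz over the last 200 ms relative to the -1000/-900 ms baseline."""
    cfg = ss.SimConfig(seed=31, evoked_amp_random=0.0, ramp_amplitude=3.0, session_duration=7200.0,
                       n_units_per_animal=60)
    log = ss.generate_behavior(cfg)
    units = ss.generate_spikes(cfg, log, rng=np.random.default_rng(32))
    presses = ss.select_preparatory_presses(log, ss.SelectionConfig())
    deltas, summaries = [], []
    for u in units:
        d, s = preparatory_activity(u.spike_times, presses)
        deltas.append(d)
        summaries.append(s)
    assert d[0] == 0.0  # baseline bin references itself
    assert np.mean(summaries) == pytest.approx(2.5, abs=0.2)


def test_preparatory_stationary_null(rng):
    spikes = np.sort(rng.uniform(0, 2000, 20000))  # 10 Hz homogeneous
    presses = np.sort(rng.uniform(10, 1990, 300))
    _, summary = preparatory_activity(spikes, presses)
    assert abs(summary) < 1.0


def test_paired_pulse_ratio_identical_responses():
    firsts = np.arange(30, dtype=float) * 10.0
    ipis = np.full(30, 0.4)
    spikes = np.sort(np.concatenate([firsts + 0.02, firsts + 0.4 + 0.02]))
    ratios = paired_pulse_ratio(spikes, firsts, ipis)
    assert ratios[0.4] == pytest.approx(1.0)


def test_paired_pulse_recovers_adaptation_law():
    """Measured ratio at 400 ms matches the generator's recovery gain
    1 - 0.5*exp(-0.4/0.3) ~ 0.868; 100 ms pairs are excluded."""
    cfg = ss.SimConfig(
        seed=41, baseline_log_mean=np.log(5.0), baseline_log_sd=0.2,
        evoked_amp_random=80.0, evoked_amp_unit_sd=0.0, ramp_amplitude=0.0,
        n_units_per_animal=40,
    )
    log, firsts, ipis = ss.synthetic.generate_sound_pairs(
        cfg, n_pairs_per_ipi=100, rng=np.random.default_rng(41)
    )
    units = ss.generate_spikes(cfg, log, rng=np.random.default_rng(42))
    per_ipi = {}
    for u in units:
        for k, v in paired_pulse_ratio(u.spike_times, firsts, ipis).items():
            per_ipi.setdefault(k, []).append(v)
    assert 0.1 not in per_ipi  # excluded from the summary
    measured = np.nanmean(per_ipi[0.4])
    expected = 1.0 - 0.5 * np.exp(-0.4 / 0.3)
    assert measured == pytest.approx(expected, abs=0.05)


def test_paired_pulse_undefined_for_nonpositive_first_response():
    firsts = np.array([10.0, 20.0])
    ipis = np.array([0.4, 0.4])
    # spikes only in baseline -> negative first response
    spikes = np.sort(np.concatenate([firsts - 0.1]))
    ratios = paired_pulse_ratio(spikes, firsts, ipis)
    assert np.isnan(ratios[0.4])
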