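"""Light-evoked response classification against the surrogate-PSTH null."""

import numpy as np
import pytest

import selfsound as ss
from selfsound.opto import (
    InsufficientBaselineError,
    analyze_opto_session,
    classify_opto,
    delta_fr,
    population_fractions,
    surrogate_null,
)


def regular_train(rate_hz, t_stop, t_start=0.0):
    return np.arange(t_start, t_stop, 1.0 / rate_hz)


def test_delta_fr_single_locked_spike():
    """1 spike at +3 ms on each of 50 trials, silent baseline: 200 Hz in
    the first bin, 0 elsewhere."""
    lights = 2.5 * np.arange(1, 51)
    spikes = np.sort(lights + 0.003)
    d, counts, n_base = delta_fr(spikes, lights)
    assert d[0] == pytest.approx(200.0)
    assert np.allclose(d[1:], 0.0)
    assert counts[0] == 50
    assert n_base == 0


def test_delta_fr_silenced_unit():
    """Baseline 20 Hz, silent after light: dFR = -20 Hz in every bin."""
    lights = 5.0 * np.arange(1, 21)
    spikes = []
    for L in lights:
        spikes.extend(L - 0.1 + 0.05 * np.arange(2))  # 2 spikes per 100 ms baseline
    d, _, n_base = delta_fr(np.sort(spikes), lights)
    assert np.allclose(d, -20.0)
    assert n_base == 40


def test_surrogate_null_calibration(rng):
    """Stationary Poisson: the sign-matched one-tailed p is calibrated per
    tail, so a fraction ~2*alpha of bins falls below alpha (each sign's
    tail contributes alpha)."""
    duration = 500.0
    lights = np.sort(rng.uniform(10.0, duration - 10.0, 150))
    lights = lights[np.concatenate(([True], np.diff(lights) > 0.5))]
    ps = []
    for i in range(30):
        spikes = np.sort(rng.uniform(0, duration, int(20 * duration)))
        _, p = surrogate_null(spikes, lights, duration=duration, seed=i)
        ps.append(p)
    ps = np.concatenate(ps)
    assert abs((ps < 0.05).mean() - 0.10) < 0.03
    assert abs((ps < 0.20).mean() - 0.40) < 0.06
    assert (ps < 0.001).mean() < 0.01


def test_surrogate_null_extreme_observation():
    """A locked response far outside the null support gets p = 0 at the
    pooled resolution of 1/(n_surrogates * 20)."""
    lights = 2.5 * np.arange(1, 41)
    background = regular_train(10.0, 105.0)
    locked = np.concatenate([lights + 0.003, lights + 0.004])
    spikes = np.sort(np.concatenate([background, locked]))
    _, p = surrogate_null(spikes, lights, duration=105.0, seed=0)
    assert p[0] == 0.0


def test_zero_spike_unit_not_significant():
    lights = 2.5 * np.arange(1, 21)
    d, counts, n_base = delta_fr(np.array([]), lights)
    _, p = surrogate_null(np.array([]), lights, duration=55.0, seed=0)
    assert np.allclose(d, 0.0)
    assert np.all(p == 1.0)
    label, _ = classify_opto(d, p, counts, n_base)
    assert label == "none"


def test_insufficient_baseline_raises():
    # lights every 0.15 s leave no clear 200 ms segment
    lights = 0.15 * np.arange(1, 100)
    with pytest.raises(InsufficientBaselineError):
        surrogate_null(np.array([1.0]), lights, duration=15.0, seed=0)


def test_surrogate_determinism():
    rng = np.random.default_rng(5)
    lights = 2.5 * np.arange(1, 41)
    spikes = np.sort(rng.uniform(0, 105, 800))
    _, p1 = surrogate_null(spikes, lights, duration=105.0, seed=11)
    _, p2 = surrogate_null(spikes, lights, duration=105.0, seed=11)
    assert np.array_equal(p1, p2)


def _p(vals):
    p = np.ones(20)
    for i, v in vals.items():
        p[i] = v
    return p


def test_classify_latency_convention():
    """Latency is the end of the first significant bin: bin [0,5) -> 5 ms;
    a first significant bin at [10,15) ms is too late in terminal mode but
    admissible in soma mode."""
    delta = np.zeros(20)
    counts = np.zeros(20, dtype=int)
    delta[0], counts[0] = 50.0, 50
    label, lat = classify_opto(delta, _p({0: 0.0}), counts, 100, mode="terminal")
    assert label == "excitatory_short_latency" and lat == 5.0

    delta2 = np.zeros(20)
    counts2 = np.zeros(20, dtype=int)
    delta2[2], counts2[2] = 50.0, 50
    label2, _ = classify_opto(delta2, _p({2: 0.0}), counts2, 100, mode="terminal")
    assert label2 == "none"
    label3, lat3 = classify_opto(delta2, _p({2: 0.0}), counts2, 100, mode="soma")
    assert label3 == "excitatory_short_latency" and lat3 == 15.0


def test_classify_spike_count_gate():
    delta = np.zeros(20)
    counts = np.zeros(20, dtype=int)
    delta[0], counts[0] = 50.0, 9  # below the 10-spike minimum
    label, _ = classify_opto(delta, _p({0: 0.0}), counts, 100)
    assert label == "none"


def test_classify_inhibitory_run():
    """Four consecutive suppressed bins at 15-35 ms with ample baseline
    spikes are inhibitory; fewer than 3 bins or < 20 baseline spikes are
    not."""
    delta = np.zeros(20)
    delta[3:7] = -5.0
    p = _p({3: 0.01, 4: 0.02, 5: 0.01, 6: 0.04})
    counts = np.zeros(20, dtype=int)
    assert classify_opto(delta, p, counts, 100)[0] == "inhibitory"
    assert classify_opto(delta, p, counts, 19)[0] == "none"
    p2 = _p({3: 0.01, 4: 0.02, 6: 0.04})  # broken run
    delta2 = np.zeros(20)
    delta2[[3, 4, 6]] = -5.0
    assert classify_opto(delta2, p2, counts, 100)[0] == "none"


def test_excitatory_takes_precedence():
    delta = np.zeros(20)
    delta[0] = 50.0
    delta[3:7] = -5.0
    counts = np.zeros(20, dtype=int)
    counts[0] = 40
    p = _p({0: 0.0, 3: 0.01, 4: 0.01, 5: 0.01})
    assert classify_opto(delta, p, counts, 100)[0] == "excitatory_short_latency"


def test_population_fractions_printed_precision():
    labels = ["excitatory_short_latency"] * 9 + ["none"] * 185 + ["none"] * 10
    depths = [400.0] * 194 + [800.0] * 10
    out = population_fractions(labels, depths)
    assert out["upper"]["n"] == 194
    assert out["upper"]["excitatory_short_latency"]["percent"] == 4.64
    assert out["lower"]["excitatory_short_latency"]["count"] == 0


def test_opsin_session_detection_and_layer_specificity():
    """Truly excited deep units are labelled excitatory with short latency;
    no superficial unit is."""
    cfg = ss.SimConfig(seed=81, opto_session_duration=400.0, opto_direct_fraction=0.3,
                       opto_inhibited_fraction=0.0)
    units, log = ss.generate_opto_session(cfg, opsin=True, n_units=40)
    lights = log.of_type("light_on")
    table = analyze_opto_session(units, lights, duration=log.session_duration, seed=3)
    truth = np.array([u.truth["opto_excited"] for u in units])
    labelled = (table.label == "excitatory_short_latency").to_numpy()
    assert truth.sum() >= 3
    assert (labelled & truth).sum() >= 0.9 * truth.sum()
    shallow = table.depth_um.to_numpy() < 600.0
    assert not (labelled & shallow).any()
    assert np.all(table.latency_ms[labelled] <= 10.0)
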