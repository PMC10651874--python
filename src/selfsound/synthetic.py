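"""Synthetic session generator.

Emulates head-fixed recordings in which a mouse presses a lever in bouts,
every press triggers a 100 ms sound, the same sound also plays at random
every 5-10 s, and sorted units fire as inhomogeneous Poisson processes:

* a log-normal baseline rate per unit,
* a rectangular evoked transient confined to 10-50 ms after each sound,
  scaled by the attenuation factor ``a`` for self-generated sounds and by
  an exponential-recovery adaptation gain ``g(dt) = 1 - A*exp(-dt/tau)``
  where ``dt`` is the time since the previous sound of either kind,
* a linear firing-rate ramp beginning ``ramp_onset`` seconds before each
  press (motor preparatory activity),
* optionally, short-latency optogenetic excitation (deep units only)
  and/or inhibition locked to 100 ms light pulses.

Because every rate component is additive and non-negative (inhibition is
realised by thinning), spike trains are sampled exactly by superposing
independent Poisson realisations of each component.

All randomness flows from ``SimConfig.seed`` through
``numpy.random.SeedSequence``, so identical configurations give
byte-identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import EventLog, UnitRecord, sort_events

RESPONSE_WINDOW = (0.010, 0.050)  # evoked transient support, s after sound onset


@dataclass
class WaveformTemplate:
    """Per-class means/SDs of the two waveform features, microseconds."""

    trough_to_peak_us: float
    trough_to_peak_sd_us: float
    half_width_us: float
    half_width_sd_us: float


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    The defaults describe a two-hour lever-press session with >250 presses,
    random sounds every 5-10 s, 14% narrow-waveform units, and a moderate
    preparatory ramp; effect sizes (attenuation, evoked amplitude,
    adaptation) are configurable so that every downstream stage has a
    ground-truth oracle.
    """

    seed: int
    session_duration: float = 7200.0
    n_animals_per_genotype: int = 9
    n_units_per_animal: int = 20

    # log-normal baseline firing rates (Hz): median exp(mu), spread sigma
    baseline_log_mean: float = float(np.log(4.5))
    baseline_log_sd: float = 0.5

    # evoked transient in the 10-50 ms window
    evoked_amp_random: float = 50.0  # Hz above baseline
    evoked_amp_unit_sd: float = 0.25  # log-sd of the mean-one per-unit gain
    attenuation: float = 0.6  # a: self amplitude = a * random amplitude
    attenuation_late: Optional[float] = None  # a after the switch ordinal
    attenuation_switch: int = 300  # self-sound ordinal where `attenuation_late` begins
    #: optional (upper, lower) attenuation step across `depth_boundary_um`
    attenuation_by_depth: Optional[tuple[float, float]] = None
    depth_boundary_um: float = 600.0

    # motor preparatory ramp: linear, 0 at -ramp_onset to ramp_amplitude at press
    ramp_amplitude: float = 3.0  # Hz at press time
    ramp_onset: float = 0.6  # s before press

    # inter-sound adaptation gain g(dt) = 1 - A*exp(-dt/tau)
    adaptation_depth: float = 0.5
    adaptation_tau: float = 0.3  # s

    # lever-press bout structure
    ipi_range: tuple[float, float] = (2.0, 6.0)  # within-bout inter-press interval, s
    bout_length_mean: float = 15.0  # geometric mean presses per bout
    pause_range: tuple[float, float] = (30.0, 120.0)  # inter-bout pause, s
    hold_range: tuple[float, float] = (0.15, 0.40)  # lever hold duration, s

    sound_duration: float = 0.1
    random_sound_interval: tuple[float, float] = (5.0, 10.0)

    depth_range: tuple[float, float] = (100.0, 1100.0)  # um, uniform

    # waveform classes
    interneuron_fraction: float = 0.14
    broad_template: WaveformTemplate = dataclasses.field(
        default_factory=lambda: WaveformTemplate(700.0, 70.0, 300.0, 30.0)
    )
    narrow_template: WaveformTemplate = dataclasses.field(
        default_factory=lambda: WaveformTemplate(300.0, 30.0, 150.0, 15.0)
    )
    waveform_fs: float = 30000.0
    waveform_noise: float = 0.01  # fraction of trough amplitude

    # optogenetic stimulation
    opto_session_duration: float = 600.0
    opto_pulse_period: tuple[float, float] = (2.0, 3.0)
    opto_pulse_duration: float = 0.1
    opto_direct_fraction: float = 0.05  # of deep units, when opsin expressed
    opto_latency_range: tuple[float, float] = (0.002, 0.008)  # s
    opto_latency_jitter: float = 0.0003  # s, per-spike
    opto_spikes_per_pulse: float = 1.5  # mean evoked spikes per pulse
    opto_excited_inhibited_fraction: float = 0.5  # excited units also inhibited
    opto_inhibited_fraction: float = 0.08  # of all units, inhibition only
    opto_inhibition_onset: float = 0.010  # s after light onset
    opto_inhibition_duration: float = 0.060  # s
    opto_inhibition_strength: float = 0.85  # fractional rate reduction

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.session_duration < 0:
            raise ValueError("session_duration must be non-negative")
        if self.attenuation < 0:
            raise ValueError("attenuation factor must be >= 0")
        if self.ramp_onset <= 0:
            raise ValueError("ramp_onset must be positive")
        if self.adaptation_tau <= 0:
            raise ValueError("adaptation_tau must be positive")
        if not 0.0 <= self.interneuron_fraction <= 1.0:
            raise ValueError("interneuron_fraction must lie in [0, 1]")
        for name in ("ipi_range", "pause_range", "random_sound_interval", "hold_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")

    @classmethod
    def high_snr(cls, seed: int, attenuation: float = 0.6, **overrides) -> "SimConfig":
        """Conditions for parameter-recovery studies: strong, clean evoked
        transients and no preparatory ramp, so the analytic modulation index
        (a-1)/(a+1) is the ground truth for the full pipeline."""
        defaults = dict(
            baseline_log_mean=float(np.log(5.0)),
            baseline_log_sd=0.3,
            evoked_amp_random=50.0,
            evoked_amp_unit_sd=0.2,
            ramp_amplitude=0.0,
        )
        defaults.update(overrides)
        return cls(seed=seed, attenuation=attenuation, **defaults)


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(config: SimConfig, rng: Optional[np.random.Generator] = None) -> EventLog:
    """Simulate the behavioral/stimulus event stream of one session.

    Presses arrive in bouts (geometric length, uniform within-bout interval,
    uniform inter-bout pause); each press emits a ``sound_self`` at the press
    time, a release after the hold, and a reward; ``sound_random`` events
    arrive with uniform 5-10 s gaps independent of behavior.
    """
    if config.session_duration < 0:
        raise ValueError("session_duration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.session_duration
    if T == 0:
        return EventLog.empty(0.0)

    times: list[float] = []
    types: list[str] = []
    durs: list[float] = []

    p_bout = 1.0 / config.bout_length_mean
    t = rng.uniform(5.0, 30.0)  # settling time before the first bout
    while t < T:
        bout_len = rng.geometric(p_bout)
        for _ in range(bout_len):
            t += rng.uniform(*config.ipi_range)
            if t >= T:
                break
            hold = rng.uniform(*config.hold_range)
            times += [t, t, min(t + hold, T)]
            types += ["press", "sound_self", "release"]
            durs += [hold, config.sound_duration, 0.0]
            if t + 0.1 < T:
                times.append(t + 0.1)
                types.append("reward")
                durs.append(0.0)
        t += rng.uniform(*config.pause_range)

    t = rng.uniform(*config.random_sound_interval)
    while t < T:
        times.append(t)
        types.append("sound_random")
        durs.append(config.sound_duration)
        t += rng.uniform(*config.random_sound_interval)

    times_a, types_a, durs_a = sort_events(times, types, durs)
    return EventLog(times_a, types_a, durs_a, T)


# ---------------------------------------------------------------------------
# spikes


def adaptation_gain(dt: np.ndarray, depth: float, tau: float) -> np.ndarray:
    """Exponential-recovery gain ``1 - A*exp(-dt/tau)``; gain 1 for the
    first sound (``dt`` infinite)."""
    return 1.0 - depth * np.exp(-np.asarray(dt, dtype=float) / tau)


def _sound_gains(config: SimConfig, log: EventLog):
    """Per-sound times, self flags, adaptation gains and self ordinals."""
    s_times, s_self = log.sounds()
    gaps = np.diff(s_times, prepend=-np.inf)
    with np.errstate(over="ignore"):
        gains = adaptation_gain(gaps, config.adaptation_depth, config.adaptation_tau)
    if len(gains):
        gains[0] = 1.0  # first sound: fully recovered
    ordinals = np.cumsum(s_self)  # 1-based ordinal among self sounds
    return s_times, s_self, gains, ordinals


def _effective_attenuation(config: SimConfig, depth_um: float, self_ordinals: np.ndarray) -> np.ndarray:
    """Attenuation factor per self sound for a unit at the given depth."""
    if config.attenuation_by_depth is not None:
        upper, lower = config.attenuation_by_depth
        a0 = lower if depth_um >= config.depth_boundary_um else upper
    else:
        a0 = config.attenuation
    a = np.full(len(self_ordinals), a0)
    if config.attenuation_late is not None:
        a[self_ordinals > config.attenuation_switch] = config.attenuation_late
    return a


def make_waveform(
    config: SimConfig,
    trough_to_peak_us: float,
    half_width_us: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Biphasic trough-then-peak template sampled at ``waveform_fs``.

    The window spans ~0.5 ms before to ~1.3 ms after the trough.  The trough
    is Gaussian with the requested half-width (FWHM), followed by a smaller
    positive peak at the requested trough-to-peak separation.
    """
    dt_us = 1e6 / config.waveform_fs
    n_pre = int(round(495.0 / dt_us))
    n_post = int(round(1287.0 / dt_us))
    t = (np.arange(n_pre + n_post + 1) - n_pre) * dt_us
    sigma_t = half_width_us / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_p = max(trough_to_peak_us / 3.0, 2.0 * dt_us)
    w = -np.exp(-0.5 * (t / sigma_t) ** 2)
    w += 0.35 * np.exp(-0.5 * ((t - trough_to_peak_us) / sigma_p) ** 2)
    w += config.waveform_noise * rng.standard_normal(len(t))
    return w


def _sample_unit_shape(config: SimConfig, rng: np.random.Generator):
    """Draw a cell class and its waveform; returns (class, waveform, ttp, hw)."""
    is_narrow = rng.random() < config.interneuron_fraction
    tpl = config.narrow_template if is_narrow else config.broad_template
    ttp = rng.normal(tpl.trough_to_peak_us, tpl.trough_to_peak_sd_us)
    hw = rng.normal(tpl.half_width_us, tpl.half_width_sd_us)
    ttp = max(ttp, 60.0)
    hw = max(hw, 30.0)
    wf = make_waveform(config, ttp, hw, rng)
    return ("pIN" if is_narrow else "pPN"), wf, ttp, hw


def _poisson_homogeneous(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def generate_spikes(
    config: SimConfig,
    log: EventLog,
    animal_id: str = "A0",
    genotype: str = "WT",
    rng: Optional[np.random.Generator] = None,
) -> list[UnitRecord]:
    """Realise ``n_units_per_animal`` inhomogeneous-Poisson units for one
    behavioral session.  Each unit's rate is baseline + evoked transients
    (attenuated and adaptation-scaled) + the pre-press ramp."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = log.session_duration
    s_times, s_self, gains, ordinals = _sound_gains(config, log)
    press_times = log.of_type("press")
    win_lo, win_hi = RESPONSE_WINDOW
    win_len = win_hi - win_lo

    units: list[UnitRecord] = []
    for i in range(config.n_units_per_animal):
        lam = float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd))
        depth = float(rng.uniform(*config.depth_range))
        cell_class, wf, ttp, hw = _sample_unit_shape(config, rng)
        unit_gain = float(
            np.exp(rng.normal(-0.5 * config.evoked_amp_unit_sd**2, config.evoked_amp_unit_sd))
        )
        amp_random = config.evoked_amp_random * unit_gain

        spikes = [_poisson_homogeneous(lam, T, rng)]

        if len(s_times) and amp_random > 0:
            amp = amp_random * gains
            a_eff = np.ones(len(s_times))
            a_eff[s_self] = _effective_attenuation(config, depth, ordinals[s_self])
            amp = amp * a_eff
            counts = rng.poisson(np.maximum(amp, 0.0) * win_len)
            total = int(counts.sum())
            if total:
                starts = np.repeat(s_times + win_lo, counts)
                spikes.append(starts + rng.uniform(0.0, win_len, total))

        if len(press_times) and config.ramp_amplitude > 0:
            mean_extra = config.ramp_amplitude * config.ramp_onset / 2.0
            counts = rng.poisson(mean_extra, len(press_times))
            total = int(counts.sum())
            if total:
                # density rises linearly toward the press: inverse-CDF sampling
                u = rng.random(total)
                offsets = config.ramp_onset * (1.0 - np.sqrt(u))
                spikes.append(np.repeat(press_times, counts) - offsets)

        st = np.concatenate(spikes)
        st = np.sort(st[(st >= 0.0) & (st < T)])
        units.append(
            UnitRecord(
                unit_id=f"{animal_id}_u{i:03d}",
                animal_id=animal_id,
                genotype=genotype,
                depth_um=depth,
                spike_times=st,
                waveform=wf,
                fs=config.waveform_fs,
                truth={
                    "baseline_hz": lam,
                    "amp_random_hz": amp_random,
                    "attenuation": float(
                        _effective_attenuation(config, depth, np.array([1]))[0]
                    ),
                    "cell_class": cell_class,
                    "trough_to_peak_us": ttp,
                    "half_width_us": hw,
                },
            )
        )
    return units


def generate_session(
    config: SimConfig,
    animal_id: str = "A0",
    genotype: str = "WT",
    seed_seq: Optional[np.random.SeedSequence] = None,
) -> tuple[list[UnitRecord], EventLog]:
    """One animal's full session: behavior first, then spikes."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(seed_seq)
    log = generate_behavior(config, rng)
    units = generate_spikes(config, log, animal_id, genotype, rng)
    return units, log


def generate_cohort(
    config: SimConfig, genotype: str = "WT", n_animals: Optional[int] = None
) -> dict[str, tuple[list[UnitRecord], EventLog]]:
    """Sessions for ``n_animals`` animals of one genotype, keyed by animal id."""
    if n_animals is None:
        n_animals = config.n_animals_per_genotype
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n_animals)
    out = {}
    for i, child in enumerate(children):
        aid = f"{genotype}_{i:02d}"
        out[aid] = generate_session(config, aid, genotype, child)
    return out


# ---------------------------------------------------------------------------
# optogenetics


def generate_opto_session(
    config: SimConfig,
    opsin: bool = True,
    animal_id: str = "O0",
    rng: Optional[np.random.Generator] = None,
    n_units: Optional[int] = None,
) -> tuple[list[UnitRecord], EventLog]:
    """Passive session with 100 ms light pulses every 2-3 s.

    With ``opsin=True`` a configured fraction of units deeper than the layer
    boundary receive short-latency, low-jitter excitation (optionally
    followed by inhibition), and a fraction of all units are inhibited only.
    With ``opsin=False`` no unit's rate depends on the light.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.opto_session_duration
    n_units = config.n_units_per_animal if n_units is None else n_units

    lights = []
    t = rng.uniform(*config.opto_pulse_period)
    while t < T - config.opto_pulse_duration:
        lights.append(t)
        t += rng.uniform(*config.opto_pulse_period)
    lights = np.asarray(lights)
    log = EventLog(
        lights,
        np.full(len(lights), "light_on", dtype="U12"),
        np.full(len(lights), config.opto_pulse_duration),
        T,
    )

    units: list[UnitRecord] = []
    for i in range(n_units):
        lam = float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd))
        depth = float(rng.uniform(*config.depth_range))
        cell_class, wf, ttp, hw = _sample_unit_shape(config, rng)
        deep = depth > config.depth_boundary_um

        # draw fates with a fixed number of rng calls so that unit streams
        # stay aligned between opsin and no-opsin runs
        u_excite, u_inhib, u_post = rng.random(3)
        excited = opsin and deep and (u_excite < config.opto_direct_fraction)
        inhibited = opsin and (
            (excited and u_post < config.opto_excited_inhibited_fraction)
            or (not excited and u_inhib < config.opto_inhibited_fraction)
        )
        latency = float(rng.uniform(*config.opto_latency_range))

        st = _poisson_homogeneous(lam, T, rng)
        if inhibited and len(lights):
            lo = lights + config.opto_inhibition_onset
            idx = np.searchsorted(lo, st, side="right") - 1
            idx = np.clip(idx, 0, len(lo) - 1)
            in_win = (st >= lo[idx]) & (st < lo[idx] + config.opto_inhibition_duration)
            drop = in_win & (rng.random(len(st)) < config.opto_inhibition_strength)
            st = st[~drop]
        if excited and len(lights):
            counts = rng.poisson(config.opto_spikes_per_pulse, len(lights))
            total = int(counts.sum())
            if total:
                evoked = (
                    np.repeat(lights, counts)
                    + latency
                    + config.opto_latency_jitter * rng.standard_normal(total)
                )
                st = np.concatenate([st, evoked])
        st = np.sort(st[(st >= 0.0) & (st < T)])

        units.append(
            UnitRecord(
                unit_id=f"{animal_id}_u{i:03d}",
                animal_id=animal_id,
                genotype="WT",
                depth_um=depth,
                spike_times=st,
                waveform=wf,
                fs=config.waveform_fs,
                truth={
                    "baseline_hz": lam,
                    "cell_class": cell_class,
                    "opto_excited": bool(excited),
                    "opto_inhibited": bool(inhibited),
                    "opto_latency_s": latency if excited else None,
                },
            )
        )
    return units, log


# ---------------------------------------------------------------------------
# paired random sounds (adaptation probe)


def generate_sound_pairs(
    config: SimConfig,
    ipis: tuple[float, ...] = (0.1, 0.2, 0.4, 0.7, 1.0),
    n_pairs_per_ipi: int = 60,
    pair_gap: float = 4.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[EventLog, np.ndarray, np.ndarray]:
    """Passive paired-sound stimulus log: pairs of random sounds at the
    requested inter-pulse intervals, pairs separated by ``pair_gap`` so the
    first sound of each pair is fully recovered.  Returns the event log,
    the first-sound times and the per-pair IPI labels (pairs are
    interleaved across IPIs)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = np.tile(np.asarray(ipis, dtype=float), n_pairs_per_ipi)
    labels = rng.permutation(labels)
    first = pair_gap + np.cumsum(np.asarray([0.0] + [pair_gap + i for i in labels[:-1]]))
    times = np.sort(np.concatenate([first, first + labels]))
    T = float(times[-1] + pair_gap)
    log = EventLog(
        times,
        np.full(len(times), "sound_random", dtype="U12"),
        np.full(len(times), config.sound_duration),
        T,
    )
    return log, first, labels
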