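"""Inclusion/exclusion rules for sounds and lever presses.

Two confounds motivate these rules: sensory adaptation (sounds arriving
shortly after another sound respond less) and behavioral state (random
sounds falling outside lever-pressing bouts sample a quieter state).
A refractory gap against the previous sound of *any* type handles the
first; the random-sound selection rule handles the second.

Refractory gaps are always computed against the full physical stimulus
history, including sounds that other rules later discard: adaptation
depends on what the ear heard, not on analysis choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import EventLog

RANDOM_RULES = ("preceded_by_self", "pre_press_window", "lever_held")


@dataclass
class SelectionConfig:
    refractory: float = 1.0  # s, minimum onset-to-onset gap to the previous sound
    random_rule: str = "preceded_by_self"
    pre_press_window: float = 1.0  # s, for rule `pre_press_window`
    block_size: int = 300  # self sounds per block
    block_refractory: float = 0.5  # s, refractory used inside block analyses
    min_session_self: int = 400  # below this the session is excluded
    min_block_events: int = 20  # minimum retained sounds per class per block
    preparatory_gap: float = 2.0  # s, silence required before a press

    def __post_init__(self) -> None:
        if self.refractory < 0 or self.block_refractory < 0:
            raise ValueError("refractory gaps must be >= 0")
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        if self.random_rule not in RANDOM_RULES:
            raise ValueError(
                f"unknown random_rule {self.random_rule!r}; expected one of {RANDOM_RULES}"
            )


def _refractory_ok(times: np.ndarray, refractory: float) -> np.ndarray:
    """True where the gap to the immediately preceding sound (any type) is
    at least ``refractory``; a sound with no predecessor passes vacuously."""
    gaps = np.diff(times, prepend=-np.inf)
    return gaps >= refractory


def _random_rule_mask(log: EventLog, times: np.ndarray, is_self: np.ndarray, cfg: SelectionConfig) -> np.ndarray:
    """Behavioral-state mask over the sound stream (only meaningful where
    ``~is_self``)."""
    if cfg.random_rule == "preceded_by_self":
        prev_is_self = np.concatenate(([False], is_self[:-1]))
        return prev_is_self
    if cfg.random_rule == "pre_press_window":
        presses = log.of_type("press")
        if len(presses) == 0:
            return np.zeros(len(times), dtype=bool)
        nxt = np.searchsorted(presses, times, side="right")  # first press strictly after
        has_next = nxt < len(presses)
        gap = np.where(has_next, presses[np.minimum(nxt, len(presses) - 1)] - times, np.inf)
        return has_next & (gap <= cfg.pre_press_window)
    # lever_held: a press has occurred and its release has not
    presses = log.of_type("press")
    releases = log.of_type("release")
    if len(presses) == 0:
        return np.zeros(len(times), dtype=bool)
    i_press = np.searchsorted(presses, times, side="right") - 1
    held = i_press >= 0
    last_press = presses[np.maximum(i_press, 0)]
    if len(releases) == 0:
        return held
    # release that terminates that press: first release strictly after it
    j_rel = np.searchsorted(releases, last_press, side="right")
    has_rel = j_rel < len(releases)
    rel_t = np.where(has_rel, releases[np.minimum(j_rel, len(releases) - 1)], np.inf)
    return held & (times < rel_t)


def select_sounds(log: EventLog, cfg: SelectionConfig, refractory: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
    """Retained (self_times, random_times) after the refractory gap and the
    configured random-sound behavioral-state rule."""
    times, is_self = log.sounds()
    if len(times) == 0:
        return np.empty(0), np.empty(0)
    refractory = cfg.refractory if refractory is None else refractory
    ok = _refractory_ok(times, refractory)
    rule = _random_rule_mask(log, times, is_self, cfg)
    keep_self = is_self & ok
    keep_random = ~is_self & ok & rule
    return times[keep_self], times[keep_random]


@dataclass
class BlockSplit:
    """Early/late self-sound blocks with their retained sounds; ``excluded``
    marks sessions failing the count criteria."""

    excluded: bool
    reason: str
    early_self: np.ndarray
    late_self: np.ndarray
    early_random: np.ndarray
    late_random: np.ndarray


def _empty_split(reason: str) -> BlockSplit:
    e = np.empty(0)
    return BlockSplit(True, reason, e, e, e, e)


def split_blocks(log: EventLog, cfg: SelectionConfig) -> BlockSplit:
    """Split the session into early/late blocks of self sounds.

    Blocks are defined on the ordinal sequence of *all* self sounds: the
    first ``block_size`` are the early block and the subsequent
    ``block_size`` (or the remainder) the late block.  Random sounds belong
    to the block whose time span (first to last self sound, half-open on
    the right) contains them.  Retention inside blocks uses
    ``block_refractory`` plus the configured random rule.  Sessions with
    fewer than ``min_session_self`` self sounds in total, or fewer than
    ``min_block_events`` retained self or random sounds in either block,
    are excluded.
    """
    times, is_self = log.sounds()
    self_times = times[is_self]
    n_self = len(self_times)
    if n_self < cfg.min_session_self:
        return _empty_split(f"only {n_self} self sounds (< {cfg.min_session_self})")

    b = cfg.block_size
    early_all = self_times[:b]
    late_all = self_times[b : 2 * b]

    ok = _refractory_ok(times, cfg.block_refractory)
    rule = _random_rule_mask(log, times, is_self, cfg)
    kept_self = times[is_self & ok]
    kept_random = times[~is_self & ok & rule]

    def in_span(vals: np.ndarray, span: np.ndarray) -> np.ndarray:
        if len(span) == 0:
            return vals[:0]
        return vals[(vals >= span[0]) & (vals < span[-1])]

    early_self = kept_self[(kept_self >= early_all[0]) & (kept_self <= early_all[-1])]
    late_self = kept_self[(kept_self >= late_all[0]) & (kept_self <= late_all[-1])]
    early_random = in_span(kept_random, early_all)
    late_random = in_span(kept_random, late_all)

    for name, arr in (
        ("early self", early_self),
        ("late self", late_self),
        ("early random", early_random),
        ("late random", late_random),
    ):
        if len(arr) < cfg.min_block_events:
            return _empty_split(f"{len(arr)} retained {name} sounds (< {cfg.min_block_events})")
    return BlockSplit(False, "", early_self, late_self, early_random, late_random)


def select_preparatory_presses(log: EventLog, cfg: SelectionConfig) -> np.ndarray:
    """Presses preceded by at least ``preparatory_gap`` of silence (no sound
    of either type); presses with no prior sound are retained."""
    presses = log.of_type("press")
    if len(presses) == 0:
        return presses
    sounds, _ = log.sounds()
    if len(sounds) == 0:
        return presses
    # last sound strictly before each press (the press's own sound is
    # simultaneous, not prior)
    idx = np.searchsorted(sounds, presses, side="left") - 1
    has_prev = idx >= 0
    gap = np.where(has_prev, presses - sounds[np.maximum(idx, 0)], np.inf)
    return presses[gap >= cfg.preparatory_gap]


def selection_table(log: EventLog, cfg: SelectionConfig) -> pd.DataFrame:
    """Audit table: one row per sound with its retention decision."""
    times, is_self = log.sounds()
    ok = _refractory_ok(times, cfg.refractory)
    rule = _random_rule_mask(log, times, is_self, cfg)
    retained = np.where(is_self, ok, ok & rule)
    reasons = []
    for i in range(len(times)):
        if retained[i]:
            reasons.append("")
        elif not ok[i]:
            reasons.append(f"gap < {cfg.refractory} s")
        else:
            reasons.append(f"failed {cfg.random_rule}")
    return pd.DataFrame(
        {
            "time_s": times,
            "type": np.where(is_self, "sound_self", "sound_random"),
            "retained": retained,
            "reason": reasons,
        }
    )
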