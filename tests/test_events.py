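"""Event-selection rules, checked against an independent brute-force
rule interpreter on small random logs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfsound.events import (
    SelectionConfig,
    select_preparatory_presses,
    select_sounds,
    selection_table,
    split_blocks,
)
from selfsound.types import EventLog

from conftest import make_log


# ---------------------------------------------------------------------------
# brute-force oracle: literal per-event application of the stated rules


def brute_force_select(log: EventLog, cfg: SelectionConfig):
    times, is_self = log.sounds()
    presses = sorted(log.of_type("press"))
    releases = sorted(log.of_type("release"))
    kept_self, kept_random = [], []
    for i, (t, s) in enumerate(zip(times, is_self)):
        gap_ok = i == 0 or (t - times[i - 1]) >= cfg.refractory
        if not gap_ok:
            continue
        if s:
            kept_self.append(t)
            continue
        if cfg.random_rule == "preceded_by_self":
            ok = i > 0 and is_self[i - 1]
        elif cfg.random_rule == "pre_press_window":
            ok = any(0 < p - t <= cfg.pre_press_window for p in presses)
        else:  # lever_held
            prior = [p for p in presses if p <= t]
            if not prior:
                ok = False
            else:
                p = prior[-1]
                later = [r for r in releases if r > p]
                ok = (not later) or (later[0] > t)
        if ok:
            kept_random.append(t)
    return np.array(kept_self), np.array(kept_random)


def test_hand_traced_example():
    spec = [(1.0, "R"), (6.5, "R"), (7.0, "S"), (7.6, "S"), (9.0, "R"), (9.5, "S"),
            (12.0, "R"), (13.5, "R"), (15.0, "S")]
    log = make_log(spec)
    s, r = select_sounds(log, SelectionConfig())
    assert list(s) == [15.0]
    assert list(r) == [9.0, 12.0]


def test_empty_log():
    s, r = select_sounds(EventLog.empty(), SelectionConfig())
    assert len(s) == 0 and len(r) == 0


def test_single_self_sound_kept():
    log = make_log([(5.0, "S")])
    s, r = select_sounds(log, SelectionConfig())
    assert list(s) == [5.0]


def test_unknown_rule_rejected():
    with pytest.raises(ValueError):
        SelectionConfig(random_rule="nope")


@st.composite
def small_logs(draw):
    n = draw(st.integers(0, 20))
    times = sorted(
        draw(st.lists(st.floats(0.0, 60.0, allow_nan=False), min_size=n, max_size=n))
    )
    kinds = draw(st.lists(st.sampled_from(["S", "R"]), min_size=n, max_size=n))
    return list(zip(times, kinds))


@settings(max_examples=200, deadline=None)
@given(spec=small_logs(), rule=st.sampled_from(["preceded_by_self", "pre_press_window", "lever_held"]),
       refractory=st.sampled_from([0.0, 0.5, 1.0, 2.0]))
def test_matches_brute_force_oracle(spec, rule, refractory):
    log = make_log(spec)
    cfg = SelectionConfig(refractory=refractory, random_rule=rule)
    s, r = select_sounds(log, cfg)
    bs, br = brute_force_select(log, cfg)
    assert np.array_equal(s, bs)
    assert np.array_equal(r, br)


@settings(max_examples=100, deadline=None)
@given(spec=small_logs())
def test_refractory_monotonicity(spec):
    """Raising the refractory gap never adds sounds to the retained set."""
    log = make_log(spec)
    prev_s = prev_r = None
    for refractory in (0.0, 0.5, 1.0, 2.0, 5.0):
        s, r = select_sounds(log, SelectionConfig(refractory=refractory))
        if prev_s is not None:
            assert set(s) <= set(prev_s)
            assert set(r) <= set(prev_r)
        prev_s, prev_r = s, r


def test_outputs_are_subsets_of_inputs():
    spec = [(float(t), k) for t, k in zip(range(0, 40, 2), "SRSRSRSRSRSRSRSRSRSR")]
    log = make_log(spec)
    s, r = select_sounds(log, SelectionConfig())
    sounds, _ = log.sounds()
    assert set(s) | set(r) <= set(sounds)


# ---------------------------------------------------------------------------
# blocks


def _alternating_log(n_self, self_gap=6.0):
    """Self sounds every `self_gap` s with a random sound between each pair,
    so both classes survive the refractory and preceded-by-self rules."""
    spec = []
    for i in range(n_self):
        t = 10.0 + i * self_gap
        spec.append((t, "S"))
        spec.append((t + self_gap / 2.0, "R"))
    return make_log(spec)


def test_blocks_ordinal_definition():
    log = _alternating_log(700)
    split = split_blocks(log, SelectionConfig())
    assert not split.excluded
    all_self = log.of_type("sound_self")
    assert split.early_self.max() <= all_self[299]
    assert split.late_self.min() >= all_self[300]
    assert split.late_self.max() <= all_self[599]
    # random sounds fall in the span of their block
    assert split.early_random.max() < all_self[299]
    assert split.late_random.min() >= all_self[300]


def test_short_sessions_excluded():
    assert split_blocks(_alternating_log(350), SelectionConfig()).excluded
    assert split_blocks(EventLog.empty(), SelectionConfig()).excluded


def test_late_block_takes_remaining_when_under_600():
    log = _alternating_log(450)
    split = split_blocks(log, SelectionConfig())
    assert not split.excluded
    assert len(split.late_self) <= 150


# ---------------------------------------------------------------------------
# preparatory presses


def test_preparatory_press_gap_rule():
    base = [(8.5, "R")]
    log = make_log(base + [(10.0, "S")])
    assert 10.0 not in select_preparatory_presses(log, SelectionConfig())
    log2 = make_log([(7.9, "R"), (10.0, "S")])
    assert 10.0 in select_preparatory_presses(log2, SelectionConfig())
    log3 = make_log([(10.0, "S")])
    assert 10.0 in select_preparatory_presses(log3, SelectionConfig())


def test_selection_table_audit():
    log = make_log([(1.0, "R"), (6.0, "S"), (6.2, "R")])
    table = selection_table(log, SelectionConfig())
    assert len(table) == 3
    assert not table.retained.iloc[0]  # no predecessor -> fails preceded_by_self
    assert table.retained.iloc[1]
    assert not table.retained.iloc[2]  # 0.2 s gap
    assert "gap" in table.reason.iloc[2]
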