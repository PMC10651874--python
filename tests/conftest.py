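import numpy as np
import pytest

from selfsound.types import EventLog, sort_events


def make_log(sound_spec, session_duration=None, extra=()):
    """Build an EventLog from [(time, 'S'|'R'), ...] plus optional extra
    (time, type, duration) events; presses are added for every self sound."""
    times, types, durs = [], [], []
    for t, kind in sound_spec:
        if kind == "S":
            times += [t, t]
            types += ["press", "sound_self"]
            durs += [0.2, 0.1]
        else:
            times.append(t)
            types.append("sound_random")
            durs.append(0.1)
    for t, ty, d in extra:
        times.append(t)
        types.append(ty)
        durs.append(d)
    if session_duration is None:
        session_duration = (max(times) + 1.0) if times else 0.0
    ti, ty, du = sort_events(times, types, durs)
    return EventLog(ti, ty, du, session_duration)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
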