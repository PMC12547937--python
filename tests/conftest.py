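import numpy as np
import pytest

from ecphys.ephys import PulseProtocol
from ecphys.traces import CapacitanceRecording, Pulse


@pytest.fixture(scope="session")
def pool10():
    return PulseProtocol.pool10()


def make_capacitance_trace(protocol, cm_fn, cm0=10.8, sample_interval=10.0,
                           pre_dur=1000.0, peak_current=-150.0, cell_id="fix"):
    """Build a CapacitanceRecording whose Cm is ``cm_fn(times)``.

    Sample times cover the pre-train window, interpulse gaps, and the
    post-train window; none fall inside a pulse.
    """
    pulses = protocol.pulses
    t0 = pulses[0].start
    segments = [(t0 - pre_dur, t0)]
    for p, q in zip(pulses, pulses[1:]):
        segments.append((p.end, q.start))
    segments.append((pulses[-1].end, pulses[-1].end + protocol.post_train_window * 1000.0))
    times = np.concatenate([np.arange(a, b, sample_interval) for a, b in segments])
    cm = cm_fn(times)
    annotated = tuple(
        Pulse(p.start, p.duration, p.v_from, p.v_to, peak_current=peak_current)
        for p in pulses
    )
    return CapacitanceRecording(cell_id=cell_id, time=times, cm=cm, pulses=annotated, cm0=cm0)


def staircase_cm(protocol, step_per_pulse, cm0=10.8, only_short=False):
    """Cm that steps up by a fixed amount at the end of each (short) pulse."""
    def fn(times):
        cm = np.full_like(times, cm0 * 1000.0)
        for p in protocol.pulses:
            if only_short and p.duration > protocol.short_pulse_max_ms:
                continue
            cm[times >= p.end] += step_per_pulse
        return cm
    return fn
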