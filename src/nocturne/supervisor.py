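"""The data-collection supervisor as a pure, replayable state machine.

Overnight collection from three Bluetooth wearables fails in mundane ways —
devices slip out of range, packets pause — and a child's parents should not
have to babysit it.  The supervisor automates the session:

* ``START`` — find and connect the devices, send activation commands; once
  activation is acknowledged, collection begins.
* ``NORMAL`` — streaming; state re-evaluated every 3 s, and collected data
  is uploaded continuously so an eventual failure cannot lose the night.
* ``DELAY`` — entered on any abnormal event; re-evaluated every 1 s.  A
  cleared fault returns to ``NORMAL``; a delay maintained for more than
  10 minutes escalates.
* ``PROBLEM`` — attempt recovery by re-initiating the device connection;
  success returns to ``NORMAL``, failure uploads what was collected and
  terminates.
* ``END`` — the user stopped collection: close connections, upload, done.
* ``TERMINATED`` — absorbing failure-exit state (distinct from the ordinary
  ``END``).

The machine is finite and total over the documented (state, event) pairs in
:data:`TRANSITIONS`; undocumented pairs raise :class:`ProtocolError`, never
silently self-loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "State",
    "EventKind",
    "SupervisorState",
    "DeviceEvent",
    "SupervisorLog",
    "ProtocolError",
    "TRANSITIONS",
    "DELAY_ESCALATION_SECONDS",
    "step",
    "run",
]

DELAY_ESCALATION_SECONDS = 600.0   # "over 10 min" — strictly greater
NORMAL_TICK_SECONDS = 3.0
DELAY_TICK_SECONDS = 1.0


class State(str, Enum):
    START = "START"
    NORMAL = "NORMAL"
    END = "END"
    DELAY = "DELAY"
    PROBLEM = "PROBLEM"
    TERMINATED = "TERMINATED"


class EventKind(str, Enum):
    DEVICES_CONNECTED = "devices_connected"
    ACTIVATION_ACK = "activation_ack"
    USER_STOP = "user_stop"
    FAULT = "fault"
    FAULT_CLEARED = "fault_cleared"
    REINIT_SUCCESS = "reinit_success"
    REINIT_FAILURE = "reinit_failure"
    TICK = "tick"


@dataclass(frozen=True)
class SupervisorState:
    value: State
    entered_at: float


@dataclass(frozen=True)
class DeviceEvent:
    time: float
    kind: EventKind


@dataclass
class SupervisorLog:
    records: list[tuple[float, State, EventKind, State]] = field(default_factory=list)
    uploads: list[float] = field(default_factory=list)   # data-upload markers

    @property
    def final_state(self) -> State:
        return self.records[-1][3] if self.records else State.START


class ProtocolError(RuntimeError):
    """An event arrived in a state where it is undefined."""


#: the documented transition table.  DELAY+tick and PROBLEM+reinit_failure
#: carry extra semantics (escalation clock, upload-then-terminate) handled in
#: :func:`step`/:func:`run`; the *target states* here are the defaults.
TRANSITIONS: dict[tuple[State, EventKind], State] = {
    (State.START, EventKind.DEVICES_CONNECTED): State.START,
    (State.START, EventKind.ACTIVATION_ACK): State.NORMAL,
    (State.START, EventKind.USER_STOP): State.END,
    (State.START, EventKind.TICK): State.START,
    (State.NORMAL, EventKind.TICK): State.NORMAL,
    (State.NORMAL, EventKind.FAULT): State.DELAY,
    (State.NORMAL, EventKind.USER_STOP): State.END,
    (State.DELAY, EventKind.TICK): State.DELAY,          # escalates after >600 s
    (State.DELAY, EventKind.FAULT): State.DELAY,
    (State.DELAY, EventKind.FAULT_CLEARED): State.NORMAL,
    (State.DELAY, EventKind.USER_STOP): State.END,
    (State.PROBLEM, EventKind.TICK): State.PROBLEM,
    (State.PROBLEM, EventKind.REINIT_SUCCESS): State.NORMAL,
    (State.PROBLEM, EventKind.REINIT_FAILURE): State.TERMINATED,
    (State.END, EventKind.TICK): State.END,
    (State.TERMINATED, EventKind.TICK): State.TERMINATED,
}


def step(state: SupervisorState, event: DeviceEvent) -> SupervisorState:
    """One deterministic transition; undefined pairs raise ProtocolError.

    A tick in ``DELAY`` escalates to ``PROBLEM`` when the delay has been
    maintained strictly longer than 10 minutes.
    """
    key = (state.value, event.kind)
    if key not in TRANSITIONS:
        raise ProtocolError(
            f"event {event.kind.value!r} is undefined in state {state.value.value!r}"
        )
    target = TRANSITIONS[key]
    if (
        state.value is State.DELAY
        and event.kind is EventKind.TICK
        and event.time - state.entered_at > DELAY_ESCALATION_SECONDS
    ):
        target = State.PROBLEM
    if target is state.value:
        return state  # self-loop keeps the original entry time
    return SupervisorState(value=target, entered_at=event.time)


def run(trace: list[DeviceEvent]) -> SupervisorLog:
    """Replay a time-ordered event trace from ``START``.

    Upload markers are recorded on every ``NORMAL`` tick (continuous
    streaming), at ``END``, and before ``TERMINATED`` — so the un-uploaded
    span at any exit is bounded by one normal tick interval.
    """
    times = [e.time for e in trace]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("trace events must be time-ordered")
    log = SupervisorLog()
    state = SupervisorState(State.START, trace[0].time if trace else 0.0)
    for event in trace:
        new = step(state, event)
        log.records.append((event.time, state.value, event.kind, new.value))
        if state.value is State.NORMAL and event.kind is EventKind.TICK:
            log.uploads.append(event.time)
        if new.value in (State.END, State.TERMINATED) and state.value is not new.value:
            log.uploads.append(event.time)  # terminal upload before exit
        state = new
    return log
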