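"""Replay device-event traces through the data-collection supervisor.

The supervisor automates an overnight Bluetooth collection session: faults
move it to DELAY, a delay maintained over 10 minutes escalates to PROBLEM,
and a failed recovery uploads what was collected before terminating, so a
night is never silently lost.
"""

from nocturne.supervisor import DeviceEvent, EventKind, run

# a night where a fault clears after five minutes
healthy = [
    DeviceEvent(0.0, EventKind.DEVICES_CONNECTED),
    DeviceEvent(1.0, EventKind.ACTIVATION_ACK),
    DeviceEvent(3.0, EventKind.TICK),
    DeviceEvent(100.0, EventKind.FAULT),
    DeviceEvent(400.0, EventKind.FAULT_CLEARED),
    DeviceEvent(28_800.0, EventKind.USER_STOP),
]
log = run(healthy)
print("recovered-fault trace:")
for time, src, event, dst in log.records:
    if src != dst:
        print(f"  t={time:8.0f}s  {src.value:8s} --{event.value}--> {dst.value}")
print(f"  final state {log.final_state.value}, {len(log.uploads)} upload markers")

# a fault that never clears: >600 s in DELAY escalates, recovery fails
failing = [DeviceEvent(0.0, EventKind.ACTIVATION_ACK),
           DeviceEvent(10.0, EventKind.FAULT)]
failing += [DeviceEvent(10.0 + k, EventKind.TICK) for k in range(1, 605)]
failing += [DeviceEvent(620.0, EventKind.REINIT_FAILURE)]
log = run(failing)
print("\nunrecoverable-fault trace:")
for time, src, event, dst in log.records:
    if src != dst:
        print(f"  t={time:8.0f}s  {src.value:8s} --{event.value}--> {dst.value}")
print(f"  final state {log.final_state.value}; data uploaded before "
      f"termination at t={log.uploads[-1]:.0f}s")
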