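"""Generate one synthetic monitored night and inspect its planted ground truth.

A night carries pelvic bioimpedance (falls as the bladder fills), a
moisture-sensor resistance (drops at the wetting moment), heartbeat times,
and 6-axis ankle motion — plus the ground truth the generator planted.
"""

import nocturne as nc

config = nc.SimConfig(seed=1, sleep_duration=2 * 3600.0, ne_fraction=1.0)
night = nc.simulate_night(config, night_index=0)

print(f"night {night.night_id}: enuretic={night.is_ne_day}")
print(f"  wetting moment (planted): {night.true_ne_moment:.0f} s")
print(f"  heart-rate ramp planted:  {night.hr_ramp_present}")
print(f"  bioimpedance drift:       {night.bi_drift_slope:.1f} ohm/h")
in_series = sum(e.in_series for e in night.planted_lm_events)
print(f"  planted limb movements:   {len(night.planted_lm_events)} "
      f"({in_series} in periodic series)")
for name, ch in sorted(night.channels.items()):
    print(f"  channel {name:8s}: {ch.samples.shape} at {ch.rate or 'event'} Hz")

# the moisture channel recovers the wetting moment independently
detected = nc.detect_wet_moment(night.channel("moisture"))
print(f"  wetting moment (detected from moisture): {detected:.0f} s "
      f"(error {abs(detected - night.true_ne_moment):.3f} s)")
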