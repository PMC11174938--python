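"""Probability labels, the alarm rule, and the four rule-based estimators.

Each window gets a linear-in-time wetting probability (1.0 at the wetting
moment on enuretic nights; 0.70 at the end of dry nights); the alarm rule
fires strictly above 0.85.  Rule estimators AND per-modality conditions
over 10-minute blocks, so their positive sets nest.
"""

import nocturne as nc
from nocturne import estimators, labels

config = nc.SimConfig(seed=4, n_nights=6, sleep_duration=3600.0,
                      hr_ramp_probability=1.0)
nights = nc.simulate.simulate_balanced_cohort(config)
frames = []
for night in nights:
    grid = nc.resample_and_align(night)
    frame = nc.extract_features(night, grid)
    curve = labels.probability_curve(night, grid)
    frames.append(frame)
    kind = "enuretic" if night.is_ne_day else "dry"
    alarms = labels.alarm_windows(curve.p)
    first = f"first alarm at {curve.window_ends[alarms[0]]:.0f} s" if alarms.size else "no alarm"
    print(f"{night.night_id} ({kind:8s}): max target p={curve.p.max():.2f}, {first}")

theta = estimators.calibrate_theta_bid(frames)
print(f"\ncalibrated bladder threshold theta_bid = {theta:.1f} ohm")
rule_config = estimators.RuleConfig(theta_bid=theta)
for name in estimators.RULE_ESTIMATORS:
    positives = sum(
        bool(d.positive)
        for frame in frames
        for d in estimators.rule_estimate_night(name, frame, rule_config)
    )
    print(f"  {name:6s}: {positives:4d} positive blocks")
print("more conditions -> fewer positives: RE_ALL <= RE_BH/RE_BL <= RE_B")
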