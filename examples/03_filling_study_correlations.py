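"""Correlate bioimpedance features with injected bladder volume.

Emulates an in-hospital saline-filling (urodynamic) study: the bladder is
filled at a known rate while pelvic bioimpedance is recorded.  The designed
cumulative feature BID tracks volume more faithfully than raw BI, whose
window means are corrupted by movement artifacts.
"""

import nocturne as nc
from nocturne import analysis

config = nc.SimConfig(seed=3)
sessions = [
    nc.simulate_uds_session(config, capacity=150.0 + 5 * i, session_index=i)
    for i in range(30)
]
table = analysis.uds_feature_correlations(sessions)
print(table.round(3).to_string(index=False))

per = table[table.scope == "per_session_mean"].set_index("feature")
print(f"\n|r| with injected volume: BID {per.loc['BID', 'r_abs']:.3f} "
      f"vs raw BI {per.loc['BI_raw', 'r_abs']:.3f}")
print("BID's correlation is negative (impedance falls as volume rises) and "
      "stronger than raw BI's, because artifact steps are clipped out of it.")
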