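"""Simulate a treadmill session, recover speed from the two sensors, and
segment rest/run bouts with the fuzzy threshold."""

import numpy as np

from caimnet import (
    SimConfig,
    bout_kinematics,
    compute_velocity,
    segment_bouts,
    session_qc,
    simulate_sensors,
    simulate_speed,
)

cfg = SimConfig(seed=7)
speed, planted = simulate_speed(cfg)

# round-trip through the two-sensor geometry (sensors 78 degrees apart)
theta = np.deg2rad(78.0)
L, R = simulate_sensors(speed, theta)
recovered = compute_velocity(L, R, theta)
print(f"sensor round-trip max error: {np.abs(recovered.v - speed.v).max():.2e} cm/s")

seg = segment_bouts(recovered)
qc = session_qc(seg)
kin = bout_kinematics(recovered, seg)
print(f"planted run bouts: {len(planted)}, recovered: {kin['n_bouts']}")
print(f"time in rest {qc.time_in_rest_s:.0f} s / run {qc.time_in_run_s:.0f} s, "
      f"eligible for locomotion analysis: {qc.eligible_for_locomotion_analysis}")
print(f"mean bout duration {kin['mean_bout_duration_s']:.1f} s, "
      f"mean bout speed {kin['mean_bout_speed']:.1f} cm/s")
# a session qualifies when it holds >= 60 s of each state and >= 5 run bouts
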