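"""Generate synthetic finger-to-nose keypoint trajectories.

Builds one asymptomatic and one strongly bradykinetic performance of the
finger-to-nose task and compares their basic movement statistics.  The
severity score counts how many symptom mechanisms (sequence effect,
amplitude decrement, pauses, tremor) are active.
"""

import numpy as np

from pdmotion import SimConfig, simulate_task_trajectories
from pdmotion import io as pio

healthy = SimConfig(seed=1)
symptomatic = SimConfig(
    freq_slope_hz_per_s=-0.05,    # movement slows by 0.05 Hz every second
    amp_decrement_per_cycle=0.05, # each repetition shrinks by 5%
    pause_dwell_s=0.4,            # 0.4 s dwell at each movement endpoint
    tremor_amp=0.02,              # 2 cm-scale 5 Hz tremor
    seed=1,
)

for name, cfg in (("healthy", healthy), ("symptomatic", symptomatic)):
    traj = simulate_task_trajectories(cfg)
    wrist = traj.trajectories["wrist"] - traj.trajectories["hip"]
    reach = np.linalg.norm(wrist, axis=1)
    print(f"{name}: {traj.n_frames} frames at {traj.fps:.0f} fps, "
          f"severity score {traj.sma_score}, "
          f"wrist reach range {reach.min():.3f}-{reach.max():.3f} units")

pio.write_trajectories([simulate_task_trajectories(healthy)], "scratch_example_trajectory.csv")
print("wrote one record to scratch_example_trajectory.csv "
      "(long format: frame, keypoint, x, y, z)")
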