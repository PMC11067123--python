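"""Build the enumerated kinematic channels for both clinical tasks.

Each video becomes a fixed set of max-abs-scaled scalar signals: keypoint
position norms in the hip-origin frame and three-point joint angles, with
velocity/acceleration forward differences and Gaussian-filtered variants.
"""

from pdmotion import SimConfig, simulate_task_trajectories, build_channel_set
from pdmotion.kinematics import ChannelKey

for task in ("FTN", "HPS"):
    traj = simulate_task_trajectories(SimConfig(task=task, seed=2))
    cs = build_channel_set(traj)
    print(f"{task}: {len(cs)} channels total, "
          f"{len(cs.keys_for(filter_width_s=0.0))} unfiltered, "
          f"{len(cs.keys_for('position', 0.0))} positional signals")

cs = build_channel_set(simulate_task_trajectories(SimConfig(seed=2)))
elbow = cs[ChannelKey("theta_e", "position", 0.1)]
print(f"example channel 'theta_e.position.0.1' (elbow angle, 0.1 s filter): "
      f"{len(elbow)} samples in [{elbow.min():.2f}, {elbow.max():.2f}] "
      f"(dimensionless after max-abs scaling)")
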