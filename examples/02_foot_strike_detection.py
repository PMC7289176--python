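"""Detect foot strikes from ankle vertical velocity and inspect step timing.

Each landing shows a peak of downward ankle velocity; the strike is placed
where that peak decays through 35% of its height.  Detected times are
compared against the generator's true contact schedule.
"""

import numpy as np

from gaitvid import FeatureConfig, GaitSimParams, simulate_bout, step_times
from gaitvid.features import detect_events
from gaitvid.preprocess import filter_trajectory, threshold_and_impute

bout, truth = simulate_bout(GaitSimParams(seed=4, cadence_spm=96.0, pixel_noise_sd=1.0))
traj = filter_trajectory(threshold_and_impute(bout))
events = detect_events(traj, FeatureConfig())

print("left strikes  (s):", np.round(events.left, 2))
print("true contacts (s):", np.round(truth.contact_times_left, 2))
err_frames = 30.0 * np.max(np.abs(events.left - truth.contact_times_left))
print(f"worst left-foot timing error: {err_frames:.1f} frames")

seq = step_times(events)
print(f"\n{events.n_strikes} merged strikes -> {len(seq.step_times)} step times, "
      f"mean {seq.step_times.mean():.3f} s")
print(f"time on left foot {seq.per_foot_time['left']:.2f} s, "
      f"right {seq.per_foot_time['right']:.2f} s")
print("\nStrikes within a frame or two of truth mean the 35% crossing rule is")
print("locating ground contact, not just velocity peaks.")
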