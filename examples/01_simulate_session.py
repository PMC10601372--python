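"""Simulate one self-initiated lever-pull session and inspect its trials.

Builds a 5-minute synthetic session on the 30 Hz imaging clock: a lever
trace with threshold-crossing pulls, the derived trial table (success =
2.5 mm threshold held 0.6 s), and the 20-variable behavior matrix.
"""

import numpy as np

import levercode as lc

config = lc.TaskConfig()
bundle = lc.simulate_behavior(config, duration=300.0, skill=0.8, seed=1)

trials = bundle.trials
n_success = (trials["outcome"] == "success").sum()
print(f"frames: {bundle.n_frames} at {bundle.frame_rate:g} Hz")
print(f"trials: {len(trials)} ({n_success} rewarded, "
      f"success rate {n_success / len(trials):.2f})")
print(trials.head())

lever = bundle.behavior.column("lever_pos")
print(f"lever range: {lever.min():.2f} .. {lever.max():.2f} mm "
      f"(travel limit {config.travel_limit} mm)")
print("behavior columns:", ", ".join(lc.CANONICAL_COLUMNS))

# The success rate tracks the `skill` parameter; each rewarded trial's
# reward frame trails its command frame by the ~176 ms device delay.
d = trials.dropna(subset=["reward_frame"])
delays = (d["reward_frame"] - d["command_frame"]) / config.frame_rate
print(f"reward delay: {delays.mean() * 1e3:.0f} ms on every rewarded trial")
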