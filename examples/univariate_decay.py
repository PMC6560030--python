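"""Univariate decaying-encoding model at ROI level.

Simulates a small cohort whose ROI response at state 1 decays
geometrically (50% per repetition) and recovers the effect with the
parametric-modulator regression, then shows the reward-versus-loss
feedback contrast.
"""

import numpy as np
import pandas as pd

from futurestate.glm import (decay_modulator, reward_feedback_model,
                             univariate_decay_model)

rng = np.random.default_rng(3)
events = pd.DataFrame(
    [{"maze_id": m, "repetition": r, "state": s, "of_interest": True,
      "outcome": ("reward" if m % 2 else "loss") if s in ("FEEDBACK", "REST")
      else "none"}
     for m in range(1, 9) for r in range(1, 5)
     for s in ("S1", "FEEDBACK", "REST")])

participants = []
for _ in range(14):
    amp = np.where(events["state"] == "S1",
                   2.0 * decay_modulator(events["repetition"]), 0.0)
    amp = amp + np.where((events["state"] == "FEEDBACK")
                         & (events["outcome"] == "reward"), 0.8, 0.0)
    participants.append((amp + rng.normal(0, 0.4, len(events)), events))

effects, group = univariate_decay_model(participants, state="S1")
print(f"decay modulator values: {tuple(decay_modulator(np.arange(1, 5)).tolist())}")
print(f"group decay effect at S1: mean={group.mean:.3f}, "
      f"t({group.df})={group.t:.2f}, p={group.p:.2g}")

fb = [reward_feedback_model(a, e) for a, e in participants]
print(f"mean reward-vs-loss feedback effect: {np.mean(fb):+.3f} "
      "(positive = larger response to reward)")
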