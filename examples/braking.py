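"""Per-beat arm braking: speed drop Δv and mean deceleration ā = Δv/Δt.

Each metronome beat ends at rest, so the hand speed peaks mid-beat and decays;
the braking interval runs from the speed peak to the first zero crossing (or
the beat's end).  Sharper braking means a later peak, shorter Δt and a larger
|ā|.
"""

import numpy as np

from armbiomech import kinematics as kin
from armbiomech import synthetic as syn

config = syn.CohortConfig(subject_amplitude_sd=0.0)
athlete = syn.SubjectProfile("A01", group="A", height=1.77)
script = syn.build_combination_script(1)
trial = syn.generate_motion_trial(athlete, script, config, np.random.default_rng(2))

speed = kin.linear_speed(trial.right)
records = kin.braking_metrics(speed, trial.boundaries)
print("beat  v_peak   Δv      Δt      ā")
for r in records:
    print(f"{r.beat_index:3d}  {r.v_peak:6.3f}  {r.delta_v:6.3f}  "
          f"{r.delta_t:6.3f}  {r.a_bar:8.3f}")
mean_abar = np.mean([r.a_bar for r in records])
print(f"mean ā over the combination: {mean_abar:.3f} m/s² "
      "(negative = deceleration; larger magnitude = stronger braking)")
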