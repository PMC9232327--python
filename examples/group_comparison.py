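"""Two-group comparison: amplitude difference, t-test, correlation panel.

Generates the full default cohort and compares the groups' hand-averaged 3D
track lengths (combination 1), then correlates track length with mean
standardized RMS within group B.
"""

import numpy as np

from armbiomech import emg as emg_mod
from armbiomech import kinematics as kin
from armbiomech import stats
from armbiomech import synthetic as syn

bundle = syn.generate_cohort(syn.CohortConfig(seed=7))

lengths = {"A": [], "B": []}
rms_b = []
for p in bundle.profiles:
    trial = bundle.motion[(p.subject_id, 1)]
    avg = kin.hand_average(
        kin.summarize_track(trial.left, p.height, "left", p.subject_id),
        kin.summarize_track(trial.right, p.height, "right", p.subject_id),
    )
    lengths[p.group].append(avg.length_3d)
    if p.group == "B":
        mvic = bundle.mvic[p.subject_id]
        e = bundle.emg[(p.subject_id, 1)]
        rms_b.append(np.mean([
            emg_mod.standardize(emg_mod.rms(v), mvic.reference_rms[name])
            for name, v in e.channels.items()
        ]))

sa, sb, diff = stats.group_summary(lengths, metric="track_length_3d")
res = stats.independent_t_test(lengths["A"], lengths["B"])
print(f"group A: {sa.mean:.3f} ± {sa.sd:.3f} m (n={sa.n})")
print(f"group B: {sb.mean:.3f} ± {sb.sd:.3f} m (n={sb.n})")
print(f"difference (A−B): {diff:.3f} m, t = {res.t:.3f}, p = {res.p:.4f}"
      + (" *" if res.significant_05 else ""))
corr = stats.pearson_correlation(lengths["B"], rms_b, pair=("track", "rms"))
print(f"group B track length vs standardized RMS: r = {corr.r:.3f} "
      f"(p = {corr.p:.4f}, {corr.grade})")
print("A larger group-A mean reflects the configured 15% amplitude surplus; "
      "the positive correlation follows from the speed-driven EMG envelope.")
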