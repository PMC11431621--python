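"""Ensemble time-separated MI curve of a dyad, and where it peaks.

300 replicate simulations are sampled at a late, stationary time; for
each time separation tau the pairs (theta1(t*), theta0(t* - tau)) feed
the KSG estimator via 10 jackknife subsets of 250 pairs.  A true
leader-follower interaction puts the maximum at tau = T / fps (here
0.5 s, with agent 0 presumed leader on tau > 0); a non-interacting pair
gives a flat curve with no significant peak.  Run time ~10 s.
"""

import numpy as np

from tsmi import LFConfig, simulate_independent_pair, simulate_lf_dyad
from tsmi.mi import default_tau_grid, mi_curve_ensemble
from tsmi.peaks import loess, peak_significance

grid = default_tau_grid()          # 101 points on [-2.5 s, +2.5 s]

for label, make in (("leader-follower (alpha=0)", simulate_lf_dyad),
                    ("independent pair", lambda c: simulate_independent_pair(c))):
    if "independent" in label:
        reps = [make(LFConfig(sigma=0.00039, phi=0.1, n_steps=24100,
                              seed=1000 + i)) for i in range(300)]
    else:
        reps = [make(LFConfig(n_steps=24100, seed=i)) for i in range(300)]
    curve = mi_curve_ensemble(reps, grid, t_star=24000, seed=1)
    smooth = loess(curve.tau, curve.mi_mean, f=0.2, degree=2)
    tau_peak = curve.tau[int(np.argmax(smooth))]
    significant, score = peak_significance(curve, tau_peak)
    print(f"{label}:")
    print(f"  smoothed-curve maximum at tau = {tau_peak:+.2f} s, "
          f"MI = {curve.mi_mean.max():.2f} nats")
    print(f"  peak vs plateau: z = {score:.1f} -> "
          f"{'significant' if significant else 'not significant'}")
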