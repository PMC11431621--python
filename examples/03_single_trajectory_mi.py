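"""Estimate the MI curve from a single trajectory with window sampling.

Real experiments yield one record, not 300 replicates.  Sample pairs
drawn naively from consecutive frames are mutually correlated and
inflate the estimate, so the series is tiled into length-W windows and
one time point is drawn per window from a symmetric triangular density.
Small windows recover the peak but overestimate the tails; W of about
the curve's decay time (here 100 steps = 2.5 s) tracks the ensemble
curve closely.  Run time ~10 s.
"""

import numpy as np

from tsmi import LFConfig, simulate_lf_dyad
from tsmi.mi import default_tau_grid, mi_curve_single

grid = default_tau_grid()

for W in (5, 20, 100):
    # trajectory length chosen so every resample holds ~250 sample pairs,
    # keeping the KSG sample-size bias identical across W
    track = simulate_lf_dyad(LFConfig(n_steps=250 * W, seed=42))
    curve = mi_curve_single(track.theta0, track.theta1, grid, W=W,
                            n_resamples=10, dt=track.dt, seed=7)
    i_peak = int(np.nanargmax(curve.mi_mean))
    tail = np.abs(curve.tau) >= 2.0
    print(f"W = {W:3d} steps ({W / 40:5.3f} s): "
          f"peak {curve.mi_mean[i_peak]:.2f} nats at "
          f"tau = {curve.tau[i_peak]:+.2f} s, "
          f"mean tail MI = {np.nanmean(curve.mi_mean[tail]):.2f} nats")
print("the peak location is stable in W; the tail level falls towards the")
print("ensemble value as W grows past the curve's decay timescale")
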