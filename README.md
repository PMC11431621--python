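# tsmi — time-separated mutual information for leader–follower dyads

When two animals move together — two fish circling a tank, say — one of
them often *appears* to lead.  Proving that the second animal is actually
reacting to the first, rather than independently doing the same thing a
moment later, is hard: transfer entropy and causation entropy answer the
question in principle but need far more data than a thirty-minute
tracking session provides.  `tsmi` implements a lighter-weight
alternative: the **time-separated mutual information**

    MI(θ₁(t); θ₀(t−τ)),   scanned over the separation τ,

between the two animals' angular positions.  For any interaction in
which a follower tracks a leader's past state with delay T, this curve
has a local maximum at τ = T and decays monotonically as |τ − T| grows —
so a statistically significant, off-centre peak is evidence consistent
with a leader–follower interaction, and its location is the follower's
reaction timescale.  By convention τ > 0 presumes agent 0 leads; the
τ < 0 branch carries the index-swapped pairing, so mixed leadership shows
up as peaks on both sides.

The package provides, as plain Python modules with a thin `tsmi` CLI on
top:

- `tsmi.simulate` — the ring leader–follower dyad (drift Ω, noise σ,
  delay T, leadership-swap probability α), independent drift–diffusion
  pairs, free/ring Gaussian walkers, and the free walker's closed-form
  self-MI ½·ln(1 + t/τ) as an analytic oracle.
- `tsmi.mi` — KSG k-nearest-neighbour MI (variant I(1), max-norm) and MI
  curves from replicate ensembles (jackknife errors) or from a single
  trajectory (triangular window sampling), plus mirror combination.
- `tsmi.sampling` — decorrelated time-point selection: one draw per
  length-W window from a symmetric triangular density; jackknife subsets.
- `tsmi.prep` — TRex-style planar track preprocessing: polar transform,
  headings, head/tail flip repair (threshold π − 0.6), alignment angles
  with 15-s rolling means, drift/noise estimation from wrapped increments.
- `tsmi.peaks` — quadratic LOESS, per-fraction peak localisation,
  reaction-timescale extraction T̂, and a peak-significance rule.
- `tsmi.synth` — renders angular simulations into TRex-like planar CSV
  tracks with head/tail flips and missing frames, so the full pipeline
  runs without any recorded data.

See `docs/methods.md` for the model, estimator choices and limitations,
and `examples/` for short narrative scripts (one per capability).

## Worked example

Simulate the calibrated dyad (Ω = 0.0067 rad/step, σ = 0.0039 rad/step,
T = 20 steps at 40 fps), render it to planar tracks with tracking
artefacts, preprocess, and recover the reaction timescale from a single
trajectory:

```sh
python examples/04_track_pipeline.py
```

prints

```
mean alignment of leader   A01 = 2.87 rad (~pi)
mean alignment of follower A10 = 0.28 rad (~0)
peak locations across smoothing fractions: [0.5 0.5 0.5 0.5 0.5 0.5 0.5 0.5 0.5 0.5] s
reaction timescale T-hat = 0.500 s (band 0.000 s; ground truth 0.500 s)
```

The alignment angles identify who leads (the follower points at the
leader, the leader points away); the MI peak sits at the same 0.5 s for
every LOESS smoothing fraction, and averaging them recovers the
configured delay exactly.  The ensemble counterpart
(`examples/02_ensemble_mi_peak.py`) contrasts this with a non-interacting
pair, whose flat curve fails the significance rule (z ≈ 1 vs z ≈ 83):

```
leader-follower (alpha=0):
  smoothed-curve maximum at tau = +0.50 s, MI = 3.93 nats
  peak vs plateau: z = 82.9 -> significant
independent pair:
  smoothed-curve maximum at tau = +2.50 s, MI = 2.76 nats
  peak vs plateau: z = 1.1 -> not significant
```

The same analyses are available from the shell:

```sh
tsmi simulate --n-steps 25000 --seed 5 --out track.csv
tsmi mi track.csv --mode single -W 100 --out curve.csv
tsmi peak curve.csv --branch pos --out peaks.csv
```

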