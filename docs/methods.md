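# Methods

`tsmi` asks a narrow question about a pair of tracked animals: are their
trajectories consistent with one following the other after a sensory-motor
delay?  It answers it with the time-separated mutual information
MI(θ₁(t); θ₀(t−τ)) scanned over the separation τ, which for a genuine
leader–follower interaction exhibits a local maximum at the follower's
reaction delay and decays monotonically away from it.

## The dyad model

Two point agents move on a circle (angles in [0, 2π)).  Per time step:

    θ_L(t) = θ_L(t−1) + Ω + W_L(t)          W ~ N(0, σ²)
    θ_F(t) = θ_L(t−T) + W_F(t)

The leader performs a drift–diffusion; the follower re-targets the
leader's position T steps in the past, plus its own error.  With
probability α per step the leader/follower *labels* swap.  Model
assumptions worth keeping in mind:

- The follower tracks a *position*, not a velocity; after a swap the new
  follower reads the new leader's recorded history at t−T, which can
  produce a jump up to the current separation.  This is the literal
  reading of the update rule; real fish presumably blend more smoothly.
- Before the first T steps the leader history is clamped to its initial
  position (agents immobile prior to start).  The clamp applies to the
  initial transient only.
- Both agents share one noise scale σ.  A consequence used in the tests:
  the follower's per-step increments are Ω + W_L(t−T) + W_F(t) − W_F(t−1)
  with variance 3σ², so the pooled two-agent increment standard deviation
  converges to √2·σ on dyad output.  Pooled (Ω, σ) estimation is therefore
  a *consistent* recovery only for independent drift–diffusion pairs; on
  dyad data it is a calibration summary, not a round-trip inverse.
- RNG design: leader noise, follower noise, swap draws and the initial
  angle use four independent sub-streams of one seed, so changing α alone
  does not perturb the noise sequences (clean ablations).

Default parameters mirror the calibration used throughout: Ω = 0.0067
rad/step and σ = 0.0039 rad/step at 40 steps/s (values estimated from a
strongly polarized experimental pair), T = 20 steps = 0.5 s (a visual
reaction-time guess), α = 0.00021 (15 expected swaps per 30 min), initial
offset φ = 0.5 rad (0.1 rad with σ = 0.00039 for the non-interacting
control, which otherwise drifts apart too quickly to be a fair control).

## KSG mutual information

`mi.ksg_mi` implements the k-nearest-neighbour estimator (variant I(1)):
ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩ with max-norm distances in the joint
space and strictly-closer marginal counts.  Choices:

- k = 4 by default (field standard; configurable).  Estimates are in
  nats; a bits conversion is display-only.
- Exact ties make neighbour counts ill-defined, so a deterministic,
  seeded jitter of 1e-10 × data scale is always added.
- Negative small-sample estimates are returned unclipped; clipping would
  bias curve comparisons.
- Wrapped angles are treated as points on the line by default ("linear"
  mode), matching the plain application the analyses assume; a "chord"
  mode embedding θ → (cos θ, sin θ) is available.
- Sample-size bias: for the low-noise dyad the true MI (≈6 nats at the
  peak) exceeds what N ≈ 250 samples can resolve, and the estimate
  saturates near ln N.  Comparisons between curves are therefore always
  made at matched sample counts, so the saturation cancels.  This is also
  why single-trajectory runs elsewhere in the package pick trajectory
  lengths of ≈250·W steps: each windowed resample then holds ≈250 pairs,
  matching the 250-pair ensemble subsets.

An independent histogram plug-in estimator (equal-frequency bins,
Miller–Madow correction) and scikit-learn's KSG implementation serve as
oracles in the test suite only.

## MI curves and their error bars

**Ensembles** (`mi_curve_ensemble`): 300 replicates are simulated, the
pair (θ₁(t*), θ₀(t*−τ)) is collected across replicates at a late sampling
step t* = 24000 (600 s — far into the stationary regime), and 10 random
subsets of 250 pairs give a mean and standard error per τ.  The subset
index sets are drawn once per curve and reused across τ, so the curve is
smooth and peak localisation is stable.  Note these subsets overlap
(250-of-300), so the quoted errors describe subset scatter, not the
ensemble-level sampling fluctuation; they are the resolution at which the
study's comparisons are meant.

**Single trajectories** (`mi_curve_single`): the θ₁ series is tiled into
windows of W steps; each resample draws one time point per window from
the symmetric triangular density f(t) = 4(t−t_i)/W² (below the midpoint,
mirrored above), rounded to the nearest in-window index.  Pairs whose
shifted index leaves the series or lands on a masked frame are dropped;
10 independent redraws give the mean and SE.  Windowing controls the
inflation that arises when correlated consecutive samples are treated as
independent.  Two facts established numerically and worth knowing:

- the naive (every-point) estimate only *over*-estimates where the true
  dependence is modest; at separations where the true MI is large the
  sample redundancy instead biases it slightly low.  The inflation also
  needs a short record — a 2000-step naive record of the σ² = 0.1 ring
  walker is grossly inflated, a 40000-step one barely.
- no feasible W fully decorrelates the dyad's samples (its positional
  noise decorrelates over ~(π/σ)² ≈ 6.5·10⁵ steps), leaving a small
  residual inflation of ≈ +0.01–0.02 nats (≈0.5% of the curve) on the
  decaying flank at W = 100, still present at W = 300.  It is invisible
  at jackknife resolution and does not move the peak, but a comparison
  with fully replicated error bars (below) can resolve it; one such
  high-precision convergence test in the suite documents this as a known
  deviation rather than hiding it.

**Replicated errors** (`mi_curve_ensemble_groups`, `mi_curve_segments`):
for curve-to-curve comparisons, quoted errors must include replication-
level noise that overlapping subsets and within-trajectory redraws cannot
see.  These variants compute one estimate per fully independent ensemble
(or per disjoint trajectory segment) and report the scatter across 10–20
of them.  Sample counts are held at 250 per estimate so KSG bias cancels
between the sides being compared.

**Mirror convention** (`mirror_combine`): τ > 0 presumes agent 0 leads;
the index-swapped estimate is placed at −τ (valid at steady state by time
translation).  Curves from mixed-leadership runs (α > 0) show maxima on
both branches.

**τ grid**: default 101 points on [−2.5, +2.5] s.  At 40 fps this spacing
(0.05 s) is exactly 2 steps, so every grid point maps to a whole-step
lag; an 81-point grid would fall between steps and alias after rounding.

## Track preprocessing

Planar per-frame centroid/head tracks (TRex-style, 40 fps, cm) are
re-centred on the tank middle and converted to polar coordinates; heading
ψ is the angle of the centroid→head vector.  Head/tail misidentification
produces spurious ≈180° heading jumps; whenever the wrapped jump between
consecutive valid frames exceeds π − 0.6 rad the new heading is replaced
by the previous (already corrected) one.  Jumps are measured as wrapped
angular distance and corrections cascade, which makes the pass idempotent
and robust to runs of flipped frames.  Missing frames are masked, never
interpolated; paired operations drop a frame if either member is masked.
The alignment angle A_ij (unsigned angle between i's heading and the
i→j centroid vector, smoothed with a mask-aware centred 15-s rolling
mean) identifies leader-follower episodes: the follower points at the
leader (A ≈ 0), the leader away (A ≈ π).  Drift and noise are estimated
as mean and SD of the pooled wrapped per-frame increments (wrapped
differencing into (−π, π] — raw differencing would corrupt Ω at every
lap boundary).

## Peak localisation and the reaction timescale

`peaks.loess` is a single-pass locally weighted regression: tricube
weights over the nearest ⌈fN⌉ points, local *quadratic* fits by default
(quadratics preserve curvature at a peak; degree configurable).  For each
smoothing fraction f in {0.05, …, 0.5} the branch maximum is located; a
maximum on the branch boundary is flagged as "no interior peak".  T̂ is
the mean of |τ_peak| over the retained fractions and the band width their
spread.  Significance is decided against the long-|τ| plateau (largest
25% of |τ|): peak − plateau > z·√(SE²_peak + SE²_plateau) with z = 2 and
the plateau SE taken conservatively as the mean of its points' SEs.  The
decision rule is this package's formalisation of "a statistically
significant peak"; it is reported transparently with its z-score.

At the default study conditions the branch-peak location from one
300-replicate curve scatters by ±0.05 s (the peak top is broad and
saturated); averaging the small-f band (0.05–0.2), where the sharp
simulated peak remains an interior feature, is the extraction the
reproduction script uses.

## Synthetic tracking data

`synth.render_planar` turns an angular dyad into planar tracks so the
whole pipeline is testable without recordings: radius r_mean = 30 cm
(inside the 26.2/125.1 cm annulus) with stationary AR(1) jitter
(coefficient 0.95 — fish do not teleport radially), head half a body
length (5 cm fish) along the instantaneous direction of angular motion,
head/tail flips with probability p_flip per frame, missing frames with
probability p_miss.  The renderer emulates the two artefacts the
preprocessing must repair and nothing else: no burst-and-coast kinematics,
no wall interactions, no radial behaviour.  Passing end-to-end tests
therefore shows the pipeline is correct and robust to these artefacts,
not that real fish satisfy the dyad model.

## Problem sizes used in tests and the reproduction script

Ensembles are 300 replicates of 24100 steps (the canonical conditions);
the end-to-end recovery runs use 25000-step single trajectories with
W = 100 and artefact rates p_flip = 0.02, p_miss = 0.005; walker checks
use σ² = 0.1, sampling at t* = 500 with windows of 300 steps; the
analytic free-walker check averages 10 independent 2000-replicate
ensembles.  These sizes give sub-minute runs per analysis while keeping
every standard error small relative to the effects asserted.

## Known limitations

- The dyad is one-dimensional and angular; radial dynamics are ignored.
- Only two agents; no interaction network inference, no transfer entropy.
- The linear treatment of wrapped angles mismeasures distances across the
  wrap point; chord mode exists but is not the default because the
  analyses are calibrated to the plain convention.
- Quoted jackknife/resample errors understate replication-level noise
  (see above); use the `_groups`/`_segments` variants for comparisons.
- Behavioural-mode segmentation (smooth vs irregular laps) is out of
  scope; episodes are assumed homogeneous over the analysed record.
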