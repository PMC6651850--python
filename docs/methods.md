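# Methods

## Pose representation

A skeleton frame is reduced to nine unit 3-vectors. The eight limb
bones (shoulder→elbow, elbow→wrist, hip→knee, knee→ankle, both sides)
are normalized differences of joint positions, so they are invariant to
translation and to body size. They are expressed in a local body frame
rebuilt independently at every frame:

1. midpoints of the four proximal limb segments: upper-arm midpoint =
   (shoulder + elbow)/2 per side, upper-leg midpoint = (hip + knee)/2;
2. provisional up = (mean of upper-arm midpoints) − (mean of upper-leg
   midpoints), normalized;
3. provisional left = normalized sum of the two normalized left
   directions (left minus right upper-arm midpoints; same for legs);
4. forward = up × left, normalized;
5. ground alignment: up is snapped to the world ground normal (0,1,0),
   forward is the ground-plane projection of the provisional forward,
   and left is rebuilt as up × forward, guaranteeing an orthonormal
   triad with left and forward exactly in the ground plane;
6. origin = hip midpoint projected to the ground (irrelevant to the
   score, since only rotations affect bone vectors).

"Middle of the upper arm" is read as the midpoint of the shoulder–elbow
*segment*, not the shoulder joint: that is the natural reading and it
makes the up axis robust to arm pose. The provisional left directions
are normalized *before* averaging so that unequal arm and leg spans
weight the two halves equally. Sign conventions (which way "left"
points) cancel out of the method entirely: both skeletons are processed
with the same convention, and only angle *differences* enter the cost.
A frame is rejected as degenerate when the provisional up and left
axes are within 1° of (anti)parallel or when the forward axis is within
1e-6 of vertical; such frames are dropped with a logged count.

The ninth dimension is the body forward vector in *world* coordinates.
Rotating the whole body about the vertical axis by φ leaves the eight
local bone vectors bit-identical and changes only this dimension, by
exactly φ — the property the test suite checks directly.

## Cost, alignment, and score

The frame-pair cost is the sum over dimensions of the angle between
corresponding unit vectors, each term clamped at `max_angle` (default
90°). The clamp encodes the assumption that corresponding bones of two
people doing the same exercise stay within a quarter turn; it also
bounds the per-pair cost at `max_angle·dims`, which makes the score
normalization exact and keeps it in [0, 100] for arbitrary inputs.

Alignment is classic unconstrained DTW: steps (1,0), (0,1), (1,1);
boundary (1,1)→(n,m); O(n·m) dynamic program (implemented as a
vectorized anti-diagonal sweep; a 3000×3000 alignment runs in a few
seconds and ~140 MB). Backtracking breaks ties diagonal > vertical >
horizontal — the choice is not forced by the method; diagonal
preference yields the shortest path among cost-minimal ones and makes
runs deterministic. An optional Sakoe–Chiba band is available but off
by default. A brute-force enumerator over all warping paths (≤8 frames
per side) serves as the oracle in tests.

The score is `100·(1 − DTW/(max_angle·dims·s))` with `s` the optimal
path length. Dividing by `s` rather than by `n+m` or path-independent
constants makes the normalizer the true per-path maximum, so the bound
is attained exactly at the clamp.

Eight-dimensional mode (`dims=8`, bones only) is kept as an ablation;
combined with world-frame bone extraction it reproduces the naive
pipeline whose sensitivity to heading motivates the local frame.

## Calibration and reliability

Raw scores overestimate relative to human raters (real performances
rarely push bone differences toward 90°, so raw scores compress into
the top of the scale). Calibration fits `rating = intercept +
slope·raw` by ordinary least squares — expert on algorithm, in that
direction, so the model maps raw scores onto the expert scale — and
predictions are clipped to [0, 100]. Pearson r is reported with its
t statistic `t = r·√(n−2)/√(1−r²)`.

Inter-rater reliability uses ICC(2,k): two-way random effects, absolute
agreement, average of k raters, computed from the ANOVA mean squares as
`(MSR − MSE)/(MSR + (MSC − MSE)/n)`. The average-measures form is the
right one when the raters' mean is the gold standard. The 95% CI uses
the standard F interval for the single-rater ICC(2,1) with
Satterthwaite degrees of freedom, stepped up by Spearman–Brown; when
residual variance is exactly zero the interval degenerates to [1, 1].

## Numerical choices

- Dot products within 1e-12 of ±1 are snapped to exactly 0°/180°
  before the arccos. Without this, last-ulp noise on identical unit
  vectors becomes ~1e-6-degree phantom angles that accumulate over
  thousands of matched pairs; with it, a motion scored against itself
  is exactly 100%. The snap floor (≈8×10⁻⁵ degrees) is far below any
  meaningful pose difference.
- Bones shorter than 1e-6 m are degenerate (direction undefined).
- Backtracking tie comparisons use exact float equality, which is safe
  because the compared values are sums of identical terms.

## Synthetic data

The generator stands in for a Kinect-V2 capture of a whole-body
exercise: pelvis fixed at (0, 1, 0), upright trunk, fixed shoulder/hip
anchors from template segment lengths (upper arm 0.30 m, forearm
0.27 m, thigh 0.45 m, shank 0.42 m, shoulder width 0.35 m, hip width
0.30 m, trunk height 0.50 m), and each limb bone swinging away from
vertical by a sinusoid with per-bone amplitude 20–60°, frequency
0.2–0.5 Hz, and seeded phase and swing plane — smooth, exercise-like
coordination at 30 Hz. Randomness is `numpy.random.default_rng`
(PCG64) under an explicit seed, reproducible across platforms.

Trainee motions are derived by perturbations applied in a fixed order
— speed resampling, time warp, per-bone angular noise, whole-body
heading rotation — whose order matters only for mixed specifications,
which carry no closed-form expectation. Perturbations act on bone
*directions* with positions rebuilt by forward chaining, so bone
lengths are preserved exactly and injected errors are in the cost's
own unit, degrees. Time resampling interpolates anchor positions
linearly and slerps bone directions; the monotone warp samples the
motion through a seeded, strictly increasing piecewise-linear map of
the time axis onto itself (8 segments; slopes within ±strength of 1).
Per-bone noise rotates each bone by |N(0, σ)| about a random axis
perpendicular to it, so the injected angle equals the rotation angle.

What the generator does *not* emulate: sensor jitter and dropout,
self-occlusion, biomechanically realistic choreography (joint limits,
balance), or inter-subject anthropometric variation during a
comparison. A green test therefore establishes the algebraic and
algorithmic properties of the pipeline — invariances, closed forms,
monotonicity, statistical correctness — not field accuracy against
human raters, which requires real recordings and an expert panel.

## Known limitations

- Scores are insensitive to rhythm: a trainee moving at a wildly
  different tempo but through the right poses scores near 100 by
  design of DTW. Penalizing tempo mismatch would need an added path-
  shape term.
- All nine dimensions are weighted equally; there is no per-body-part
  weighting or localization of errors.
- Joint confidence/tracking states are not modeled; every present
  joint is treated as tracked, and frames with missing joints are
  dropped rather than imputed.
- The dense DP matrix costs 8·n·m bytes twice over; beyond ~10⁴ frames
  per side, banding or streaming would be needed.
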