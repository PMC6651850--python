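# motionscore

Training-free performance scoring of skeleton exercise motion against a
reference recording.

Home-based rehabilitation exergames need to tell a user *how well* they
reproduced a coach's movement, not just whether it was right or wrong.
Classifier-based approaches need per-exercise training data and expert
labels; `motionscore` instead converts a dynamic-time-warping (DTW)
distance between two skeleton recordings directly into a 0–100% score
with a closed-form normalization, so any new exercise works out of the
box. It targets Kinect-V2-style capture: 12 limb joints (shoulders,
elbows, wrists, hips, knees, ankles) at ~30 Hz in a y-up world frame.

## Method

Each frame is reduced to nine unit 3-vectors:

- the **eight limb bone vectors** (upper/lower arm, upper/lower leg,
  both sides), expressed in a **local body frame** rebuilt at every
  frame from the subject's own limb geometry (up pinned to the ground
  normal; left/forward in the ground plane). This makes the bones
  invariant to where the subject stands and which way they face.
- the **body forward vector** in world coordinates, which carries the
  heading as its own ninth dimension.

The frame-pair cost is the summed angular difference over the nine
dimensions, each clamped at 90°. DTW finds the warping path
`P = (p_1 … p_s)` minimizing the cumulative cost

```
DTW(S, T) = min_P Σ C(s_ik, t_jk)
```

subject to the boundary, monotonicity, and unit-step conditions, and the
score is the closed-form percentage

```
score = 100 · (1 − DTW(S, T) / (90 · 9 · s))
```

where `s` is the optimal path length. Identical motions — including
motions that differ only by tempo fluctuations — score 100; a motion
with every matched dimension at the 90° clamp scores 0. Because raw
scores run high relative to human raters, an affine calibration
(`rating = a + b · raw`, ordinary least squares on a small panel of
expert-rated subjects) maps them onto the expert scale; Pearson *r* and
the intraclass correlation ICC(2,k) quantify agreement with and among
raters.

## Worked example

Generate a synthetic trainer/trainee pair in which the trainee performs
the identical movement but stands rotated 30° and has 5° of per-bone
angular jitter, then score it:

```bash
motionscore synth --out pair --duration 4 --orientation-offset 30 --noise-sd 5 --seed 42
motionscore score --trainer pair/trainer.csv --trainee pair/trainee.csv \
    --out report.json --pretty
```

which prints

```
raw score 92.29% (distance 7489.9 deg over 120 pairs)
```

and writes

```json
{
  "raw_pct": 92.29431394314553,
  "distance_deg": 7489.926847262554,
  "path_length": 120,
  "dims": 9,
  "max_angle": 90.0,
  "frames_ref": 120,
  "frames_test": 120,
  "dropped_frames": 0,
  "frame_kind": "local"
}
```

The 30° heading offset alone would cost exactly 30° per matched pair —
a score of `100·(1 − 30/810) = 96.30%` — and the jitter accounts for
the rest. With `--frame world` (bone vectors left in world coordinates)
the same pair scores far lower, because the heading error leaks into
all eight bones; that contrast is the point of the local body frame.

Library use mirrors the CLI:

```python
from motionscore import read_motion, score_motions

ref = read_motion("pair/trainer.csv")
test = read_motion("pair/trainee.csv")
score, alignment = score_motions(ref, test)
print(score.raw_pct)
```

Other subcommands: `motionscore calibrate` fits the expert calibration
line from a scores CSV and a ratings CSV, and `motionscore reliability`
reports ICC(2,k) with its 95% CI plus pairwise Pearson correlations for
a rater panel.

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline from scratch: it scores a
seeded panel of 21 synthetic trainee performances of varying quality,
fits the expert calibration on an emulated three-rater panel, computes
the reliability statistics, and scores a pure 30° heading offset
against its closed form, then writes a JSON results file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## File formats

- **Motion CSV**: header `time,ShoulderLeft_x,ShoulderLeft_y,…` with
  the 12 joints ×(x,y,z) in canonical order; one row per frame; meters,
  y up. Rows with missing joints are dropped; unknown extra columns
  (e.g. `Head_x`) are ignored.
- **Motion JSON-lines**: `{"t": 0.033, "joints": {"ShoulderLeft": [x,y,z], …}}`.
- **Ratings CSV**: `subject,rater1,rater2,…`, one row per subject,
  values on a 0–100 scale.

See `docs/methods.md` for the model's assumptions, parameter choices,
and known limitations.
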