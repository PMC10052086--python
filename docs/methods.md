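# Methods

## Scene model

The synthetic generator emulates a fixed RealSense-style RGB-D camera
mounted ~1 m above hydroponic lettuce in a greenhouse compartment.  Each
head is modelled as a **spherical cap** (a dome of base radius `a` and
cap height `h ≤ a`) standing on the ground plane.  The choice is
deliberate: caps have closed-form projected area (`πa²`) and volume
(`πh(3a² + h²)/6`), so the whole measurement chain can be checked against
analytic oracles rather than against itself.

Frames are rendered by **exact ray casting**: every pixel ray is
intersected with the tilted ground plane and with each plant's cap
sphere, and the nearest hit wins.  This makes three things true by
construction: (i) the depth raster, the pinhole intrinsics and the
back-projection code are mutually consistent; (ii) overlap is resolved as
per-pixel maximum elevation, so occluded leaf area contributes nothing to
coverage or volume; (iii) the ground-truth mask is exactly the set of
pixels whose winning surface is a plant.  Depth gets additive Gaussian
noise and is quantised to the storage unit (0.1 mm); RGB is flat green
with per-plant colour jitter over a grey floor plus pixel noise, which is
all the built-in excess-green segmenter needs — learned segmenters can be
plugged in as external 0/255 masks.

Growth is logistic in both base radius and cap height.  At each spacing
event the surviving heads (evenly thinned, as spacing staff would) are
re-laid on a regular near-square grid at the new density; per-head state
(trait multipliers, weight deviation, colour) persists across events.
Ground-truth fresh weight follows a quadratic allometry in the
area × height indicator, `w = c₀ + c₁x + c₂x²` plus a persistent per-head
deviation, clamped at zero.

### Parameters that matter

| parameter | default | why |
|---|---|---|
| image size / GSD | 256×256 px at 2 mm/px | ~0.26 m² evaluation area; full ladder renders in < 1 s/frame batch |
| camera height | 1000 mm | rig geometry the pipeline targets |
| plane tilt | 2° (0–5° in studies) | "slight skewness in camera mounting" that RANSAC must absorb |
| depth noise | 2 mm (1σ) | depth-sensor noise at 1 m range |
| radius growth | 30 → 190 mm, rate 0.08/day | ~6-week cycle; traverses the full density ladder with 4–7 days between spacings |
| height growth | 20 → 160 mm, rate 0.08/day | heads wider than tall (cap model requires `h ≤ a`); harvest height ~13 cm |
| trait jitter | 3% (lognormal, per head) | head-to-head biological variation |
| allometry | c = (5, 0.0234, 10⁻⁶), noise 20 g | places the 250 g crossing at ≈ 7842 cm³, matching the published threshold scale; 20 g scatter reproduces a ~15–25 g calibration MAE |
| density ladder | 92, 60, 45, 30, 23, 18, 15 heads/m² | the spacing system's available densities |
| RANSAC | 1000 iterations, 5 mm inlier threshold, seeded | plane support is large and clean; refinement is a total-least-squares fit on the consensus set |
| coverage spacing trigger | 98% | operational closure threshold (see below) |
| harvest threshold | 7840 cm³ / 250 g target | published calibration; recomputed whenever calibration pairs are supplied |

Realized densities differ from the nominal ladder values by a few percent
because an integer number of heads is laid on a finite imaged area (e.g.
24 heads on 0.26 m² is 91.6/m², not 92).  The batch records both; all
downstream arithmetic (light loss, area per plant) uses the realized
schedule, the ladder values remain the labels.

## Spacing-day construction and the light-loss indicator

The light-loss indicator balances two losses at a spacing event: floor
light lost after spacing (`100 − C_t`) and light lost to overlapping
leaves before it (`C_t − C_{t−1}·d_t/d_{t−1}`).  A geometric analysis of
rigid discs on a square lattice shows the balance point is **not** where
discs first touch: at strict tangency the canopy covers only ~79% of the
floor and the indicator reads +35 to +50 ("far too early") — the package
demonstrates this with the generator's `tangency` policy.  The balance
point sits at *canopy closure*, where the disc union approaches full
cover (disc radius ≈ 0.62–0.65 of the grid pitch, union coverage
≈ 97–98%).  That the indicator's optimum lands at ~98% coverage is the
geometric counterpart of the operational rule of spacing once coverage
reaches 98%.

The generator's default `balanced` policy therefore constructs
optimally-timed events directly: each day it predicts the light loss that
would be measured if spacing happened now versus tomorrow — using the
same measurement operator (rendered ground-truth masks) and the same
frame timing (the "before" coverage comes from the previous day's frame)
as the evaluation pipeline — and spaces on whichever day is nearer the
zero crossing.  With one frame and one decision per day, the measured
light loss at a balance-timed event is bounded by roughly half the daily
swing of the indicator, in practice within ±5 coverage points at every
ladder step.  Delaying the same construction by five days drives every
event negative ("too late"); the `coverage` policy spaces at a plain
coverage threshold.

## Numerical choices

- **Heights** are signed point-to-plane distances of back-projected
  lettuce pixels, positive toward the camera, clipped at zero after noise
  (a vertical-difference mode is provided; for near-horizontal planes the
  two differ by < cos 5° ≈ 0.4%).  The plane is fitted once per batch on
  the planting-day frame and reused — the camera is assumed static.
- **Volume integration** weights each pixel's height by its ground
  footprint computed from the finite-difference Jacobian of the
  back-projected (x, y) maps, not by a constant GSD².  A constant pixel
  area underestimates a dome's volume by ≈ 3R/4z (≈ 3.8% for a 50 mm cap
  under a 1 m camera) because pixels near the silhouette are foreshortened
  on the sloped surface; the Jacobian recovers the closed-form cap volume
  to ≈ 0.1%.  The coordinate maps are lightly smoothed (3×3 mean) so
  sensor noise does not dominate the derivatives.  Pure orthographic
  height maps, which carry no depth, fall back to GSD².
- **mIoU** treats a class absent from both masks as IoU 1, making the
  metric total and equal to 1 exactly when the masks agree.
- **Weight calibration** fits the quadratic on an indicator scale
  normalised by its maximum (the raw normal equations are ill-conditioned
  at x ~ 10⁴); the harvest threshold is the smallest non-negative crossing
  of the target weight with non-negative slope, and is +∞ (never harvest)
  when the fitted curve stays below the target — as happens for a batch
  kept so dense that occlusion caps the indicator.
- **Degenerate inputs** are rejected loudly: < 3 non-collinear points for
  a plane, < 3 distinct indicator values for a calibration, density
  increases in a schedule, empty masks for coverage, caps taller than
  wide.
- The on-peak electricity window is half-open, [07:00, 23:00); MJ→kWh is
  the exact 1/3.6.  The six-compartment ledger keeps the printed
  operational totals alongside the printed components because three of
  the six columns were rounded inconsistently in the source (components
  of one column sum to 7.21 against a printed 7.24); net profit is
  computed from the printed totals, which reproduces five of six printed
  net profits exactly and the sixth within 0.01 €/m².

## What the generator does and does not emulate

It emulates: top-down RGB-D geometry with a tilted ground plane and
pinhole projection, sensor depth noise and quantisation, logistic growth
with head-to-head variation, overlap and occlusion at high density,
stepwise density reduction on a grid, destructive weekly weighing with
scatter, and the saturation of image-derived traits as the canopy closes
(measured volume and indicator flatten while true weight keeps rising —
which is why harvest calibration should include a late/harvest-day
sample).

It does not emulate: leaf-level morphology or colour variation of real
lettuce, stereo-matching artefacts and depth shadows of a real
active-stereo sensor, climate-driven growth variation, head compaction
late in the cycle, gutter-row mechanics (plants re-lay on grids), or
malformation/tip-burn quality losses.  Passing tests therefore show that
the *measurement chain and decision logic* are correct under controlled
geometry and noise — not that a particular segmenter or growth model fits
real greenhouse frames.

## Problem sizes

The default batch is 42 days × one 256×256 frame/day, which renders and
analyses end-to-end in a few seconds; the noise-robustness studies use
100 seeded trials (plane fit on 128×128 planting frames; calibration on
~42 weekly pairs).  These sizes keep the whole suite comfortably
reproducible on a laptop while leaving every acceptance margin intact.

## Known limitations

- The light-loss balance construction decides once per day; sub-daily
  framing would tighten measured event losses further.
- Small head counts at the low ladder densities (4–6 heads in view) make
  realized density, and hence the light-loss ratio, sensitive to single
  heads; a larger evaluation area reduces this.
- The excess-green segmenter is a deliberately simple stand-in interface
  for learned segmenters and is only expected to be near-perfect on the
  synthetic colour model.
- Perspective bookkeeping (Jacobian footprints) assumes a single
  ground-referenced surface; multi-layer canopies or undercut leaf
  geometry would need a mesh-based integral.
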