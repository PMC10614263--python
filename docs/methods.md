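# Methods

This note documents the models and procedures implemented in `gliamotion`,
the parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions taken where the design was open.

## Scope and data model

The package analyzes 4D fluorescence time-lapse stacks (frame, z, y, x) of
labeled microglia in live tissue. All physical quantities derive from two
calibration numbers carried with every object: the pixel size (µm/px) and
the frame interval (s). Axis order is (t, z, y, x), y before x, 0-based
indexing, everywhere. Defaults emulate confocal imaging of lectin-labeled
microglia in acute brain slices: 512×512 px covering a ~140 µm field
(0.273 µm/px), 10 frames at 1 frame/min, 15 z-planes at 2 µm spacing.

## Preprocessing

The scoring algorithm compares pixel occupancy between consecutive frames,
so preprocessing is designed never to create spurious occupancy changes:

- **Maximum-intensity z-projection** over an optional slab given in µm.
- **Drift correction**: integer-pixel translation per frame, estimated by
  phase correlation against frame 0. Registering to frame 0 (not pairwise)
  prevents error accumulation; integer shifts avoid the mask smearing that
  subpixel interpolation would introduce into a pixel-presence analysis.
  Constant (degenerate) frames get shift (0, 0) with a logged warning.
  Border pixels shifted in from outside are filled with the frame median
  (the background level).
- **Bleach correction**: frame t is rescaled by mean(frame 0)/mean(frame t),
  making the frame-mean exactly constant. This is exact when the imaged
  content is statistically stationary; a single-exponential fit
  (`method="exp_fit"`) is available when cell content itself trends.
- **Binarization**: one Otsu threshold computed on frame 0 and applied to
  every frame. Per-frame thresholds would convert threshold jitter into
  fake extension/retraction events, which is fatal to the stability index.
  A fixed manual threshold is available.

## Extension events and the stability index

A new extension at frame t ≥ 1 is an 8-connected component of
(occupied at t) ∧ (unoccupied at t−1) that (i) touches the foreground of
frame t−1, (ii) has at least `min_event_px` = 4 pixels (single-pixel shot
noise flickers must not count), and (iii) lies nearest to a segmented cell,
to which it is assigned. Components adjacent to no cell are discarded as
noise. Retractions are not scored; the index is defined on extensions only.

Persistence is counted inclusively from onset: the largest k such that in
every frame onset … onset+k−1 at least `overlap_fraction` = 0.5 of the
onset footprint is occupied, after dilating each frame mask by 1 px. The
dilation tolerates single-pixel boundary breathing of the binarized
outline; exact-pixel matching would misclassify persistent extensions whose
edge flickers. An event is **stable** iff its persistence reaches
`ceil(min_persistence_s / frame_interval_s)` frames — 3 frames for the
default 180 s window at 60 s/frame. The stability index of a cell is
n_stable/n_events; a cell with zero events yields an explicitly *undefined*
result that is excluded (and counted) in group statistics rather than
imputed.

Note one consequence of the 0.5 overlap rule: a footprint whose immediate
surroundings are mostly permanent foreground could in principle be scored
persistent by its neighbours. With ≥ 4-px events and the 1-px dilation this
requires more than half the footprint to sit within 1 px of permanent
structure; the randomized oracle tests place events with ≥ 3 px clearance
and verify exact agreement with brute-force enumeration.

## Segmentation and morphometry

- **Cells** are 8-connected components of the binarized reference frame
  (frame 0) with ≥ `min_cell_area_px` = 50 px. Border-touching cells are
  flagged and refused by all morphometry (their measures would be
  truncated).
- **Soma**: morphological opening of the cell mask with a disk of radius
  `soma_open_radius_um` = 2 µm; the largest surviving component is the soma.
  This is deterministic and parameter-light; thin cells get an empty soma.
- **Soma perimeter**: marching-squares contour length of the soma mask at
  the 0.5 level of a 1-px-Gaussian-smoothed mask, × pixel size. Raw binary
  marching squares overestimates smooth boundaries by ~5 % and varies ~6 %
  with orientation; on the smoothed mask a digital disk measures within
  ~0.5 % of 2πr at any orientation. Naive pixel-edge counting (up to ~27 %
  high) is not used.
- **Phagocytic cup**: operationalized as an enclosed background cavity at a
  process terminal. A morphological closing (disk radius
  `cup_closing_radius_um` = 1 µm) seals the cup mouth; hole-filling the
  closed mask then exposes the cavity (the closing alone is insufficient —
  its erosion re-enters shallow mouths). Candidates must exceed
  `min_cup_area_px` = 5 px and lie near a skeleton endpoint; the largest
  candidate's area × (pixel size)² is reported, or *absent* when none
  qualifies — a valid result. The recovered area includes the sealed mouth
  region, so it is accurate to roughly the closing radius. For real data
  with manually outlined cups, `cup_area_from_roi` measures a drawn ROI
  instead; the automated mode is the tested default.
- **Ramification** (tracing proxy): the cell mask minus the soma (dilated
  1 px to clear rim residue) is thinned to a 1-px skeleton. Endpoints have
  exactly one 8-neighbor; branch points are connected clusters of pixels
  with ≥ 3 neighbors (a junction in a thinned image can occupy several
  adjacent pixels — counting pixels instead of clusters would overcount).
  Spur twigs of ≤ 2 px hanging off a junction are pruned as thinning
  artifacts. Length accumulates 1 px per axial step and √2 per diagonal
  step; a diagonal edge whose two pixels also share an axial neighbor is
  skipped so corner pixels are not double-counted. Total process length is
  reported per cell (not per process) and labeled as such.

## Group statistics

Summaries are mean ± SEM (sd/√n, ddof = 1). Two groups are compared with an
unpaired two-sided t-test (equal variances by default; Welch available);
three or more with one-way ANOVA followed by all-pairs Tukey HSD. Undefined
stability indices are dropped with a logged count before analysis. The unit
of analysis defaults to the cell; animal ids are carried through so
per-animal means can be produced (`per_animal`) when cells within an animal
should not be treated as independent — both tables are emitted, labeled.
Tests are two-sided at α = 0.05.

## The synthetic-data generator

Geometry: each cell is a disk soma (radius 5 µm) with 5 piecewise-linear
primary processes (8 µm, two bending segments, ~0.8 µm wide) grown from the
rim, laid out on a jittered grid so cells never touch. Kinetics: at each
frame, every free process tip sprouts a new ~1.5 µm terminal extension with
probability `extension_prob`; with probability `stable_fraction` the
extension persists through the final frame and the tip advances, otherwise
it retracts after `unstable_lifetime_frames` = 1 frame, and the tip must
stay quiet one further frame so re-growth is never confused with the
retracted extension. Event onsets are restricted to frames
1 … n_frames − 3 so every sampled persistent extension can actually display
the full 3-frame stability window before the movie ends; without this, a
late "stable" event would be unobservably truncated and its ground-truth
label would contradict any observer. Every realized extension is recorded
with its onset, novel-pixel footprint and label; the true stability index
is (stable events)/(all events), undefined at zero events.

Rendering: geometry → Gaussian z-profile across planes → 2D Gaussian PSF
blur (σ = 0.3 µm) → uniform background (0.05) → artifacts in physical
order: cumulative stage drift (border filled at background level), then
exponential photobleaching exp(−rate·t), then Poisson shot noise at
`noise_scale` = 50 photons per intensity unit. With drift, bleach and noise
all zero the artifact stage is exactly the identity. One explicitly seeded
NumPy generator drives everything; identical seed + config is bit-identical.

What the simulator does **not** emulate: tissue background structure and
vasculature, labeling heterogeneity, slice-surface activation gradients,
z-drift, cell migration, process thinning/thickening, and retraction of
pre-existing (non-event) processes. Passing the recovery tests therefore
shows the algorithm chain is correct under controlled acquisition physics —
not that segmentation or thresholding is robust to every real-tissue
artifact.

## Validation strategy and problem sizes

- **Oracle equivalence**: on 100+ randomized toy binary series (explicit
  blocks with known onsets and lifetimes adjacent to a static base), the
  pipeline's SI must exactly equal a brute-force oracle that enumerates
  every (block, lifetime) pair against the 3-frame rule.
- **Parameter recovery**: simulated fields (6 cells, 36 tips, ~80–110
  events) at stable fractions 0.2/0.5/0.8; estimated SI within 0.10 of
  truth noiseless and drift-free, within 0.15 with shot noise, 1 px/frame
  drift and 0.05/frame bleach after full preprocessing. Measured errors are
  ~0 and ≤ 0.04 respectively.
- **Preprocessing**: integer drifts recovered exactly; bleach factors match
  exp(rate·t) to < 1e−6 on noiseless uniform stacks.
- **Morphometry**: digital disk perimeter within 5 % of 2πr (measured
  ~0.03 %); 50-px bar skeleton within 5 % (measured ~3 %); "+"-mask
  topology exact; calibration equivariance (×k → ×k, ×k²) exact to
  round-off.
- **Statistics**: 3-group null simulation (n = 8/group, 1 000 reps) keeps
  the type-I error in [0.03, 0.07]; the contrast with SI means
  (0.4, 0.4, 0.8), sd 0.2, n = 8/group (200 reps) is detected with power
  > 0.8. The sd of 0.2 reflects the per-cell SI spread observed in
  simulated fields with ~15 events per cell.
- **Determinism**: two runs with the same config and seed produce
  byte-identical CSVs (report files carry no timestamps and fixed float
  formatting for this reason).

Simulation sizes in tests and the acceptance script (512² fields, ≤ 6
cells, ~250 events per recovery sweep, 1 000/200 statistical replicates)
were chosen to give stable estimates at interactive runtimes on one CPU.

## Known limitations

- Registration is translation-only; rotational or non-rigid tissue motion
  is out of scope and will appear as spurious events.
- The binarization threshold comes from frame 0; gross focus loss later in
  a movie violates the single-threshold assumption.
- The cup surrogate measures *enclosed* cavities; wide-open cups that the
  closing radius cannot seal are reported absent.
- Per-process (as opposed to per-cell) length statistics and Sholl analysis
  are not implemented.
- Mixed-effects models are not provided; the per-animal averaging path is
  the supported way to respect within-animal correlation.
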