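# gliamotion

Quantitative analysis of microglial process motility and morphology in
time-lapse fluorescence imaging of live brain tissue.

Microglia — the resident immune cells of the brain — continuously extend and
retract fine processes to surveil their surroundings. Neuroinflammation
perturbs these dynamics: injured-brain microglia grow restless processes, a
larger cell body and bigger phagocytic cups, and lose ramification. This
package measures all of those endpoints from 4D confocal time-lapse stacks
(T×Z×Y×X), and ships a ground-truthed synthetic time-lapse simulator so that
every stage of the measurement can be validated without microscope data.

## The core measurement: the stability index

Frames are compared pixel-by-pixel after maximum-intensity z-projection,
drift registration and photobleach correction. A **new process extension**
at frame *t* is a connected set of pixels occupied at *t* but not at *t−1*,
adjacent to a cell's existing footprint. An extension that remains in place
for at least 3 minutes (3 frames at 1 frame/min — present in a series of
three consecutive images) is **stable**, and

&nbsp;&nbsp;&nbsp;&nbsp;SI = (stable extensions) / (all extensions) ∈ [0, 1]

is the **stability index** of a cell. Low SI means restless, destabilized
processes. "Remains in place" is operationalized as ≥ 50 % of the onset
footprint still occupied in each frame of the window, with a 1-px dilation
tolerance for boundary breathing.

Around this sit:

- **preprocessing** — max z-projection over a chosen slab, integer-pixel
  phase-correlation registration to frame 0, frame-mean bleach
  normalization, single Otsu threshold from frame 0 applied to all frames;
- **segmentation & morphometry** — per-cell soma perimeter
  (marching-squares contour, µm), phagocytic-cup area (largest enclosed
  cavity at a process terminal, µm²), and skeleton-based ramification
  (total process length, branch points, endpoints);
- **group statistics** — mean ± SEM summaries, unpaired *t*-test for two
  groups, one-way ANOVA with Tukey HSD for three or more;
- **a synthetic-data generator** — disk somata with branched processes whose
  tips stochastically sprout persistent or transient extensions, rendered
  with PSF blur, stage drift, photobleaching and shot noise, with every true
  event recorded.

## Worked example

`examples/02_stability_index.py` simulates six microglia imaged for 10 min
at 1 frame/min with drift (1 px/frame), photobleaching (0.05/frame) and shot
noise, then runs the full measurement chain:

```
true events: 89, true SI: 0.438
detected events: 92
  cell 1: 7/15 stable -> SI = 0.467
  cell 2: 9/16 stable -> SI = 0.562
  cell 3: 3/14 stable -> SI = 0.214
  cell 4: 9/15 stable -> SI = 0.600
  cell 5: 8/17 stable -> SI = 0.471
  cell 6: 6/15 stable -> SI = 0.400
pooled estimated SI: 0.457
```

The simulator labeled 43.8 % of the 89 true extensions stable; the pipeline,
working only from the rendered noisy images, recovers 0.457 — within 0.02.
`examples/04_group_statistics.py` extends this to a three-arm
healthy/injured/treated design and prints the ANOVA + Tukey table
(the injured arm separates from both others at p < 10⁻⁴; the treated arm is
statistically indistinguishable from healthy).

The other examples cover simulation (`01`), morphometry (`03`): simulated
5-µm somata measure a perimeter of ≈ 31.7 µm against the analytic
2πr = 31.4 µm, and per-cell process length ≈ 39.4 µm against a simulated
40 µm.

A thin CLI wraps the same library calls:

```bash
gliamotion all --seed 1 --outdir run/      # simulate + analyze + report
gliamotion report --results healthy run_h/stability_index.csv \
                  --results treated run_t/stability_index.csv --outdir rep/
```

## Layout

```
src/gliamotion/      library (simulate, preprocess, segmentation, motility,
                     morphometry, stats_report, pipeline, cli)
examples/            one narrative script per capability
tests/               pytest suite, including end-to-end validation
scripts/acceptance.py  recompute the validation numbers
docs/methods.md      models, assumptions, parameter choices, limitations
```
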