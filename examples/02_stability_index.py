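"""Score process motility end to end and compare with the ground truth.

Simulates a field of microglia with stage drift, photobleaching and shot
noise, runs the full correction chain (max z-projection, drift registration,
bleach normalization, binarization), detects new process extensions between
consecutive frames, classifies each by the 3-minute persistence rule, and
prints the per-cell stability index next to the simulated truth.
"""

from gliamotion import (SimulationConfig, preprocess_stack, score_series,
                        segment_cells, simulate_timelapse)

config = SimulationConfig(n_cells=6, n_primary_processes=6,
                          extension_prob=0.45, stable_fraction=0.5,
                          drift_px_per_frame=(1.0, 0.0), bleach_rate=0.05,
                          seed=1)
stack, truth = simulate_timelapse(config)
corrected, binary = preprocess_stack(stack)
seg = segment_cells(binary)
events, per_cell = score_series(binary, seg)

print(f"true events: {truth.n_events}, true SI: {truth.stability_index:.3f}")
print(f"detected events: {len(events)}")
for r in per_cell:
    print(f"  cell {r.cell_id}: {r.n_stable}/{r.n_events} stable "
          f"-> SI = {r.stability_index:.3f}")
_, pooled = score_series(binary, seg, per_cell=False)
print(f"pooled estimated SI: {pooled[0].stability_index:.3f}")
print("-> the pooled estimate should sit within ~0.15 of the truth even "
      "with drift, bleaching and shot noise present.")
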