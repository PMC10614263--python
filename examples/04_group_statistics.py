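"""Compare stability indices across three treatment groups.

Builds a three-arm design (healthy control, untreated injury, treated
injury) by simulating each arm with a different true stable fraction,
scoring every cell, and running a one-way ANOVA with Tukey HSD post-hoc
comparisons on the per-cell stability indices. Summaries are mean +/- SEM.
"""

import pandas as pd

from gliamotion import (GroupTable, SimulationConfig, compare_groups,
                        preprocess_stack, score_series, segment_cells,
                        simulate_timelapse, summarize)

ARMS = {"healthy": 0.8, "cp_saline": 0.35, "cp_treated": 0.75}

rows = []
for arm_idx, (arm, stable_fraction) in enumerate(ARMS.items()):
    for seed in (1, 2, 3):  # three animals per arm
        cfg = SimulationConfig(n_cells=4, n_primary_processes=6,
                               extension_prob=0.45,
                               stable_fraction=stable_fraction,
                               seed=100 * arm_idx + seed)
        stack, _ = simulate_timelapse(cfg)
        _, binary = preprocess_stack(stack)
        seg = segment_cells(binary)
        _, per_cell = score_series(binary, seg)
        for r in per_cell:
            rows.append({"group": arm, "animal_id": seed,
                         "cell_id": r.cell_id, "value": r.stability_index})

table = GroupTable("stability_index", "fraction", pd.DataFrame(rows))
print(summarize(table).to_string(index=False,
                                 float_format=lambda v: f"{v:.3f}"))
comp = compare_groups(table)
print(f"\none-way ANOVA: F = {comp.statistic:.2f}, p = {comp.pvalue:.2g}")
print(comp.pairwise.to_string(index=False,
                              float_format=lambda v: f"{v:.4f}"))
print("-> the injured untreated arm should separate from both the healthy "
      "and treated arms (small adjusted p), mirroring a rescue design.")
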