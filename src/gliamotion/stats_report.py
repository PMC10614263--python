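"""Group statistics and report generation.

Summaries are mean ± SEM; two groups are compared with an unpaired two-sided
t-test (equal-variance by default, Welch optional), three or more with
one-way ANOVA followed by all-pairs Tukey HSD. The unit of analysis defaults
to the cell, with animal ids carried so per-animal means can be analyzed
instead when cells within an animal are not independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["GroupTable", "ComparisonResult", "summarize", "compare_groups",
           "build_report", "plot_groups"]

log = logging.getLogger(__name__)


@dataclass
class GroupTable:
    """Tidy per-observation table for one measurement.

    ``data`` columns: group, animal_id, cell_id, value. Non-finite values
    (e.g. undefined stability indices) are dropped with a logged count.
    """

    name: str
    units: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"GroupTable missing column(s) {sorted(missing)}")
        for col in ("animal_id", "cell_id"):
            if col not in self.data.columns:
                self.data[col] = 0
        n_bad = int((~np.isfinite(self.data["value"])).sum())
        if n_bad:
            log.info("GroupTable %s: dropping %d undefined/non-finite values",
                     self.name, n_bad)
            self.data = self.data[np.isfinite(self.data["value"])]
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, name: str, units: str,
                    groups: Dict[str, np.ndarray]) -> "GroupTable":
        frames = [
            pd.DataFrame({"group": g, "cell_id": np.arange(len(v)),
                          "value": np.asarray(v, dtype=float)})
            for g, v in groups.items()
        ]
        return cls(name, units, pd.concat(frames, ignore_index=True))

    def per_animal_means(self) -> "GroupTable":
        agg = (self.data.groupby(["group", "animal_id"], as_index=False)
               ["value"].mean())
        agg["cell_id"] = -1
        return GroupTable(self.name + "_per_animal", self.units, agg)

    @property
    def group_names(self) -> List[str]:
        return sorted(self.data["group"].unique())


@dataclass
class ComparisonResult:
    measurement: str
    summary: pd.DataFrame          # group, n, mean, sem
    method: str                    # "ttest" or "anova_tukey"
    statistic: float               # t or F
    pvalue: float
    pairwise: Optional[pd.DataFrame] = None  # Tukey adjusted p's (>=3 groups)


def summarize(table: GroupTable) -> pd.DataFrame:
    """Per-group n, mean and SEM (= sd/sqrt(n), ddof=1).

    Groups with a single observation get SEM = NaN with a warning; the mean
    is still reported.
    """
    if table.data.empty:
        raise ParameterError("summarize: empty table")
    rows = []
    for g, sub in table.data.groupby("group", sort=True):
        v = sub["value"].to_numpy(dtype=float)
        if v.size < 2:
            log.warning("summarize: group %r has n=%d; SEM undefined",
                        g, v.size)
            sem = float("nan")
        else:
            sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
        rows.append({"group": g, "n": int(v.size),
                     "mean": float(np.mean(v)), "sem": sem})
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sem"])


def compare_groups(table: GroupTable, welch: bool = False) -> ComparisonResult:
    """Two groups: unpaired two-sided t-test; >=3: one-way ANOVA + Tukey HSD."""
    names = table.group_names
    if len(names) < 2:
        raise ParameterError(
            f"compare_groups needs >= 2 groups, got {len(names)}")
    samples = [table.data.loc[table.data["group"] == g, "value"]
               .to_numpy(dtype=float) for g in names]
    for g, v in zip(names, samples):
        if v.size < 2:
            raise ParameterError(f"group {g!r} has n={v.size} < 2")
    summ = summarize(table)
    if len(names) == 2:
        res = sps.ttest_ind(samples[0], samples[1], equal_var=not welch)
        return ComparisonResult(table.name, summ, "ttest",
                                float(res.statistic), float(res.pvalue))
    f_res = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group1": names[i], "group2": names[j],
                "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                "p_adj": float(tukey.pvalue[i, j]),
            })
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff",
                                           "p_adj"])
    return ComparisonResult(table.name, summ, "anova_tukey",
                            float(f_res.statistic), float(f_res.pvalue),
                            pairwise)


def build_report(tables: List[GroupTable],
                 comparisons: List[ComparisonResult],
                 outdir: str | Path,
                 metadata: Optional[dict] = None,
                 per_animal: bool = False) -> List[Path]:
    """Write tidy per-endpoint CSVs, summary/significance tables and metadata.

    Output is deterministic (no timestamps; fixed float formatting), so two
    runs with identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {outdir}: {exc}") from exc
    written: List[Path] = []
    if not tables and not comparisons:
        log.warning("build_report: no analyses supplied; metadata only")
    for table in tables:
        p = outdir / f"{table.name}.csv"
        table.data.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        s = outdir / f"{table.name}_summary.csv"
        summarize(table).to_csv(s, index=False, float_format="%.6g")
        written.append(s)
        if per_animal and table.data["animal_id"].nunique() > 1:
            pa = table.per_animal_means()
            p2 = outdir / f"{pa.name}.csv"
            pa.data.to_csv(p2, index=False, float_format="%.6g")
            written.append(p2)
    sig_rows = []
    for comp in comparisons:
        sig_rows.append({"measurement": comp.measurement, "method": comp.method,
                         "statistic": comp.statistic, "pvalue": comp.pvalue})
        if comp.pairwise is not None:
            p = outdir / f"{comp.measurement}_tukey.csv"
            comp.pairwise.to_csv(p, index=False, float_format="%.6g")
            written.append(p)
    if sig_rows:
        p = outdir / "significance.csv"
        pd.DataFrame(sig_rows).to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    meta = dict(metadata or {})
    meta.setdefault("package", "gliamotion")
    p = outdir / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(p)
    return written


def plot_groups(comp: ComparisonResult, path: str | Path) -> Path:
    """Bar plot of group means ± SEM for one comparison (QC figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    s = comp.summary
    ax.bar(s["group"], s["mean"], yerr=s["sem"], capsize=4,
           color="#9ecae1", edgecolor="k")
    ax.set_ylabel(comp.measurement)
    ax.set_title(f"{comp.method}: p = {comp.pvalue:.3g}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
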