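#!/usr/bin/env python
"""Per-phase kinematics: velocity by migratory segment, straightness by label.

Compares mean per-step velocity across the approach / within / reverse
segments (Mann-Whitney pairwise + one-way ANOVA) and whole-track
straightness between reverse-migrated and non-reverse-migrated cells.
Writes the comparison table and a summary figure under results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from rmtrack import anova_oneway, group_comparison

RESULTS = Path(__file__).resolve().parent.parent / "results"
metrics = pd.read_csv(RESULTS / "metrics.csv")

segments = ("approach", "within", "reverse")
vel = {s: metrics.loc[metrics["segment"] == s, "mean_velocity"].dropna()
       for s in segments}

rows = []
for a, b in (("approach", "within"), ("within", "reverse"),
             ("approach", "reverse")):
    r = group_comparison(vel[a], vel[b], test="mann_whitney")
    rows.append({"comparison": f"velocity {a} vs {b}", **r.as_dict()})
    print(f"velocity {a:8s} ({r.mean_a:4.2f} ± {r.sem_a:.2f} µm/min) vs "
          f"{b:8s} ({r.mean_b:4.2f} ± {r.sem_b:.2f}): p = {r.p_value:.2e} "
          f"{r.significance}")
anova = anova_oneway(*(vel[s] for s in segments))
print(f"one-way ANOVA across segments: F = {anova['statistic']:.1f}, "
      f"p = {anova['p_value']:.2e} {anova['significance']}")

whole = metrics[metrics["segment"] == "whole"]
strs = {lab: whole.loc[whole["rm_label"] == flag, "straightness"].dropna()
        for lab, flag in (("rM", True), ("non-rM", False))}
r = group_comparison(strs["rM"], strs["non-rM"], test="mann_whitney")
rows.append({"comparison": "whole-track straightness rM vs non-rM",
             **r.as_dict()})
print(f"straightness rM ({r.mean_a:.3f} ± {r.sem_a:.3f}) vs non-rM "
      f"({r.mean_b:.3f} ± {r.sem_b:.3f}): p = {r.p_value:.2e} {r.significance}")

pd.DataFrame(rows).to_csv(RESULTS / "group_comparisons.csv", index=False)

fig, axes = plt.subplots(1, 2, figsize=(9, 4))
means = [vel[s].mean() for s in segments]
sems = [vel[s].sem() for s in segments]
axes[0].bar(segments, means, yerr=sems, capsize=4, color="#4878a8")
axes[0].set_ylabel("mean velocity (µm/min)")
axes[0].set_title("velocity by migratory segment (±SEM)")
data = [strs["rM"], strs["non-rM"]]
axes[1].bar(["rM", "non-rM"], [np.mean(d) for d in data],
            yerr=[np.std(d, ddof=1) / np.sqrt(len(d)) for d in data],
            capsize=4, color=["#a84848", "#888888"])
axes[1].set_ylabel("whole-track straightness")
axes[1].set_title("straightness by rM label (±SEM)")
fig.tight_layout()
(RESULTS / "figures").mkdir(exist_ok=True)
fig.savefig(RESULTS / "figures" / "segment_kinematics.png", dpi=150)
print(f"comparisons -> {RESULTS / 'group_comparisons.csv'}; "
      f"figure -> results/figures/segment_kinematics.png")
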