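"""Statistical battery over the per-animal cohort summaries.

Averages technical replicates per animal, then runs the tests appropriate
to each comparison: one-sample t (Bonferroni alpha = 0.025) on hour-wise
line-length deltas, repeated-measures ANOVA with Tukey's post hoc on the
pulse-triggered means, a two-way repeated-measures ANOVA (band x hour) on
band power, and a group comparison of contralateral burst ratios.  Writes
results/stats_appendix.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from optolfp.stats_report import (average_replicates, one_sample_t, posthoc,
                                  rm_anova, two_way_rm_anova)
from optolfp.io_core import ValidationError

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    hourly = pd.read_csv(RESULTS / "line_length_hourly.csv")
    pulse = pd.read_csv(RESULTS / "pulse_response.csv")
    bands = pd.read_csv(RESULTS / "band_power.csv")
    bursts = pd.read_csv(RESULTS / "burst_ratio.csv")
    stats = {}

    # hour-wise deltas: one-sample t vs 0, Bonferroni over hours 2 and 3
    per_animal = average_replicates(hourly, ["animal", "session_type", "hour"],
                                    "delta")
    for st in sorted(per_animal["session_type"].unique()):
        for h in (2, 3):
            vals = per_animal[(per_animal["session_type"] == st)
                              & (per_animal["hour"] == h)]["delta"]
            try:
                res = one_sample_t(vals.to_numpy(), 0.0, n_comparisons=2)
                stats[f"delta_L_{st}_hour{h}"] = res.to_dict()
            except ValidationError as exc:
                stats[f"delta_L_{st}_hour{h}"] = {"error": str(exc)}

    # pulse response: RM ANOVA over pre/before/after + Tukey
    pa = average_replicates(pulse, ["animal", "session_type", "metric"])
    for st in sorted(pa["session_type"].unique()):
        wide = (pa[pa["session_type"] == st]
                .pivot(index="animal", columns="metric", values="value")
                [["pre", "before", "after"]])
        res = rm_anova(wide.to_numpy())
        res.posthoc = posthoc([wide[c].to_numpy() for c in wide], "tukey")
        res.extra["conditions"] = list(wide.columns)
        stats[f"pulse_response_{st}"] = res.to_dict()

    # band power: two-way RM ANOVA (band x hour) on reference sessions
    ref = bands[bands["session_type"] == "ref"]
    ba = average_replicates(ref, ["animal", "band", "hour"], "auc")
    effects = two_way_rm_anova(ba, "auc", ["band", "hour"], "animal")
    stats["band_power_ref"] = {k: v.to_dict() for k, v in effects.items()}

    # contralateral burst ratio: construct vs virus-free
    kept = bursts[~bursts["dropped_gs"] & (bursts["channel"] == "HCc")]
    ka = average_replicates(kept, ["group", "animal"], "burst_ratio")
    stats["contralateral_burst_ratio_means"] = {
        g: float(v) for g, v in
        ka.groupby("group")["burst_ratio"].mean().items()
    }

    out = RESULTS / "stats_appendix.json"
    out.write_text(json.dumps(stats, indent=2, sort_keys=True, default=str)
                   + "\n")
    print(f"wrote {out}")
    for key in sorted(stats):
        entry = stats[key]
        if isinstance(entry, dict) and "p" in entry:
            print(f"{key:32s} {entry['test']:18s} stat={entry['statistic']:8.3f}"
                  f" p={entry['p']:.4g} (alpha={entry['alpha']})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
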