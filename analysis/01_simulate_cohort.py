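"""Simulate the study cohorts and write them to disk as EDF + events CSV.

Healthy (saline) silencer-group animals each get a reference session and
two stimulation sessions (0.05 Hz and 0.1 Hz), two replicates each;
epileptic (kainate) animals from the silencer and virus-free groups get
reference sessions.  Sessions are written at test scale (10-min "hours",
1 kHz) so the whole cohort simulates in about a minute; the signal
structure is identical to study scale.

Signals land under scratch/cohort/ (binary EDF); the session manifest goes
to results/cohort_manifest.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from optolfp.io_core import SessionLayout, write_recording
from optolfp.synthetic_lfp import default_config, simulate_experiment

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

FS_RAW = 1000.0
LAYOUT = SessionLayout(hour_s=600.0, fadeoff_s=100.0)
MASTER_SEED = 20260101

SALINE_SESSIONS = ["ref", "stim_0.05", "stim_0.1"]
N_ANIMALS = 3
N_REPLICATES = 2
KAINATE_GROUPS = ["PACK", "no_virus"]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    counter = 0

    def simulate(group, treatment, session, animal, rep):
        nonlocal counter
        seed = (MASTER_SEED + 1009 * counter) % (2 ** 31)
        counter += 1
        cfg = default_config(group, treatment, session, layout=LAYOUT,
                             fs_raw=FS_RAW, seed=seed)
        rec, _ = simulate_experiment(cfg)
        stem = f"{group}_{treatment}_a{animal}_{session.replace('.', '')}_r{rep}"
        write_recording(rec, OUT / f"{stem}.edf", OUT / f"{stem}.csv")
        rows.append({"group": group, "treatment": treatment,
                     "session_type": session, "animal": animal,
                     "replicate": rep, "seed": seed, "stem": stem,
                     "n_gs": len(rec.annotations.intervals("GS"))})

    for animal in range(N_ANIMALS):
        for session in SALINE_SESSIONS:
            for rep in range(N_REPLICATES):
                simulate("PACK", "saline", session, animal, rep)
    for group in KAINATE_GROUPS:
        for animal in range(2):
            simulate(group, "kainate", "ref", animal, 0)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(RESULTS / "cohort_manifest.csv", index=False)
    print(f"wrote {len(rows)} sessions to {OUT}")
    print(f"generalized seizures per group:\n"
          f"{manifest.groupby('group')['n_gs'].sum().to_string()}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
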