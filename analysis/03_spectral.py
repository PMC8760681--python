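"""Hour-wise band-power (delta/theta/beta/gamma AUC) analysis.

Welch PSDs at raw rate per analysis hour, band AUCs referenced to hour 1.
Writes results/band_power.csv and prints the per-band decline, which
mirrors the line-length habituation (all bands fall over the session) and
the additional suppression during the 0.1-Hz light-ON hour.
"""

import sys
from pathlib import Path

import pandas as pd

from optolfp.io_core import SessionLayout, read_recording
from optolfp.preprocess import build_mask
from optolfp.spectral import hourly_band_power

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
LAYOUT = SessionLayout(hour_s=600.0, fadeoff_s=100.0)


def main():
    manifest = pd.read_csv(RESULTS / "cohort_manifest.csv")
    saline = manifest[manifest["treatment"] == "saline"]
    rows = []
    for _, row in saline.iterrows():
        rec = read_recording(COHORT / f"{row.stem}.edf",
                             COHORT / f"{row.stem}.csv")
        sig = build_mask(rec, channel="right")  # spectra on raw-rate data
        bp = hourly_band_power(sig, LAYOUT, stim=row.session_type != "ref")
        for h, bands in bp.hours.items():
            for band, auc in bands.items():
                rows.append({**row.to_dict(), "hour": h, "band": band,
                             "auc": auc, "delta": bp.deltas[h][band]})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "band_power.csv", index=False)
    print("mean band AUC (mV^2) by session type and hour:")
    print(df.groupby(["session_type", "band", "hour"])["auc"].mean()
          .unstack().round(4).to_string())
    ref = df[(df["session_type"] == "ref") & (df["hour"] > 1)]
    print("\nmean AUC change vs hour 1 in reference sessions:")
    print(ref.groupby(["band", "hour"])["delta"].mean().unstack()
          .round(4).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
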