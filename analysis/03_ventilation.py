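#!/usr/bin/env python
"""Ventilation-volume proxy: VRMG tables and per-trial plateau fits.

Builds VRMG (ventilation rate x relative mouth gape) for every observed
window, normalises it to the trial maximum, and fits the two-segment
plateau model of log MO2 on normalised VRMG for trials with >= 30%
ventilation coverage.  A high-VRMG slope far below the low-VRMG slope is
the plateau signature: oxygen utilisation falls as ventilation volume
rises.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from cobia_resp.summary_io import analyze_ventilation

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pd.read_csv(RESULTS / "mo2_records.csv")
    vent_rows, seg_rows = [], []
    plateaus = fitted = 0
    for tdir in sorted((RESULTS / "trials").iterdir()):
        rec = records[records["trial_id"] == tdir.name]
        vent_raw = pd.read_csv(tdir / "ventilation.csv")
        va = analyze_ventilation(rec.reset_index(drop=True), vent_raw)
        obs = va.obs.copy()
        obs.insert(0, "trial_id", tdir.name)
        vent_rows.append(obs)
        if va.segmented is None:
            print(f"{tdir.name}: coverage {va.coverage:.2f} -> no segmented fit")
            continue
        fitted += 1
        s = va.segmented
        plateau = s.slope_high < 0.25 * s.slope_low
        plateaus += plateau
        seg_rows.append(
            dict(trial_id=tdir.name, coverage=va.coverage,
                 n_pairs=va.n_pairs, ols_slope=va.ols_slope, **asdict(s))
        )
        print(
            f"{tdir.name}: coverage {va.coverage:.2f}, breakpoint "
            f"{s.breakpoint:.2f}, slopes {s.slope_low:.2f} -> {s.slope_high:.2f}"
            f" ({'plateau' if plateau else 'no plateau'})"
        )
    pd.concat(vent_rows, ignore_index=True).to_csv(
        RESULTS / "ventilation.csv", index=False
    )
    pd.DataFrame(seg_rows).to_csv(RESULTS / "segmented_fits.csv", index=False)
    print(
        f"\nplateau (high slope < 25% of low slope) in {plateaus}/{fitted} "
        f"fitted trials"
    )


if __name__ == "__main__":
    main()
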