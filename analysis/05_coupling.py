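#!/usr/bin/env python
"""Alpha / high-gamma coupling per region across the 89 analysis epochs.

Aggregates the 5 ms high-gamma grid onto the 25 ms alpha epochs and
correlates the two region-mean percent-change series; regions injected
with anti-phased modulations should show strongly negative Pearson r.
"""

from pathlib import Path

import pandas as pd

from study_scenario import scenario
from dyntract.coupling import roi_coupling
from dyntract.spectral import ALPHA, HIGH_GAMMA, band_percent_change
from dyntract.synth import schedule_events, synthesize_recording

RESULTS = Path("results")


def main() -> None:
    cfg = scenario()
    events = schedule_events(cfg)
    rec, _ = synthesize_recording(cfg, events)
    sites = [c.site_id for c in cfg.channels]
    electrodes = cfg.electrode_frame()

    frames = []
    for mark in ("closure_onset", "opening_onset"):
        a = band_percent_change(rec, ALPHA, events, mark, sites=sites)
        g = band_percent_change(rec, HIGH_GAMMA, events, mark, sites=sites)
        frames.append(roi_coupling(a, g, electrodes))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(RESULTS / "coupling.csv", index=False)

    print("Pearson r between alpha and high-gamma percent change (n = 89 epochs):")
    print(table.round(3).to_string(index=False))
    anti = table[table.roi.str.startswith("lateral_occipital")]
    print(f"\nmean r in occipital regions (anti-phased injections): "
          f"{anti.r.mean():.2f}")
    print(f"wrote {RESULTS}/coupling.csv")


if __name__ == "__main__":
    main()
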