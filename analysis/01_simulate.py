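#!/usr/bin/env python
"""Generate the simulated study session: recording, electrodes, ground truth.

Writes the event schedule and electrode table under results/, the raw
recording (HDF5, large) under scratch/, and the injected ground-truth
curves as JSON.
"""

from pathlib import Path

import numpy as np

from study_scenario import scenario
from dyntract import io as dio
from dyntract.synth import schedule_events, synthesize_recording

RESULTS = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    cfg = scenario()
    events = schedule_events(cfg)
    rec, truth = synthesize_recording(cfg, events)

    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    dio.write_events_tsv(events, RESULTS / "events_true.tsv")
    dio.write_electrodes_tsv(cfg.electrode_frame(), RESULTS / "electrodes.tsv")
    truth.to_json(RESULTS / "ground_truth.json")
    dio.write_recording_h5(rec, SCRATCH / "session.h5")

    durs = [e.duration_ms for e in events.of_kind("closure")]
    print(f"simulated {rec.duration_s:.0f} s session, {len(rec.channels)} channels "
          f"at {rec.sampling_rate:.0f} Hz")
    print(f"events: {events.counts()}; median closure duration "
          f"{np.median(durs):.0f} ms (target 176 ms)")
    print(f"injected profiles: {len(cfg.profiles)} across "
          f"{len({p.roi for p in cfg.profiles})} regions")
    print(f"wrote {RESULTS}/events_true.tsv, electrodes.tsv, ground_truth.json; "
          f"recording in {SCRATCH}/session.h5")


if __name__ == "__main__":
    main()
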