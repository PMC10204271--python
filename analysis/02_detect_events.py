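#!/usr/bin/env python
"""Detect eye closure/opening events from the simulated EOG channel.

High-passes the EOG with the 1.0 s time constant, applies the 50 uV
deflection criterion and the 2 s opposite-event exclusion, and compares
the detections with the ground-truth schedule.
"""

from pathlib import Path

import numpy as np

from study_scenario import scenario
from dyntract import io as dio
from dyntract.eog import EOGTrace, detect_events, highpass_time_constant
from dyntract.synth import schedule_events, synthesize_recording

RESULTS = Path("results")


def main() -> None:
    cfg = scenario()
    truth_events = schedule_events(cfg)
    rec_path = Path("scratch/session.h5")
    if rec_path.exists():
        rec = dio.read_recording_h5(rec_path)
    else:
        rec, _ = synthesize_recording(cfg, truth_events)

    trace = highpass_time_constant(EOGTrace(rec.eog(), rec.sampling_rate))
    detected = detect_events(trace, min_per_kind=cfg.n_events_per_kind)
    dio.write_events_tsv(detected, RESULTS / "events_detected.tsv")

    errs = [abs(d.onset_ms - t.onset_ms) for d, t in zip(detected, truth_events)]
    print(f"detected {detected.counts()} vs scheduled {truth_events.counts()}")
    print(f"onset error: median {np.median(errs):.1f} ms, max {max(errs):.1f} ms")
    print(f"insufficient-count flags: {detected.insufficient}")
    print(f"wrote {RESULTS}/events_detected.tsv")


if __name__ == "__main__":
    main()
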