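import numpy as np
import pytest

from dyntract.connectivity import ComodulationEpoch
from dyntract.synth import (
    ModulationProfile,
    SimConfig,
    default_channels,
    schedule_events,
    synthesize_recording,
)


def montage(groups: dict[str, tuple[str, int]]) -> list:
    """Channel table from {roi: (hemisphere, n_sites)}, ROIs spatially separated."""
    from dyntract.synth import ChannelSpec

    channels = []
    for r, (roi, (hemi, n)) in enumerate(groups.items()):
        sign = -1.0 if hemi == "L" else 1.0
        for s in range(n):
            channels.append(
                ChannelSpec(
                    site_id=f"{roi}_s{s}", patient_id=f"P{s % 4}",
                    roi=roi, hemisphere=hemi,
                    x_mm=sign * (30.0 + 5.0 * r), y_mm=-80.0 + 40.0 * r + 2.0 * s,
                    z_mm=5.0 * s,
                    flat_x_mm=10.0 * r + 3.0 * s, flat_y_mm=sign * (5.0 + 4.0 * s),
                )
            )
    return channels


@pytest.fixture(scope="session")
def modulated_run():
    """Small simulated session with +50% alpha injected into one region."""
    cfg = SimConfig(
        n_events_per_kind=8,
        profiles=[
            ModulationProfile("lateral_occipital_L", "alpha", "closure_onset",
                              onset_ms=50.0, duration_ms=1000.0, peak_pct=50.0)
        ],
        seed=3,
    )
    events = schedule_events(cfg)
    rec, truth = synthesize_recording(cfg, events)
    return cfg, events, rec, truth


@pytest.fixture(scope="session")
def null_run():
    """Simulated session with no injected modulation."""
    cfg = SimConfig(n_events_per_kind=8, seed=7)
    events = schedule_events(cfg)
    rec, truth = synthesize_recording(cfg, events)
    return cfg, events, rec, truth


def brute_force_comodulation(
    aug_masks: dict, att_masks: dict, centers_ms, band: str, min_run: int = 8
) -> list[ComodulationEpoch]:
    """Independent oracle: enumerate every pair x window start x bin directly,
    then merge overlapping qualifying windows into maximal epochs."""
    rois = sorted(set(aug_masks) | set(att_masks))
    out = []
    for polarity, masks in (("co-augmentation", aug_masks), ("co-attenuation", att_masks)):
        for i, a in enumerate(rois):
            for b in rois[i + 1:]:
                if a not in masks or b not in masks:
                    continue
                ma = [bool(x) for x in masks[a]]
                mb = [bool(x) for x in masks[b]]
                T = len(ma)
                good_starts = []
                for s in range(T - min_run + 1):
                    ok = True
                    for k in range(s, s + min_run):
                        if not (ma[k] and mb[k]):
                            ok = False
                            break
                    if ok:
                        good_starts.append(s)
                # merge overlapping/adjacent qualifying windows
                merged = []
                for s in good_starts:
                    e = s + min_run - 1
                    if merged and s <= merged[-1][1] + 1:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([s, e])
                for s, e in merged:
                    out.append(
                        ComodulationEpoch(
                            a, b, band, polarity,
                            float(centers_ms[s]), float(centers_ms[e]), e - s + 1,
                        )
                    )
    return out


def epochs_as_set(epochs):
    return {
        (e.roi_a, e.roi_b, e.band, e.polarity, e.start_ms, e.end_ms, e.n_bins)
        for e in epochs
    }
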