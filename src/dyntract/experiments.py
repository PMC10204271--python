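"""Seeded desk-scale experiments used for validation and the analysis scripts.

Each function runs the full pipeline path on generator output with known
ground truth and returns the quantities a replicate is judged on:
parameter recovery of an injected alpha augmentation, false-positive
control under the null, alpha/high-gamma coupling recovery, and bootstrap
coverage.  Replicates are ~seconds each so suites of 20 stay in the
minutes range on one CPU.
"""

from __future__ import annotations

import numpy as np

from .coupling import aggregate_gamma_to_epochs, pearson_alpha_gamma
from .eog import EOGTrace, detect_events, highpass_time_constant
from .roi_stats import roi_series, studentized_bootstrap
from .spectral import ALPHA, HIGH_GAMMA, band_percent_change
from .synth import ChannelSpec, ModulationProfile, SimConfig, schedule_events, synthesize_recording

TARGET_ROI = "lateral_occipital_L"
OTHER_ROIS = ("lateral_occipital_R", "pIFG_L", "pIFG_R")


def _montage(target_sites: int = 8, other_sites: int = 4) -> list[ChannelSpec]:
    groups = [(TARGET_ROI, "L", target_sites)] + [
        (r, r[-1], other_sites) for r in OTHER_ROIS
    ]
    channels = []
    for g, (roi, hemi, n) in enumerate(groups):
        sign = -1.0 if hemi == "L" else 1.0
        for s in range(n):
            channels.append(
                ChannelSpec(
                    site_id=f"{roi}_s{s}", patient_id=f"P{s % 4}",
                    roi=roi, hemisphere=hemi,
                    x_mm=sign * (30.0 + 5.0 * g), y_mm=-80.0 + 40.0 * g + 2.0 * s,
                    z_mm=5.0 * s,
                )
            )
    return channels


def alpha_recovery_replicate(
    seed: int,
    n_events: int = 30,
    onset_ms: float = 50.0,
    duration_ms: float = 1000.0,
    peak_pct: float = 50.0,
    level: float = 0.95,
    n_resamples: int = 2000,
) -> dict:
    """Inject +peak% alpha into one region; recover onset, peak and specificity.

    Returns the detected onset error (ms), peak error (percentage points),
    and the list of other regions with any significant run (either
    polarity).  Events are re-detected from the synthesized EOG, so the
    whole detection-to-statistics path is exercised.
    """
    cfg = SimConfig(
        n_events_per_kind=n_events,
        channels=_montage(),
        profiles=[ModulationProfile(TARGET_ROI, "alpha", "closure_onset",
                                    onset_ms, duration_ms, peak_pct)],
        seed=seed,
    )
    truth_events = schedule_events(cfg)
    rec, truth = synthesize_recording(cfg, truth_events)
    trace = highpass_time_constant(EOGTrace(rec.eog(), rec.sampling_rate))
    events = detect_events(trace, min_per_kind=n_events)
    pm = band_percent_change(rec, ALPHA, events, "closure_onset",
                             sites=[c.site_id for c in cfg.channels])
    roi = roi_series(pm, cfg.electrode_frame(), level=level,
                     n_resamples=n_resamples, seed=seed)
    target = roi[roi["roi"] == TARGET_ROI]
    sig = bool(target["sig_aug"].any())
    onset = float(target["onset_ms"].iloc[0]) if sig else np.nan
    peak = float(target["mean"].max())
    others = roi[roi["roi"] != TARGET_ROI]
    false_rois = sorted(
        set(others.loc[others["sig_aug"] | others["sig_att"], "roi"])
    )
    return {
        "target_significant": sig,
        "onset_error_ms": onset - onset_ms if sig else np.nan,
        "peak_error_pct": peak - peak_pct,
        "false_rois": false_rois,
    }


def null_control_replicate(
    seed: int,
    level: float = 0.9999,
    n_resamples: int = 2000,
    bands=("alpha", "high_gamma"),
) -> dict:
    """No injected modulation: count significant cells across regions/bands."""
    from .connectivity import (
        build_dynamic_edges, filter_streamlines, find_comodulation, pair_adjacency,
    )
    from .synth import default_roi_centroids, synthesize_streamlines

    cfg = SimConfig(n_events_per_kind=16, channels=_montage(4, 4), seed=seed)
    events = schedule_events(cfg)
    rec, _ = synthesize_recording(cfg, events)
    centroids = default_roi_centroids(cfg.channels)
    legit, _ = filter_streamlines(synthesize_streamlines(centroids, seed=seed)[0])
    adjacency = pair_adjacency(legit, centroids)
    n_sig = n_edges = 0
    for band in bands:
        spec = ALPHA if band == "alpha" else HIGH_GAMMA
        pm = band_percent_change(rec, spec, events, "closure_onset",
                                 sites=[c.site_id for c in cfg.channels])
        roi = roi_series(pm, cfg.electrode_frame(), level=level,
                         n_resamples=n_resamples, seed=seed)
        n_sig += int(roi["sig_aug"].sum() + roi["sig_att"].sum())
        aug = {r: g.sort_values("time_ms")["sig_aug"].to_numpy()
               for r, g in roi.groupby("roi")}
        att = {r: g.sort_values("time_ms")["sig_att"].to_numpy()
               for r, g in roi.groupby("roi")}
        epochs = find_comodulation(aug, att, pm.grid.analysis_centers, band)
        edges, _ = build_dynamic_edges(epochs, adjacency)
        n_edges += len(edges)
    return {"n_significant_cells": n_sig, "n_edges": n_edges}


def coupling_recovery_replicate(
    seed: int,
    alpha_pct: float = 50.0,
    gamma_pct: float = -15.0,
    n_events: int = 16,
) -> float:
    """Anti-phased alpha/high-gamma injection in one region: Pearson r."""
    cfg = SimConfig(
        n_events_per_kind=n_events,
        channels=_montage(4, 0)[:4],
        profiles=[
            ModulationProfile(TARGET_ROI, "alpha", "closure_onset", 50.0, 1000.0, alpha_pct),
            ModulationProfile(TARGET_ROI, "high_gamma", "closure_onset", 50.0, 1000.0, gamma_pct),
        ],
        seed=seed,
    )
    events = schedule_events(cfg)
    rec, _ = synthesize_recording(cfg, events)
    sites = [c.site_id for c in cfg.channels]
    a_map = band_percent_change(rec, ALPHA, events, "closure_onset", sites=sites)
    g_map = band_percent_change(rec, HIGH_GAMMA, events, "closure_onset", sites=sites)
    a = a_map.values[:, a_map.grid.analysis_mask].mean(axis=0)
    g = g_map.values[:, g_map.grid.analysis_mask].mean(axis=0)
    g25 = aggregate_gamma_to_epochs(
        g, g_map.grid.analysis_centers, a_map.grid.analysis_centers
    )
    return pearson_alpha_gamma(a, g25).r


def bootstrap_coverage(
    seed: int,
    n_datasets: int = 1000,
    n: int = 30,
    level: float = 0.95,
    n_resamples: int = 1000,
) -> float:
    """Empirical coverage of the bootstrap-t interval for a N(0,1) mean."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_datasets):
        v = rng.normal(size=n)
        _, lo, hi = studentized_bootstrap(v, level, n_resamples, seed=rng)
        hits += lo <= 0.0 <= hi
    return hits / n_datasets
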