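"""End-to-end orchestration: events -> spectral maps -> region statistics ->
coupling -> streamline-gated dynamic connectivity.

A single seed fans out to per-stage generators through ``SeedSequence`` so
each stage is individually reproducible; a manifest records configuration,
seeds, library versions and per-stage record counts.  Outputs contain no
timestamps, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .connectivity import (
    ChanceModel, chance_probability, filter_streamlines, find_comodulation,
    pair_adjacency, build_dynamic_edges,
)
from .coupling import roi_coupling
from .eog import EOGTrace, detect_events, highpass_time_constant
from .recording import Recording
from .roi_stats import FlatMapGeometry, distance_shell_profile, roi_series
from .spectral import BANDS, MARKS, EpochGrid, band_percent_change
from .synth import SimConfig, default_roi_centroids, synthesize_recording, synthesize_streamlines

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for one pipeline run.

    Exactly one input source must be given: ``simulate`` (a
    :class:`~dyntract.synth.SimConfig`) or a recording path plus electrode
    table.  Bootstrap and run-length settings default to the study's
    99.99% / 8-bin rule; desk-scale runs usually lower the level and
    resample count.
    """

    simulate: SimConfig | None = None
    recording_path: str | None = None
    electrodes_path: str | None = None
    streamlines_path: str | None = None
    out_dir: str | None = None
    bands: tuple[str, ...] = ("alpha", "high_gamma")
    marks: tuple[str, ...] = MARKS
    level: float = 0.9999
    n_resamples: int = 2000
    min_run: int = 8
    min_sites: int = 4
    eog_threshold_uv: float = 50.0
    eog_separation_s: float = 2.0
    min_events_per_kind: int = 16
    closure_polarity: int = 1
    capture_radius_mm: float = 3.0
    shell_profile: bool = False
    seed: int = 0

    def validate(self) -> None:
        if (self.simulate is None) == (self.recording_path is None):
            raise ValueError(
                "exactly one input source required: set `simulate` or `recording_path`"
            )
        if self.simulate is None and self.electrodes_path is None:
            raise ValueError("`electrodes_path` is required with a real recording")
        for name in ("level",):
            if not 0 < self.level < 1:
                raise ValueError("`level` must lie in (0, 1)")
        for name in ("n_resamples", "min_run", "min_sites", "eog_threshold_uv",
                     "eog_separation_s", "capture_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"`{name}` must be positive")
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")
        unknown = set(self.marks) - set(MARKS)
        if unknown:
            raise ValueError(f"unknown marks {sorted(unknown)}")


def _roi_key(roi: str, hemi: str, ambiguous: set[str]) -> str:
    return f"{roi}/{hemi}" if roi in ambiguous else roi


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every requested band and mark.

    Returns a bundle with the detected events, percent-change maps, region
    series, coupling table, dynamic edge table and manifest; writes them
    under ``config.out_dir`` when set.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_boot = np.random.default_rng(seeds[1])

    # ---- inputs
    if config.simulate is not None:
        sim = config.simulate
        rec, truth = synthesize_recording(sim)
        electrodes = sim.electrode_frame()
        centroids = default_roi_centroids(sim.channels)
        sset, _labels = synthesize_streamlines(centroids, seed=int(seeds[2].generate_state(1)[0] % (2**31)))
    else:
        rec = dio.read_recording_h5(config.recording_path)
        electrodes = dio.read_electrodes_tsv(config.electrodes_path)
        truth = None
        if config.streamlines_path:
            sset = dio.read_streamlines_trk(config.streamlines_path)
            g = electrodes.groupby("roi")[["x_mm", "y_mm", "z_mm"]].mean()
            centroids = {r: g.loc[r].to_numpy(dtype=float) for r in g.index}
        else:
            sset, centroids = None, None

    # ---- events
    if rec.eog_channel is None:
        raise ValueError("events stage: recording has no EOG channel")
    trace = highpass_time_constant(EOGTrace(rec.eog(), rec.sampling_rate))
    events = detect_events(
        trace,
        threshold=config.eog_threshold_uv,
        separation=config.eog_separation_s,
        min_per_kind=config.min_events_per_kind,
        closure_polarity=config.closure_polarity,
    )
    if len(events) == 0:
        raise ValueError("events stage: no eye events detected")
    for kind, flag in events.insufficient.items():
        if flag:
            logger.warning("fewer than %d %s events detected", config.min_events_per_kind, kind)

    sites = [c for c in rec.channels if c != rec.eog_channel]
    dup = electrodes.groupby("roi")["hemisphere"].nunique()
    ambiguous = set(dup[dup > 1].index)

    # ---- spectral + region statistics
    pct_maps, roi_frames, coupling_frames, shell_frames = {}, [], [], []
    for mark in config.marks:
        for band_name in config.bands:
            band = BANDS[band_name]
            pm = band_percent_change(rec, band, events, mark, sites=sites)
            pct_maps[(band_name, mark)] = pm
            roi_frames.append(
                roi_series(
                    pm, electrodes, level=config.level,
                    n_resamples=config.n_resamples, seed=rng_boot,
                    min_sites=config.min_sites, min_run=config.min_run,
                )
            )
            if config.shell_profile and "flat_x_mm" in electrodes:
                shell_frames.append(
                    distance_shell_profile(
                        pm, electrodes, FlatMapGeometry.regular(),
                        level=config.level, n_resamples=config.n_resamples,
                        seed=rng_boot, min_run=config.min_run,
                    ).assign(band=band_name, mark=mark)
                )
        if "alpha" in config.bands and "high_gamma" in config.bands:
            coupling_frames.append(
                roi_coupling(
                    pct_maps[("alpha", mark)], pct_maps[("high_gamma", mark)],
                    electrodes, min_sites=config.min_sites,
                )
            )
    roi_df = pd.concat(roi_frames, ignore_index=True) if roi_frames else pd.DataFrame()
    coupling_df = (
        pd.concat(coupling_frames, ignore_index=True) if coupling_frames else pd.DataFrame()
    )
    shell_df = pd.concat(shell_frames, ignore_index=True) if shell_frames else pd.DataFrame()

    # ---- connectivity
    edge_frames = []
    chance: dict[str, float] = {}
    n_epochs_dropped = 0
    if sset is not None and centroids is not None and not roi_df.empty:
        legit, rejects = filter_streamlines(sset)
        logger.info("streamlines: kept %d of %d", len(legit), len(sset))
        adjacency = pair_adjacency(legit, centroids, config.capture_radius_mm)
        for (band_name, mark) in pct_maps:
            sub = roi_df[(roi_df["band"] == band_name) & (roi_df["mark"] == mark)]
            if sub.empty:
                continue
            aug_masks, att_masks, chis = {}, {}, []
            for (roi, hemi), grp in sub.groupby(["roi", "hemisphere"]):
                grp = grp.sort_values("time_ms")
                key = _roi_key(roi, hemi, ambiguous)
                aug_masks[key] = grp["sig_aug"].to_numpy(dtype=bool)
                att_masks[key] = grp["sig_att"].to_numpy(dtype=bool)
                chis.append(aug_masks[key].mean())
            centers = np.sort(sub["time_ms"].unique())
            epochs = find_comodulation(
                aug_masks, att_masks, centers, band_name, min_run=config.min_run
            )
            edges, dropped = build_dynamic_edges(epochs, adjacency)
            n_epochs_dropped += dropped
            edges["mark"] = mark
            edge_frames.append(edges)
            chance[f"{band_name}:{mark}"] = chance_probability(
                ChanceModel(R=max(len(aug_masks), 2), T=centers.size,
                            L=config.min_run, chi=float(np.mean(chis)))
            )
    edges_df = (
        pd.concat(edge_frames, ignore_index=True) if edge_frames
        else pd.DataFrame(columns=["roi_a", "roi_b", "band", "polarity",
                                   "t_start_ms", "t_end_ms", "n_streamlines", "mark"])
    )

    # ---- manifest + outputs
    import dyntract
    import scipy

    manifest = {
        "seed": config.seed,
        "config": _jsonable(config),
        "versions": {
            "dyntract": dyntract.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "events": events.counts(),
            "events_insufficient": events.insufficient,
            "sites": len(sites),
            "roi_rows": int(len(roi_df)),
            "coupling_rows": int(len(coupling_df)),
            "edges": int(len(edges_df)),
            "comodulation_epochs_without_streamline": n_epochs_dropped,
        },
        "chance_probability": chance,
    }

    bundle = {
        "recording": rec, "events": events, "electrodes": electrodes,
        "pct_maps": pct_maps, "roi_series": roi_df, "coupling": coupling_df,
        "shell_profile": shell_df, "edges": edges_df, "manifest": manifest,
        "ground_truth": truth,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_events_tsv(events, out / "events.tsv")
        dio.write_electrodes_tsv(electrodes, out / "electrodes.tsv")
        roi_df.to_csv(out / "roi_series.csv", index=False)
        coupling_df.to_csv(out / "coupling.csv", index=False)
        if not shell_df.empty:
            shell_df.to_csv(out / "shell_profile.csv", index=False)
        dio.write_edges_csv(edges_df, out / "dynamic_edges.csv")
        step = BANDS[config.bands[0]].bin_width_time_ms if config.bands else 25.0
        dio.write_edges_frames_json(edges_df, out / "dynamic_edges_frames.json", step)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return bundle


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
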