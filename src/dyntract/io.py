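"""Standard-format serialization for every pipeline object.

Recordings go to HDF5; event and electrode tables to TSV; streamlines to
TRK (nibabel) with region masks in a JSON sidecar; percent-change maps to
long CSV or HDF5; dynamic edge tables to CSV and frame-indexed JSON.
Times are ms relative to the event mark, voltages uV, distances mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import nibabel as nib

from .connectivity import BoxMask, StreamlineSet
from .eog import EventSet, EyeEvent
from .recording import Recording
from .spectral import BANDS, EpochGrid, PercentChangeMap

ELECTRODE_COLUMNS = [
    "site_id", "patient_id", "roi", "hemisphere",
    "x_mm", "y_mm", "z_mm", "excluded", "exclusion_reason",
]


# -- recording ---------------------------------------------------------------

def write_recording_h5(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data_uv", data=rec.data, compression="gzip")
        f.attrs["sampling_rate_hz"] = rec.sampling_rate
        f.attrs["eog_channel"] = rec.eog_channel or ""
        f.create_dataset(
            "channels", data=np.array(rec.channels, dtype=h5py.string_dtype())
        )


def read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data_uv"][()]
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        eog = f.attrs["eog_channel"] or None
        return Recording(data, float(f.attrs["sampling_rate_hz"]), channels, eog)


# -- events ------------------------------------------------------------------

def write_events_tsv(events: EventSet, path) -> None:
    df = pd.DataFrame(
        [{"kind": e.kind, "onset_ms": e.onset_ms, "offset_ms": e.offset_ms} for e in events]
    )
    if df.empty:
        df = pd.DataFrame(columns=["kind", "onset_ms", "offset_ms"])
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> EventSet:
    df = pd.read_csv(path, sep="\t")
    try:
        evs = [EyeEvent(r.kind, float(r.onset_ms), float(r.offset_ms)) for r in df.itertuples()]
    except (AttributeError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed event TSV {path}: {exc}") from exc
    return EventSet(evs)


# -- electrodes --------------------------------------------------------------

def write_electrodes_tsv(electrodes: pd.DataFrame, path) -> None:
    cols = [c for c in ELECTRODE_COLUMNS if c in electrodes.columns]
    extra = [c for c in electrodes.columns if c not in cols]
    electrodes[cols + extra].to_csv(path, sep="\t", index=False)


def read_electrodes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("site_id", "roi", "hemisphere", "excluded") if c not in df.columns]
    if missing:
        raise ValueError(f"electrode TSV {path} lacks columns {missing}")
    df["exclusion_reason"] = df.get("exclusion_reason", "").fillna("") if "exclusion_reason" in df else ""
    return df


# -- streamlines -------------------------------------------------------------

def write_streamlines_trk(sset: StreamlineSet, path) -> None:
    """TRK with per-vertex quantitative anisotropy; masks in a JSON sidecar."""
    tractogram = nib.streamlines.Tractogram(
        streamlines=[s.astype(np.float32) for s in sset.streamlines],
        data_per_point={"qa": [q.astype(np.float32)[:, None] for q in sset.qa]},
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))
    sidecar = {
        "parenchyma": _box_dict(sset.parenchyma),
        "exclusion_masks": [_box_dict(m) for m in sset.exclusion_masks],
    }
    Path(str(path) + ".masks.json").write_text(json.dumps(sidecar, indent=1))


def _box_dict(mask: BoxMask | None):
    if mask is None:
        return None
    return {"name": mask.name, "lo": list(mask.lo), "hi": list(mask.hi)}


def _box_from(d) -> BoxMask | None:
    if d is None:
        return None
    return BoxMask(d["name"], tuple(d["lo"]), tuple(d["hi"]))


def read_streamlines_trk(path) -> StreamlineSet:
    try:
        trk = nib.streamlines.load(str(path))
    except Exception as exc:
        raise ValueError(f"unreadable TRK file {path}: {exc}") from exc
    tg = trk.tractogram
    streamlines = [np.asarray(s, dtype=float) for s in tg.streamlines]
    if "qa" in tg.data_per_point:
        qa = [np.asarray(q, dtype=float).ravel() for q in tg.data_per_point["qa"]]
    else:
        qa = [np.zeros(len(s)) for s in streamlines]
    parenchyma, masks = None, []
    sidecar = Path(str(path) + ".masks.json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        parenchyma = _box_from(d.get("parenchyma"))
        masks = [_box_from(m) for m in d.get("exclusion_masks", [])]
    return StreamlineSet(streamlines, qa, parenchyma, masks)


# -- percent-change maps -----------------------------------------------------

def write_pct_map_csv(pct_map: PercentChangeMap, path) -> None:
    pct_map.to_frame().to_csv(path, index=False)


def write_pct_map_h5(pct_map: PercentChangeMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values_pct", data=pct_map.values)
        f.create_dataset("sites", data=np.array(pct_map.sites, dtype=h5py.string_dtype()))
        f.attrs["band"] = pct_map.band
        f.attrs["mark"] = pct_map.mark
        f.attrs["bin_width_ms"] = pct_map.grid.bin_width_ms
        f.attrs["n_trials"] = pct_map.n_trials
        f.attrs["n_dropped"] = pct_map.n_dropped


def read_pct_map_h5(path) -> PercentChangeMap:
    with h5py.File(path, "r") as f:
        band = f.attrs["band"]
        grid = EpochGrid(bin_width_ms=float(f.attrs["bin_width_ms"]))
        sites = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sites"][()]]
        return PercentChangeMap(
            band=str(band), mark=str(f.attrs["mark"]), sites=sites, grid=grid,
            values=f["values_pct"][()], n_trials=int(f.attrs["n_trials"]),
            n_dropped=int(f.attrs["n_dropped"]),
        )


# -- generic write-then-read -------------------------------------------------

def roundtrip(obj, path):
    """Write ``obj`` to ``path`` in its standard format and read it back."""
    if isinstance(obj, Recording):
        write_recording_h5(obj, path)
        return read_recording_h5(path)
    if isinstance(obj, EventSet):
        write_events_tsv(obj, path)
        return read_events_tsv(path)
    if isinstance(obj, PercentChangeMap):
        write_pct_map_h5(obj, path)
        return read_pct_map_h5(path)
    if isinstance(obj, StreamlineSet):
        write_streamlines_trk(obj, path)
        return read_streamlines_trk(path)
    if isinstance(obj, pd.DataFrame):
        write_electrodes_tsv(obj, path)
        return read_electrodes_tsv(path)
    raise TypeError(f"no serializer for {type(obj).__name__}")


# -- dynamic edges -----------------------------------------------------------

def write_edges_csv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, index=False)


def write_edges_frames_json(edges: pd.DataFrame, path, step_ms: float) -> None:
    """Frame-indexed JSON for animation front-ends: one frame per window start."""
    frames: dict[str, list] = {}
    for row in edges.itertuples():
        t = row.t_start_ms
        while t <= row.t_end_ms:
            frames.setdefault(f"{t:.0f}", []).append(
                {
                    "roi_a": row.roi_a, "roi_b": row.roi_b, "band": row.band,
                    "polarity": row.polarity, "n_streamlines": int(row.n_streamlines),
                }
            )
            t += step_ms
    Path(path).write_text(json.dumps({"step_ms": step_ms, "frames": frames}, indent=1))
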