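"""Synthetic recordings, electrode tables and streamline sets with ground truth.

The generator emulates the statistical structure of the study inputs so the
whole pipeline runs offline: 1000 Hz multi-channel iEEG whose alpha (10 Hz
carrier) and high-gamma (70-110 Hz band-passed noise) components carry
event-locked envelope modulations per region; an EOG channel with >50 uV
deflections spanning each eye closure/opening; spontaneous eye movements
alternating closure/opening with >2 s separation and log-normal durations
matched to the observed medians (176 ms closure, IQR 143-217 ms; 175 ms
opening, IQR 128-215 ms); and white-matter streamline fixtures containing
known legitimacy violators.  Everything is bit-reproducible under a fixed
seed, and the injected percent-change curves are recorded as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .connectivity import BoxMask, StreamlineSet
from .eog import EventSet, EyeEvent
from .recording import Recording
from .spectral import BANDS, MARKS, EpochGrid

_NORMAL_IQR = 1.3489795003921634  # q75 - q25 of the standard normal, in SD units


class ScheduleInfeasibleError(ValueError):
    pass


@dataclass(frozen=True)
class ChannelSpec:
    site_id: str
    patient_id: str
    roi: str
    hemisphere: str
    x_mm: float = 0.0
    y_mm: float = 0.0
    z_mm: float = 0.0
    flat_x_mm: float | None = None
    flat_y_mm: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class ModulationProfile:
    """Event-locked envelope modulation injected into one region and band.

    ``onset_ms`` is relative to the behavioural mark; the percent-change
    envelope ramps up and down as a raised cosine over ``ramp_ms`` and
    plateaus at ``peak_pct`` in between.
    """

    roi: str
    band: str                 # "alpha" | "high_gamma"
    mark: str = "closure_onset"
    onset_ms: float = 50.0
    duration_ms: float = 1000.0
    peak_pct: float = 50.0
    ramp_ms: float = 100.0

    def __post_init__(self):
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {tuple(BANDS)}")
        if self.mark not in MARKS:
            raise ValueError(f"mark must be one of {MARKS}")
        if self.duration_ms < 2 * self.ramp_ms:
            raise ValueError("duration_ms must cover both ramps")

    def shape(self, t_ms: np.ndarray) -> np.ndarray:
        """Envelope weight (0..1) at times relative to the mark, ms."""
        u = np.asarray(t_ms, dtype=float) - self.onset_ms
        w = np.zeros_like(u)
        inside = (u >= 0) & (u <= self.duration_ms)
        ui = u[inside]
        wi = np.ones_like(ui)
        if self.ramp_ms > 0:
            up = ui < self.ramp_ms
            wi[up] = 0.5 * (1 - np.cos(np.pi * ui[up] / self.ramp_ms))
            down = ui > self.duration_ms - self.ramp_ms
            wi[down] = 0.5 * (1 - np.cos(np.pi * (self.duration_ms - ui[down]) / self.ramp_ms))
        w[inside] = wi
        return w


def default_channels(
    rois: dict[str, str] | None = None, sites_per_roi: int = 4
) -> list[ChannelSpec]:
    """A small occipito-frontal montage: ``rois`` maps label -> hemisphere."""
    if rois is None:
        rois = {
            "lateral_occipital_L": "L",
            "lateral_occipital_R": "R",
            "pIFG_L": "L",
            "pIFG_R": "R",
        }
    channels = []
    for r, (roi, hemi) in enumerate(rois.items()):
        sign = -1.0 if hemi == "L" else 1.0
        for s in range(sites_per_roi):
            channels.append(
                ChannelSpec(
                    site_id=f"{roi}_s{s}",
                    patient_id=f"P{s % 4}",
                    roi=roi,
                    hemisphere=hemi,
                    x_mm=sign * (30.0 + 5.0 * r),
                    y_mm=-80.0 + 20.0 * r + 2.0 * s,
                    z_mm=5.0 * s,
                    flat_x_mm=10.0 * r + 3.0 * s,
                    flat_y_mm=sign * (5.0 + 4.0 * s),
                )
            )
    return channels


@dataclass
class SimConfig:
    """Study conditions for the synthetic recording.

    Defaults follow the source cohort: 1000 Hz sampling, at least 16
    spontaneous events per kind, closure durations with median 176 ms
    (IQR 143-217 ms), opening durations with median 175 ms (IQR
    128-215 ms), successive events separated by well over 2 s, and an EOG
    deflection of 100 uV (the detection criterion is 50 uV).
    """

    sampling_rate: float = 1000.0
    n_events_per_kind: int = 16
    closure_duration_median_ms: float = 176.0
    closure_duration_iqr_ms: tuple[float, float] = (143.0, 217.0)
    opening_duration_median_ms: float = 175.0
    opening_duration_iqr_ms: tuple[float, float] = (128.0, 215.0)
    inter_event_gap_s: tuple[float, float] = (2.5, 3.5)
    first_event_s: float = 5.0
    recording_duration_s: float | None = None
    channels: list[ChannelSpec] = field(default_factory=default_channels)
    profiles: list[ModulationProfile] = field(default_factory=list)
    noise_uv: float = 5.0            # broadband 1/f background SD
    alpha_base_uv: float = 10.0      # baseline alpha carrier peak amplitude
    gamma_base_uv: float = 4.0       # baseline high-gamma SD
    eog_deflection_uv: float = 100.0
    eog_noise_uv: float = 5.0
    eog_rise_ms: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_events_per_kind < 0:
            raise ValueError("n_events_per_kind must be non-negative")
        if self.eog_deflection_uv <= 50.0:
            raise ValueError("eog_deflection_uv must exceed the 50 uV criterion")
        if self.inter_event_gap_s[0] <= 2.0:
            raise ValueError("inter-event gap must exceed the 2 s separation rule")
        rois = {c.roi for c in self.channels}
        for p in self.profiles:
            if p.roi not in rois:
                raise ValueError(f"profile references ROI {p.roi!r} absent from channel table")
            if p.onset_ms < -200.0:
                raise ValueError(
                    "profile onset reaches into the baseline window (onset_ms < -200)"
                )

    def electrode_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.channels])


@dataclass
class GroundTruth:
    """Oracle for recovery tests: what was injected, where and when."""

    events: EventSet
    # (roi, band, mark) -> percent change at the band grid's bin centres
    curves: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    streamline_labels: pd.DataFrame | None = None

    def curve(self, roi: str, band: str, mark: str) -> np.ndarray:
        grid = EpochGrid.for_band(BANDS[band])
        return self.curves.get((roi, band, mark), np.zeros(grid.centers.size))

    def to_json(self, path) -> None:
        payload = {
            "events": [
                {"kind": e.kind, "onset_ms": e.onset_ms, "offset_ms": e.offset_ms}
                for e in self.events
            ],
            "curves": [
                {"roi": r, "band": b, "mark": m, "pct": v.tolist()}
                for (r, b, m), v in self.curves.items()
            ],
            "streamline_labels": (
                None if self.streamline_labels is None
                else self.streamline_labels.to_dict(orient="records")
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _lognormal_durations(rng, n: int, median_ms: float, iqr_ms: tuple[float, float]) -> np.ndarray:
    # median and IQR pin the two log-normal parameters exactly
    mu = np.log(median_ms)
    sigma = np.log(iqr_ms[1] / iqr_ms[0]) / _NORMAL_IQR
    return np.exp(rng.normal(mu, sigma, size=n))


def schedule_events(config: SimConfig) -> EventSet:
    """Alternating closure/opening schedule obeying the 2 s separation rule.

    Durations are log-normal, matched to the per-kind median and IQR;
    successive events are separated by a uniform gap drawn from
    ``config.inter_event_gap_s`` (offset to next onset), which exceeds 2 s
    so no event is ever excluded by the separation rule.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_events_per_kind
    if n == 0:
        return EventSet([])
    dur_c = _lognormal_durations(
        rng, n, config.closure_duration_median_ms, config.closure_duration_iqr_ms
    )
    dur_o = _lognormal_durations(
        rng, n, config.opening_duration_median_ms, config.opening_duration_iqr_ms
    )
    events = []
    t = config.first_event_s * 1000.0
    for i in range(n):
        for kind, dur in (("closure", dur_c[i]), ("opening", dur_o[i])):
            events.append(EyeEvent(kind, t, t + dur))
            t = t + dur + rng.uniform(*config.inter_event_gap_s) * 1000.0
    if config.recording_duration_s is not None:
        need = events[-1].offset_ms / 1000.0 + 3.0
        if need > config.recording_duration_s:
            raise ScheduleInfeasibleError(
                f"{2 * n} events with gaps in {config.inter_event_gap_s} s need "
                f">= {need:.1f} s, but recording_duration_s = "
                f"{config.recording_duration_s}"
            )
    return EventSet(events)


def _pink_noise(rng, n: int) -> np.ndarray:
    """Unit-variance noise with a 1/f power spectrum (flat below 0.5 Hz)."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0)), n)
    return x / x.std()


def _envelope(config: SimConfig, events: EventSet, roi: str, band: str,
              n_samples: int) -> np.ndarray:
    """Multiplicative amplitude envelope 1 + pct(t)/100 for one (roi, band)."""
    fs = config.sampling_rate
    env = np.ones(n_samples)
    for p in config.profiles:
        if p.roi != roi or p.band != band:
            continue
        kind, which = p.mark.rsplit("_", 1)
        for e in events.of_kind(kind):
            t_mark = e.onset_ms if which == "onset" else e.offset_ms
            i0 = int(round((t_mark + p.onset_ms) / 1000.0 * fs))
            m = int(round(p.duration_ms / 1000.0 * fs))
            sl = slice(max(i0, 0), min(i0 + m, n_samples))
            if sl.start >= sl.stop:
                continue
            t_rel = np.arange(sl.start - i0, sl.stop - i0) / fs * 1000.0 + p.onset_ms
            env[sl] += p.peak_pct / 100.0 * p.shape(t_rel)
    return env


def _eog_trace(config: SimConfig, events: EventSet, n_samples: int, rng) -> np.ndarray:
    """Sub-threshold noise plus a monophasic trapezoidal deflection per event."""
    fs = config.sampling_rate
    sos = butter(4, 30.0, btype="low", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n_samples))
    x *= config.eog_noise_uv / x.std()
    rise = config.eog_rise_ms
    for e in events:
        sign = 1.0 if e.kind == "closure" else -1.0
        i0 = int(round(e.onset_ms / 1000.0 * fs))
        i1 = int(round(e.offset_ms / 1000.0 * fs))
        i1 = min(i1, n_samples)
        if i0 >= n_samples:
            continue
        t = np.arange(i0, i1) / fs * 1000.0 - e.onset_ms
        dur = e.offset_ms - e.onset_ms
        w = np.minimum(1.0, np.minimum(t / rise, (dur - t) / rise))
        x[i0:i1] += sign * config.eog_deflection_uv * np.clip(w, 0.0, 1.0)
    return x


def synthesize_recording(
    config: SimConfig, events: EventSet | None = None
) -> tuple[Recording, GroundTruth]:
    """Generate the multi-channel recording and its ground truth.

    Each iEEG channel is 1/f background noise plus a 10 Hz alpha carrier and
    a 70-110 Hz noise component whose envelopes follow the channel's region
    profiles; the EOG channel carries one supra-threshold deflection per
    event.  Bit-identical under a fixed ``config.seed``.
    """
    config.validate()
    if events is None:
        events = schedule_events(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fs = config.sampling_rate
    if len(events):
        last = max(e.offset_ms for e in events)
    else:
        last = 0.0
    duration_s = config.recording_duration_s or (last / 1000.0 + 5.0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    rois = sorted({c.roi for c in config.channels})
    env = {
        (roi, band): _envelope(config, events, roi, band, n)
        for roi in rois
        for band in ("alpha", "high_gamma")
    }
    sos_gamma = butter(4, [70.0, 110.0], btype="band", fs=fs, output="sos")

    names = [c.site_id for c in config.channels] + ["EOG"]
    data = np.empty((len(names), n))
    for i, ch in enumerate(config.channels):
        bg = config.noise_uv * _pink_noise(rng, n)
        phase = rng.uniform(0, 2 * np.pi)
        alpha = config.alpha_base_uv * env[(ch.roi, "alpha")] * np.sin(
            2 * np.pi * 10.0 * t + phase
        )
        gnoise = sosfiltfilt(sos_gamma, rng.standard_normal(n))
        gnoise /= gnoise.std()
        gamma = config.gamma_base_uv * env[(ch.roi, "high_gamma")] * gnoise
        data[i] = bg + alpha + gamma
    data[-1] = _eog_trace(config, events, n, rng)

    truth = GroundTruth(events=events)
    for p in config.profiles:
        grid = EpochGrid.for_band(BANDS[p.band])
        key = (p.roi, p.band, p.mark)
        cur = truth.curves.get(key, np.zeros(grid.centers.size))
        truth.curves[key] = cur + p.peak_pct * p.shape(grid.centers)
    rec = Recording(data, fs, names, eog_channel="EOG")
    return rec, truth


# ---------------------------------------------------------------------------
# streamline fixtures

def default_roi_centroids(channels: list[ChannelSpec] | None = None) -> dict[str, np.ndarray]:
    """ROI centroid = mean electrode position per ROI of the montage."""
    if channels is None:
        channels = default_channels()
    df = pd.DataFrame([asdict(c) for c in channels])
    g = df.groupby("roi")[["x_mm", "y_mm", "z_mm"]].mean()
    return {roi: g.loc[roi].to_numpy(dtype=float) for roi in g.index}


def _serpentine(start: np.ndarray, length_mm: float, seg_mm: float = 20.0) -> np.ndarray:
    """Zig-zag polyline with 60-degree turns (legitimate bends, long arc)."""
    direction = np.array([1.0, 0.0, 0.0])
    tilt_up = np.array([np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0])
    tilt_dn = np.array([np.cos(np.radians(30)), -np.sin(np.radians(30)), 0.0])
    pts = [start.astype(float)]
    total = 0.0
    k = 0
    while total < length_mm:
        d = tilt_up if k % 2 == 0 else tilt_dn
        pts.append(pts[-1] + seg_mm * d)
        total += seg_mm
        k += 1
    return np.array(pts)


def synthesize_streamlines(
    roi_centroids: dict[str, np.ndarray],
    seed: int = 0,
    qa_valid: float = 0.10,
    include_violators: bool = True,
    n_vertices: int = 21,
    parenchyma: BoxMask | None = None,
    exclusion_masks: list[BoxMask] | None = None,
) -> tuple[StreamlineSet, pd.DataFrame]:
    """Streamline fixture: one valid line per ROI pair plus labeled violators.

    Violators cover every legitimacy criterion: length < 10 mm, length
    > 250 mm, an 80-degree turn, a vertex with quantitative anisotropy
    below 0.05, and a vertex inside an exclusion mask.  The returned label
    table is the ground truth for filter tests.
    """
    names = sorted(roi_centroids)
    if len(names) < 2:
        raise ValueError("need at least 2 ROIs to build streamlines")
    if parenchyma is None:
        parenchyma = BoxMask("parenchyma", (-150.0, -150.0, -150.0), (150.0, 150.0, 150.0))
    if exclusion_masks is None:
        exclusion_masks = [BoxMask("thalamus", (-10.0, -10.0, -10.0), (10.0, 10.0, 10.0))]
    rng = np.random.default_rng(seed)

    streamlines, qa, labels = [], [], []

    def add(v, q, valid, reason, connects=""):
        streamlines.append(np.asarray(v, dtype=float))
        qa.append(np.asarray(q, dtype=float))
        labels.append(
            {"index": len(labels), "valid": valid, "reason": reason, "connects": connects}
        )

    u = np.linspace(0.0, 1.0, n_vertices)[:, None]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p0, p1 = roi_centroids[a], roi_centroids[b]
            line = p0 + u * (p1 - p0)
            # small lateral bow keeps it off the exclusion box between midline pairs
            bow = np.sin(np.pi * u[:, 0])[:, None] * np.array([0.0, 0.0, 25.0])
            v = line + bow
            if np.linalg.norm(p1 - p0) < 10.0:
                v = line  # degenerate montage; leave straight
            add(v, np.full(n_vertices, qa_valid), True, "", f"{a}-{b}")

    if include_violators:
        base = roi_centroids[names[0]]
        short = np.stack([base + (20.0, 0, 0), base + (25.0, 0, 0)])
        add(short, np.full(2, qa_valid), False, "length")

        snake = _serpentine(base + (0, 30.0, 0), 300.0)
        add(snake, np.full(len(snake), qa_valid), False, "length")

        bend = np.stack([
            base + (0, -30.0, 0),
            base + (30.0, -30.0, 0),
            base + (30.0 + 30.0 * np.cos(np.radians(80)), -30.0 + 30.0 * np.sin(np.radians(80)), 0),
        ])
        add(bend, np.full(3, qa_valid), False, "turning angle")

        lowqa = base + u * np.array([100.0, 0.0, 0.0])
        q = np.full(n_vertices, qa_valid)
        q[n_vertices // 2] = 0.02
        add(lowqa, q, False, "qa")

        through = np.stack([np.array([-40.0, 0.0, 0.0]), np.array([0.0, 0.0, 0.0]),
                            np.array([40.0, 0.0, 0.0])])
        add(through, np.full(3, qa_valid), False, f"inside {exclusion_masks[0].name}")

    sset = StreamlineSet(streamlines, qa, parenchyma, list(exclusion_masks))
    return sset, pd.DataFrame(labels)
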