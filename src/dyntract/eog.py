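"""Eye-closure / eye-opening event detection from an EOG trace.

Events are marked on the high-pass-filtered EOG (first-order RC, time
constant 1.0 s) as deflections exceeding 50 microvolts.  A closure event
followed or preceded by an opening within 2 s is discarded (and vice
versa), so that the pre-event baseline and post-event window of each
retained event are uncontaminated by the opposite movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

KINDS = ("closure", "opening")


@dataclass(frozen=True)
class EOGTrace:
    """Single-channel EOG voltage trace in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    time_constant: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class EyeEvent:
    kind: str
    onset_ms: float
    offset_ms: float

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not self.offset_ms > self.onset_ms:
            raise ValueError("offset must follow onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class EventSet:
    """Time-ordered, non-overlapping eye events with per-kind sufficiency flags.

    ``insufficient[kind]`` is True when fewer than the requested minimum
    number of events of that kind survived detection and exclusion; this is
    a cohort-inclusion warning, not an error.
    """

    events: list[EyeEvent] = field(default_factory=list)
    insufficient: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.onset_ms)
        for a, b in zip(self.events, self.events[1:]):
            if b.onset_ms < a.offset_ms:
                raise ValueError("events overlap")

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def of_kind(self, kind: str) -> list[EyeEvent]:
        return [e for e in self.events if e.kind == kind]

    def counts(self) -> dict[str, int]:
        return {k: len(self.of_kind(k)) for k in KINDS}


def highpass_time_constant(trace: EOGTrace) -> EOGTrace:
    """First-order RC high-pass with cutoff ``1/(2*pi*RC)`` Hz.

    A voltage step of height V decays to ``V * exp(-t/RC)``, i.e. to
    V/e one time constant after the step.
    """
    if trace.time_constant <= 0:
        raise ValueError("time_constant must be positive")
    if not np.all(np.isfinite(trace.samples)):
        raise ValueError("EOG trace contains non-finite samples")
    dt = 1.0 / trace.sampling_rate
    a = trace.time_constant / (trace.time_constant + dt)
    # y[n] = a * (y[n-1] + x[n] - x[n-1])
    y = lfilter([a, -a], [1.0, -a], trace.samples)
    return EOGTrace(y, trace.sampling_rate, trace.time_constant)


def _deflections(x: np.ndarray, sampling_rate: float, threshold: float,
                 release: float) -> list[tuple[int, int]]:
    """Supra-threshold intervals with hysteresis: onset at the crossing of
    ``threshold``, offset at the return below ``release``."""
    above = x > threshold
    if not above.any():
        return []
    rising = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    out = []
    last_end = -1
    below = x < release
    for i in rising:
        if i <= last_end:
            continue
        rel = np.flatnonzero(below[i:])
        end = i + int(rel[0]) if rel.size else x.size - 1
        out.append((int(i), end))
        last_end = end
    return out


def detect_events(
    trace: EOGTrace,
    threshold: float = 50.0,
    separation: float = 2.0,
    min_per_kind: int = 16,
    closure_polarity: int = 1,
    release_fraction: float = 0.5,
) -> EventSet:
    """Detect eye closures and openings as supra-threshold EOG deflections.

    Parameters
    ----------
    trace : EOGTrace
        High-pass-filtered EOG (see :func:`highpass_time_constant`).
    threshold : float
        Deflection criterion in microvolts (default 50).
    separation : float
        Events of opposite kind closer than this many seconds are both
        removed.
    min_per_kind : int
        Below this count the kind is flagged insufficient (warning only).
    closure_polarity : {1, -1}
        Sign of the closure deflection on this montage; openings take the
        opposite sign.
    release_fraction : float
        The offset is marked where the deflection returns below
        ``release_fraction * threshold`` (hysteresis against chatter).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if closure_polarity not in (1, -1):
        raise ValueError("closure_polarity must be +1 or -1")
    x = trace.samples
    ms = 1000.0 / trace.sampling_rate
    release = release_fraction * threshold

    raw: list[EyeEvent] = []
    for kind, sign in (("closure", closure_polarity), ("opening", -closure_polarity)):
        for i, j in _deflections(sign * x, trace.sampling_rate, threshold, release):
            raw.append(EyeEvent(kind, i * ms, j * ms))
    raw.sort(key=lambda e: e.onset_ms)

    kept = apply_separation_rule(raw, separation)
    out = EventSet(kept)
    out.insufficient = {k: len(out.of_kind(k)) < min_per_kind for k in KINDS}
    return out


def apply_separation_rule(events: list[EyeEvent], separation: float = 2.0) -> list[EyeEvent]:
    """Drop every closure within ``separation`` seconds of an opening and
    vice versa.

    Proximity is the gap between the two events' [onset, offset] intervals;
    removal is decided on the original set, so both members of a close pair
    are dropped and the rule is idempotent.
    """
    sep_ms = separation * 1000.0
    drop = set()
    for i, a in enumerate(events):
        for j, b in enumerate(events):
            if j <= i or a.kind == b.kind:
                continue
            gap = max(a.onset_ms, b.onset_ms) - min(a.offset_ms, b.offset_ms)
            if gap <= sep_ms:
                drop.add(i)
                drop.add(j)
    return [e for k, e in enumerate(events) if k not in drop]
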