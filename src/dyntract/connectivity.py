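"""Streamline-gated dynamic functional connectivity ("dynamic tractography").

A pair of regions is declared transiently strengthened (weakened) when both
show significant band-amplitude augmentation (attenuation) continuously for
at least the minimum run of time bins — 8 bins, i.e. 200 ms on the 25 ms
alpha grid or 40 ms on the 5 ms high-gamma grid — *and* at least one
legitimate white-matter streamline connects them.  Streamline legitimacy
follows standard deterministic-tractography criteria: minimum quantitative
anisotropy 0.05 at every vertex, maximum turning angle 70 degrees, arc
length 10-250 mm, inside the brain parenchyma and outside the brainstem,
basal ganglia and thalamus.

The analytic chance (Type I error) model for observing co-modulation at one
or more pairs is ``(R/2)(R-1)(T-L+1) * chi^L * chi^L``: unordered pair
count, times window-start count, times the joint probability that two
regions with independent per-bin significance rate ``chi`` are both
significant at all ``L`` bins of a window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# chance-probability model

@dataclass(frozen=True)
class ChanceModel:
    """Parameters of the analytic co-modulation chance probability."""

    R: int = 52          # number of regions
    T: int = 89          # analysis bins in the 2200 ms window
    L: int = 8           # minimum run, bins
    chi: float = 0.0     # mean per-region fraction of significant bins, 0..1

    def __post_init__(self):
        if self.R < 2:
            raise ValueError("R must be at least 2")
        if self.L > self.T:
            raise ValueError("L cannot exceed T")
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")


def chance_probability(model: ChanceModel) -> float:
    """Analytic chance of co-modulation >= L bins at >= 1 region pair."""
    return (
        (model.R / 2.0)
        * (model.R - 1.0)
        * (model.T - model.L + 1.0)
        * model.chi**model.L
        * model.chi**model.L
    )


# ---------------------------------------------------------------------------
# co-modulation epochs

@dataclass(frozen=True)
class ComodulationEpoch:
    """Maximal interval over which two regions are continuously co-significant."""

    roi_a: str
    roi_b: str
    band: str
    polarity: str          # "co-augmentation" | "co-attenuation"
    start_ms: float
    end_ms: float          # centre of the last bin of the run
    n_bins: int


def _maximal_runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of maximal True runs >= min_run."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s + 1 >= min_run]


def find_comodulation(
    aug_masks: dict[str, np.ndarray],
    att_masks: dict[str, np.ndarray],
    centers_ms: np.ndarray,
    band: str,
    min_run: int = 8,
) -> list[ComodulationEpoch]:
    """Co-modulation epochs for every unordered region pair.

    For each pair and polarity, the two masks are intersected and maximal
    runs of at least ``min_run`` bins are emitted (equivalently: all
    qualifying ``min_run``-bin sliding windows, merged).
    """
    rois = sorted(set(aug_masks) | set(att_masks))
    centers_ms = np.asarray(centers_ms, dtype=float)
    epochs: list[ComodulationEpoch] = []
    for polarity, masks in (("co-augmentation", aug_masks), ("co-attenuation", att_masks)):
        for i, a in enumerate(rois):
            for b in rois[i + 1:]:
                if a not in masks or b not in masks:
                    continue
                both = np.asarray(masks[a], dtype=bool) & np.asarray(masks[b], dtype=bool)
                for s, e in _maximal_runs(both, min_run):
                    epochs.append(
                        ComodulationEpoch(
                            a, b, band, polarity,
                            float(centers_ms[s]), float(centers_ms[e]), e - s + 1,
                        )
                    )
    return epochs


# ---------------------------------------------------------------------------
# streamlines

@dataclass(frozen=True)
class BoxMask:
    """Axis-aligned box in mm, the desk-scale stand-in for a volumetric mask."""

    name: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p <= hi), axis=1)


@dataclass
class StreamlineSet:
    """Polylines in mm with per-vertex quantitative anisotropy and region masks."""

    streamlines: list[np.ndarray]            # each (n_i, 3)
    qa: list[np.ndarray]                     # each (n_i,)
    parenchyma: BoxMask | None = None
    exclusion_masks: list[BoxMask] = field(default_factory=list)

    def __post_init__(self):
        if len(self.streamlines) != len(self.qa):
            raise ValueError("streamlines and qa must be the same length")
        for s, q in zip(self.streamlines, self.qa):
            if s.shape[0] < 2:
                raise ValueError("each streamline needs at least 2 vertices")
            if q.shape[0] != s.shape[0]:
                raise ValueError("qa must be per-vertex")

    def __len__(self):
        return len(self.streamlines)

    def subset(self, idx: list[int]) -> "StreamlineSet":
        return StreamlineSet(
            [self.streamlines[i] for i in idx],
            [self.qa[i] for i in idx],
            self.parenchyma,
            list(self.exclusion_masks),
        )


def streamline_length(vertices: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(vertices, axis=0), axis=1).sum())


def turning_angles_deg(vertices: np.ndarray) -> np.ndarray:
    """Angle between successive segment directions at every interior vertex."""
    seg = np.diff(vertices, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate (coincident-vertex) segment")
    u = seg / norms[:, None]
    cosang = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def classify_streamline(
    vertices: np.ndarray,
    qa: np.ndarray,
    parenchyma: BoxMask | None,
    exclusion_masks: list[BoxMask],
    qa_min: float = 0.05,
    max_turn_deg: float = 70.0,
    len_min_mm: float = 10.0,
    len_max_mm: float = 250.0,
) -> str | None:
    """Reason the streamline is illegitimate, or None if it passes all criteria."""
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    if np.any(seg == 0):
        return "degenerate"
    if np.min(qa) < qa_min:
        return "qa"
    if vertices.shape[0] > 2 and np.max(turning_angles_deg(vertices)) > max_turn_deg:
        return "turning angle"
    length = float(seg.sum())
    if not len_min_mm <= length <= len_max_mm:
        return "length"
    if parenchyma is not None and not parenchyma.contains(vertices).all():
        return "outside parenchyma"
    for mask in exclusion_masks:
        if mask.contains(vertices).any():
            return f"inside {mask.name}"
    return None


def filter_streamlines(
    sset: StreamlineSet,
    qa_min: float = 0.05,
    max_turn_deg: float = 70.0,
    len_min_mm: float = 10.0,
    len_max_mm: float = 250.0,
) -> tuple[StreamlineSet, pd.DataFrame]:
    """Keep legitimate streamlines; report a per-streamline verdict table.

    Returns the retained subset and a DataFrame with columns
    ``index, kept, reason`` (reason empty for kept streamlines).
    """
    kept, rows = [], []
    for i, (v, q) in enumerate(zip(sset.streamlines, sset.qa)):
        reason = classify_streamline(
            v, q, sset.parenchyma, sset.exclusion_masks,
            qa_min, max_turn_deg, len_min_mm, len_max_mm,
        )
        if reason is None:
            kept.append(i)
        rows.append({"index": i, "kept": reason is None, "reason": reason or ""})
    return sset.subset(kept), pd.DataFrame(rows)


def pair_adjacency(
    legit: StreamlineSet,
    roi_centroids: dict[str, np.ndarray],
    capture_radius_mm: float = 3.0,
) -> dict[tuple[str, str], int]:
    """ROI pairs connected by >= 1 legitimate streamline, with streamline counts.

    Each endpoint is assigned to the nearest ROI centroid within the capture
    radius; streamlines with an unassignable endpoint, or with both
    endpoints in the same ROI, contribute no pair.
    """
    names = list(roi_centroids)
    if len(names) < 2:
        raise ValueError("need at least 2 ROIs for adjacency")
    cents = np.array([roi_centroids[n] for n in names], dtype=float)

    def assign(p: np.ndarray) -> str | None:
        d = np.linalg.norm(cents - p, axis=1)
        k = int(np.argmin(d))
        return names[k] if d[k] <= capture_radius_mm else None

    counts: dict[tuple[str, str], int] = {}
    for v in legit.streamlines:
        a, b = assign(v[0]), assign(v[-1])
        if a is None or b is None or a == b:
            continue
        key = tuple(sorted((a, b)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def build_dynamic_edges(
    epochs: list[ComodulationEpoch],
    adjacency: dict[tuple[str, str], int],
) -> tuple[pd.DataFrame, int]:
    """Edge table: co-modulation epochs whose pair has streamline support.

    Co-augmentation maps to a strengthened edge, co-attenuation to a
    weakened one; epochs whose pair lacks a legitimate streamline are
    dropped and counted.
    """
    rows, n_dropped = [], 0
    for ep in epochs:
        key = tuple(sorted((ep.roi_a, ep.roi_b)))
        if key not in adjacency:
            n_dropped += 1
            continue
        rows.append(
            {
                "roi_a": key[0],
                "roi_b": key[1],
                "band": ep.band,
                "polarity": "strengthened" if ep.polarity == "co-augmentation" else "weakened",
                "t_start_ms": ep.start_ms,
                "t_end_ms": ep.end_ms,
                "n_streamlines": adjacency[key],
            }
        )
    cols = ["roi_a", "roi_b", "band", "polarity", "t_start_ms", "t_end_ms", "n_streamlines"]
    return pd.DataFrame(rows, columns=cols), n_dropped
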