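"""Region-level statistics: site selection, studentized bootstrap, run-length
significance and distance-from-calcarine shell profiles.

The unit of resampling is the electrode site within a region (hemispheres
kept separate); an amplitude modulation is declared significant when the
confidence interval excludes the baseline (zero percent change) for at
least eight consecutive time bins — two oscillatory cycles.  The default
99.99% level corresponds to a Bonferroni correction for 500 repeated
comparisons at a family-wise alpha of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import PercentChangeMap

EXCLUSION_REASONS = ("seizure-onset zone", "interictal spikes", "MRI lesion", "artefact")


def bonferroni_comparisons(level: float = 0.9999, family_alpha: float = 0.05) -> float:
    """Number of repeated comparisons for which a CI level is the Bonferroni
    equivalent: ``family_alpha / (1 - level)`` (0.9999 -> 500)."""
    return family_alpha / (1.0 - level)


def select_analysis_sites(
    electrodes: pd.DataFrame, min_sites: int = 4
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop excluded sites; keep regions with enough clean sites.

    Parameters
    ----------
    electrodes : pandas.DataFrame
        One row per site with at least ``site_id, roi, hemisphere,
        excluded`` columns.
    min_sites : int
        A (roi, hemisphere) group enters region-level statistics only with
        at least this many included sites; its sites remain available for
        shell profiles regardless.

    Returns
    -------
    included : pandas.DataFrame
        Rows of non-excluded sites.
    retained : list of (roi, hemisphere)
        Groups eligible for region-level statistics.
    """
    if electrodes.empty:
        raise ValueError("electrode table is empty")
    included = electrodes[~electrodes["excluded"].astype(bool)].copy()
    counts = included.groupby(["roi", "hemisphere"]).size()
    retained = [key for key, n in counts.items() if n >= min_sites]
    return included, retained


def studentized_bootstrap(
    values: np.ndarray,
    level: float = 0.9999,
    n_resamples: int = 100_000,
    seed: int | np.random.Generator | None = None,
    chunk: int = 20000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap-t (studentized) confidence interval for the mean.

    Sites are resampled with replacement; each resample contributes the
    pivot ``t* = (mean* - mean) / se*`` with the analytic standard error of
    the resample, and the interval is ``mean - quantile(t*, .) * se``.  The
    same resample indices serve every time bin, preserving the temporal
    structure of the band.

    Parameters
    ----------
    values : array, shape (n_sites,) or (n_sites, n_bins)
    level : float
        Two-sided confidence level (default 0.9999).
    n_resamples : int
        At least 1000 for stable tail quantiles; use many more for the
        99.99% level.
    seed : int, Generator or None

    Returns
    -------
    mean, lower, upper : arrays of shape () or (n_bins,)
        Degenerate (all-identical) inputs give lower == upper == mean.
    """
    v = np.asarray(values, dtype=float)
    scalar = v.ndim == 1
    if scalar:
        v = v[:, None]
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if n_resamples < 1000:
        raise ValueError("n_resamples must be at least 1000 for stable tail quantiles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mean = v.mean(axis=0)
    se = v.std(axis=0, ddof=1) / np.sqrt(n)

    t_stats = np.empty((n_resamples, v.shape[1]))
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(b, n))
        res = v[idx]                                   # (b, n, T)
        m_star = res.mean(axis=1)
        se_star = res.std(axis=1, ddof=1) / np.sqrt(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (m_star - mean) / se_star
        t[se_star == 0] = 0.0
        t_stats[done:done + b] = t
        done += b

    alpha = 1.0 - level
    q_lo = np.quantile(t_stats, alpha / 2.0, axis=0)
    q_hi = np.quantile(t_stats, 1.0 - alpha / 2.0, axis=0)
    lower = mean - q_hi * se
    upper = mean - q_lo * se
    zero = se == 0
    lower[zero] = mean[zero]
    upper[zero] = mean[zero]
    if scalar:
        return float(mean[0]), float(lower[0]), float(upper[0])
    return mean, lower, upper


def _run_mask(condition: np.ndarray, min_run: int) -> np.ndarray:
    """True only within maximal runs of at least ``min_run`` bins."""
    from .connectivity import _maximal_runs

    out = np.zeros(condition.size, dtype=bool)
    for s, e in _maximal_runs(condition, min_run):
        out[s:e + 1] = True
    return out


@dataclass
class SignificanceResult:
    aug_mask: np.ndarray
    att_mask: np.ndarray
    onset_ms: float | None
    onset_aug_ms: float | None
    onset_att_ms: float | None


def detect_significant_runs(
    lower: np.ndarray,
    upper: np.ndarray,
    centers_ms: np.ndarray,
    min_run: int = 8,
) -> SignificanceResult:
    """Run-length significance: CI excluding zero for >= min_run consecutive bins.

    Augmentation requires the lower bound above baseline (zero), attenuation
    the upper bound below; runs shorter than ``min_run`` are discarded
    entirely.  The onset latency is the centre of the first bin of the
    earliest surviving run.
    """
    centers_ms = np.asarray(centers_ms, dtype=float)
    aug = _run_mask(np.asarray(lower) > 0.0, min_run)
    att = _run_mask(np.asarray(upper) < 0.0, min_run)

    def first(mask):
        idx = np.flatnonzero(mask)
        return float(centers_ms[idx[0]]) if idx.size else None

    on_aug, on_att = first(aug), first(att)
    onsets = [x for x in (on_aug, on_att) if x is not None]
    return SignificanceResult(aug, att, min(onsets) if onsets else None, on_aug, on_att)


def roi_series(
    pct_map: PercentChangeMap,
    electrodes: pd.DataFrame,
    level: float = 0.9999,
    n_resamples: int = 100_000,
    seed: int | np.random.Generator | None = None,
    min_sites: int = 4,
    min_run: int = 8,
) -> pd.DataFrame:
    """Per-region bootstrap mean, CI and significance masks on the analysis grid.

    Returns a long DataFrame with columns ``roi, hemisphere, band, mark,
    time_ms, mean, lo, hi, sig_aug, sig_att, onset_ms, n_sites``.
    """
    included, retained = select_analysis_sites(electrodes, min_sites)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = pct_map.grid.analysis_centers
    frames = []
    for roi, hemi in retained:
        sites = included[(included["roi"] == roi) & (included["hemisphere"] == hemi)][
            "site_id"
        ].tolist()
        sites = [s for s in sites if s in pct_map.sites]
        if len(sites) < min_sites:
            continue
        vals = np.stack([pct_map.site_values(s) for s in sites])[:, pct_map.grid.analysis_mask]
        mean, lo, hi = studentized_bootstrap(vals, level, n_resamples, rng)
        sig = detect_significant_runs(lo, hi, centers, min_run)
        frames.append(
            pd.DataFrame(
                {
                    "roi": roi,
                    "hemisphere": hemi,
                    "band": pct_map.band,
                    "mark": pct_map.mark,
                    "time_ms": centers,
                    "mean": mean,
                    "lo": lo,
                    "hi": hi,
                    "sig_aug": sig.aug_mask,
                    "sig_att": sig.att_mask,
                    "onset_ms": sig.onset_ms if sig.onset_ms is not None else np.nan,
                    "n_sites": len(sites),
                }
            )
        )
    cols = ["roi", "hemisphere", "band", "mark", "time_ms", "mean", "lo", "hi",
            "sig_aug", "sig_att", "onset_ms", "n_sites"]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# distance-from-calcarine shell profiles

@dataclass(frozen=True)
class FlatMapGeometry:
    """Flattened-surface geometry for the shell analysis.

    ``mesh_points`` are 2-D flat-map coordinates in mm in a frame where the
    calcarine sulcus is the x-axis (distance to the calcarine is ``|y|``)
    and the lateral-sulcus boundary the origin line: points with y < 0 are
    ventral, y > 0 dorsal.
    """

    mesh_points: np.ndarray  # (M, 2) mm

    def distance_mm(self) -> np.ndarray:
        return np.abs(self.mesh_points[:, 1])

    def side(self) -> np.ndarray:
        return np.where(self.mesh_points[:, 1] < 0, "Ventral", "Dorsal")

    @classmethod
    def regular(cls, extent_mm: float = 50.0, spacing_mm: float = 2.0) -> "FlatMapGeometry":
        g = np.arange(-extent_mm, extent_mm + spacing_mm / 2, spacing_mm)
        xx, yy = np.meshgrid(g, g)
        return cls(np.column_stack([xx.ravel(), yy.ravel()]))


def distance_shell_profile(
    pct_map: PercentChangeMap,
    electrodes: pd.DataFrame,
    geometry: FlatMapGeometry,
    interp_radius_mm: float = 10.0,
    shell_width_mm: float = 10.0,
    level: float = 0.9999,
    n_resamples: int = 100_000,
    seed: int | np.random.Generator | None = None,
    min_run: int = 8,
) -> pd.DataFrame:
    """Amplitude modulation by 10 mm distance band from the calcarine sulcus.

    Each mesh point takes the mean value of the electrodes within
    ``interp_radius_mm`` (flat-map Euclidean distance); mesh points are
    grouped into (Ventral/Dorsal, 10 mm band) shells, the shell value being
    the mean over its covered mesh points.  Shells with no covered mesh
    point are reported with NaN values (missing, not zero).  Significance
    per shell comes from the studentized bootstrap over the contributing
    electrodes with the run-length rule.
    """
    included = electrodes[~electrodes["excluded"].astype(bool)]
    included = included[included["site_id"].isin(pct_map.sites)]
    included = included.dropna(subset=["flat_x_mm", "flat_y_mm"])
    if included.empty:
        raise ValueError("no included electrodes with flat-map coordinates")
    epos = included[["flat_x_mm", "flat_y_mm"]].to_numpy(dtype=float)
    evals = np.stack([pct_map.site_values(s) for s in included["site_id"]])
    evals = evals[:, pct_map.grid.analysis_mask]
    centers = pct_map.grid.analysis_centers
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mesh = geometry.mesh_points
    d2 = ((mesh[:, None, :] - epos[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= interp_radius_mm**2          # (M, E)
    covered = within.any(axis=1)
    weights = within / np.maximum(within.sum(axis=1, keepdims=True), 1)
    mesh_vals = weights @ evals                  # (M, T); rows of uncovered points are 0

    side = geometry.side()
    band_idx = np.floor(geometry.distance_mm() / shell_width_mm).astype(int)
    rows = []
    for s in ("Ventral", "Dorsal"):
        for b in range(int(band_idx.max()) + 1):
            in_shell = (side == s) & (band_idx == b)
            if not in_shell.any():
                continue
            lo_mm, hi_mm = b * shell_width_mm, (b + 1) * shell_width_mm
            label = f"{s}_{lo_mm:.0f}-{hi_mm:.0f}mm"
            cov = in_shell & covered
            if not cov.any():
                rows.append(
                    pd.DataFrame(
                        {
                            "shell": label, "side": s, "dist_lo_mm": lo_mm,
                            "dist_hi_mm": hi_mm, "time_ms": centers,
                            "value": np.nan, "sig_aug": False, "sig_att": False,
                            "n_electrodes": 0, "covered": False,
                        }
                    )
                )
                continue
            shell_vals = mesh_vals[cov].mean(axis=0)
            contrib = within[cov].any(axis=0)
            n_e = int(contrib.sum())
            if n_e >= 2:
                _, lo, hi = studentized_bootstrap(evals[contrib], level, n_resamples, rng)
                sig = detect_significant_runs(lo, hi, centers, min_run)
                aug, att = sig.aug_mask, sig.att_mask
            else:
                aug = att = np.zeros(centers.size, dtype=bool)
            rows.append(
                pd.DataFrame(
                    {
                        "shell": label, "side": s, "dist_lo_mm": lo_mm,
                        "dist_hi_mm": hi_mm, "time_ms": centers,
                        "value": shell_vals, "sig_aug": aug, "sig_att": att,
                        "n_electrodes": n_e, "covered": True,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
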