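"""Alpha / high-gamma temporal coupling per region.

The two bands live on different time grids (25 ms vs 5 ms bins); high-gamma
percent change is first aggregated onto the 89-epoch 25 ms grid, then the
hypothesis that alpha augmentation co-occurs with high-gamma attenuation
(or vice versa) is tested with a Pearson correlation across the 89 epochs
between -200 and +2000 ms, with a two-sided p-value from the exact t
transform on n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CouplingResult:
    r: float
    p: float
    n: int
    valid: bool = True


def aggregate_gamma_to_epochs(
    gamma_values: np.ndarray,
    fine_centers_ms: np.ndarray,
    coarse_centers_ms: np.ndarray,
    half_width_ms: float = 12.5,
) -> np.ndarray:
    """Average 5 ms bins onto the 25 ms epoch grid.

    Each epoch takes the mean of the fine bins whose centres fall within
    ``half_width_ms`` of the epoch centre; edge epochs use the fine bins
    that exist.
    """
    g = np.asarray(gamma_values, dtype=float)
    fine = np.asarray(fine_centers_ms, dtype=float)
    coarse = np.asarray(coarse_centers_ms, dtype=float)
    if g.shape[-1] != fine.size:
        raise ValueError("gamma values and fine grid lengths differ")
    step = np.diff(fine)
    if step.size and not np.allclose(step, step[0]):
        raise ValueError("fine grid is not uniform")
    # alignment: every coarse centre must sit on the fine lattice
    if fine.size > 1:
        off = (coarse - fine[0]) / step[0]
        if not np.allclose(off, np.round(off)):
            raise ValueError("25 ms epoch grid is not aligned with the 5 ms grid")
    out = np.empty(coarse.size)
    for j, c in enumerate(coarse):
        sel = np.abs(fine - c) <= half_width_ms + 1e-9
        if not sel.any():
            raise ValueError(f"no fine bins near epoch centre {c} ms")
        out[j] = g[sel].mean()
    return out


def pearson_alpha_gamma(alpha_epochs: np.ndarray, gamma_epochs: np.ndarray) -> CouplingResult:
    """Pearson correlation between band percent-change series."""
    a = np.asarray(alpha_epochs, dtype=float)
    g = np.asarray(gamma_epochs, dtype=float)
    if a.shape != g.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 epochs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(g))):
        raise ValueError("series must be finite")
    if np.ptp(a) == 0 or np.ptp(g) == 0:
        return CouplingResult(np.nan, np.nan, a.size, valid=False)
    res = stats.pearsonr(a, g)
    return CouplingResult(float(res.statistic), float(res.pvalue), a.size)


def roi_coupling(
    alpha_map,
    gamma_map,
    electrodes: pd.DataFrame,
    min_sites: int = 4,
) -> pd.DataFrame:
    """Per-(roi, hemisphere) coupling between the region-mean band series.

    Alpha is taken on its analysis grid; high gamma is aggregated from the
    5 ms grid onto the alpha epochs first.  Returns columns
    ``roi, hemisphere, mark, r, p, n``.
    """
    from .roi_stats import select_analysis_sites

    included, retained = select_analysis_sites(electrodes, min_sites)
    a_centers = alpha_map.grid.analysis_centers
    g_centers = gamma_map.grid.analysis_centers
    rows = []
    for roi, hemi in retained:
        sites = included[(included["roi"] == roi) & (included["hemisphere"] == hemi)][
            "site_id"
        ].tolist()
        sites = [s for s in sites if s in alpha_map.sites and s in gamma_map.sites]
        if len(sites) < min_sites:
            continue
        a = np.stack([alpha_map.site_values(s) for s in sites]).mean(axis=0)
        g = np.stack([gamma_map.site_values(s) for s in sites]).mean(axis=0)
        a = a[alpha_map.grid.analysis_mask]
        g = aggregate_gamma_to_epochs(
            g[gamma_map.grid.analysis_mask], g_centers, a_centers
        )
        res = pearson_alpha_gamma(a, g)
        rows.append(
            {"roi": roi, "hemisphere": hemi, "mark": alpha_map.mark,
             "r": res.r, "p": res.p, "n": res.n}
        )
    return pd.DataFrame(rows, columns=["roi", "hemisphere", "mark", "r", "p", "n"])
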