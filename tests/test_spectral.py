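"""Gaussian kernel design, complex demodulation and percent-change epoching."""

import numpy as np
import pytest

from dyntract.eog import EventSet, EyeEvent
from dyntract.spectral import (
    ALPHA,
    HIGH_GAMMA,
    EpochGrid,
    band_percent_change,
    demodulate,
    design_gaussian_lowpass,
    epoch_percent_change,
    half_power_frequency,
)

FS = 1000.0


# ---------------------------------------------------------------------------
# grid geometry

@pytest.mark.parametrize("band,expected", [(ALPHA, 89), (HIGH_GAMMA, 441)])
def test_analysis_grid_bin_counts(band, expected):
    grid = EpochGrid.for_band(band)
    assert grid.n_analysis == expected
    assert grid.analysis_centers[0] == -200.0
    assert grid.analysis_centers[-1] == 2000.0


def test_frequency_bin_centers():
    assert ALPHA.freq_centers.tolist() == [9.0, 11.0]
    assert HIGH_GAMMA.freq_centers.tolist() == [75.0, 85.0, 95.0, 105.0]


# ---------------------------------------------------------------------------
# kernel

def test_kernel_time_domain_half_power():
    k = design_gaussian_lowpass(39.4, FS)
    t_ms = (np.arange(k.size) - k.size // 2) / FS * 1000.0
    power = (k / k.max()) ** 2
    crossing = np.interp(39.4, t_ms[t_ms >= 0], power[t_ms >= 0])
    assert crossing == pytest.approx(0.5, abs=0.01)


@pytest.mark.parametrize(
    "t_h_ms,f_h_expected,tol",
    [
        (39.4, 2.8, 0.05),       # alpha resolution pair
        (7.9, 13.97, 0.15),      # ln2/(2 pi t_h); the printed 14.2 Hz is ~2% off duality
    ],
)
def test_time_frequency_duality(t_h_ms, f_h_expected, tol):
    k = design_gaussian_lowpass(t_h_ms, FS)
    assert half_power_frequency(k, FS) == pytest.approx(f_h_expected, abs=tol)


def test_doubling_time_halves_frequency():
    f1 = half_power_frequency(design_gaussian_lowpass(20.0, FS), FS)
    f2 = half_power_frequency(design_gaussian_lowpass(40.0, FS), FS)
    assert f1 / f2 == pytest.approx(2.0, rel=0.01)


def test_kernel_unit_dc_gain():
    assert design_gaussian_lowpass(39.4, FS).sum() == pytest.approx(1.0, abs=1e-12)


def test_kernel_shorter_than_two_samples_raises():
    with pytest.raises(ValueError):
        design_gaussian_lowpass(1.0, FS)


# ---------------------------------------------------------------------------
# demodulation

def test_zero_signal_gives_zero_amplitude():
    k = design_gaussian_lowpass(39.4, FS)
    amp, _ = demodulate(np.zeros(5000), FS, 10.0, k)
    assert np.all(amp == 0.0)


def test_pure_tone_returns_peak_amplitude_any_phase():
    k = design_gaussian_lowpass(39.4, FS)
    t = np.arange(8000) / FS
    steady = []
    for phase in np.linspace(0, 2 * np.pi, 7):
        amp, valid = demodulate(np.sin(2 * np.pi * 10.0 * t + phase), FS, 10.0, k)
        steady.append(amp[valid][1000:-1000])
    steady = np.array(steady)
    assert steady.mean() == pytest.approx(1.0, abs=0.01)
    assert np.ptp(steady.mean(axis=1)) < 0.01  # phase invariance


def test_off_band_tone_is_rejected():
    k = design_gaussian_lowpass(39.4, FS)
    f_h = half_power_frequency(k, FS)
    t = np.arange(8000) / FS
    amp, valid = demodulate(np.sin(2 * np.pi * (10.0 + 3 * f_h) * t), FS, 10.0, k)
    assert amp[valid][1000:-1000].max() <= 0.05


def test_kernel_longer_than_signal_raises():
    k = design_gaussian_lowpass(39.4, FS)
    with pytest.raises(ValueError):
        demodulate(np.zeros(10), FS, 10.0, k)


def test_edge_samples_flagged_unreliable():
    k = design_gaussian_lowpass(39.4, FS)
    _, valid = demodulate(np.zeros(2000), FS, 10.0, k)
    assert not valid[0] and not valid[-1] and valid[k.size // 2 + 1]


# ---------------------------------------------------------------------------
# percent change

ONE_EVENT = EventSet([EyeEvent("closure", 5000.0, 5176.0)])
GRID = EpochGrid.for_band(ALPHA)


def test_constant_amplitude_gives_zero_percent_everywhere():
    amp = np.full(10_000, 3.7)
    pct, n_used, _ = epoch_percent_change(amp, FS, ONE_EVENT, "closure_onset", GRID)
    assert n_used == 1
    np.testing.assert_allclose(pct, 0.0, atol=1e-9)


def test_step_amplitude_gives_50_percent_plateau():
    amp = np.ones(10_000)
    amp[5000:] = 1.5
    pct, _, _ = epoch_percent_change(amp, FS, ONE_EVENT, "closure_onset", GRID)
    c = GRID.centers
    plateau = pct[(c >= 100.0) & (c <= 1900.0)]
    assert np.all(np.abs(plateau - 50.0) < 2.0)
    assert np.all(np.abs(pct[GRID.baseline_mask]) < 1e-9)


def test_baseline_mean_is_exactly_zero():
    rng = np.random.default_rng(0)
    amp = 1.0 + 0.1 * rng.random(10_000)
    pct, _, _ = epoch_percent_change(amp, FS, ONE_EVENT, "closure_onset", GRID)
    assert pct[GRID.baseline_mask].mean() == pytest.approx(0.0, abs=1e-9)


def test_percent_change_invariant_to_rescaling():
    rng = np.random.default_rng(1)
    amp = 1.0 + 0.2 * rng.random(10_000)
    pct1, _, _ = epoch_percent_change(amp, FS, ONE_EVENT, "closure_onset", GRID)
    pct10, _, _ = epoch_percent_change(10.0 * amp, FS, ONE_EVENT, "closure_onset", GRID)
    np.testing.assert_allclose(pct1, pct10, rtol=1e-9)


def test_zero_baseline_raises():
    with pytest.raises(ValueError):
        epoch_percent_change(np.zeros(10_000), FS, ONE_EVENT, "closure_onset", GRID)


def test_events_outside_recording_are_dropped():
    amp = np.ones(10_000)
    amp[5000:] = 2.0
    events = EventSet(
        [EyeEvent("closure", 5000.0, 5176.0), EyeEvent("closure", 9500.0, 9676.0)]
    )
    pct, n_used, n_dropped = epoch_percent_change(amp, FS, events, "closure_onset", GRID)
    assert (n_used, n_dropped) == (1, 1)


def test_all_events_outside_recording_raises():
    events = EventSet([EyeEvent("closure", 100.0, 276.0)])
    with pytest.raises(ValueError):
        epoch_percent_change(np.ones(5000), FS, events, "closure_onset", GRID)


def test_offset_locked_baseline_referenced_to_onset():
    """Baseline normalisation uses the pre-onset window even when epochs are
    aligned to the movement offset."""
    amp = np.ones(12_000)
    amp[5000:] = 1.5  # step at the onset, not the offset
    events = EventSet([EyeEvent("closure", 5000.0, 5200.0)])
    pct, _, _ = epoch_percent_change(amp, FS, events, "closure_offset", GRID)
    c = GRID.centers
    # at the offset mark the amplitude has been 1.5 since onset: +50% vs pre-onset
    plateau = pct[(c >= 100.0) & (c <= 1500.0)]
    assert np.all(np.abs(plateau - 50.0) < 2.0)


def test_map_baseline_zero_on_recording(modulated_run):
    cfg, events, rec, _ = modulated_run
    pm = band_percent_change(rec, ALPHA, events, "closure_onset",
                             sites=[c for c in rec.channels if c != "EOG"][:2])
    base = pm.values[:, pm.grid.baseline_mask].mean(axis=1)
    np.testing.assert_allclose(base, 0.0, atol=1e-9)
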