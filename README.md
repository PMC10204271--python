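# dyntract

Time-resolved analysis of eye-movement-related intracranial EEG band
amplitudes and their conversion into streamline-gated dynamic
functional-connectivity edge tables ("dynamic tractography").

## The problem

When the eyes close, the posterior dominant rhythm — the 8–12 Hz alpha
oscillation of occipital cortex — surges; when they open, it collapses and
broadband high-gamma activity (70–110 Hz), a marker of local cortical
activation, rises. This package implements the full analysis chain that
turns raw intracranial EEG + electro-oculography recordings of spontaneous
eye closures and openings into:

1. event-locked **percent-change maps** of alpha and high-gamma amplitude
   per electrode site,
2. region-level **significance time courses** (studentized-bootstrap
   confidence bands with a run-length criterion),
3. **alpha/high-gamma coupling** statistics per region, and
4. a time-resolved **edge table** of strengthened/weakened connections
   between region pairs, gated by legitimate white-matter streamlines.

Because clinical recordings of this kind are not publicly distributable,
the package ships a first-class synthetic generator (`dyntract.synth`) that
emulates the statistical structure of the inputs — event schedules, band
envelopes, EOG deflections, streamline sets — with known ground truth, so
every stage is testable offline.

## The method in brief

**Band amplitude** is estimated by complex demodulation, equivalent to a
Gabor transform: the signal is multiplied by `exp(-i·2π·f₀·t)` at each
frequency-bin centre (alpha: 9, 11 Hz on 25 ms bins; high gamma:
75…105 Hz on 5 ms bins) and low-pass filtered with a Gaussian FIR kernel.
The kernel's temporal and spectral half-power widths obey the Gaussian
duality `f_h · t_h = ln 2 / 2π`, so the ±39.4 ms alpha kernel resolves
±2.8 Hz. Amplitude is expressed as percent change against the
600–200 ms pre-onset baseline, trial-averaged first.

**Significance** per region uses the bootstrap-t (studentized bootstrap)
across electrode sites: a modulation is declared when the CI excludes the
baseline for ≥ 8 consecutive bins (two oscillatory cycles). The
production 99.99% level is the Bonferroni equivalent of 500 repeated
comparisons at family-wise α = 0.05.

**Connectivity**: a region pair is transiently strengthened (weakened) when
both regions are continuously co-augmented (co-attenuated) for ≥ 8 bins —
200 ms on the alpha grid, 40 ms on the gamma grid — *and* at least one
legitimate streamline joins them (quantitative anisotropy ≥ 0.05, turns
≤ 70°, length 10–250 mm, inside parenchyma, outside brainstem / basal
ganglia / thalamus). The analytic chance of such co-modulation anywhere is

    P ≈ (R/2)(R−1)(T−L+1) · χ^L · χ^L

with `R` regions, `T` bins, run length `L = 8` and per-bin significance
fraction `χ`.

## Worked example

```python
from dyntract import PipelineConfig, run_pipeline
from dyntract.synth import ModulationProfile, SimConfig

sim = SimConfig(
    n_events_per_kind=8,
    profiles=[ModulationProfile("lateral_occipital_L", "alpha",
                                "closure_onset", 50.0, 1000.0, 50.0)],
    seed=3,
)
bundle = run_pipeline(PipelineConfig(
    simulate=sim, bands=("alpha",), marks=("closure_onset",),
    level=0.95, n_resamples=1000, min_events_per_kind=8, seed=11,
))
roi = bundle["roi_series"]
sig = roi[roi.sig_aug]
print(sig.roi.unique(), sig.onset_ms.iloc[0], round(sig["mean"].max(), 1))
```

prints

```
['lateral_occipital_L'] 125.0 50.2
```

i.e. the +50% alpha augmentation injected into the left lateral occipital
region from +50 ms is recovered there — and only there — with onset latency
125 ms (three 25 ms bins late at this desk-scale event count, comparable to
the kernel's ±39.4 ms temporal resolution plus the 100 ms ramp) and a peak
of +50.2%.

The same chain at study scale is laid out as numbered drivers under
`analysis/` (simulate → detect events → spectral maps → region statistics →
coupling → dynamic edges), each writing its tables under `results/`. For
example `analysis/05_coupling.py` reports a mean Pearson r of −0.64 between
alpha and high-gamma percent change across the occipital regions of the
simulated session, and `analysis/06_connectivity.py` prints the analytic
Type I error table and the dynamic edge table of the simulated session.

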