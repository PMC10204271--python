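# Methods

This note documents the models, defaults and numerical choices behind
`dyntract`, what the synthetic generator does and does not emulate, and the
known limitations.

## Spectral estimation

Band amplitude (the square root of power) is estimated by complex
demodulation: `a(t) = 2·|lowpass(x(t)·e^(−i2πf₀t))|`, with a
Gaussian-shaped FIR low-pass — equivalent to a Gabor transform. The
Gaussian is parameterised by its *time-domain half-power half-width* `t_h`
(the squared kernel drops to 50% at ±`t_h`), giving σ = `t_h`/√(ln 2),
truncation at ±4σ, and unit DC gain. By Gaussian duality the transfer
function's half-power half-width is `f_h = ln 2 / (2π t_h)`: 2.80 Hz for
the alpha kernel (`t_h` = 39.4 ms) and 13.97 Hz for the high-gamma kernel
(`t_h` = 7.9 ms). The quoted high-gamma pair (±7.9 ms, ±14.2 Hz) violates
that product by ~2%; the time-domain value is taken as primary and the
spectral width follows from it.

The amplitude scale uses the pure-tone peak convention (a sinusoid of peak
amplitude A returns A in steady state). The convention cancels in percent
change; it is fixed only for reproducibility. Samples within one kernel
half-length of a recording edge are flagged unreliable; epochs are always
cut from a signal demodulated in full, so no per-epoch filter transients
exist.

Frequency-bin centres span each band at the bin width: alpha 9 and 11 Hz
(2 Hz bins over 8–12 Hz), high gamma 75, 85, 95, 105 Hz (10 Hz bins over
70–110 Hz); the per-site band amplitude is their mean.

## Epoch grid and baseline

Epochs span −1000…+2000 ms around each behavioural mark (closure
onset/offset, opening onset/offset) on an inclusive bin-centre grid (25 ms
alpha / 5 ms gamma); the analysis window −200…+2000 ms therefore holds 89
alpha and 441 gamma bins. Percent change is trial-average-then-normalise:
amplitudes are averaged across events per bin, then referenced to the mean
over the baseline bins (−600…−200 ms **relative to movement onset**, even
for offset-locked epochs — an offset-aligned epoch is normalised against
the same event's pre-onset baseline). A per-trial-normalisation variant is
deliberately not the default; the trial-averaged convention matches a
single mean trace per region. For onset-locked marks the baseline bins are
part of the epoch itself, which makes the baseline mean of the map zero to
machine precision by construction.

Events whose epoch window leaves the recording are dropped and counted; a
zero baseline mean is an error (percent change undefined).

## Region statistics

The resampling unit is the electrode site within a (region, hemisphere)
group; excluded sites (seizure-onset zone, interictal spikes, MRI lesion,
artefact) never enter statistics, and groups with fewer than 4 clean sites
are dropped from region-level analysis (their sites still serve the
distance-shell profiles). Patient-level clustering is intentionally
ignored; hemispheres are analysed separately.

Confidence bands use the bootstrap-t: resample sites with replacement,
pivot `t* = (mean* − mean)/se*` with the analytic standard error of each
resample (no nested bootstrap), interval `mean − q(t*)·se`. The same
resample indices are used across time bins, preserving temporal structure.
Degenerate (zero-variance) inputs return a point interval rather than an
error. Defaults: level 0.9999 (the Bonferroni equivalent of 500 repeated
comparisons at family-wise α 0.05) with 100 000 resamples for tail-quantile
stability; desk-scale analyses and the test suite use 0.95 with 2000
resamples. At n = 8 sites the extreme tail quantiles of the bootstrap-t are
heavy-tailed, so the 99.99% level needs large resample counts to be stable
— another reason desk-scale runs use 95%.

Significance uses the run-length rule: augmentation where the lower bound
exceeds 0 (the baseline anchor) for ≥ 8 consecutive bins, attenuation where
the upper bound is below 0; shorter runs are discarded entirely, and the
onset latency is the centre of the first bin of the earliest surviving run.

### Distance-shell profiles

On the flattened cortical surface (2-D mm coordinates with the calcarine
sulcus as the reference axis and the lateral-sulcus boundary separating
ventral from dorsal), each mesh point takes the mean value of the
electrodes within 10 mm (flat-map Euclidean distance; 3-D geodesics are out
of scope); mesh points are grouped into (side, 10 mm distance band) shells;
a shell's value is the mean over its covered mesh points and its
significance comes from the bootstrap over contributing electrodes. Shells
without covered mesh points are reported missing (NaN), never zero.

## Coupling

High-gamma percent change is aggregated onto the 25 ms epoch grid (mean of
the 5 ms bins whose centres fall within ±12.5 ms of each epoch centre; edge
epochs use the bins that exist), then the region-mean alpha and gamma
series are correlated across the 89 epochs with Pearson r and a two-sided
p-value from the exact t transform (n − 2 df) — not a permutation test,
since the epoch count is fixed at 89. Zero-variance series are flagged
invalid rather than raised.

## Connectivity

Co-modulation epochs are maximal runs (≥ 8 bins) of the intersection of two
regions' same-polarity significance masks, equivalent to merging all
qualifying sliding windows (200 ms / 25 ms steps for alpha; 40 ms / 5 ms
for gamma); an independent brute-force enumeration over pairs × window
starts × bins backs this equivalence in the tests. The analytic chance
model multiplies unordered pairs `R(R−1)/2`, window starts `T−L+1`, and the
joint probability `χ^L·χ^L` that both regions are independently significant
at all `L` bins; per-bin independence is assumed exactly as in the source
design, with no autocorrelation correction, so the value is a design-scale
Type I error, not a calibrated p-value.

Streamline legitimacy: minimum per-vertex quantitative anisotropy 0.05,
vertex-wise turning angle ≤ 70° between successive segments (streamlines
are used as given; no re-sampling), arc length 10–250 mm, all vertices
inside the parenchyma mask and outside the brainstem / basal ganglia /
thalamus masks. Desk fixtures use axis-aligned box masks from a JSON
sidecar; volumetric masks can be substituted behind the same `BoxMask`
interface. Degenerate coincident-vertex segments reject the streamline with
its own reason. Endpoints are assigned to the nearest region centroid
within a 3 mm capture radius (electrode-scale; the original tracking seeds
regions directly, which has no desk-scale equivalent); a pair is adjacent
when ≥ 1 legitimate streamline has one endpoint in each region.
Co-augmentation maps to a strengthened edge, co-attenuation to weakened;
opposite-polarity overlap produces no edge.

## Synthetic generator

What it emulates: 1000 Hz multi-channel recordings; alternating spontaneous
closures/openings separated by uniform 2.5–3.5 s gaps (so the 2 s
opposite-event exclusion never fires on ground truth); per-kind log-normal
durations with the two parameters pinned by the target median and IQR
(closure 176 ms, 143–217 ms; opening 175 ms, 128–215 ms — the distribution
family itself is a modelling choice, as only the quantiles are known); a
1/f background (unit-variance spectrum-shaped noise, default 5 µV SD); a
10 Hz alpha carrier (default 10 µV peak) and 70–110 Hz band-passed noise
(default 4 µV SD) whose envelopes follow per-region raised-cosine
percent-change profiles (100 ms ramps, to avoid spectral splatter that
would contaminate the band estimates); and an EOG channel with sub-threshold
low-passed noise plus one 100 µV trapezoidal deflection (10 ms rise/fall)
spanning each event. The alpha carrier is phase-continuous with a random
initial phase per channel: phase resets at event boundaries would inject
broadband transients into the high-gamma band, and the analysis is
amplitude-only, so phase structure is irrelevant. Everything is
bit-reproducible under a fixed seed, and injected percent-change curves are
recorded as ground truth (exactly zero throughout the baseline window by
construction — profiles reaching into the baseline are rejected).

What it does not emulate: epileptiform activity, sleep states, realistic
head geometry or volume conduction, travelling-wave phase structure,
inter-site effect heterogeneity within a region, or thalamic sources.
Passing recovery tests on this generator therefore demonstrates the
correctness of the estimation chain under its stated statistical
assumptions, not robustness to clinical artefacts.

Streamline fixtures contain one gently bowed valid polyline per region pair
(QA 0.10) plus one deliberate violator per criterion (5 mm, 300 mm
serpentine with legal 60° turns, single 80° bend, one 0.02-QA vertex, a
line through the thalamus box), labeled with the violated criterion.

## Problem sizes and defaults of the desk-scale experiments

The validation experiments (`dyntract.experiments`) use a 4-region montage
(8 sites in the target region, 4 elsewhere), 30 events per kind for
parameter recovery, 16 elsewhere, 95% CI with 2000 resamples for recovery
and 99.99% with 2000 for the null control, 20 seeded replicates each, and
1000 replicate datasets for bootstrap coverage. These sizes keep a full
replicate in the seconds range while leaving the statistical conclusions
(onset within two bins, peak within 10 percentage points, empty null) well
resolved.

## Known limitations

- Onset latencies inherit the kernel's temporal smearing: a strong
  modulation can cross the significance threshold up to ~2 bins before its
  true onset (the same phenomenon that motivates treating onsets within the
  ±39.4 ms resolution as simultaneous).
- The chance model's independence assumption makes its probabilities
  optimistic for temporally autocorrelated masks.
- EOG event detection is automated from a single channel with a
  configurable polarity convention; it does not attempt video-style
  verification or blink/closure disambiguation.
- The distance-shell analysis operates purely in flat-map coordinates
  supplied with the electrode table; no surface reconstruction is
  performed.
- Connectivity is undirected; no effective-connectivity or directionality
  estimation is attempted.
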