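# Methods

This note records the models behind each stage, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Line-scan PIV

A kymograph is modeled as rows = successive line scans (time), columns =
position along the vessel; positive velocity moves intensity toward
increasing column index.  Velocity estimation cross-correlates consecutive
line pairs inside sliding blocks:

* each line is mean-subtracted (removes the illumination offset that would
  otherwise dominate the correlation) and L2-normalized, so correlation
  values are bounded by 1 and the block-averaged peak height doubles as the
  quality score;
* correlations are circular (FFT-based).  On streaks of symmetric profile
  the cross-streak interference terms then come in pairs mirrored about the
  true lag, leaving the correlation exactly symmetric around it — which is
  why the 3-point parabolic refinement recovers half-pixel shifts
  essentially exactly rather than with the classic pixel-locking bias;
* equal peaks tie-break toward the smaller |lag| (minimal-motion prior);
* defaults: 32 lines per block, 50% overlap, search range n_pixels/4.
  Blocks that cannot be correlated (constant intensity) yield quality 0 and
  NaN velocity rather than a guess.

Units: shift [px/line] × pixel size [µm] / line period [ms] ≡ mm/s.

## LFP conditioning and spectra

The raw trace is never filtered in place: SD detection needs the DC
component, power analyses use a conditioned copy (zero-phase 2nd-order
Butterworth 1 Hz high-pass plus a Q=30 notch at 60 Hz; forward-backward
filtering keeps event timing unbiased).

Band power integrates the periodogram over theta 2–10, alpha 10–15, beta
15–30, low-gamma 30–80, high-gamma 80–120 Hz.  Bands abut; a bin exactly on
a shared edge belongs to the lower band, so contiguous bands partition the
2–120 Hz range exactly (Parseval consistency holds to numerical precision).
The conventional analysis window is 120 s; shorter windows work but warn.

The band-wise CWT uses an analytic Morlet-type wavelet with ≈6 cycles of
effective support (pywt `cmor2.0-0.9549`), a logarithmic scale grid with 8
voices per octave across the band, and the scale-averaged coefficient
magnitude as the band series.  Traces are decimated to 500 Hz before the
transform (declared in the output; 500 Hz comfortably exceeds twice the
highest band edge).  The wavelet discretization precision is raised to 14
because the library default leaves a ~1% broadband error floor that would
masquerade as out-of-band response.

## Event detection

**SDs** are detected on the raw trace smoothed by a 0.5 s moving average —
SDs are multi-second DC events and sample-level noise would chatter the
threshold; the window length is a parameter.  The rule is transcribed
literally: candidate when the smoothed trace falls below baseline mean −
10×SD, confirmed when that persists > 10 s, concluded at recovery to 80% of
the baseline level ("80% of baseline" is read as mean − 0.2·|mean|, i.e.
≥ 0.8×mean for the positive baselines these rigs produce).  Amplitude is
measured on the raw-trace minimum within the event — on noisy traces this
overshoots the rendered depth by the expected extremum of the noise (≈4.5 σ
over a minute at 1 kHz), which is well inside the 5% recovery target for
the amplitudes of interest.  After closure the baseline is re-estimated
from the following 60 s using median and 1.4826×MAD rather than mean/SD, so
a shifted post-event level is tracked and a following SD partially inside
the window cannot poison the statistics.  The initial baseline window
defaults to the 60 s preceding the injection (or trace start); a trace that
never recovers yields a truncated event flagged as such.

**PIPs** threshold each band's CWT series at baseline mean + 2×SD of that
series; supra-threshold runs longer than 2 s become events, events closer
than 0.5 s merge, and overlapping events union their band labels.  Whether
the theta-and-alpha wording is a conjunction or disjunction is ambiguous, so
both policies exist; `either_band` is the default because the conjunction
reading would make the alpha criterion redundant for pure-theta bursts.
Runs are filtered for duration *before* gap-merging — merging first would
let isolated noise crossings inflate an event's duration.  Detection is
invariant to trace-wide DC offsets because it operates on the conditioned
trace.

## Segmentation and metrics

Velocity is smoothed with a 30 s moving median (single-block LS-PIV
outliers must not define the nadir; width configurable).  The nadir found
on the smoothed trace is then refined to the unsmoothed argmin within one
smoothing half-window: the moving median is robust but biases the argmin on
asymmetric drop/creep profiles.  Ischemia is pinned to [peak drop,
+300 s]; partial recovery starts at the first crossing of 0.8× baseline
vRBC sustained ≥ 10 s (transient spikes excluded — the persistence
requirement is a declared choice, not a published rule), and is flagged
absent when no such crossing exists.  A trace whose post-injection smoothed
minimum stays above 95% of baseline raises "no ischemic drop detected".

RBC distance is the trapezoidal ∫v dt in mm, with linear bridging of gaps
and an error when gaps exceed 20% of the period.  All internal units are
seconds and mm/s; AUC-style outputs are reported in mV·min and mm at the
interface.

## Stimulus synthesis

"Band-limited drive" is realized as a superposition of equal-amplitude
sinusoids at every integer frequency in the band, endpoints inclusive (a
shared edge frequency, e.g. 10 Hz, belongs to both adjacent bands'
component sets).  Phases are drawn once per component from the seeded
generator to bound the crest factor and are recorded in the waveform
metadata.  The normalized sum is quantized mid-rise with 2^bits levels
(reconstruction at level midpoints), making the worst-case error exactly
2^-(bits+1) of full scale; integer DAC codes are exported alongside.
Schedules present each band once per block in seeded random order, 60 s on
with a 60 s interstimulus interval.  Light intensity is rig metadata; no
photometric or channel-kinetics model is included.

## Statistics

The location test is the closed-form chi-squared goodness-of-fit against a
uniform split, df = k−1.  For counts (39, 18) this gives statistic 7.7368
and asymptotic p ≈ 0.0054; published analyses of such counts sometimes print
larger p-values (e.g. 0.02) reflecting per-animal structure or a different
test variant that cannot be recovered from a count pair — the closed form is
implemented as printed and the discrepancy left documented rather than
reconciled.  An exact mode enumerates the full multinomial distribution for
small totals and is checked in the tests against an independent brute-force
enumeration of all k^n outcome assignments.  Pearson correlations use the
t-transform p-value with df = n−2.  p-values are reported to 4 significant
figures; no multiple-testing correction is applied at the report level.
Group-level mixed-effects modeling is deliberately out of scope: the report
is a descriptive per-experiment document.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *geometry and statistics* of the recordings,
not their biophysics — no ion dynamics, receptor kinetics, or photocurrents:

* kymographs: Gaussian-profile dark streaks (unlabeled cells excluding the
  intravascular dye) on a bright background, plug flow (all streaks share
  the instantaneous velocity), wrap-around positions, additive Gaussian
  noise.  Real kymographs add flow profiles across the lumen, diameter
  changes, focus drift and shot noise — recovery results here bound the
  estimator's behavior under the stated noise model only.
* LFP: Gaussian baseline noise around a +4 mV DC level; SDs as smooth
  trapezoids (sigmoidal 5 s fall, plateau, sigmoidal 5 s recovery — rise and
  fall times are a modeling choice, as published traces show but do not
  parameterize them); PIPs as Tukey-windowed tone bursts whose
  `rel_amplitude` is the burst RMS over the baseline RMS.  Real SDs have
  richer shapes (negative ultraslow potentials, partial recoveries), so
  passing tests demonstrate rule transcription and metric recovery, not
  waveform realism.
* scenarios: the velocity time course is a monotone-segment (PCHIP) curve —
  baseline, rapid drop to the nadir fraction, slow creep, transient recovery
  above 80%, late plateau near 35% — with SD onsets placed strictly inside
  the interval where velocity < 35% of baseline and every PIP after the last
  SD, emulating the observed spatio-temporal ordering.  Event *placement* is
  a deterministic function of the configuration; the seed drives only the
  noise streams, so two seeds give different noise but identical ground
  truth.  PIP durations follow the ~2.3 ± 0.5 s pattern truncated at 2.2 s:
  the >2 s detection rule would censor the lower tail, and ground-truth
  tables are meant to be exactly recoverable by the detectors.
* the published drop/recovery tension (transient recovery above 80% of
  baseline followed by a ~35% plateau, while "partial recovery" is defined
  by the 80% crossing) is kept: the profile does both, and segmentation
  implements the crossing rule as printed.

Defaults describe the experimental conditions (≈5 min baseline, 10 kHz LFP,
4 mV baseline mean, recovery onset ≈45 min after injection).  Tests and the
acceptance script run structurally identical scenarios at reduced scale —
13-minute scenarios, 0.5–2 kHz LFP sampling for DC-event work, ~0.65M-line
kymographs — because SDs and the velocity dynamics are sub-Hz phenomena for
which these sizes preserve detector semantics; the sizes are stated in the
relevant functions and are package choices.

## Known limitations

* Single-channel semantics: no propagation-speed estimation, no SD subtype
  classification, no vessel segmentation or diameter estimation.
* The LS-PIV block length and quality threshold are declared defaults, not
  recovered from any publication.
* Amplitude-on-raw-minimum slightly overestimates SD depth on noisy traces
  (see above); using the smoothed trace instead would bias long-plateau
  events low.  The choice is declared, not neutral.
* The exact multinomial mode of the chi-squared test is combinatorial and
  guarded against totals whose composition count exceeds 2·10^5.
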