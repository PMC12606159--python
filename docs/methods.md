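# Methods

This note documents the conventions, parameter choices and limitations
behind each stage of the pipeline. It is written for a reader who wants
to know exactly what the numbers mean, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Spectrograms

Frames start at hop-spaced sample offsets with no centering or edge
padding; frame `i` is labelled by its start time `i·hop/fs` and bin `k`
by its center frequency `k·Δf` (0-based, `Δf = fs/n_dft`). The hop is
`floor(n_dft·(1 − overlap))` samples — 819 at the default 8192-point /
90% settings, since 819.2 is not an integer — giving a time step of
0.0085 s at 96 kHz and 0.017 s at 48 kHz, and frequency resolutions of
11.7 and 5.9 Hz. Each cell holds the squared magnitude of the
Hann-windowed one-sided DFT, with non-DC/non-Nyquist bins doubled so a
frame's cells sum to `n_dft` times the windowed frame energy
(Parseval). Energies are kept linear throughout; dB appears only in
presentation and in the SNR estimate. The 3-dB analysis bandwidth uses
the Hann figure of 1.44 bins (16.9 Hz at the default resolution).

The framing is computed directly (sliding windows + FFT) rather than
through a general STFT helper so that selection boxes in source time
map exactly onto frames with no hidden padding conventions; the window
itself comes from `scipy.signal.get_window`.

Band-pass filtering is a zero-phase forward–backward Butterworth
(`sosfiltfilt`), order 4 by default and configurable. Zero phase means
no group delay, so filtering cannot shift annotation boundaries. The
filter family and order are deliberately exposed as configuration: the
choice is not dictated by the analysis, only the 20–1000 Hz band is.

## Selection measurements

* A selection box includes frames whose start time lies in
  `[start, end)` and bins whose center lies in `[low, high]`.
* Percentile frequencies use the discrete "first bin whose ascending
  cumulative energy reaches q × total" rule, with no interpolation.
  This makes them reproducible and exactly testable against a
  cumulative-sum oracle, at the cost of quantization to the bin grid.
* DUR90 is the central interval: the span between the first frames at
  which the time-marginal cumulative energy reaches 5% and 95%.
* DUR comes from the annotation boundaries, not from energy, matching
  how analysts box calls in the waveform view.
* Peak frequency is the single maximum-energy cell in the box, ties
  broken toward the lower frequency. A time-aggregated-spectrum variant
  would also be defensible; the cell convention is documented and
  pinned by tests.
* Aggregate entropy is the Shannon entropy (bits) of the normalized
  energy distribution over all in-box cells, bounded by log2 of the
  cell count. Note this 2-D (time × frequency) definition yields larger
  values than a frequency-marginal variant would; within this package
  only ordering comparisons between call types are meaningful.
* The SNR estimate is frame-based: 20 ms frames, per-frame mean power
  in dB, signal level the 95th percentile of in-selection frames, noise
  level the 15th percentile of the selection plus up to 1 s of leading
  context. The vendor algorithm it stands in for is unpublished, so the
  percentiles and frame length are exposed as parameters and the
  contract is validated against generator truth (±3 dB at a 15 dB
  injection) rather than against the vendor tool.
* Harmonic counting scans the time-aggregated in-box spectrum for a
  fundamental (strongest local peak, or a hint), then counts
  consecutive partials at integer multiples (±1 bin) that both exceed a
  −20 dB threshold relative to the strongest partial and are genuine
  local peaks. "Harmonics present" requires at least two partials; a
  lone tone is not harmonic structure. Field analysts count harmonics
  visually; this fixed criterion is the package's testable surrogate.

## Taxonomy and bouts

The label grammar concatenates unit names (`MoanGrowl`,
`MoanGrowlMoanWhoop`); parsing is greedy longest-prefix over the eight
unit names, which is unambiguous because no unit name is a prefix of
another. Hum and Grunt are accepted only inside combinational labels —
they are never observed as stand-alone calls. The Croak/Growl duration
rule is strict on the Croak side: exactly 0.5 s classifies as Growl.

"Produced sequentially without ambient noise separating them" is
operationalized as an inter-call gap of at most 0.1 s (configurable):
discrete annotations need a small positive epsilon. Bouts are maximal
runs whose silent gaps are strictly under 3 s; runs of one remain
singletons. Overlapping calls at different amplitude classes are
treated as different callers: they are never merged and are segmented
into parallel bouts per amplitude class. When amplitude classes are
missing the calls are assumed compatible — the package does not guess
tie-breaks the data cannot support.

Measurability screening keeps quality-3 calls with SNR strictly above
10.5 dB; types with fewer than five measured calls are dropped before
classification. Percentages in summary tables round half-up (one
decimal for shares of total, matching 8212/23 416 → 35.1%), and shares
under 0.1% display as "—".

## Classification

Correlation pruning runs once on the full matrix before
cross-validation, removing from each |r| > 0.7 pair the parameter with
the larger mean absolute correlation, never touching the always-keep
set (aggregate entropy by default, retained for its discriminating
power despite its correlation with the percentile-frequency family).
Running the pruning outside the LOOCV loop mirrors the published
sequence but is, strictly, a small information leak; it is documented
as such rather than silently changed.

The discriminant axes solve the generalized symmetric eigenproblem
`S_B a = λ S_W a` with unbiased pooled within-class covariance, axes
scaled to unit pooled within-class variance. Priors are class
frequencies — the published chance levels equal class proportions
(102/394 → 26%), which identifies the frequency-weighted convention.
Classification uses the Gaussian linear rule with those priors. A
singular pooled covariance (possible in folds containing n = 5
classes) receives a ridge of `1e−8 · trace/p` with a warning.

Derived statistics: Clopper–Pearson exact binomial CI for accuracy;
Cohen's kappa from the confusion marginals; variance explained as
eigenvalue shares; "contributions" per discriminant as normalized
absolute standardized coefficients (coefficients times pooled
within-class standard deviations) — the literature rarely defines
"contribution" precisely, so this operationalization is pinned here and
in tests; Welch's heteroscedastic one-way ANOVA (via statsmodels) for
differences in discriminant scores; and parameter stability as
CV = sd/mean per (parameter, type, site) cell with medians taken over
cells per parameter. Cells with non-positive means are excluded with a
warning since CV is undefined there.

## Diel statistics

Only calls starting in the first 5 minutes of each analysed hour are
counted (`[hh:00, hh:05)`, half-open); hours with no calls enter as
zero-count windows. Hour-of-day profiles report mean ± SE across all
windows sharing the hour-of-day (not across days) — the alternative SE
convention exists, and this choice is documented rather than inferable.
Day/night labels come from a site-specific sunrise/sunset table when
one covers the date, else from the fixed 06:00–17:59 / 18:00–05:59
split; windows take the label of their start time and twilight is not
modelled separately. Sun times are an input table, not an astronomical
computation — this keeps the dependency surface small and the labels
auditable. The day/night comparison is a two-sided Wilcoxon rank-sum
(Mann–Whitney) test — appropriate for zero-heavy, non-normal counts —
with tie correction and continuity correction in the large-sample
normal approximation, and fully tied data reported as p = 1.
Across-site p-values are Benjamini–Hochberg adjusted; sites with an
empty group or no detections are reported "not applicable" and excluded
from the adjustment.

## Synthetic generator

The generator's purpose is spectral-statistical fidelity sufficient to
exercise every analysis stage with known truth; it makes no attempt at
perceptually realistic seal voices, and absolute amplitudes are
arbitrary (only SNR is meaningful — no source-level information exists
for these calls).

Archetype defaults follow the published per-type parameters: Croak and
Growl are band-limited Gaussian noise (0.33 s / 230 Hz / 226 Hz and
2.94 s / 246 Hz / 249 Hz respectively), the Moan a 0.67 s harmonic
stack on an 80 Hz fundamental with five partials, the Whoop a 0.14 s
linear upsweep (150–400 Hz), the Rumble a 2.21 s broadband pulse train
(22 pulses/s). The Whine, Hum and Grunt are only qualitatively
described in the field data; their tonal parameters here (f0 180, 120
Hz; 3, 2 harmonics) are plausible package choices, not published
values. Tonal partials decay 6 dB per partial so the fundamental is
always the peak-frequency bin; durations are Gaussian draws truncated
by resampling above a physical floor (which shifts, e.g., the Growl
duration mean about 2.5% above its nominal value — the tests check
against the exact truncated-normal expectation). All calls carry 10 ms
cosine ramps; combinational calls join members with a 10 ms crossfade
and zero silent gap.

Whole recordings place bout arrivals as an inhomogeneous Poisson
process over an hourly rate profile shaped like the observed diel
pattern (night peak, late-afternoon secondary peak, midday low), with
intra-bout gaps uniform on 0.2–2.9 s and at least 3.5 s between
distinct bouts so the generated bout structure is exactly recoverable
by the 3 s rule. Per-call SNR is set by scaling the call against the
ambient noise RMS measured in the 20–1000 Hz band, which makes the
10.5 dB screening rule exercisable end to end. Recording audio defaults
to a 4 kHz sample rate (the calls live below 1 kHz) so minutes-scale
audio stays tractable; day-scale diel simulations use the
truth-log-only path or the direct per-window Poisson count generator.
All randomness flows from one seed through spawned substreams, so
identical (config, seed) pairs are bit-identical and archetype-menu
changes do not perturb unrelated draws.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: propagation and multipath, distance-dependent
spectral shaping, overlapping callers beyond the amplitude-class
device, non-Gaussian and nonstationary ambient noise (vessels, snapping
shrimp, fish choruses), individual vocal variation within a type, and
observer effects in manual boxing. The feature-matrix generator draws
the six discriminant parameters independently per class (diagonal
covariance); real parameters co-vary within calls, so classification
accuracies on synthetic features (≈ 68% overall at the published class
sizes) are structural analogues of — not estimates of — field results.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale by design:
synthetic recordings of 3–20 minutes, feature matrices at the published
394-call class sizes, 100-replicate power studies for the day/night
contrast (Poisson means 4 vs 2 over 50 days give near-certain
detection; equal rates stay at the nominal false-positive level), and
1000-replicate null calibration of the rank-sum test. Oracles are
exact: cumulative-sum re-implementations for the percentile measures,
refit-per-row loops for LOOCV, closed-form Fisher directions,
beta-quantile binomial bounds, the direct Welch formula and exhaustive
rank-sum enumeration at tiny n.

Degenerate inputs fail loudly rather than silently: empty selections,
constant columns in correlation pruning, singular covariances without
the ridge enabled, non-positive durations, unparseable labels (the
offending suffix is named), and empty day/night groups all raise; the
recoverable cases (missing SNR, missing sun-table dates, missing
leading context) warn and fall back as documented above.

## Known limitations

* The cell-based aggregate entropy and the single-cell peak frequency
  are fixed conventions among several defensible ones; absolute values
  are not comparable across packages using other conventions.
* Correlation pruning outside the cross-validation loop leaks a small
  amount of information, as noted.
* The published 95% CI for overall field accuracy is asymmetric in a
  way no standard binomial interval reproduces; this package reports
  Clopper–Pearson and does not attempt to match those bounds.
* Bout attribution to individual callers is an assumption (consistent
  structure and amplitude), not an identification; amplitude classes
  are taken as given.
* Site-specific field results (per-site day/night means and p-values,
  field median CVs, the exact 63%/0.52 classification figures) require
  the original recordings and are out of reach of synthetic data; the
  package covers them with structural properties instead.
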