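# Methods

## Spectral differentiation

All metrics operate on smoothed firing rates sampled at f = 200 Hz: spike
times are binarized into half-open 5 ms bins ([t, t+Δ), 0-based; a bin is 1
iff it contains at least one spike) and convolved with a Gaussian kernel of
10 ms SD truncated at ±25 ms. The truncated kernel is renormalized to unit
mass so constant inputs map to constant outputs; convolution is zero-padded
("same" length). Rates are the convolution times f, so an isolated spike
integrates to one.

For an ensemble of N units, an analysis window of length W (default 3 s) is
cut into floor(W/S) non-overlapping state windows of length S (default
300 ms; S is snapped to an integer number of samples). Each state is the
concatenation over units of the per-unit power spectrum: the unnormalized
forward DFT (no 1/n factor — required for the amplitude bound below), squared
magnitude, non-negative frequencies only, giving floor(f·S/2)+1 entries per
unit. Raw differentiation of a window is the median Euclidean distance over
all unordered pairs of state vectors; with an even pair count the median is
the mean of the two middle values.

Normalization: the rates are first divided by one scalar — the mean rate
over all units of the ensemble (restricted to the RS or FS class being
analyzed) over the entire session — and the raw value is divided by sqrt(N)
and by S²:

    ND = ND_raw(FR / mean(FR)) · N^(−1/2) · S^(−2)

The sqrt(N) factor compensates the growth of state-space dimensionality
with ensemble size (verified empirically: normalized ND of i.i.d. subsamples
of 10–60 units is flat within a few percent); the S² factor compensates the
quadratic growth of total DFT power with the number of samples per state.
Normalized ND is exactly invariant under uniform rescaling of all rates, and
raw differentiation scales exactly as Q² when all rates are scaled by Q.

Bounds. Each DFT coefficient of a signal of amplitude ≤ A is at most A·f·S,
so each PSD entry is at most A²f²S², the raw median distance is bounded by
N·A²f²S², and the normalized value by A²f². Both bounds are implemented as
printed in their source; note the pair is mutually consistent only up to a
sqrt(N) bookkeeping factor — the normalized bound is used as the practical
ceiling (for mean-normalized amplitudes ≲ 50, ND < 10⁸ s⁻²) and only its
independence of N and S is relied on. Every pipeline run records a bound
check (max observed normalized amplitude, all windows within A²f²) in its
JSON summary.

Variants. A Tukey taper with shape parameter 1 can be applied per state
segment before the DFT to probe boundary-leakage sensitivity; segmentation
is unchanged. The mean-firing-rate differentiation (mfrD) control metric
divides each unit's rate by that unit's own session mean (unlike ND's single
ensemble scalar — the two normalizations deliberately differ), averages the
normalized rates across units within each state, and takes the population
variance (1/n) of the per-state means within each window.

Windowing. Windows tile each epoch independently and never straddle epoch
boundaries; incomplete trailing windows are dropped. Ensembles below 10
units are refused (singular extreme units dominate the median otherwise).
Evoked (trial-locked) differentiation uses one 300 ms window starting at
each event with 60 ms states (5 states); events overrunning the recording
are skipped with a warning.

Stimulus differentiation treats each pixel as a unit and is otherwise the
identical computation, including the mean normalization (the ensemble-mean
pixel value is used, for symmetry with the neural case).

## Characteristic timescales

Piecewise-constant signals: the characteristic timescale (CT) is the mean
duration of maximal constant runs, excluding the possibly truncated first
and last runs. Only run lengths matter. The generated flashes stimulus
(1.75 s gray alternating 0.25 s black-or-white) starts with a gray epoch and
ends with a flash epoch so the interior runs contain equal counts of both
durations and the mean is exactly 1 s.

All other signals: the autocorrelation (biased 1/n estimator of the
normalized autocovariance, FFT-based) is fit in log space to a continuous
two-phase linear decay

    log ac(x) = −a − x/t1              (x < c)
    log ac(x) = −a − c/t1 − (x−c)/t2   (x ≥ c)

with box constraints 0 < t1 ≤ 1.5 s, 0.5 ≤ t2 ≤ 20 s, 0.03 ≤ c ≤ 0.2 s,
a ≥ 0; the fast timescale t1 is the CT used downstream. Lag 0 and
nonpositive autocorrelation values are masked before the log; weights are
uniform; the optimizer is bounded trust-region least squares started from 5
deterministic t1 values (0.05–1.2 s), so the fit is seedless and
reproducible. Fits landing on a box constraint (other than a = 0) are
flagged. Model-generated autocorrelations are recovered essentially exactly.
One numerical caveat: for a pure fast exponential fit over a long lag range,
the t2 ≥ 0.5 s constraint forces the tail branch to mis-fit and drags t1
down (e.g. t1 = 0.15 instead of 0.2 at 0.5 s of lags); timescale checks on
near-single-exponential decays therefore use lag ranges comparable to the
expected t1 (≤ 0.25 s).

ND-vs-state-length surveys use a log-spaced grid of 20 state lengths from
10 ms to 3 s (snapped to integer sample counts, duplicates merged), each S
required to fit at least twice into W. Curve optima are classified as
interior, beyond-range (max at the longest probed S), or zero; a maximum at
the shortest probed S is flagged as the ensemble "loss of optimality"
signature. Power-law decay beyond the CT is fit by least squares on
log ND vs log S.

## Group statistics

Pairwise stimulus-category comparisons use the Games–Howell procedure:
Welch statistic with Welch–Satterthwaite degrees of freedom, referred to the
studentized-range distribution with k = number of groups (implemented
in-package on scipy's studentized-range distribution and cross-checked
against an independent implementation in the tests). Multiplicity control is
Benjamini–Hochberg (statsmodels step-up; α = 0.01 by default), with
significance stars at adjusted p < 0.01 / 0.001 / 0.0001. Hit/miss contrasts
of evoked ND (and, in parallel, of mean firing rate) use a two-sample Welch
t-test per ensemble, BH-corrected across ensembles; ensembles with fewer
than 3 trials of either outcome are skipped. The stimulus-name → category
map follows the five-level meaningfulness ordering (none, simple artificial,
shuffled, complex artificial, natural). Behavioral state is split at a mean
running speed of 2 cm/s per window (boundary counts as running; the
threshold is configurable since no canonical value exists). A linear
mixed-effects alternative for area/layer/category effects is deliberately
out of scope; the pipeline's tidy CSV outputs are designed to feed external
mixed-model routines directly.

## Synthetic data: what it emulates, and what it does not

The generators supply every input shape the pipeline reads, as pure
functions of (parameters, seed):

* **Piecewise-constant signals** — uniform integers in [0, 255], resampled
  on a fixed schedule with consecutive values forced distinct, so the
  realized run length equals the nominal CT exactly. The sparse variant
  holds a baseline outside a configurable active fraction of segments.
* **Stimulus movies** — gray (constant), flashes (1.75 s gray / 0.25 s
  full-field black-or-white), gratings/Gabors (per-pixel piecewise constant,
  CT 250 ms), shuffled movies (CT 1/30 s), and a naturalistic surrogate:
  per-pixel AR(1) with 0.8 s correlation time driven through 3 shared
  spatial factors. Real natural movies cannot be redistributed; the
  surrogate targets only the property the analyses rely on — high temporal
  correlation, hence lower pixelwise differentiation at 300 ms states than
  gratings (asserted in the tests), alongside zero differentiation for gray.
* **Spiking** — inhomogeneous Poisson by thinning against the rate maximum.
  Passive sessions modulate each unit's baseline (uniform 2–10 spikes/s)
  with a unit-specific piecewise-constant signal at the stimulus category's
  CT. Virtual-neuron ensembles add per-spike Gaussian jitter or per-copy
  offsets to a single seed train, clipping (not wrapping) at session edges.
* **Change-detection sessions** — 40 image changes at 4 s spacing, each a
  hit with probability 0.5; on hits every unit's rate is multiplied by
  (1 + hit_effect) for the 300 ms post-change, with hit_effect = 1 (a rate
  doubling) by default. A multiplicative transient is the simplest mechanism
  that produces both the elevated firing and the elevated evoked ND that
  successful detection shows; 30 units per session. The running-speed trace
  is smoothed non-negative noise.
* **Ramp ensembles** — excitability and modulation depth ramp linearly
  through the session so that successive windows span a graded range of true
  differentiation. This is the instrument used for the taper-robustness
  check: between statistically identical windows, rank agreement measures
  only estimator noise (the median over 45 pairwise distances is itself
  noisy), whereas the robustness claim concerns the ordering of genuinely
  differing windows, which is preserved under tapering (Spearman ≈ 0.99).

What passing tests show is that the implementation has the advertised
mathematical properties (scaling laws, bounds, oracle equivalence, timescale
recovery, calibrated statistics) and that the qualitative phenomena — flat-
then-power-law curves for dense signals, interior optima for sparse ones,
loss of optimality for jittered ensembles, hit/miss detectability — emerge
under the stated generative mechanisms. The generators do not emulate
refractoriness, spike-sorting artifacts, cross-unit correlations beyond
shared stimulus drive, area- or layer-specific effect sizes, or non-Poisson
firing statistics; quantitative ND values on real recordings will differ.

Two parameter regimes deserve note. The sparse-signal optimum tracks the CT
only at moderate sparseness (active fraction ≈ 0.4, where about half the
states are occupied at S = CT); at extreme sparseness the optimum genuinely
shifts to longer state lengths because the median needs a majority of
distinct state pairs. And the hit/miss power test (≥ 80% detection per
session at α = 0.01 over 100 sessions) is a property of the default effect
size; the null calibration (false-positive rate ≤ 2.5% at α = 0.01 over 200
sessions, i.e. α plus Monte-Carlo allowance) holds with hit_effect = 0.

## Numerical choices and degenerate inputs

* Bin edges half-open, time 0-based; a waveform width exactly at 0.4 ms is
  classified RS (FS is defined by the strict inequality).
* S values are rounded to the nearest integer sample count; fewer than 2
  states, zero ensemble mean rate, zero-variance autocorrelation input,
  unsorted or out-of-range spike times, and unmapped stimulus names all
  raise immediately with messages naming the offender. Missing unit
  metadata and degenerate statistical groups degrade gracefully (excluded /
  NaN with a warning).
* CSV floats are written with 10 significant digits; reruns under a fixed
  seed are byte-identical. Every artifact carries the resolved config and
  its SHA-256 hash.
* Problem sizes in the test suite (sessions of tens of units and a few
  minutes, 100–500 Monte-Carlo replicates) were chosen so the full suite
  runs in about half a minute while keeping every Monte-Carlo margin small
  relative to the tested effect.
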