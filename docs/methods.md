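# Methods

This note documents the model behind `strideseg`, the parameters that
matter, the numerical choices, what the synthetic data does and does not
emulate, and the known limitations. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and assumptions

Gait is modelled as a cyclostationary process: a walking bout is a
sequence of strides whose waveform morphology is similar stride-to-stride
and whose stride time (the interval between successive occurrences of the
same gait event) drifts slowly inside a physiological band. The method
assumes

* at least two consecutive strides inside every analysis window — hence
  the window half-width `Nmax` and the requirement that a recording be at
  least `2·Nmax + 1` samples long before anything is estimated;
* stride frequency within `[fmin, fmax]` = 0.5–3 Hz, giving admissible
  stride times `Nmin = max(2, round(fsamp/fmax))` and
  `Nmax = round(fsamp/fmin)` samples;
* that a gait event appears in each channel as a consistent landmark
  (extremum, zero-crossing, abrupt change or zero-energy plateau) at a
  roughly constant intra-stride phase, so the delay between two channels'
  event trains is approximately constant within one walking bout.

Isolated single strides violate the first assumption and are not
detectable; this is inherent to the design, not an implementation limit.

## Parameters

| name | meaning | unit | default | rationale |
|------|---------|------|---------|-----------|
| `fmin`, `fmax` | stride-frequency band | Hz | 0.5, 3 | physiological limits of human stride frequency |
| `eta` | window step | samples | `round(0.1 s · fsamp)` | ~100 ms, ≈30 % of the shortest stride time; gives `~N/η ≥ 8` replicated votes per stride |
| `estimators` | local cyclicity estimators | — | (1,2,3,4) | correlation, AMDF and amplitude-pair estimators track the fundamental frequency; DTW adds shape similarity robust to intra-stride warps |
| `hv` | stride-confidence threshold | — | 0.11 | the stable value the confidence-threshold selection protocol converges to on free-walking smartphone data; can be re-derived for any dataset via `evaluation.select_threshold` |
| `hr` | noise-variability threshold | channel units | 0.1 g (acc), 5 °/s (gyr) | quiet-sensor noise floors of shoe-mounted IMUs; see the study note below |
| `h` | replication ratio | — | 0.75 | "close to 1" but tolerant of boundary windows that cannot all vote |
| `merge_tol` | pre-grouping merge | samples | 1 | noise misplaces detections by a few samples; one sample is the minimal corrective merge |
| DTW band | Sakoe–Chiba radius | samples | `max(2, N/10)` | bounds cost at `O(N·band)` while tolerating small warps |
| `smooth_len` | fusion smoothing window | samples | `Nmin`, odd-forced | see "Fusion trace smoothing" |

### The noise threshold in the synthetic study

`hr` can encode either the measured sensor-noise variability or the
minimal expected dynamic range of the observed activity when that is
known a priori. The library defaults (0.1 g, 5 °/s) are of the first
kind. The synthetic study trials carry deliberately heavy in-band noise
(SNR 10 dB), whose peak-to-peak excursion over one stride (~0.5 g)
dwarfs a quiet-sensor threshold; `synthgait.study_setup()` therefore uses
the second kind — half the clean template's peak-to-peak range per
channel, which *is* the known activity level of the emulated gait. This
is a property of the study conditions, fixed once, not a tuning knob.

## Numerical choices

**Energy-normalised autocorrelation.** The correlation estimator is
`S1(N) = Σ w(ν)w(ν−N) / sqrt(Σw(ν)²·Σw(ν−N)²)` over `ν ∈ [0, N)`. By
Cauchy–Schwarz it attains 1 exactly when the current stride is
proportional to the previous one — at the true period, for every window
phase. A mean-normalised form `(1/N)Σ w(ν)w(ν−N)` is not phase-safe:
when the strip boundary lands on the waveform peak, the duplicated
boundary sample satisfies `(P·r₁ + w(0)w(−1))/(P+1) > r₀` for any smooth
signal whose peak² exceeds its mean square, biasing the argmax to `P+1`.

**Score → posterior.** Scores are shifted so their minimum is zero and
normalised to sum 1; a flat score vector maps to the uniform
distribution. This is robust to negative correlation values and avoids
the temperature hyperparameter a softmax would introduce. Fusion is an
elementwise product with a floor of 1e-12 per element (one dissenting
estimator cannot annihilate a candidate), computed in log space in the
batched path.

**Ties and the subharmonic guard.** A strictly periodic signal scores
identically at its period and all multiples; float summation order alone
would decide the argmax. Two guards make the estimate well defined:
mismatch costs below 1e-9 of the window amplitude flush to zero before
the reciprocal AMDF/DTW mapping, and the argmax treats values within a
relative 1e-9 as tied, resolving to the smallest admissible `N`. On
*fused* posteriors one more guard applies: the argmax halves to `N/2`
while the posterior mass near `N/2` exceeds twice the uniform mass. A
near-uniform noisy component, amplified by the estimator product, can
tilt an exact `P`-vs-`2P` tie a few fold toward `2P` while the mass at
`P` stays far above uniform; a signal truly cyclic at `2P` keeps
essentially no mass at `P`, so the two regimes are separated by orders of
magnitude. The guard is not applied to single-estimator posteriors,
where weak estimators are legitimately flat.

**Fusion trace smoothing.** The aligned sparse trains are stacked,
column-summed and convolved with a unit-area symmetric triangular window.
Its length defaults to `Nmin` (forced odd), *not* `Nmax`: triangular
tents of half-width `L/2` centred on spikes spaced exactly `L/2` apart
form a partition of unity, so with `L = Nmax` the fused trace becomes
constant — and every stride peak vanishes — precisely when the stride
time sits at `Nmax/2`, the middle of the admissible band and the typical
human stride time at 25 Hz. A window of length `Nmin` still absorbs the
few samples of residual cross-component misalignment while never
bridging two admissible stride positions.

**Sparse-train alignment.** Inter-component lags are the argmax of
normalised cross-correlation over `τ ∈ [−Nmax, Nmax]`, estimated per
gait sequence (carrying posture may change between bouts). Both trains
are first tapered with a 5-sample triangular kernel: with ±1-sample
fiducial jitter, exact-sample coincidence of delta spikes is nearly
random, and a lag one stride period off can otherwise win. Sequences
with fewer than 3 strides fall back to the whole-recording lag; exact
ties resolve to the smallest `|τ|`, then the negative lag.

**Peak-height thresholding.** Final peaks are kept or dropped by the
valley of a Silverman-bandwidth Gaussian KDE over the peak heights,
between the two strongest density modes — but only when the valley is
significant (density below half the weaker mode's). Otherwise the
distribution is treated as unimodal and all peaks are trusted; a second
fixed threshold would contradict the unsupervised design. The KDE grid
extends 3 bandwidths beyond the data range so modes at the extremes are
detectable.

**Other conventions.** Sample indices are 0-based; the time of index `n`
is `n/fsamp`. Window centres start at the first fully valid position
`Nmax` (no partial windows). The stride-time track `g(n)` uses
nearest-centre interpolation with ties to the earlier centre and edge
clamping. The replication filter's expected count is
`l_exp = min(d̂, t̂)/η` — the windows whose right half can contain the
point; the variant `t̂/η`, which grows with absolute time and rejects
every late stride, is available behind `use_printed_lexp` for
comparison. Modal values (stride time, merged position) break ties
toward the smaller value. Final stride times are inter-peak intervals;
the peak-to-preceding-minimum variant is available behind
`interval_from_minima`. Sequence merging adds per-component sequences
best-first (ascending mean absolute error against `g`); the opposite
order is available behind `worst_first`. P95 uses the nearest-rank rule.
Stride matching uses ±100 ms; recall is TP/(TP+FN), with the fall-out
FP/(FP+TN) reported alongside.

## What the synthetic generator emulates — and what it does not

`synthgait` renders stride-time random walks (`T_i = clip(T_{i−1} +
N(0, σ), 1/1.2 s, 1/0.55 s)`, σ = 0.02 s) through per-channel templates
(sums of Gaussian bumps over intra-stride phase with a designated
fiducial phase), with per-stride ±10 % amplitude jitter, per-channel
fiducial delays, silent gaps longer than `Nmax`, a gradual linear morph
between two template banks (transitions), and additive white Gaussian
noise at a stated per-channel SNR on the active portion. The default
trial is 60 s at 25 Hz, SNR 10 dB, one 4 s gap, one 5-stride transition,
a 3 s silent lead-in and ~2 s tail (recordings begin before walking
does; it also means no true stride falls before the first valid window
centre).

It does **not** emulate: biomechanically coupled channel dynamics,
coloured or drifting sensor noise, intra-stride timing warps by default
(a warp option exists to stress DTW), left/right asymmetry, turning,
stairs, or sensor re-orientation mid-recording. Passing tests therefore
show that the pipeline recovers strides whose morphology, timing
statistics and noise match these assumptions — they do not certify
performance on arbitrary real recordings, where transitions are less
gradual and noise is structured.

Ground-truth sequence spans are defined the way the extractor reports
them — onset one stride time before the first fiducial, end at the last
fiducial of the bout — so coverage scores measure extraction quality,
not a bookkeeping convention mismatch.

## Problem sizes

The default test suite and the acceptance script run entirely on
synthetic data at 25 Hz: five 60 s trials (~45 strides each) for the
end-to-end checks, a sweep of all 43 admissible periods × ~36 window
phases × 4 estimators for periodic recovery, 101 injected lags plus 20
jittered repeats for alignment recovery, and 100 random windows for the
estimator-vs-oracle comparison. These sizes were chosen so the whole
evidence base regenerates in a few seconds while every admissible period
and lag is covered exhaustively rather than sampled.

## Known limitations

* Stride times are integer samples; at 25 Hz one sample is 40 ms and
  quantisation dominates the error budget. No sub-sample interpolation
  of fiducials or fusion peaks is attempted.
* The regression `r²` between detected and true stride times on a single
  60 s trial is unstable: the stride-time random walk explores only a
  narrow range, so `r²` — a variance ratio — can be small even when MAE
  is a fraction of a sample. MAE, P95, bias and RPC are the meaningful
  accuracy measures at this scale.
* Strides shorter than `Nmin` after a detection error are dropped, not
  repaired; isolated single strides and the first stride of a bout that
  begins before sample `Nmax` are undetectable by construction.
* The confidence `v` of a window over structured noise can match that of
  genuine gait, so silence rejection rests on the dynamic-range
  threshold `hr` and on multi-component fusion, not on `hv` alone.
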