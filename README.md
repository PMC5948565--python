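# strideseg

Template-free, unsupervised stride segmentation of inertial signals.

Wearable accelerometers and gyroscopes record walking as quasi-periodic
multi-channel time series. Most stride detectors either chase peaks
(fragile in free-living recordings) or match a stride template (which must
be learned per subject and sensor position). `strideseg` takes a third
route: it treats gait as a cyclostationary process and tracks its *local
fundamental frequency* — the stride time — the way a pitch tracker follows
a voice, then reconstructs the exact stride positions from the redundancy
of many overlapping analysis windows. No templates, no training, two
optional thresholds.

## The method

For a compound signal `X(n, s)` (channels `s`, sampling rate `fsamp`),
analysis windows `w_k,s(ν) = X(n_k + ν, s)`, `ν ∈ [−Nmax, Nmax]`, slide
with a small step `η`. Admissible stride times come from the
physiological band 0.5–3 Hz: `Nmin = fsamp/fmax`, `Nmax = fsamp/fmin`.

1. **Local cyclicity estimation.** For every admissible `N`, four
   estimators score how well the presumed current stride `w[0..N)` matches
   the previous one `w[−N..0)`: energy-normalised autocorrelation,
   inverted average magnitude difference, maximum amplitude pairs, and
   banded dynamic time warping (labels 1–4). Scores become posteriors
   `p(N | θ)`; the per-component stride time is
   `N_k,s = argmax_N Π_e p(N | θ_e,s)` with confidence
   `v_k,s = max_N Π_e p(N | θ_e,s)`, and the product over *all* components
   and estimators gives the global `N_k`, interpolated into the
   stride-time track `g(n)`.
2. **Stride positioning.** A fiducial function locates the gait-event
   landmark inside each window (paired maxima `[M]`, minima `[m]`,
   zero-crossings `[z]`, abrupt changes `[h]`, zero-energy plateaus
   `[s]`), giving candidates `t_k,s = n_k + m*`. Because ~`N/η` windows
   cover each stride, genuine fiducials accumulate replicated votes;
   candidates are consolidated into triplets `(d̂, t̂, v̂)` and kept only
   when their vote count is close to the expected replication
   (`l_cnt / l_exp > h`). Optional thresholds remove unreliable strides:
   confidence `v̂ < hv` and per-stride dynamic range `< hr`.
3. **Gait sequences.** Walking bouts are cut by backtracing: consecutive
   strides stay in one sequence while `|(t_i − t_{i−1}) − g(t_i)| < Nmin`;
   anything larger is a silence or disturbance.
4. **Fusion and enhancement.** The component whose inter-stride intervals
   best agree with `g` becomes the reference; other components' sparse
   confidence trains `r(n) = Σ v̂_i δ(n − t̂_i)` are aligned to it by
   per-sequence cross-correlation lags, stacked, smoothed with a
   triangular window, and the peaks of the fused trace — thresholded by an
   unsupervised KDE two-class split of their heights — are the final
   stride events `(d_i, t_i, v_i)`.

The evaluation module implements sample-level sequence coverage,
±100 ms stride matching, absolute-error and Bland–Altman agreement
statistics (RPC = 1.96 σ), signed fiducial bias, and the
precision/recall-intersection protocol for selecting the stride-confidence
threshold `hv`.

Because labelled free-living gait recordings cannot ship with a package,
`strideseg.synthgait` generates multi-channel synthetic trials with
exhaustive ground truth — stride-time random walks in the observed
0.55–1.2 Hz band, per-channel Gaussian-bump stride templates with
designated fiducials, per-channel delays, amplitude jitter, silent gaps,
gradual template transitions, and white sensor noise at a stated SNR — so
every stage is testable end to end.

## Worked example

```python
import strideseg as ss
from strideseg.synthgait import study_setup
from strideseg.evaluation import match_strides, timing_accuracy

trial = ss.make_trial(seed=42)          # 60 s, 25 Hz, SNR 10 dB, 1 gap, 1 transition
cfg, specs = study_setup()              # band 0.5-3 Hz, template-matched hr
result = ss.segment(trial.signal, cfg, specs=specs)

truth = trial.truth_for(result.reference.channel)
rep = match_strides(result.strides.t, truth, cfg.fsamp)
```

prints (via the fields shown):

```
reference component : acc_x-[M]
lags per sequence   : [6, 6, 6, 6, 6]
final strides       : 48  (ground truth 45)
gait sequences      : [(72, 692), (804, 1411)]
stride F-score      : 0.968  (TP 45, FP 3, FN 0)
stride-time MAE     : 1.02 samples
position bias       : +0.09 +/- 0.42 samples
```

The pipeline picked the accelerometer maxima as reference, estimated a
constant 6-sample lag for the gyroscope-trough component (its 3-sample
channel delay plus the fiducial-phase offset), recovered both walking
bouts around the 4-second silence, found all 45 true strides within
±100 ms (3 extra detections near the bout edges), and measured stride
times to about one sample at 25 Hz.

The same pipeline runs from a shell:

```sh
strideseg simulate --seed 42 --out trial/
strideseg segment trial/signal.csv --out seg/
strideseg evaluate seg/strides.csv trial/truth.csv --out eval/
```

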