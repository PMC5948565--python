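"""Evaluation of segmentation output against ground truth.

Four views, each with its own granularity:

* sequence coverage -- per-sample four-class confusion between predicted
  and true gait-sequence spans, with sensitivity / specificity /
  precision / recall / F;
* stride matching -- a prediction within +-100 ms of a true stride border
  is a true positive (the closest prediction per border), surplus and
  stray predictions are false positives, unmatched borders false
  negatives;
* timing accuracy -- absolute-error statistics of matched stride times,
  least-squares regression, signed fiducial bias, and Bland-Altman
  agreement (RPC = 1.96 sigma of the paired differences);
* threshold selection -- the stride-confidence threshold at which the
  precision and recall curves intersect, averaged over trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "CoverageReport",
    "MatchReport",
    "TimingReport",
    "sequence_coverage",
    "match_strides",
    "timing_accuracy",
    "select_threshold",
    "p95_nearest_rank",
]

MATCH_TOL_S = 0.1  # +-100 ms matching tolerance for stride borders


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


@dataclass
class CoverageReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    fall_out: float
    f_score: float


def sequence_coverage(
    pred_spans: list[tuple[int, int]],
    truth_spans: list[tuple[int, int]],
    ell: int,
) -> CoverageReport:
    """Per-sample confusion between predicted and true sequence spans.

    Span bounds are inclusive sample indices.  ``recall`` is the standard
    TP/(TP+FN); the fall-out FP/(FP+TN) is reported alongside for
    completeness.
    """

    def mask(spans):
        m = np.zeros(ell, dtype=bool)
        for a, b in spans:
            if not 0 <= a <= b < ell:
                raise ValueError(f"span ({a}, {b}) outside [0, {ell})")
            m[a : b + 1] = True
        return m

    p, t = mask(pred_spans), mask(truth_spans)
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    precision, recall, f = _prf(tp, fp, fn)
    return CoverageReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (fp + tn) if fp + tn else 0.0,
        precision=precision,
        recall=recall,
        fall_out=fp / (fp + tn) if fp + tn else 0.0,
        f_score=f,
    )


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (truth_i, pred_i)


def match_strides(
    pred: np.ndarray, truth: np.ndarray, fsamp: float, tol_s: float = MATCH_TOL_S
) -> MatchReport:
    """Match predicted stride instants to true stride borders.

    Each truth border claims the closest unclaimed prediction within
    +-``tol_s`` seconds (borders processed in order of their best
    available distance); every unclaimed prediction is a false positive
    and every unclaimed border a false negative.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    tol = tol_s * fsamp
    used_pred = np.zeros(len(pred), dtype=bool)
    pairs: list[tuple[int, int]] = []
    # greedy best-distance-first assignment: globally closest pairs match
    # first, so a prediction between two borders goes to the nearer one
    cand = [
        (abs(pred[j] - truth[i]), i, j)
        for i in range(len(truth))
        for j in range(len(pred))
        if abs(pred[j] - truth[i]) <= tol
    ]
    matched_truth = np.zeros(len(truth), dtype=bool)
    for dist, i, j in sorted(cand):
        if matched_truth[i] or used_pred[j]:
            continue
        matched_truth[i] = True
        used_pred[j] = True
        pairs.append((i, j))
    tp = int(matched_truth.sum())
    fp = int((~used_pred).sum())
    fn = int((~matched_truth).sum())
    precision, recall, f = _prf(tp, fp, fn)
    return MatchReport(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f_score=f,
        pairs=sorted(pairs),
    )


def p95_nearest_rank(values: np.ndarray) -> float:
    """Nearest-rank 95th percentile: value at rank ceil(0.95 n)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return float("nan")
    rank = int(np.ceil(0.95 * v.size))
    return float(v[max(rank, 1) - 1])


@dataclass
class TimingReport:
    ae_mean: float
    ae_median: float
    ae_sd: float
    ae_p95: float
    bias_mean: float
    bias_sd: float
    bias_median: float
    r2: float = float("nan")
    sse: float = float("nan")
    ba_mean_diff: float = float("nan")
    rpc: float = float("nan")
    relative_rpc: float = float("nan")
    cv: float = float("nan")


def timing_accuracy(
    pred_d: np.ndarray,
    truth_d: np.ndarray,
    pred_t: np.ndarray | None = None,
    truth_t: np.ndarray | None = None,
) -> TimingReport:
    """Accuracy and agreement statistics over matched stride pairs.

    ``pred_d``/``truth_d`` are paired stride times; the optional
    ``pred_t``/``truth_t`` are the paired stride positions used for the
    signed fiducial bias.  Fewer than two pairs leave the regression and
    Bland-Altman fields undefined (NaN) while the error statistics are
    still reported.
    """
    pred_d = np.asarray(pred_d, dtype=float)
    truth_d = np.asarray(truth_d, dtype=float)
    if pred_d.shape != truth_d.shape:
        raise ValueError("paired arrays must have equal length")
    ae = np.abs(pred_d - truth_d)
    if pred_t is None or truth_t is None:
        delays = pred_d - truth_d
    else:
        delays = np.asarray(pred_t, dtype=float) - np.asarray(truth_t, dtype=float)
    rep = TimingReport(
        ae_mean=float(ae.mean()) if ae.size else float("nan"),
        ae_median=float(np.median(ae)) if ae.size else float("nan"),
        ae_sd=float(ae.std(ddof=1)) if ae.size > 1 else 0.0,
        ae_p95=p95_nearest_rank(ae),
        bias_mean=float(delays.mean()) if delays.size else float("nan"),
        bias_sd=float(delays.std(ddof=1)) if delays.size > 1 else 0.0,
        bias_median=float(np.median(delays)) if delays.size else float("nan"),
    )
    if pred_d.size < 2:
        return rep
    if np.ptp(truth_d) > 0:
        fit = sstats.linregress(truth_d, pred_d)
        resid = pred_d - (fit.intercept + fit.slope * truth_d)
        rep.r2 = float(fit.rvalue**2)
        rep.sse = float((resid**2).sum())
    diffs = truth_d - pred_d
    means = 0.5 * (truth_d + pred_d)
    sd = float(diffs.std(ddof=1))
    rep.ba_mean_diff = float(diffs.mean())
    rep.rpc = 1.96 * sd
    mean_of_means = float(means.mean())
    rep.relative_rpc = rep.rpc / mean_of_means if mean_of_means else float("nan")
    rep.cv = sd / mean_of_means if mean_of_means else float("nan")
    return rep


def select_threshold(
    curves: list[tuple[np.ndarray, np.ndarray]],
    grid: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray]:
    """Stride-confidence threshold from precision/recall intersections.

    ``curves`` holds one (precision, recall) pair of arrays per trial,
    evaluated on ``grid`` (default 0.00-1.00, step 0.01).  Per trial the
    optimal threshold is the grid point minimising |precision - recall|
    (ties toward the smaller threshold); the selected threshold is the
    mean over trials, reported with its standard deviation.
    """
    if grid is None:
        grid = np.round(np.linspace(0.0, 1.0, 101), 2)
    per_trial = np.empty(len(curves))
    for i, (precision, recall) in enumerate(curves):
        precision = np.asarray(precision, dtype=float)
        recall = np.asarray(recall, dtype=float)
        if precision.shape != grid.shape or recall.shape != grid.shape:
            raise ValueError("curve length must match the threshold grid")
        gap = np.abs(precision - recall)
        if np.ptp(gap) < 1e-12 and np.ptp(precision) < 1e-12:
            warnings.warn("flat precision/recall curves; using the grid midpoint")
            per_trial[i] = grid[len(grid) // 2]
        else:
            per_trial[i] = grid[int(np.argmin(gap))]
    sd = float(per_trial.std(ddof=1)) if len(per_trial) > 1 else 0.0
    return float(per_trial.mean()), sd, per_trial


def regression_plot(truth_d, pred_d, path):  # pragma: no cover - cosmetic
    """Save a least-squares regression scatter (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = sstats.linregress(truth_d, pred_d)
    fig, ax = plt.subplots()
    ax.scatter(truth_d, pred_d, s=8, alpha=0.5)
    xs = np.linspace(min(truth_d), max(truth_d), 2)
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-")
    ax.set_xlabel("reference stride time")
    ax.set_ylabel("detected stride time")
    ax.set_title(f"r^2 = {fit.rvalue ** 2:.4f}")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(truth_d, pred_d, path):  # pragma: no cover - cosmetic
    """Save a Bland-Altman plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    truth_d = np.asarray(truth_d, dtype=float)
    pred_d = np.asarray(pred_d, dtype=float)
    diffs = truth_d - pred_d
    means = 0.5 * (truth_d + pred_d)
    rpc = 1.96 * diffs.std(ddof=1)
    fig, ax = plt.subplots()
    ax.scatter(means, diffs, s=8, alpha=0.5)
    for yv, style in ((diffs.mean(), "-"), (diffs.mean() + rpc, "--"),
                      (diffs.mean() - rpc, "--")):
        ax.axhline(yv, color="r", linestyle=style)
    ax.set_xlabel("mean of reference and detected")
    ax.set_ylabel("difference (reference - detected)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
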