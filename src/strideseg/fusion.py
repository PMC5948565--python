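"""Cross-component alignment, fusion and enhancement of stride positions.

Different channels see the same stride through different gait events, so
their fiducial trains are systematically delayed against each other.  The
procedure picks the component whose inter-stride intervals best agree with
the global stride-time track as reference, estimates per-sequence lags of
every other component by normalised cross-correlation of sparse
confidence trains, stacks the aligned trains, smooths the column sums
with a triangular window, and keeps the peaks that an unsupervised
KDE-based two-class split declares reliable.  The surviving peaks are the
final stride events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as sstats

from .fiducial import FiducialSpec, StrideTriplets
from .sequence import GaitSequence
from .stride_time import StrideTimeTrack

__all__ = [
    "select_reference",
    "build_sparse",
    "align",
    "fuse_and_enhance",
    "FusionResult",
]


def select_reference(
    triplets_by_comp: dict[FiducialSpec, StrideTriplets],
    track: StrideTimeTrack,
    manual: FiducialSpec | None = None,
) -> FiducialSpec:
    """Pick the reference component.

    Automatic selection minimises the mean absolute disagreement between
    the component's inter-stride intervals ``t_i - t_{i-1}`` and the
    global track ``g(t_i)``; a manual override is honoured verbatim.
    """
    if manual is not None:
        if manual not in triplets_by_comp:
            raise KeyError(f"manual reference {manual} not among components")
        return manual
    best, best_score = None, np.inf
    for spec, tri in triplets_by_comp.items():
        if len(tri) < 2:
            continue
        dt = np.diff(tri.t)
        score = float(np.mean(np.abs(track(tri.t[1:]) - dt)))
        if score < best_score:
            best, best_score = spec, score
    if best is None:
        raise ValueError("no component has at least two strides")
    return best


def build_sparse(triplets: StrideTriplets, ell: int) -> np.ndarray:
    """Sparse confidence train r(n) = sum_i v_i * delta(n - t_i).

    Collisions (two strides at the same sample) sum their confidences.
    """
    if len(triplets) and triplets.t.max() >= ell:
        raise ValueError("stride position beyond signal length")
    r = np.zeros(ell)
    np.add.at(r, triplets.t, triplets.v)
    return r


#: short triangular taper applied to both spike trains before correlating:
#: fiducial jitter of a sample or two would otherwise make exact-sample
#: coincidence of delta spikes nearly random and let a lag one stride
#: period off win the correlation
_NCC_KERNEL = np.array([1.0, 2.0, 3.0, 2.0, 1.0]) / 9.0


def _ncc_lag(ref_seg: np.ndarray, other_seg: np.ndarray, nmax: int) -> int | None:
    """Lag tau in [-nmax, nmax] maximising normalised cross-correlation.

    Positive lag means the other train runs late relative to the
    reference.  Ties resolve to the smallest |tau|, then to the negative
    lag.  Returns None when either segment has zero energy.
    """
    ref_seg = np.convolve(ref_seg, _NCC_KERNEL, mode="same")
    other_seg = np.convolve(other_seg, _NCC_KERNEL, mode="same")
    norm = np.linalg.norm(ref_seg) * np.linalg.norm(other_seg)
    if norm == 0:
        return None
    taus = np.arange(-nmax, nmax + 1)
    scores = np.empty(len(taus))
    n = len(ref_seg)
    for j, tau in enumerate(taus):
        if tau >= 0:
            a, b = ref_seg[: n - tau], other_seg[tau:]
        else:
            a, b = ref_seg[-tau:], other_seg[: n + tau]
        scores[j] = float(a @ b) / norm
    best = scores.max()
    tied = np.flatnonzero(scores >= best - 1e-12 * max(best, 1.0))
    # smallest |tau| wins; among +-tau the negative one
    order = np.lexsort((taus[tied], np.abs(taus[tied])))
    return int(taus[tied[order[0]]])


def align(
    reference: np.ndarray,
    other: np.ndarray,
    nmax: int,
    sequences: list[GaitSequence] | None = None,
    min_strides: int = 3,
) -> tuple[list[int], np.ndarray]:
    """Estimate per-sequence lags of ``other`` and undo them.

    The lag of each reference gait sequence (its span padded by ``nmax``
    on both sides) is the cross-correlation maximum over
    ``tau in [-nmax, nmax]``; samples of ``other`` are advanced by the lag
    of the nearest span.  Sequences carrying fewer than ``min_strides``
    strides give an unreliable correlation and fall back to the lag of
    the whole recording; a fully zero-energy train aligns with lag 0 and
    a warning.  Returns the list of lags (one per sequence) and the
    shifted train.
    """
    if reference.shape != other.shape:
        raise ValueError("vectors must share length")
    ell = len(reference)
    global_lag = _ncc_lag(reference, other, nmax)
    if global_lag is None:
        warnings.warn("zero-energy train during alignment; using lag 0")
        global_lag = 0
    if sequences:
        spans = [(max(0, s.onset - nmax), min(ell, s.end + nmax + 1)) for s in sequences]
    else:
        spans = [(0, ell)]
        sequences = None

    lags = []
    for i, (a, b) in enumerate(spans):
        lag = None
        if sequences is None or sequences[i].n_strides >= min_strides:
            lag = _ncc_lag(reference[a:b], other[a:b], nmax)
        lags.append(global_lag if lag is None else lag)

    centers = np.array([(a + b) / 2 for a, b in spans])
    shifted = np.zeros_like(other)
    for n in np.flatnonzero(other):
        lag = lags[int(np.argmin(np.abs(centers - n)))]
        m = n - lag
        if 0 <= m < ell:
            shifted[m] += other[n]
    return lags, shifted


@dataclass
class FusionResult:
    """Final fused strides plus the traces behind them."""

    strides: StrideTriplets
    sequences: list[tuple[int, int]]
    sequence_ids: np.ndarray
    trace: np.ndarray  # smoothed y(n)
    marginal: np.ndarray  # y~(n), column sums of the sparse matrix
    peak_threshold: float | None = None
    dropped: int = 0


def _kde_valley(heights: np.ndarray, dip_ratio: float = 0.5) -> float | None:
    """Valley of the peak-height distribution splitting two classes.

    Silverman-bandwidth Gaussian KDE over the peak heights; when the
    density shows two clearly separated modes the threshold is its
    minimum between the two strongest ones.  The separation is required
    to be significant -- valley density below ``dip_ratio`` times the
    weaker mode's density -- so a shoulder or a lone tall outlier does
    not split an effectively unimodal height distribution.  A unimodal
    (or degenerate) distribution yields no threshold: all peaks are
    trusted, consistent with the unsupervised design.
    """
    if len(heights) < 3 or np.ptp(heights) < 1e-12:
        return None
    try:
        kde = sstats.gaussian_kde(heights, bw_method="silverman")
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate spread
        return None
    bw = kde.factor * heights.std(ddof=1)
    # pad the grid so modes at the extremes are detectable local maxima
    grid = np.linspace(heights.min() - 3 * bw, heights.max() + 3 * bw, 512)
    dens = kde(grid)
    modes = sps.argrelmax(dens)[0]
    if len(modes) < 2:
        return None
    top2 = modes[np.argsort(dens[modes])[-2:]]
    lo, hi = np.sort(top2)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    if dens[valley] > dip_ratio * min(dens[lo], dens[hi]):
        return None
    return float(grid[valley])


def merge_sequences(
    scored: list[tuple[GaitSequence, object]],
    worst_first: bool = False,
) -> list[tuple[int, int]]:
    """Merge per-component sequences into global spans.

    Sequences are added best-first (ascending mean absolute error) and
    overlapping spans are merged, so reliable sequences shape the global
    span structure before unreliable ones extend it.  ``worst_first``
    switches to the literal descending order.
    """
    seqs = sorted(
        (s for s, _ in scored),
        key=lambda s: (s.reliability if s.reliability is not None else np.inf),
        reverse=worst_first,
    )
    spans: list[list[int]] = []
    for s in seqs:
        merged = [s.onset, s.end]
        keep = []
        for sp in spans:
            if sp[0] <= merged[1] and merged[0] <= sp[1]:  # overlap
                merged = [min(sp[0], merged[0]), max(sp[1], merged[1])]
            else:
                keep.append(sp)
        keep.append(merged)
        spans = keep
    return sorted((int(a), int(b)) for a, b in spans)


def fuse_and_enhance(
    aligned: dict[FiducialSpec, np.ndarray],
    nmax: int,
    nmin: int,
    reference: FiducialSpec | None = None,
    component_sequences: dict[FiducialSpec, list[GaitSequence]] | None = None,
    interval_from_minima: bool = False,
    worst_first: bool = False,
    smooth_len: int | None = None,
) -> FusionResult:
    """Fuse aligned confidence trains into the final stride events.

    The trains stack into the sparse matrix ``Y``; its column sums are
    convolved with a unit-area symmetric triangular window to produce the
    fused trace ``y(n)``.  Local maxima of ``y`` are stride candidates; a
    KDE-based two-class split of their heights drops spurious ones.  The
    final triples carry ``t_i`` at the peak, ``d_i`` as the following
    inter-peak interval (``interval_from_minima`` selects the
    peak-to-adjacent-minimum variant instead) and ``v_i`` as the mean
    prominence over both flanking minima.  Stride times falling outside
    ``[Nmin, Nmax]`` are dropped.

    ``smooth_len`` defaults to ``Nmin`` (forced odd).  A window as long
    as ``Nmax`` would be degenerate: triangular tents of half-width
    ``Nmax/2`` centred on a spike train whose spacing equals ``Nmax/2``
    sum to a constant (they form a partition of unity), so the trace
    flattens and every stride peak vanishes exactly when the stride time
    sits in the middle of the admissible band.  A window of length
    ``Nmin`` still merges residual cross-component misalignment of a few
    samples while never bridging two admissible stride positions.
    """
    if not aligned:
        raise ValueError("fuse_and_enhance needs at least one aligned train")
    if smooth_len is None:
        smooth_len = max(3, nmin)
    smooth_len |= 1  # odd length keeps the kernel centred on a sample
    mat = np.stack(list(aligned.values()))
    marginal = mat.sum(axis=0)
    tri = sps.windows.triang(smooth_len)
    tri = tri / tri.sum()
    y = np.convolve(marginal, tri, mode="same")

    peaks, _ = sps.find_peaks(y, height=1e-9)
    if len(peaks) == 0:
        warnings.warn("no peaks in the fused trace; empty result")
        return FusionResult(
            StrideTriplets(np.empty(0, int), np.empty(0, int), np.empty(0), reference),
            [],
            np.empty(0, int),
            y,
            marginal,
        )

    threshold = _kde_valley(y[peaks])
    if threshold is not None:
        peaks = peaks[y[peaks] >= threshold]
    if len(peaks) == 0:
        warnings.warn("all peaks fell below the KDE threshold; empty result")
        return FusionResult(
            StrideTriplets(np.empty(0, int), np.empty(0, int), np.empty(0), reference),
            [],
            np.empty(0, int),
            y,
            marginal,
            peak_threshold=threshold,
        )

    # flanking minima: y-minimum between consecutive kept peaks and toward
    # the trace edges, for the confidence/enhancement step
    bounds = np.concatenate(([0], peaks, [len(y) - 1]))
    mins = np.empty(len(peaks) + 1)
    for i in range(len(peaks) + 1):
        lo, hi = bounds[i], bounds[i + 1]
        mins[i] = y[lo : hi + 1].min() if hi > lo else y[lo]
    v = 0.5 * ((y[peaks] - mins[:-1]) + (y[peaks] - mins[1:]))

    # stride times from inter-peak intervals; the printed variant measures
    # from the following minimum position instead of the following peak
    if interval_from_minima:
        min_pos = np.empty(len(peaks) + 1, dtype=int)
        for i in range(len(peaks) + 1):
            lo, hi = bounds[i], bounds[i + 1]
            min_pos[i] = lo + int(np.argmin(y[lo : hi + 1]))
        gaps = peaks[1:] - min_pos[1:-1]
    else:
        gaps = np.diff(peaks)

    d = np.empty(len(peaks), dtype=int)
    keep = np.ones(len(peaks), dtype=bool)
    dropped = 0
    for i in range(len(peaks)):
        if i < len(gaps) and nmin <= gaps[i] <= nmax:
            d[i] = gaps[i]
        elif i > 0 and keep[i - 1]:  # last stride of a run reuses its predecessor
            d[i] = d[i - 1]
        else:
            keep[i] = False
            dropped += 1
    strides = StrideTriplets(peaks[keep], d[keep], np.clip(v[keep], 0, None), reference)

    if component_sequences:
        scored = [(s, spec) for spec, seqs in component_sequences.items() for s in seqs]
        spans = merge_sequences(scored, worst_first=worst_first)
    else:
        spans = (
            [(int(strides.t[0]), int(strides.t[-1]))] if len(strides) else []
        )
    seq_ids = np.full(len(strides), -1, dtype=int)
    for i, t in enumerate(strides.t):
        for j, (a, b) in enumerate(spans):
            if a <= t <= b:
                seq_ids[i] = j
                break
        else:
            if spans:
                centers = np.array([(a + b) / 2 for a, b in spans])
                seq_ids[i] = int(np.argmin(np.abs(centers - t)))
    return FusionResult(
        strides, spans, seq_ids, y, marginal, peak_threshold=threshold, dropped=dropped
    )
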