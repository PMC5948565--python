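"""Local cyclicity estimators and posterior fusion.

An analysis window ``w(nu)``, ``nu in [-Nmax, Nmax]``, is centred on a
candidate time instant.  For every admissible stride time ``N`` each
estimator scores how well the right half of the window (the presumed
current stride) matches the left half shifted by ``N`` (the presumed
previous stride).  Scores are mapped to a posterior over ``N`` and the
posteriors of several estimators -- and, one level up, of several sensor
components -- are fused by an elementwise product, the Bayesian reading of
independent evidence.

Estimator labels follow the conventional numbering: 1 autocorrelation,
2 (inverted) average magnitude difference function, 3 maximum amplitude
pairs, 4 dynamic time warping between the two adjacent presumed strides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the banded DTW recursion; plain Python otherwise
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


EPS = 1e-12
#: relative tolerance below which two scores/probabilities count as tied;
#: ties resolve toward the smallest admissible N to bias against
#: period doubling (a strictly periodic signal scores identically at P, 2P, ...)
TIE_RTOL = 1e-9
#: mismatch costs below this fraction of the window amplitude are float
#: noise on an exactly periodic window and flush to zero, so the
#: reciprocal mapping of AMDF/DTW cannot turn 1e-16-level summation
#: differences into decisive score gaps between a period and its multiples
COST_FLOOR_RTOL = 1e-9

__all__ = [
    "PosteriorCurve",
    "score_autocorr",
    "score_amdf",
    "score_map",
    "score_dtw",
    "to_posterior",
    "fuse_posteriors",
    "argmax_smallest",
    "batch_scores",
    "batch_posteriors",
    "ESTIMATOR_NAMES",
]

ESTIMATOR_NAMES = {1: "autocorr", 2: "amdf", 3: "map", 4: "dtw"}


@dataclass
class PosteriorCurve:
    """Posterior probability p(N | theta) over admissible stride times."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape:
            raise ValueError("support and probs must have equal length")
        if (self.probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        total = self.probs.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probabilities sum to {total}, expected 1")

    @property
    def argmax(self) -> int:
        """Most probable stride time; ties resolve to the smallest N.

        The subharmonic guard of :func:`pick_period` is *not* applied
        here: a single weak estimator (e.g. maximum amplitude pairs on a
        smooth signal) has a nearly flat posterior where the guard would
        overrule a legitimate maximum.  The guard acts where period
        doubling actually arises -- on fused posteriors, whose products
        amplify a near-uniform component's tilt.
        """
        return int(self.support[argmax_smallest(self.probs)])

    @property
    def confidence(self) -> float:
        return float(self.probs.max())


def argmax_smallest(values: np.ndarray, rtol: float = TIE_RTOL) -> int:
    """Index of the first value within relative ``rtol`` of the maximum."""
    values = np.asarray(values, dtype=float)
    vmax = values.max()
    tol = rtol * max(abs(vmax), 1.0)
    return int(np.argmax(values >= vmax - tol))


#: octave-error guard: the subharmonic N/2 wins when it carries at least
#: this many times the uniform posterior mass (1/|support|).  A signal of
#: period P is also exactly periodic at 2P, so when a near-uniform noisy
#: component tilts the fused product toward 2P the mass remaining at P is
#: still far above uniform; a signal truly cyclic at 2P, in contrast,
#: mismatches badly at lag P and keeps essentially no mass there.  The
#: two regimes sit orders of magnitude apart around this threshold.
HALVING_MASS = 2.0


def pick_period(probs: np.ndarray, support: np.ndarray, rtol: float = TIE_RTOL) -> int:
    """Most probable stride time with tie-break and subharmonic preference.

    The argmax (ties toward the smallest N) is halved as long as the
    posterior mass near N/2 exceeds ``HALVING_MASS`` times the uniform
    mass, guarding against period doubling when a near-uniform component
    tilts an exact P-vs-2P tie.
    """
    i = argmax_smallest(probs, rtol)
    n0 = int(support[0])
    min_mass = HALVING_MASS / len(probs)
    while True:
        n = int(support[i])
        half = int(round(n / 2))
        if half < n0 or half >= n:
            break
        lo = max(0, half - 1 - n0)
        hi = min(len(probs), half + 2 - n0)
        j = lo + int(np.argmax(probs[lo:hi]))
        if probs[j] >= min_mass:
            i = j
        else:
            break
    return i


def _check_window(window: np.ndarray, n_values: np.ndarray) -> tuple[np.ndarray, int]:
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size % 2 == 0:
        raise ValueError("window must be 1-D with odd length 2*Nmax + 1")
    center = window.size // 2
    n_values = np.asarray(n_values, dtype=int)
    if n_values.size == 0 or n_values.min() < 1 or n_values.max() > center:
        raise ValueError("N range must lie within [1, Nmax]")
    return window, center


def score_autocorr(window: np.ndarray, n_values: np.ndarray) -> np.ndarray:
    """Energy-normalised local autocorrelation.

    S1(N) = sum_{nu=0}^{N-1} w(nu) w(nu-N)
            / sqrt(sum_{nu=0}^{N-1} w(nu)^2 * sum_{nu=0}^{N-1} w(nu-N)^2)

    By Cauchy-Schwarz, S1 <= 1 with equality exactly when the current
    stride is proportional to the previous one -- i.e. at the true period
    (and its multiples), for *every* window phase.  The unnormalised mean
    (1/N) sum w(nu) w(nu-N) lacks this property: whenever the strip
    boundary lands on the waveform's peak, the duplicated boundary sample
    pushes the lag-(P+1) mean above the lag-P mean and the argmax off the
    true period by one sample.  A zero-energy strip scores 0 (no
    evidence).
    """
    window, c = _check_window(window, n_values)
    out = np.empty(len(n_values))
    for j, n in enumerate(np.asarray(n_values, dtype=int)):
        right = window[c : c + n]
        left = window[c - n : c]
        denom = np.sqrt((right @ right) * (left @ left))
        out[j] = (right @ left) / denom if denom > 0 else 0.0
    return out


def score_amdf(window: np.ndarray, n_values: np.ndarray) -> np.ndarray:
    """Inverted average magnitude difference function.

    S2(N) = 1 / (eps + (1/N) sum |w(nu) - w(nu-N)|); a perfectly periodic
    window has zero mean difference, hence a maximal score, at its period.
    """
    window, c = _check_window(window, n_values)
    floor = COST_FLOOR_RTOL * np.abs(window).mean()
    out = np.empty(len(n_values))
    for j, n in enumerate(np.asarray(n_values, dtype=int)):
        d = np.abs(window[c : c + n] - window[c - n : c]).mean()
        out[j] = 1.0 / (EPS + (d if d > floor else 0.0))
    return out


def score_map(window: np.ndarray, n_values: np.ndarray) -> np.ndarray:
    """Maximum amplitude pairs: S3(N) = max_nu (w(nu) + w(nu - N))."""
    window, c = _check_window(window, n_values)
    out = np.empty(len(n_values))
    for j, n in enumerate(np.asarray(n_values, dtype=int)):
        out[j] = (window[c : c + n] + window[c - n : c]).max()
    return out


@njit(cache=False)
def _dtw_band_cost(a: np.ndarray, b: np.ndarray, band: int) -> float:
    """Sakoe-Chiba banded DTW cost with |.| local distance, both series length n."""
    n = a.shape[0]
    big = 1e300
    prev = np.full(n, big)
    cur = np.full(n, big)
    for i in range(n):
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > n - 1:
            hi = n - 1
        for j in range(n):
            cur[j] = big
        for j in range(lo, hi + 1):
            d = a[i] - b[j]
            if d < 0.0:
                d = -d
            if i == 0 and j == 0:
                best = 0.0
            else:
                best = big
                if j > 0 and cur[j - 1] < best:  # insertion
                    best = cur[j - 1]
                if i > 0 and prev[j] < best:  # deletion
                    best = prev[j]
                if i > 0 and j > 0 and prev[j - 1] < best:  # match
                    best = prev[j - 1]
            cur[j] = d + best
        prev, cur = cur, prev
    return prev[n - 1]


def dtw_cost(a: np.ndarray, b: np.ndarray, band: int) -> float:
    """Banded DTW alignment cost between two equal-length sequences."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dtw_cost expects two equal-length 1-D arrays")
    return float(_dtw_band_cost(a, b, int(band)))


def default_band(n: int) -> int:
    """Default Sakoe-Chiba radius: max(2, N/10)."""
    return max(2, n // 10)


def score_dtw(
    window: np.ndarray, n_values: np.ndarray, band: int | None = None
) -> np.ndarray:
    """DTW similarity between the two adjacent presumed strides.

    S4(N) = 1 / (eps + DTW(w[-N..-1], w[0..N-1])); the warping band radius
    defaults to max(2, N/10).
    """
    window, c = _check_window(window, n_values)
    floor = COST_FLOOR_RTOL * np.abs(window).mean()
    out = np.empty(len(n_values))
    for j, n in enumerate(np.asarray(n_values, dtype=int)):
        r = default_band(n) if band is None else band
        cost = dtw_cost(window[c - n : c], window[c : c + n], r)
        out[j] = 1.0 / (EPS + (cost if cost > n * floor else 0.0))
    return out


_SCORERS = {1: score_autocorr, 2: score_amdf, 3: score_map, 4: score_dtw}


def to_posterior(
    scores: np.ndarray, support: np.ndarray | None = None
) -> PosteriorCurve:
    """Map raw scores to a posterior: shift so the minimum is zero, normalise.

    A flat score vector maps to the uniform distribution (no evidence).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).any():
        raise ValueError("all scores are non-finite")
    if support is None:
        support = np.arange(len(scores))
    shifted = scores - scores.min()
    total = shifted.sum()
    if total <= 0:
        probs = np.full(len(scores), 1.0 / len(scores))
    else:
        probs = shifted / total
    return PosteriorCurve(np.asarray(support), probs)


def fuse_posteriors(curves: list[PosteriorCurve]) -> PosteriorCurve:
    """Elementwise product of posteriors, floored and renormalised.

    Each probability is floored at 1e-12 before multiplying so a single
    dissenting estimator cannot annihilate a candidate outright.
    """
    if not curves:
        raise ValueError("fuse_posteriors needs at least one curve")
    support = curves[0].support
    prod = np.ones_like(curves[0].probs)
    for c in curves:
        if not np.array_equal(c.support, support):
            raise ValueError("all curves must share the same support")
        prod = prod * np.maximum(c.probs, EPS)
    return PosteriorCurve(support, prod / prod.sum())


# ---------------------------------------------------------------------------
# Batched versions used by the sliding-window sweep.  Windows are the rows of
# a (K, 2*Nmax+1) matrix; scores come back as (K, len(n_values)) matrices.
# ---------------------------------------------------------------------------


def batch_scores(
    windows: np.ndarray, n_values: np.ndarray, estimator: int
) -> np.ndarray:
    windows = np.asarray(windows, dtype=float)
    c = windows.shape[1] // 2
    n_values = np.asarray(n_values, dtype=int)
    out = np.empty((windows.shape[0], len(n_values)))
    if estimator == 1:
        for j, n in enumerate(n_values):
            right = windows[:, c : c + n]
            left = windows[:, c - n : c]
            num = (right * left).sum(axis=1)
            denom = np.sqrt((right**2).sum(axis=1) * (left**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                out[:, j] = np.where(denom > 0, num / denom, 0.0)
    elif estimator == 2:
        floor = COST_FLOOR_RTOL * np.abs(windows).mean(axis=1)
        for j, n in enumerate(n_values):
            d = np.abs(windows[:, c : c + n] - windows[:, c - n : c]).mean(axis=1)
            out[:, j] = 1.0 / (EPS + np.where(d > floor, d, 0.0))
    elif estimator == 3:
        for j, n in enumerate(n_values):
            out[:, j] = (windows[:, c : c + n] + windows[:, c - n : c]).max(axis=1)
    elif estimator == 4:
        wc = np.ascontiguousarray(windows)
        floor = COST_FLOOR_RTOL * np.abs(wc).mean(axis=1)
        out = _batch_dtw(wc, n_values.astype(np.int64), c, floor)
    else:
        raise ValueError(f"unknown estimator {estimator}")
    return out


@njit(cache=False)
def _batch_dtw(
    windows: np.ndarray, n_values: np.ndarray, c: int, floor: np.ndarray
) -> np.ndarray:
    out = np.empty((windows.shape[0], n_values.shape[0]))
    for k in range(windows.shape[0]):
        for j in range(n_values.shape[0]):
            n = n_values[j]
            band = n // 10
            if band < 2:
                band = 2
            cost = _dtw_band_cost(
                windows[k, c - n : c].copy(), windows[k, c : c + n].copy(), band
            )
            if cost <= n * floor[k]:
                cost = 0.0
            out[k, j] = 1.0 / (EPS + cost)
    return out


def batch_posteriors(scores: np.ndarray) -> np.ndarray:
    """Row-wise shift-and-normalise of a (K, nN) score matrix."""
    shifted = scores - scores.min(axis=1, keepdims=True)
    total = shifted.sum(axis=1, keepdims=True)
    flat = total[:, 0] <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = shifted / total
    if flat.any():
        probs[flat] = 1.0 / scores.shape[1]
    return probs


def batch_fuse(prob_stack: np.ndarray) -> np.ndarray:
    """Fuse a (M, K, nN) stack of posteriors along its first axis.

    Products are taken in log space with the 1e-12 floor, then renormalised
    row-wise; equivalent to repeated :func:`fuse_posteriors`.
    """
    logs = np.log(np.maximum(prob_stack, EPS)).sum(axis=0)
    logs -= logs.max(axis=1, keepdims=True)
    probs = np.exp(logs)
    return probs / probs.sum(axis=1, keepdims=True)
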