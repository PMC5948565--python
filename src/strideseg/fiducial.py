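"""Fiducial-point positioning, replication voting and reliability filtering.

A fiducial point marks a gait event (heel strike, toe-off, mid-stance)
inside one stride.  Exactly two fiducial points are expected inside an
analysis window whose estimated stride time is ``N``: one in the right
half at lag ``m`` and its predecessor one stride earlier at ``m - N``.
The definition functions below locate ``m`` for the supported fiducial
kinds.  Because consecutive windows overlap heavily (step ``eta`` is much
smaller than a stride), many windows vote for the same physical fiducial;
consolidation keeps only positions whose vote count is close to the
expected replication, which is what makes the positioning robust without
any template.

Fiducial kinds (compact notation used in method spec strings):

``M``  paired local maximum, ``argmax_m w(m) + w(m - N)``
``m``  paired local minimum, ``argmin_m w(m) + w(m - N)``
``z``  zero-crossing, ``argmin_m |w(m) - w(m - N)|`` restricted to lags
       where the channel changes sign within +-2 samples
``h``  abrupt change, the most negative first difference ``w(m) - w(m-1)``
``s``  zero energy, midpoint of the longest run with ``|w|`` below the
       noise threshold
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .signal_io import CompoundSignal, CyclicityConfig
from .stride_time import StrideTimeSeries

__all__ = [
    "FiducialSpec",
    "StrideTriplets",
    "apply_fiducial",
    "collect_candidates",
    "consolidate",
    "filter_unreliable",
    "parse_method_spec",
]

FIDUCIAL_KINDS = ("M", "m", "z", "h", "s")


@dataclass(frozen=True)
class FiducialSpec:
    """One output component: a channel plus a fiducial kind."""

    kind: str
    channel: str

    def __post_init__(self) -> None:
        if self.kind not in FIDUCIAL_KINDS:
            raise ValueError(f"fiducial kind must be one of {FIDUCIAL_KINDS}")

    def __str__(self) -> str:
        return f"{self.channel}-[{self.kind}]"


@dataclass
class StrideTriplets:
    """Consolidated strides of one component: (d_hat, t_hat, v_hat) arrays."""

    t: np.ndarray  # positions, samples (strictly increasing)
    d: np.ndarray  # stride times, samples
    v: np.ndarray  # confidences in [0, 1]
    spec: FiducialSpec | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.d = np.asarray(self.d, dtype=int)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.t) == len(self.d) == len(self.v)):
            raise ValueError("t, d, v must have equal length")
        if len(self.t) > 1 and (np.diff(self.t) <= 0).any():
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def take(self, mask: np.ndarray) -> "StrideTriplets":
        return StrideTriplets(self.t[mask], self.d[mask], self.v[mask], self.spec)


_COMPONENT_CHANNELS = {
    "acc": ("acc_x", "acc_y", "acc_z"),
    "gyr": ("gyr_x", "gyr_y", "gyr_z"),
    "mag": ("mag_x", "mag_y", "mag_z"),
    "am": ("AM",),
    "ge": ("GE",),
}


def parse_method_spec(
    text: str, channel_labels: list[str] | None = None
) -> tuple[tuple[int, ...], list[FiducialSpec]]:
    """Parse a compact method string into estimators and fiducial specs.

    The notation is ``estimators-Components-axes-[kinds]``, e.g.
    ``"1234-AccGyr-A-[M|m]"`` (all four estimators, accelerometer and
    gyroscope, all axes, maxima and minima as fiducials) or
    ``"Gyr-z-[m]"`` (default estimators, gyroscope z axis, minima).
    When ``channel_labels`` is given, specs naming absent channels raise.
    """
    m = re.fullmatch(r"(?:(\d+)-)?([A-Za-z]+)(?:-([AExyz]))?-\[([Mmzhs|]+)\]", text)
    if m is None:
        raise ValueError(f"cannot parse method spec {text!r}")
    est_str, comp_str, axes, kinds_str = m.groups()
    estimators = tuple(int(c) for c in est_str) if est_str else (1, 2, 3, 4)
    if set(estimators) - {1, 2, 3, 4}:
        raise ValueError(f"unknown estimator labels in {text!r}")
    kinds = kinds_str.split("|")
    for k in kinds:
        if k not in FIDUCIAL_KINDS:
            raise ValueError(f"unknown fiducial kind {k!r} in {text!r}")

    channels: list[str] = []
    for part in re.findall(r"AM|GE|Acc|Gyr|Mag", comp_str):
        group = _COMPONENT_CHANNELS[part.lower()]
        if len(group) == 1 or axes in (None, "A", "E"):
            channels.extend(group)
        else:
            channels.extend(c for c in group if c.endswith(axes))
    if not channels:
        raise ValueError(f"no recognised components in {text!r}")
    if channel_labels is not None:
        missing = [c for c in channels if c not in channel_labels]
        if missing:
            raise ValueError(f"spec {text!r} names absent channels {missing}")
    specs = [FiducialSpec(kind=k, channel=c) for c in channels for k in kinds]
    return estimators, specs


def apply_fiducial(
    window: np.ndarray,
    n: int,
    spec: FiducialSpec,
    hr: float = 0.0,
) -> int | None:
    """Locate the fiducial lag ``m* in [0, N]`` inside one analysis window.

    ``window`` is the full channel window of length ``2*Nmax + 1`` centred
    at the window position; returns ``None`` when the kind finds no
    admissible candidate (e.g. no zero-crossing in range).
    """
    window = np.asarray(window, dtype=float)
    c = window.size // 2
    if not 1 <= n <= c:
        raise ValueError(f"N={n} outside [1, Nmax={c}]")
    m = np.arange(n + 1)
    right = window[c : c + n + 1]
    left = window[c - n : c + 1]
    kind = spec.kind
    if kind == "M":
        return int(m[np.argmax(right + left)])
    if kind == "m":
        return int(m[np.argmin(right + left)])
    if kind == "z":
        sign = np.signbit(window)
        ok = np.zeros(n + 1, dtype=bool)
        for off in range(-2, 2):
            lo = np.clip(c + m + off, 0, window.size - 2)
            ok |= sign[lo] != sign[lo + 1]
        if not ok.any():
            return None
        cand = np.abs(right - left)
        cand[~ok] = np.inf
        return int(m[np.argmin(cand)])
    if kind == "h":
        diff = right - window[c - 1 : c + n]  # w(m) - w(m-1)
        return int(m[np.argmin(diff)])
    if kind == "s":
        quiet = np.abs(right) < hr
        if not quiet.any():
            return None
        best_len, best_mid, run_start = 0, None, None
        for i, q in enumerate(np.append(quiet, False)):
            if q and run_start is None:
                run_start = i
            elif not q and run_start is not None:
                length = i - run_start
                if length > best_len:
                    best_len = length
                    best_mid = (run_start + i - 1) // 2
                run_start = None
        return int(best_mid)
    raise AssertionError(kind)


def collect_candidates(
    signal: CompoundSignal,
    series: StrideTimeSeries,
    specs: list[FiducialSpec],
    config: CyclicityConfig,
) -> dict[FiducialSpec, StrideTriplets]:
    """Emit one stride candidate per analysis window and component.

    For window ``k`` and component spec ``s`` on channel ``c`` the
    candidate position is ``t = n_k + m*`` with stride time ``N_{k,c}``
    and confidence ``v_{k,c}``.  Candidates are returned sorted by
    position, replications and all (consolidation happens later).
    """
    nmax = config.nmax
    out: dict[FiducialSpec, StrideTriplets] = {}
    for spec in specs:
        ch = signal.channel_index(spec.channel)
        hr = config.hr_for(spec.channel)
        ts, ds, vs = [], [], []
        for k, nk in enumerate(series.centers):
            n = int(series.n_by_channel[k, ch])
            window = signal.samples[nk - nmax : nk + nmax + 1, ch]
            m_star = apply_fiducial(window, n, spec, hr=hr)
            if m_star is None:
                continue
            ts.append(nk + m_star)
            ds.append(n)
            vs.append(series.v_by_channel[k, ch])
        order = np.argsort(np.asarray(ts, dtype=int), kind="stable")
        out[spec] = _RawCandidates(
            np.asarray(ts, dtype=int)[order],
            np.asarray(ds, dtype=int)[order],
            np.asarray(vs, dtype=float)[order],
            spec,
        )
    return out


@dataclass
class _RawCandidates(StrideTriplets):
    """Unconsolidated candidates; positions may repeat."""

    def __post_init__(self) -> None:  # replications allowed
        self.t = np.asarray(self.t, dtype=int)
        self.d = np.asarray(self.d, dtype=int)
        self.v = np.asarray(self.v, dtype=float)


def _mode_smallest(values: np.ndarray) -> int:
    """Most frequent value; ties resolve to the smallest."""
    uniq, counts = np.unique(values, return_counts=True)
    return int(uniq[np.argmax(counts)])  # uniq sorted -> first max is smallest


def consolidate(
    candidates: StrideTriplets,
    eta: int,
    h: float = 0.75,
    merge_tol: int = 1,
    use_printed_lexp: bool = False,
) -> StrideTriplets:
    """Collapse replicated candidates into unique stride triplets.

    Candidates whose positions differ by at most ``merge_tol`` samples are
    grouped (noise misplaces detections by a few samples); the group
    position is the modal candidate position, the stride time the modal
    ``d`` and the confidence the mean ``v``.  A group is kept only when
    its vote count ``l_cnt`` is close to the expected replication
    ``l_exp``: ``l_cnt / l_exp > h``.  The expected count is
    ``min(d_hat, t_hat) / eta`` -- the windows whose right half can
    contain the point -- unless ``use_printed_lexp`` requests the growing
    variant ``t_hat / eta``.
    """
    if len(candidates) == 0:
        return StrideTriplets(
            np.empty(0, int), np.empty(0, int), np.empty(0), candidates.spec
        )
    t, d, v = candidates.t, candidates.d, candidates.v
    breaks = np.flatnonzero(np.diff(t) > merge_tol) + 1
    groups = np.split(np.arange(len(t)), breaks)

    ts, ds, vs = [], [], []
    for idx in groups:
        t_hat = _mode_smallest(t[idx])
        d_hat = _mode_smallest(d[idx])
        v_hat = float(v[idx].mean())
        l_cnt = len(idx)
        l_exp = (t_hat if use_printed_lexp else min(d_hat, t_hat)) / eta
        if l_exp < 1.0:
            l_exp = 1.0
        if l_cnt / l_exp > h:
            ts.append(t_hat)
            ds.append(d_hat)
            vs.append(v_hat)
    # modal positions of adjacent groups can coincide; keep the first
    ts = np.asarray(ts, dtype=int)
    keep = np.ones(len(ts), dtype=bool)
    keep[1:] = np.diff(ts) > 0
    return StrideTriplets(
        ts[keep],
        np.asarray(ds, dtype=int)[keep],
        np.asarray(vs)[keep],
        candidates.spec,
    )


def filter_unreliable(
    triplets: StrideTriplets,
    hv: float,
    hr: float,
    signal: CompoundSignal | None = None,
) -> StrideTriplets:
    """Drop low-confidence strides and strides over near-silent signal.

    A triplet survives when its confidence reaches the stride confidence
    threshold ``hv`` and the channel's dynamic range (max - min) over the
    stride interval ``[t - d, t]`` reaches the noise variability threshold
    ``hr``.  Either test is disabled by a zero threshold.
    """
    keep = triplets.v >= hv if hv > 0 else np.ones(len(triplets), dtype=bool)
    if hr > 0:
        if signal is None or triplets.spec is None:
            raise ValueError("hr filtering needs the signal and the component spec")
        x = signal.channel(triplets.spec.channel)
        for i in range(len(triplets)):
            if not keep[i]:
                continue
            lo = max(0, triplets.t[i] - triplets.d[i])
            seg = x[lo : triplets.t[i] + 1]
            if np.ptp(seg) < hr:
                keep[i] = False
    return triplets.take(keep)
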