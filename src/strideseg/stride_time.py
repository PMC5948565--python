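"""Sliding-window stride-time estimation and the global stride-time track.

Analysis windows of half-width ``Nmax`` slide over the compound signal with
step ``eta``.  Each window yields a per-component stride time ``N_{k,s}``
with confidence ``v_{k,s}`` (fused over the selected estimators) and a
globally fused stride time ``N_k`` (fused over all estimators and all
components).  The fused values interpolate (nearest neighbour) into the
track ``g(n)``, the approach's running idea of "the" stride time at any
sample, used later for sequence extraction and reliability scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .cyclicity import batch_fuse, batch_posteriors, batch_scores, pick_period
from .signal_io import CompoundSignal, CyclicityConfig

__all__ = ["StrideTimeSeries", "StrideTimeTrack", "sweep_windows", "build_track"]


@dataclass
class StrideTimeSeries:
    """Per-window stride-time estimates for every component and fused."""

    centers: np.ndarray  # (K,) window centres n_k
    n_by_channel: np.ndarray  # (K, L) N_{k,s}
    v_by_channel: np.ndarray  # (K, L) v_{k,s}
    fused_n: np.ndarray  # (K,) N_k
    channel_labels: list[str] = field(default_factory=list)
    support: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def empty(self) -> bool:
        return len(self.centers) == 0

    def to_frame(self):
        """Dump (n_k, N_{k,s}, v_{k,s}, N_k) as a pandas DataFrame."""
        import pandas as pd

        data = {"center": self.centers}
        for j, lab in enumerate(self.channel_labels):
            data[f"N_{lab}"] = self.n_by_channel[:, j]
            data[f"v_{lab}"] = self.v_by_channel[:, j]
        data["N_fused"] = self.fused_n
        return pd.DataFrame(data)


@dataclass
class StrideTimeTrack:
    """Total lookup g(n) -> fused stride time, nearest-centre interpolation."""

    values: np.ndarray  # length ell

    def __call__(self, n) -> np.ndarray | float:
        idx = np.clip(np.asarray(n, dtype=int), 0, len(self.values) - 1)
        out = self.values[idx]
        return float(out) if np.isscalar(n) else out

    def __len__(self) -> int:
        return len(self.values)


def sweep_windows(signal: CompoundSignal, config: CyclicityConfig) -> StrideTimeSeries:
    """Run the local cyclicity analysis over the whole signal.

    Window centres are ``n_k = Nmax, Nmax + eta, ...`` up to the last fully
    valid position ``ell - 1 - Nmax`` (no partial windows).  A signal
    shorter than one full window yields an empty series with a warning.
    """
    nmax, eta = config.nmax, config.eta
    support = config.support
    ell = signal.n_samples
    labels = list(signal.channel_labels)
    if ell < 2 * nmax + 1:
        warnings.warn(
            f"signal length {ell} shorter than one analysis window "
            f"({2 * nmax + 1} samples); returning empty series"
        )
        k = 0
        return StrideTimeSeries(
            centers=np.empty(0, dtype=int),
            n_by_channel=np.empty((k, signal.n_channels), dtype=int),
            v_by_channel=np.empty((k, signal.n_channels)),
            fused_n=np.empty(0, dtype=int),
            channel_labels=labels,
            support=support,
        )

    centers = np.arange(nmax, ell - nmax, eta)
    prob_per_channel = []  # each (K, nN): estimator-fused posterior of one channel
    all_probs = []  # every (channel, estimator) posterior, for the global fuse
    for ch in range(signal.n_channels):
        views = sliding_window_view(signal.samples[:, ch], 2 * nmax + 1)
        windows = views[centers - nmax]
        stack = np.stack(
            [
                batch_posteriors(batch_scores(windows, support, est))
                for est in config.estimators
            ]
        )
        all_probs.append(stack)
        prob_per_channel.append(batch_fuse(stack))

    n_by_channel = np.empty((len(centers), signal.n_channels), dtype=int)
    v_by_channel = np.empty((len(centers), signal.n_channels))
    for ch, probs in enumerate(prob_per_channel):
        n_by_channel[:, ch] = support[_argmax_rows(probs, support)]
        v_by_channel[:, ch] = probs.max(axis=1)

    fused = batch_fuse(np.concatenate(all_probs, axis=0))
    fused_n = support[_argmax_rows(fused, support)]
    return StrideTimeSeries(
        centers=centers,
        n_by_channel=n_by_channel,
        v_by_channel=v_by_channel,
        fused_n=fused_n,
        channel_labels=labels,
        support=support,
    )


def _argmax_rows(probs: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Row-wise :func:`pick_period` (tie-break + subharmonic guard)."""
    return np.array([pick_period(row, support) for row in probs])


def build_track(series: StrideTimeSeries, ell: int) -> StrideTimeTrack:
    """Expand the fused series to a total function g(n) on [0, ell).

    Each sample takes the fused stride time of its nearest window centre;
    equidistant ties go to the earlier centre, samples beyond the first or
    last centre clamp to the edge values.
    """
    if series.empty:
        raise ValueError("cannot build a track from an empty series")
    centers = series.centers
    n = np.arange(ell)
    right = np.searchsorted(centers, n)  # first centre >= n
    right = np.clip(right, 0, len(centers) - 1)
    left = np.clip(right - 1, 0, len(centers) - 1)
    # choose the nearer centre; strict '<' sends exact ties to the earlier one
    use_right = np.abs(centers[right] - n) < np.abs(n - centers[left])
    idx = np.where(use_right, right, left)
    return StrideTimeTrack(values=series.fused_n[idx].astype(float))
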