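"""Reading, resampling and configuration of multi-channel inertial signals.

Raw recordings from smartphones or body-worn IMUs arrive as delimited text
tables with one timestamp column and one column per sensor channel, usually
sampled non-equidistantly.  This module reads such tables, linearly
interpolates them onto an equidistant grid, derives virtual channels
(acceleration magnitude, angular-velocity energy) and holds the cyclicity
configuration shared by the downstream stages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompoundSignal",
    "CyclicityConfig",
    "RawSeries",
    "read_sensor_table",
    "resample_equidistant",
    "derive_channels",
    "write_sensor_table",
]

_TIME_ALIASES = ("t", "time", "timestamp", "time_s", "time_ms")


@dataclass
class RawSeries:
    """A possibly non-equidistant multi-channel recording.

    Attributes
    ----------
    timestamps : ndarray
        Sample times in seconds, strictly increasing.
    values : ndarray, shape (n, L)
        One column per channel, same order as ``channel_labels``.
    channel_labels : list of str
    time_unit : {"s", "ms"}
        Unit detected (or forced) for the time column of the source table.
    """

    timestamps: np.ndarray
    values: np.ndarray
    channel_labels: list[str]
    time_unit: str = "s"


@dataclass
class CompoundSignal:
    """Equidistantly sampled multi-channel signal X(n, s).

    Rows index time ``n`` (time of row ``n`` is ``n / fsamp`` seconds,
    0-based), columns index channels ``s``.
    """

    samples: np.ndarray
    channel_labels: list[str]
    fsamp: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[1]} sample columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fsamp <= 0:
            raise ValueError("fsamp must be positive")
        if self.samples.shape[0] < 1:
            raise ValueError("signal must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.samples[:, self.channel_index(label)]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channel_labels}") from None

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fsamp


def _default_hr(label: str) -> float:
    """Per-channel-type noise variability threshold.

    0.1 g for accelerometer-derived channels and 5 deg/s for gyroscope
    channels; 0 (disabled) for anything unrecognised.
    """
    low = label.lower()
    if low.startswith("acc") or low == "am":
        return 0.1
    if low.startswith("gyr"):
        return 5.0
    return 0.0


@dataclass
class CyclicityConfig:
    """Parameters of the local-cyclicity analysis.

    The admissible stride-time band is derived from the physiological
    stride-frequency limits ``fmin``/``fmax`` (0.5-3 Hz by default):
    ``Nmin = max(2, round(fsamp/fmax))`` and ``Nmax = round(fsamp/fmin)``
    samples.  The window step ``eta`` defaults to roughly 100 ms, about 30%
    of the shortest admissible stride time.
    """

    fsamp: float
    fmin: float = 0.5
    fmax: float = 3.0
    eta: int | None = None
    estimators: tuple[int, ...] = (1, 2, 3, 4)
    hv: float = 0.11
    hr: dict[str, float] = field(default_factory=dict)
    h: float = 0.75
    fiducial_spec: str | None = None
    merge_tol: int = 1
    use_printed_lexp: bool = False

    def __post_init__(self) -> None:
        if self.fsamp <= 0:
            raise ValueError("fsamp must be positive")
        if not 0 < self.fmin < self.fmax:
            raise ValueError("need 0 < fmin < fmax")
        if self.eta is None:
            self.eta = max(1, int(round(0.1 * self.fsamp)))
        if not 1 <= self.eta <= self.nmin:
            raise ValueError(f"eta={self.eta} outside [1, Nmin={self.nmin}]")
        bad = set(self.estimators) - {1, 2, 3, 4}
        if bad:
            raise ValueError(f"unknown estimator labels {sorted(bad)}")
        if not 0 <= self.hv <= 1:
            raise ValueError("hv must be in [0, 1]")
        if not 0 < self.h <= 1:
            raise ValueError("h must be in (0, 1]")

    @property
    def nmin(self) -> int:
        return max(2, int(round(self.fsamp / self.fmax)))

    @property
    def nmax(self) -> int:
        return int(round(self.fsamp / self.fmin))

    @property
    def support(self) -> np.ndarray:
        """Admissible stride times {Nmin, ..., Nmax} in samples."""
        return np.arange(self.nmin, self.nmax + 1)

    def hr_for(self, label: str) -> float:
        if label in self.hr:
            return self.hr[label]
        return _default_hr(label)


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_sensor_table(
    path: str,
    channel_map: dict[str, str] | None = None,
    time_column: str | None = None,
    time_unit: str | None = None,
) -> RawSeries:
    """Read a delimited sensor table into a :class:`RawSeries`.

    Parameters
    ----------
    path : str
        Comma- or tab-delimited text file with a header row.
    channel_map : dict, optional
        Maps column names in the file to channel labels; unmapped non-time
        columns keep their header names.
    time_column : str, optional
        Name of the time column; autodetected from common aliases or the
        first column otherwise.
    time_unit : {"s", "ms"}, optional
        Force the unit of the time column.  When omitted, a median spacing
        larger than 1 is interpreted as milliseconds.

    Raises
    ------
    ValueError
        On a missing time column, non-monotone timestamps (naming the
        offending row) or non-numeric cells (naming row and column).
    """
    table = pd.read_csv(path, sep=_sniff_delimiter(path))
    if table.shape[1] < 2:
        raise ValueError(f"{path}: need a time column and at least one channel")

    if time_column is None:
        lowered = {c.lower(): c for c in table.columns}
        for alias in _TIME_ALIASES:
            if alias in lowered:
                time_column = lowered[alias]
                break
        else:
            time_column = table.columns[0]
    elif time_column not in table.columns:
        raise ValueError(f"{path}: missing time column {time_column!r}")

    def _numeric(col: str) -> np.ndarray:
        series = pd.to_numeric(table[col], errors="coerce")
        bad = series.index[series.isna() & table[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric cell at row {bad[0] + 2} column {col!r}"
            )
        if series.isna().any():
            row = int(series.index[series.isna()][0])
            raise ValueError(f"{path}: empty cell at row {row + 2} column {col!r}")
        return series.to_numpy(dtype=float)

    t = _numeric(time_column)
    diffs = np.diff(t)
    if (diffs <= 0).any():
        row = int(np.argmax(diffs <= 0)) + 1
        kind = "duplicated" if diffs[row - 1] == 0 else "decreasing"
        raise ValueError(f"{path}: {kind} timestamp at row {row + 2}")

    if time_unit is None:
        time_unit = "ms" if len(t) > 1 and np.median(diffs) > 1.0 else "s"
    if time_unit not in ("s", "ms"):
        raise ValueError(f"unknown time unit {time_unit!r}")
    t_s = t / 1000.0 if time_unit == "ms" else t

    channel_map = channel_map or {}
    labels, cols = [], []
    for col in table.columns:
        if col == time_column:
            continue
        labels.append(channel_map.get(col, col))
        cols.append(_numeric(col))
    return RawSeries(
        timestamps=t_s,
        values=np.column_stack(cols),
        channel_labels=labels,
        time_unit=time_unit,
    )


def resample_equidistant(raw: RawSeries, fsamp_target: float) -> CompoundSignal:
    """Linearly interpolate a raw series onto an equidistant grid.

    The grid is anchored at the first timestamp with spacing
    ``1/fsamp_target``; its length is ``floor((tend - t0) * fsamp) + 1``.
    """
    if fsamp_target <= 0:
        raise ValueError("fsamp_target must be positive")
    t = raw.timestamps
    if t.size < 2:
        raise ValueError("resampling needs at least two samples")
    n_out = int(np.floor((t[-1] - t[0]) * fsamp_target)) + 1
    grid = t[0] + np.arange(n_out) / fsamp_target
    out = np.column_stack(
        [np.interp(grid, t, raw.values[:, j]) for j in range(raw.values.shape[1])]
    )
    return CompoundSignal(out, list(raw.channel_labels), fsamp_target)


def _find_axes(labels: list[str], sensor: str) -> list[int] | None:
    """Indices of the x/y/z channels of ``sensor`` ("acc" or "gyr")."""
    found = {}
    for i, lab in enumerate(labels):
        m = re.fullmatch(rf"{sensor}[_\- ]?([xyz])", lab.lower())
        if m:
            found[m.group(1)] = i
    if set(found) == {"x", "y", "z"}:
        return [found["x"], found["y"], found["z"]]
    return None


def derive_channels(
    signal: CompoundSignal,
    which: set[str] | tuple[str, ...] = ("AM", "GE"),
    config: CyclicityConfig | None = None,
    ge_window: int | None = None,
) -> CompoundSignal:
    """Append virtual channels to a signal.

    ``AM`` is the acceleration magnitude ``sqrt(ax^2 + ay^2 + az^2)``.
    ``GE`` is the angular-velocity energy: a centred moving average of
    ``gx^2 + gy^2 + gz^2`` over ``ge_window`` samples (default ``Nmin / 2``,
    short relative to one stride).  Existing channels are never modified.
    """
    new_cols = []
    new_labels = []
    for name in which:
        if name == "AM":
            idx = _find_axes(signal.channel_labels, "acc")
            if idx is None:
                raise ValueError("AM requires acc_x, acc_y, acc_z channels")
            new_cols.append(np.sqrt((signal.samples[:, idx] ** 2).sum(axis=1)))
            new_labels.append("AM")
        elif name == "GE":
            idx = _find_axes(signal.channel_labels, "gyr")
            if idx is None:
                raise ValueError("GE requires gyr_x, gyr_y, gyr_z channels")
            if ge_window is None:
                if config is not None:
                    ge_window = max(1, config.nmin // 2)
                else:
                    ge_window = max(
                        1, int(round(signal.fsamp / 3.0)) // 2
                    )  # Nmin/2 at the default 3 Hz upper band edge
            sq = (signal.samples[:, idx] ** 2).sum(axis=1)
            kernel = np.ones(ge_window) / ge_window
            # centred moving average; edges use the partial-window mean
            num = np.convolve(sq, kernel, mode="same")
            den = np.convolve(np.ones_like(sq), kernel, mode="same")
            new_cols.append(num / den)
            new_labels.append("GE")
        else:
            raise ValueError(f"unknown virtual channel {name!r}")
    samples = np.column_stack([signal.samples] + new_cols)
    return CompoundSignal(samples, signal.channel_labels + new_labels, signal.fsamp)


def write_sensor_table(signal: CompoundSignal, path: str, sep: str = ",") -> None:
    """Dump a signal to the same delimited format :func:`read_sensor_table` reads."""
    t = np.arange(signal.n_samples) / signal.fsamp
    frame = pd.DataFrame(
        np.column_stack([t, signal.samples]), columns=["t"] + signal.channel_labels
    )
    frame.to_csv(path, sep=sep, index=False, float_format="%.9g")
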