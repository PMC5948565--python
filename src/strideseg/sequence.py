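"""Gait-sequence extraction by backtracing against the stride-time track.

Consecutive detected strides belong to the same gait sequence when the
interval between them agrees with the globally estimated stride time at
that moment; a disagreement beyond ``Nmin`` samples can only arise from a
silence (the subject stopped) or an external disturbance, and closes the
sequence.  The walk runs backwards from the latest stride, which is why
the procedure is called backtracing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiducial import StrideTriplets
from .stride_time import StrideTimeTrack

__all__ = ["GaitSequence", "extract_sequences", "score_sequences"]


@dataclass
class GaitSequence:
    """A maximal run of consecutive strides bounded by silences."""

    onset: int
    end: int
    members: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    reliability: float | None = None

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int)
        if self.onset >= self.end:
            raise ValueError("onset must precede end")

    @property
    def n_strides(self) -> int:
        return len(self.members)


def extract_sequences(
    triplets: StrideTriplets, track: StrideTimeTrack, nmin: int
) -> list[GaitSequence]:
    """Partition a component's strides into gait sequences.

    Walking backwards from the latest stride, the pair ``(i-1, i)`` stays
    in the same sequence when ``|(t_i - t_{i-1}) - g(t_i)| < Nmin``;
    otherwise the sequence closes with onset ``t_first - d_first``
    (one stride time before its first fiducial, clamped at 0) and a new
    sequence starts at stride ``i-1``.  Every stride belongs to exactly
    one sequence; sequences are returned in time order.
    """
    n = len(triplets)
    if n == 0:
        return []
    t, d = triplets.t, triplets.d
    groups: list[list[int]] = [[n - 1]]
    for i in range(n - 1, 0, -1):
        delta = abs((t[i] - t[i - 1]) - track(int(t[i])))
        if delta < nmin:
            groups[-1].append(i - 1)
        else:
            groups.append([i - 1])
    sequences = []
    for g in reversed(groups):
        members = np.array(sorted(g), dtype=int)
        first, last = members[0], members[-1]
        onset = max(0, int(t[first]) - int(d[first]))
        sequences.append(GaitSequence(onset=onset, end=int(t[last]), members=members))
    return sequences


def score_sequences(
    sequences: list[GaitSequence], triplets: StrideTriplets, track: StrideTimeTrack
) -> list[GaitSequence]:
    """Fill each sequence's reliability: mean |d_i - g(t_i)| over members.

    Lower is better -- a reliable sequence's stride times agree with the
    global track.
    """
    for seq in sequences:
        d = triplets.d[seq.members]
        g = track(triplets.t[seq.members])
        seq.reliability = float(np.mean(np.abs(d - g)))
    return sequences


def sequences_to_frame(sequences: list[GaitSequence], component: str = ""):
    import pandas as pd

    return pd.DataFrame(
        {
            "component": component,
            "j": np.arange(len(sequences)),
            "onset": [s.onset for s in sequences],
            "end": [s.end for s in sequences],
            "n_strides": [s.n_strides for s in sequences],
            "reliability": [s.reliability for s in sequences],
        }
    )
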