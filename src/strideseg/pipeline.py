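"""End-to-end stride segmentation: signal in, final stride events out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiducial import (
    FiducialSpec,
    StrideTriplets,
    collect_candidates,
    consolidate,
    filter_unreliable,
    parse_method_spec,
)
from .fusion import FusionResult, align, build_sparse, fuse_and_enhance, select_reference
from .sequence import GaitSequence, extract_sequences, score_sequences
from .signal_io import CompoundSignal, CyclicityConfig
from .stride_time import StrideTimeSeries, StrideTimeTrack, build_track, sweep_windows

__all__ = ["SegmentationResult", "segment"]


@dataclass
class SegmentationResult:
    """Everything the pipeline produced, from windows to final strides."""

    strides: StrideTriplets
    sequences: list[tuple[int, int]]
    sequence_ids: np.ndarray
    reference: FiducialSpec
    lags: dict[FiducialSpec, list[int]]
    series: StrideTimeSeries
    track: StrideTimeTrack
    per_component: dict[FiducialSpec, StrideTriplets]
    component_sequences: dict[FiducialSpec, list[GaitSequence]]
    fusion: FusionResult
    config: CyclicityConfig = None

    def strides_frame(self):
        import pandas as pd

        fs = self.config.fsamp if self.config else 1.0
        return pd.DataFrame(
            {
                "ti_samples": self.strides.t,
                "ti_seconds": self.strides.t / fs,
                "di_samples": self.strides.d,
                "vi": self.strides.v,
                "sequence_id": self.sequence_ids,
                "component_provenance": str(self.reference),
            }
        )

    def sequences_frame(self):
        import pandas as pd

        fs = self.config.fsamp if self.config else 1.0
        return pd.DataFrame(
            {
                "sequence_id": np.arange(len(self.sequences)),
                "onset_samples": [a for a, _ in self.sequences],
                "end_samples": [b for _, b in self.sequences],
                "onset_seconds": [a / fs for a, _ in self.sequences],
                "end_seconds": [b / fs for _, b in self.sequences],
                "n_strides": [
                    int((self.sequence_ids == j).sum())
                    for j in range(len(self.sequences))
                ],
            }
        )


def _empty_result(
    series: StrideTimeSeries, config: CyclicityConfig, specs: list[FiducialSpec]
) -> SegmentationResult:
    ref = specs[0] if specs else FiducialSpec("M", "")
    empty = StrideTriplets(np.empty(0, int), np.empty(0, int), np.empty(0), ref)
    return SegmentationResult(
        strides=empty,
        sequences=[],
        sequence_ids=np.empty(0, int),
        reference=ref,
        lags={},
        series=series,
        track=StrideTimeTrack(np.empty(0)),
        per_component={},
        component_sequences={},
        fusion=None,
        config=config,
    )


def segment(
    signal: CompoundSignal,
    config: CyclicityConfig,
    specs: list[FiducialSpec] | None = None,
    reference: FiducialSpec | None = None,
) -> SegmentationResult:
    """Run the full segmentation pipeline on an equidistant signal.

    Parameters
    ----------
    signal : CompoundSignal
        Equidistantly sampled multi-channel recording.
    config : CyclicityConfig
        Analysis parameters; ``config.fiducial_spec`` (compact method
        notation) supplies the components unless ``specs`` is given.
    specs : list of FiducialSpec, optional
        Explicit output components (channel + fiducial kind).
    reference : FiducialSpec, optional
        Manual reference component; automatic selection otherwise.
    """
    if specs is None:
        if config.fiducial_spec is None:
            raise ValueError("no fiducial specs: set config.fiducial_spec or specs")
        estimators, specs = parse_method_spec(
            config.fiducial_spec, signal.channel_labels
        )
        if config.fiducial_spec.split("-")[0].isdigit():
            config.estimators = estimators

    series = sweep_windows(signal, config)
    if series.empty:
        return _empty_result(series, config, specs)
    track = build_track(series, signal.n_samples)

    candidates = collect_candidates(signal, series, specs, config)
    per_component: dict[FiducialSpec, StrideTriplets] = {}
    component_sequences: dict[FiducialSpec, list[GaitSequence]] = {}
    for spec, cand in candidates.items():
        tri = consolidate(
            cand,
            eta=config.eta,
            h=config.h,
            merge_tol=config.merge_tol,
            use_printed_lexp=config.use_printed_lexp,
        )
        tri = filter_unreliable(
            tri, hv=config.hv, hr=config.hr_for(spec.channel), signal=signal
        )
        if len(tri) == 0:
            continue
        per_component[spec] = tri
        seqs = extract_sequences(tri, track, config.nmin)
        component_sequences[spec] = score_sequences(seqs, tri, track)

    if not per_component:
        return _empty_result(series, config, specs)

    sref = select_reference(per_component, track, manual=reference)
    ell = signal.n_samples
    ref_vec = build_sparse(per_component[sref], ell)
    ref_seqs = component_sequences[sref]
    aligned: dict[FiducialSpec, np.ndarray] = {sref: ref_vec}
    lags: dict[FiducialSpec, list[int]] = {sref: [0] * max(1, len(ref_seqs))}
    for spec, tri in per_component.items():
        if spec == sref:
            continue
        vec = build_sparse(tri, ell)
        lags[spec], aligned[spec] = align(ref_vec, vec, config.nmax, ref_seqs)

    fusion = fuse_and_enhance(
        aligned,
        nmax=config.nmax,
        nmin=config.nmin,
        reference=sref,
        component_sequences=component_sequences,
    )
    return SegmentationResult(
        strides=fusion.strides,
        sequences=fusion.sequences,
        sequence_ids=fusion.sequence_ids,
        reference=sref,
        lags=lags,
        series=series,
        track=track,
        per_component=per_component,
        component_sequences=component_sequences,
        fusion=fusion,
        config=config,
    )
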