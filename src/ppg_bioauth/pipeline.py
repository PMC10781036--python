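"""End-to-end glue: cohort -> segments -> scalogram dataset -> experiment."""

from __future__ import annotations

import logging

import numpy as np

from .preprocess import PreprocessConfig, preprocess_record
from .scalogram import ScalogramConfig, WaveletSpec, build_image_matrix
from .signals import SignalRecord
from .train_eval import Dataset

logger = logging.getLogger(__name__)

__all__ = ["records_to_segments", "segments_to_dataset", "records_to_dataset"]


def records_to_segments(records: list[SignalRecord], pre_cfg: PreprocessConfig):
    """Preprocess every record and pool the surviving segments."""
    segments = []
    for rec in records:
        segs = preprocess_record(rec, pre_cfg)
        segments.extend(segs)
    logger.info("preprocessed %d records into %d surviving segments",
                len(records), len(segments))
    return segments


def segments_to_dataset(segments, scal_cfg: ScalogramConfig,
                        spec: WaveletSpec = WaveletSpec()) -> Dataset:
    """Transform segments to scalogram images with identity labels and
    record-level groups."""
    if not segments:
        raise ValueError("no segments to transform")
    images, _ = build_image_matrix(segments, scal_cfg, spec)
    labels = np.array([int(s.subject_id) for s in segments])
    group_keys = [s.record_id for s in segments]
    uniq = {k: i for i, k in enumerate(dict.fromkeys(group_keys))}
    groups = np.array([uniq[k] for k in group_keys])
    return Dataset(np.stack(images).astype(np.float32), labels, groups)


def records_to_dataset(records, pre_cfg: PreprocessConfig,
                       scal_cfg: ScalogramConfig,
                       spec: WaveletSpec = WaveletSpec()) -> Dataset:
    return segments_to_dataset(records_to_segments(records, pre_cfg), scal_cfg, spec)
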