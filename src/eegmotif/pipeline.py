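"""Multilevel feature extraction for one EEG channel.

Each 512-sample channel signal is expanded into 19 level signals: the raw
signal (level 0) plus the 18 TQWT subbands at the default Q=4, r=3, J=17
(17 detail bands, levels 1..17, and the final scaling band, level 18).
Every level signal feeds two extractors — the ternary motif pattern
histogram (486 features) and the statistical moment generator (14
features) — giving 500 features per level and 9500 per channel.

Feature columns carry their provenance (level, extractor, within-extractor
index), so downstream selection can be traced back to subbands.
"""

from __future__ import annotations

import numpy as np

from .moments import N_STATS, statistical_features
from .motifs import TMP_LEN, tmp_histogram
from .records import EEGRecord, FeatureColumn, FeatureMatrix
from .tqwt import TQWTParams, tqwt_analyze

__all__ = [
    "FEATURES_PER_LEVEL",
    "n_levels",
    "n_channel_features",
    "extract_channel_features",
    "extract_dataset_features",
]

FEATURES_PER_LEVEL = TMP_LEN + N_STATS  # 486 + 14 = 500


def n_levels(params: TQWTParams, use_scaling_band: bool = True) -> int:
    """Level-signal count: raw + J details (+ scaling band unless dropped)."""
    return 1 + params.J + (1 if use_scaling_band else 0)


def n_channel_features(params: TQWTParams, use_scaling_band: bool = True) -> int:
    return n_levels(params, use_scaling_band) * FEATURES_PER_LEVEL


def _level_signals(
    signal: np.ndarray, params: TQWTParams, use_scaling_band: bool
) -> list[np.ndarray]:
    bands = tqwt_analyze(signal, params)
    levels = [np.asarray(signal, dtype=float)] + list(bands)
    if not use_scaling_band:
        levels = levels[:-1]
    return levels


def extract_channel_features(
    signal: np.ndarray,
    params: TQWTParams | None = None,
    tau: float = 0.0,
    eps: float = 0.2,
    use_scaling_band: bool = True,
) -> tuple[np.ndarray, list[FeatureColumn]]:
    """Feature vector of one channel signal, with column provenance.

    With the defaults (J=17, scaling band kept) the vector has length
    9500 = 19 levels x (486 TMP + 14 statistical) features; each level
    contributes its TMP block first, then its statistical block.

    ``use_scaling_band=False`` supports the alternative reading of the
    level parameter in which J=18 detail bands are produced and the final
    scaling band is discarded.
    """
    params = params or TQWTParams()
    parts: list[np.ndarray] = []
    columns: list[FeatureColumn] = []
    for lvl, s in enumerate(_level_signals(signal, params, use_scaling_band)):
        try:
            parts.append(tmp_histogram(s, tau))
            parts.append(statistical_features(s, eps=eps))
        except ValueError as exc:
            raise ValueError(f"feature extraction failed at level {lvl}: {exc}") from exc
        columns.extend(FeatureColumn(lvl, "tmp", i) for i in range(TMP_LEN))
        columns.extend(FeatureColumn(lvl, "stat", i) for i in range(N_STATS))
    return np.concatenate(parts), columns


def extract_dataset_features(
    records: list[EEGRecord],
    channel: int,
    params: TQWTParams | None = None,
    tau: float = 0.0,
    eps: float = 0.2,
    use_scaling_band: bool = True,
) -> FeatureMatrix:
    """Per-record feature rows for one channel, in manifest order."""
    if not records:
        raise ValueError("no records")
    params = params or TQWTParams()
    shape = records[0].data.shape
    if not 0 <= channel < shape[0]:
        raise IndexError(f"channel {channel} out of range for {shape[0]}-channel data")
    rows = []
    columns: list[FeatureColumn] = []
    for rec in records:
        if rec.data.shape != shape:
            raise ValueError(
                f"record {rec.record_id!r} shape {rec.data.shape} differs from {shape}"
            )
        vec, columns = extract_channel_features(
            rec.data[channel], params, tau=tau, eps=eps, use_scaling_band=use_scaling_band
        )
        rows.append(vec)
    return FeatureMatrix(
        values=np.vstack(rows),
        columns=columns,
        record_ids=[r.record_id for r in records],
        subject_ids=[r.subject_id for r in records],
        labels=np.array([r.label for r in records]),
    )
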