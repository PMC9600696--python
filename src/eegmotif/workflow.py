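"""End-to-end orchestration: per-channel extract/select/classify + voting.

Runs the full architecture over every channel of a dataset: multilevel
feature extraction, thresholded-NCA selection, weighted kNN under a chosen
cross-validation scheme, then iterative hard majority voting across the
per-channel out-of-fold prediction vectors.

Two selection modes exist.  The default fits selection once on the full
dataset before cross-validation, matching the architecture's phase order
(selection is a dataset-level step preceding classification).  The nested
mode refits normalisation and selection inside each training fold and is
the leakage-free variant; it is slower and gives more conservative
accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .knn import KNNParams, PredictionVector, crossval_predict, knn_predict
from .nca import NCAParams, minmax_normalize, select_features
from .pipeline import extract_dataset_features
from .records import EEGRecord, FeatureMatrix
from .tqwt import TQWTParams
from .voting import EnsembleReport, ihmv

__all__ = ["ChannelResult", "PipelineConfig", "run_channel", "run_pipeline"]

log = logging.getLogger("eegmotif.workflow")


@dataclass
class PipelineConfig:
    tqwt: TQWTParams = field(default_factory=TQWTParams)
    knn: KNNParams = field(default_factory=KNNParams)
    nca: NCAParams = field(default_factory=NCAParams)
    selected_feature_count: int = 250
    threshold: float = 0.0
    scheme: str = "tenfold"
    seed: int = 0
    nested_selection: bool = False
    use_scaling_band: bool = True


@dataclass
class ChannelResult:
    channel: int
    prediction: PredictionVector
    selected_indices: np.ndarray


def _faithful_channel(
    fm: FeatureMatrix, channel: int, cfg: PipelineConfig
) -> ChannelResult:
    sel = select_features(
        fm.values, fm.labels, k=cfg.selected_feature_count, th=cfg.threshold, params=cfg.nca
    )
    X = minmax_normalize(fm.values)[:, sel.selected_indices]
    pred = crossval_predict(
        X,
        fm.labels,
        scheme=cfg.scheme,
        subject_ids=fm.subject_ids,
        params=cfg.knn,
        seed=cfg.seed,
        channel=channel,
    )
    return ChannelResult(channel=channel, prediction=pred, selected_indices=sel.selected_indices)


def _nested_channel(
    fm: FeatureMatrix, channel: int, cfg: PipelineConfig
) -> ChannelResult:
    """Selection refit on each training fold; no test information leaks."""
    from sklearn.model_selection import StratifiedKFold

    from .knn import _loso_folds

    y = fm.labels
    if cfg.scheme == "tenfold":
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=cfg.seed)
        folds = list(skf.split(fm.values, y))
    else:
        folds = _loso_folds(fm.subject_ids)
    preds = np.full(len(y), -1, dtype=int)
    last_sel = np.empty(0, dtype=int)
    for train, test in folds:
        Xtr_raw = fm.values[train]
        lo = Xtr_raw.min(axis=0)
        span = Xtr_raw.max(axis=0) - lo
        safe = np.where(span > 0, span, 1.0)
        sel = select_features(
            Xtr_raw, y[train], k=cfg.selected_feature_count, th=cfg.threshold, params=cfg.nca
        )
        cols = sel.selected_indices
        Xtr = np.clip((Xtr_raw[:, cols] - lo[cols]) / safe[cols], None, None)
        Xte = (fm.values[test][:, cols] - lo[cols]) / safe[cols]
        preds[test] = knn_predict(Xtr, y[train], Xte, cfg.knn)
        last_sel = cols
    return ChannelResult(
        channel=channel,
        prediction=PredictionVector(labels=preds, channel=channel, scheme=cfg.scheme, seed=cfg.seed),
        selected_indices=last_sel,
    )


def run_channel(fm: FeatureMatrix, channel: int, cfg: PipelineConfig) -> ChannelResult:
    """Selection + out-of-fold kNN predictions for one channel's features."""
    if cfg.nested_selection:
        return _nested_channel(fm, channel, cfg)
    return _faithful_channel(fm, channel, cfg)


def run_pipeline(
    records: list[EEGRecord],
    cfg: PipelineConfig | None = None,
    channels: list[int] | None = None,
    feature_matrices: dict[int, FeatureMatrix] | None = None,
) -> tuple[EnsembleReport, list[ChannelResult]]:
    """Full run over all (or selected) channels, fused with IHMV.

    Precomputed per-channel feature matrices may be supplied to avoid
    re-extracting when several schemes are run on the same dataset.
    """
    cfg = cfg or PipelineConfig()
    n_ch = records[0].n_channels
    channels = channels if channels is not None else list(range(n_ch))
    if len(channels) < 3:
        raise ValueError("voting needs at least 3 channels")
    results = []
    truth = np.array([r.label for r in records])
    for ch in channels:
        fm = (
            feature_matrices[ch]
            if feature_matrices is not None and ch in feature_matrices
            else extract_dataset_features(records, ch, cfg.tqwt, use_scaling_band=cfg.use_scaling_band)
        )
        log.info("channel %d: %d x %d features", ch, fm.n_records, fm.n_features)
        results.append(run_channel(fm, ch, cfg))
    _, report = ihmv([r.prediction for r in results], truth)
    return report, results
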