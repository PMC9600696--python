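"""Seeded synthetic multichannel EEG datasets.

Each record is a 14-channel, 512-sample (4 s at 128 Hz) epoch built as a
sum of band-limited Gaussian-noise components in the four classical EEG
rhythm bands (delta 0.5-4 Hz, theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz)
plus white noise.  The two classes differ by per-band power multipliers:
by default the second class carries 1.8x theta power and 0.6x beta power,
a theta/beta contrast of the kind reported in ADHD EEG studies, so the
classes are genuinely separable through any feature set sensitive to
subband power or waveform shape.

Subjects carry multiplicative lognormal random effects on their band
powers, shared by all of a subject's records, which makes
leave-one-subject-out validation strictly harder than record-level
ten-fold splitting.  Channels mix a shared per-band source with
channel-specific noise, so they are correlated but not identical.  All
randomness flows from one seed; generation is fully reproducible.

No claim of physiological realism is made: there is no volume conduction,
no 1/f fit, and no artifact model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .records import (
    DEFAULT_N_CHANNELS,
    DEFAULT_N_SAMPLES,
    DEFAULT_SAMPLE_RATE,
    LABEL_ADHD,
    LABEL_HEALTHY,
    EEGRecord,
    write_dataset,
)

__all__ = ["BANDS", "SynthConfig", "generate_records", "generate_dataset"]

#: classical EEG rhythm bands, Hz
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass
class SynthConfig:
    """Generation parameters; defaults give 200 records from 20 subjects."""

    n_subjects_per_class: int = 10
    records_per_subject: int = 10
    n_channels: int = DEFAULT_N_CHANNELS
    n_samples: int = DEFAULT_N_SAMPLES
    sample_rate: float = DEFAULT_SAMPLE_RATE
    #: baseline band powers, microvolt^2
    band_power: dict = field(
        default_factory=lambda: {"delta": 40.0, "theta": 25.0, "alpha": 20.0, "beta": 10.0}
    )
    #: class-2 (ADHD-like) power multipliers; other bands are 1.0
    class2_multipliers: dict = field(
        default_factory=lambda: {"theta": 1.8, "beta": 0.6}
    )
    #: std of the lognormal subject random effect on band power
    subject_effect_scale: float = 0.3
    #: fraction of band power carried by the channel-shared source
    shared_fraction: float = 0.5
    #: white-noise standard deviation, microvolts
    noise_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_per_class, self.records_per_subject) < 1:
            raise ValueError("subject and record counts must be >= 1")
        if any(v <= 0 for v in self.band_power.values()):
            raise ValueError("band powers must be > 0")
        if any(v <= 0 for v in self.class2_multipliers.values()):
            raise ValueError("class multipliers must be > 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


def _band_filters(cfg: SynthConfig) -> dict:
    nyq = cfg.sample_rate / 2.0
    filters = {}
    for name, (lo, hi) in BANDS.items():
        b, a = butter(4, [lo / nyq, hi / nyq], btype="bandpass")
        filters[name] = (b, a)
    return filters


def _band_noise(rng: np.random.Generator, ba, n: int) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise of length n."""
    b, a = ba
    x = filtfilt(b, a, rng.standard_normal(n + 256))[128 : 128 + n]
    sd = np.std(x)
    return x / sd if sd > 0 else x


def generate_records(cfg: SynthConfig | None = None) -> list[EEGRecord]:
    """Generate the dataset in memory, deterministically from ``cfg.seed``."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    filters = _band_filters(cfg)
    records: list[EEGRecord] = []
    for label in (LABEL_HEALTHY, LABEL_ADHD):
        cls = "h" if label == LABEL_HEALTHY else "a"
        for s in range(cfg.n_subjects_per_class):
            subject_id = f"subj_{cls}{s + 1:03d}"
            subject_effect = {
                band: float(np.exp(rng.normal(0.0, cfg.subject_effect_scale)))
                for band in BANDS
            }
            for rix in range(cfg.records_per_subject):
                data = np.zeros((cfg.n_channels, cfg.n_samples))
                for band in BANDS:
                    power = cfg.band_power[band] * subject_effect[band]
                    if label == LABEL_ADHD:
                        power *= cfg.class2_multipliers.get(band, 1.0)
                    amp = np.sqrt(power)
                    shared = _band_noise(rng, filters[band], cfg.n_samples)
                    w_shared = np.sqrt(cfg.shared_fraction)
                    w_own = np.sqrt(1.0 - cfg.shared_fraction)
                    for ch in range(cfg.n_channels):
                        own = _band_noise(rng, filters[band], cfg.n_samples)
                        data[ch] += amp * (w_shared * shared + w_own * own)
                data += cfg.noise_scale * rng.standard_normal(data.shape)
                records.append(
                    EEGRecord(
                        record_id=f"rec_{cls}{s + 1:03d}_{rix + 1:03d}",
                        subject_id=subject_id,
                        label=label,
                        data=data,
                        sample_rate=cfg.sample_rate,
                    )
                )
    return records


def generate_dataset(cfg: SynthConfig | None = None, out_dir: str | Path | None = None):
    """Generate records and, if ``out_dir`` is given, write them to disk.

    Returns ``(records, manifest_path)``; ``manifest_path`` is None for a
    purely in-memory dataset.
    """
    cfg = cfg or SynthConfig()
    records = generate_records(cfg)
    manifest_path = None
    if out_dir is not None:
        manifest_path = write_dataset(records, out_dir)
    return records, manifest_path
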