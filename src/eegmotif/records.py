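"""Dataset model and on-disk formats.

An EEG dataset is a directory of plain-text record matrices (one file per
fixed-length epoch, channels as rows, samples as columns) plus a CSV
manifest with columns ``record_id,subject_id,label,path``.  Labels are
stored as strings in the manifest (``healthy``/``adhd``, or already-encoded
``1``/``2``) and mapped internally to the integer codes 1 (healthy) and
2 (ADHD).  Subject ids group epochs for leave-one-subject-out validation.

Feature matrices round-trip through CSV with full float precision; column
headers carry the feature provenance ``L<level>:<extractor>:<index>``.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_HEALTHY",
    "LABEL_ADHD",
    "LABEL_CODES",
    "DEFAULT_N_CHANNELS",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_SAMPLE_RATE",
    "EEGRecord",
    "DatasetManifest",
    "FeatureColumn",
    "FeatureMatrix",
    "encode_label",
    "read_dataset",
    "write_dataset",
    "read_feature_matrix",
    "write_feature_matrix",
    "load_config",
    "setup_logging",
    "read_edf_records",
]

LABEL_HEALTHY = 1
LABEL_ADHD = 2
LABEL_CODES = {"healthy": LABEL_HEALTHY, "adhd": LABEL_ADHD, "1": LABEL_HEALTHY, "2": LABEL_ADHD}
LABEL_NAMES = {LABEL_HEALTHY: "healthy", LABEL_ADHD: "adhd"}

DEFAULT_N_CHANNELS = 14
DEFAULT_N_SAMPLES = 512
DEFAULT_SAMPLE_RATE = 128.0

#: full-precision float format used for all text matrices (exact roundtrip)
FLOAT_FMT = "%.17g"

log = logging.getLogger("eegmotif")


def encode_label(label: object) -> int:
    """Map a manifest label (string or int) to the integer code 1 or 2."""
    key = str(label).strip().lower()
    if key not in LABEL_CODES:
        raise ValueError(f"unknown class label {label!r}; expected healthy/adhd or 1/2")
    return LABEL_CODES[key]


@dataclass
class EEGRecord:
    """One fixed-length multichannel EEG epoch."""

    record_id: str
    subject_id: str
    label: int
    data: np.ndarray  # channels x samples, microvolt-scale
    sample_rate: float = DEFAULT_SAMPLE_RATE
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[0])]

    def validate(self, n_channels: int = DEFAULT_N_CHANNELS, n_samples: int = DEFAULT_N_SAMPLES) -> None:
        if self.data.ndim != 2 or self.data.shape != (n_channels, n_samples):
            raise ValueError(
                f"record {self.record_id!r}: expected {n_channels} x {n_samples} "
                f"matrix, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"record {self.record_id!r}: non-finite samples")
        if self.label not in (LABEL_HEALTHY, LABEL_ADHD):
            raise ValueError(f"record {self.record_id!r}: invalid label {self.label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class DatasetManifest:
    """Table of records in a dataset directory."""

    rows: pd.DataFrame  # record_id, subject_id, label (str), path
    sample_rate: float = DEFAULT_SAMPLE_RATE
    n_channels: int = DEFAULT_N_CHANNELS

    def validate(self) -> None:
        required = {"record_id", "subject_id", "label", "path"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.rows["record_id"].duplicated().any():
            dup = self.rows.loc[self.rows["record_id"].duplicated(), "record_id"].iloc[0]
            raise ValueError(f"duplicate record_id {dup!r} in manifest")
        labels = {encode_label(v) for v in self.rows["label"]}
        if labels != {LABEL_HEALTHY, LABEL_ADHD}:
            raise ValueError("manifest must contain both classes (healthy and adhd)")


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    rows = pd.read_csv(path, dtype=str)
    m = DatasetManifest(rows=rows)
    m.validate()
    return m


def _read_matrix(path: Path) -> np.ndarray:
    """Delimited text matrix; accepts comma or whitespace separation."""
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    return np.loadtxt(path, delimiter=delim, ndmin=2)


def read_dataset(
    manifest_path: str | Path,
    n_channels: int = DEFAULT_N_CHANNELS,
    n_samples: int = DEFAULT_N_SAMPLES,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> list[EEGRecord]:
    """Read and validate every record listed in a manifest, in manifest order."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    records = []
    for row in manifest.rows.itertuples(index=False):
        rec_path = Path(row.path)
        if not rec_path.is_absolute():
            rec_path = base / rec_path
        if not rec_path.exists():
            raise FileNotFoundError(f"record file not found: {rec_path}")
        rec = EEGRecord(
            record_id=str(row.record_id),
            subject_id=str(row.subject_id),
            label=encode_label(row.label),
            data=_read_matrix(rec_path),
            sample_rate=sample_rate,
        )
        rec.validate(n_channels=n_channels, n_samples=n_samples)
        records.append(rec)
    return records


def write_dataset(records: list[EEGRecord], out_dir: str | Path) -> Path:
    """Write records as text matrices plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "records").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rel = f"records/{rec.record_id}.txt"
        np.savetxt(out_dir / rel, rec.data, fmt=FLOAT_FMT, delimiter=",")
        rows.append(
            {
                "record_id": rec.record_id,
                "subject_id": rec.subject_id,
                "label": LABEL_NAMES[rec.label],
                "path": rel,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


@dataclass(frozen=True)
class FeatureColumn:
    """Provenance of one feature column."""

    level: int  # 0 = raw signal, 1..J are detail subbands, J+1 scaling band
    extractor: str  # "tmp" or "stat"
    index: int  # within-extractor index

    def tag(self) -> str:
        return f"L{self.level}:{self.extractor}:{self.index}"

    @classmethod
    def from_tag(cls, tag: str) -> "FeatureColumn":
        try:
            lvl, ext, idx = tag.split(":")
            return cls(level=int(lvl[1:]), extractor=ext, index=int(idx))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed feature column tag {tag!r}") from exc


@dataclass
class FeatureMatrix:
    """Records-by-features table with provenance metadata."""

    values: np.ndarray
    columns: list[FeatureColumn]
    record_ids: list[str]
    subject_ids: list[str]
    labels: np.ndarray  # integer codes, aligned with rows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column metadata length does not match column count")
        n = self.values.shape[0]
        if not (len(self.record_ids) == len(self.subject_ids) == len(self.labels) == n):
            raise ValueError("row metadata length does not match row count")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV with provenance header; values keep full precision."""
    if fm.n_records == 0:
        raise ValueError("no records in feature matrix")
    df = pd.DataFrame(fm.values, columns=[c.tag() for c in fm.columns])
    df.insert(0, "record_id", fm.record_ids)
    df.insert(1, "subject_id", fm.subject_ids)
    df.insert(2, "label", fm.labels)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature matrix not found: {path}")
    df = pd.read_csv(path)
    meta = {"record_id", "subject_id", "label"}
    if not meta <= set(df.columns):
        raise ValueError(f"feature CSV {path} missing metadata columns {sorted(meta)}")
    feat_cols = [c for c in df.columns if c not in meta]
    columns = [FeatureColumn.from_tag(c) for c in feat_cols]
    values = df[feat_cols].to_numpy(dtype=float)
    return FeatureMatrix(
        values=values,
        columns=columns,
        record_ids=[str(v) for v in df["record_id"]],
        subject_ids=[str(v) for v in df["subject_id"]],
        labels=df["label"].to_numpy(dtype=int),
    )


def load_config(path: str | Path) -> dict:
    """Read a configuration file.

    The native format is one ``key = value`` pair per line, with ``#``
    comments; ``.yaml``/``.yml`` files are also accepted.  Documented keys:
    Q, r, J, k, selected_feature_count, threshold, cv_scheme, seed.
    """
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cfg
    cfg: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        for caster in (int, float):
            try:
                cfg[key] = caster(val)
                break
            except ValueError:
                continue
        else:
            cfg[key] = val
    return cfg


def setup_logging(verbose: bool = False, logfile: str | Path | None = None) -> None:
    """Timestamped logging to stderr and optionally a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def read_edf_records(
    path: str | Path,
    subject_id: str,
    label: object,
    n_samples: int = DEFAULT_N_SAMPLES,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> list[EEGRecord]:
    """Optional European Data Format reader (requires ``mne``).

    Each EDF signal becomes a channel; the recording is cut into
    consecutive non-overlapping epochs of ``n_samples`` starting at sample
    0, dropping any trailing partial epoch.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    code = encode_label(label)
    stem = Path(path).stem
    records = []
    for i in range(data.shape[1] // n_samples):
        seg = data[:, i * n_samples : (i + 1) * n_samples]
        records.append(
            EEGRecord(
                record_id=f"{stem}_e{i:04d}",
                subject_id=subject_id,
                label=code,
                data=seg,
                sample_rate=sample_rate,
                channel_names=list(raw.ch_names),
            )
        )
    return records
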