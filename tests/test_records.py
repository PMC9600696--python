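"""Dataset and feature-matrix I/O: roundtrips, validation, config parsing."""

import numpy as np
import pandas as pd
import pytest

from eegmotif import (
    EEGRecord,
    FeatureColumn,
    FeatureMatrix,
    encode_label,
    read_dataset,
    read_feature_matrix,
    write_dataset,
    write_feature_matrix,
)
from eegmotif.records import load_config


class TestLabels:
    @pytest.mark.parametrize(
        "raw,code", [("healthy", 1), ("adhd", 2), ("ADHD", 2), ("1", 1), (2, 2)]
    )
    def test_encoding(self, raw, code):
        assert encode_label(raw) == code

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown class label"):
            encode_label("bipolar")


class TestDatasetRoundTrip:
    def test_write_then_read_is_identity(self, small_dataset, tmp_path):
        manifest = write_dataset(small_dataset, tmp_path)
        back = read_dataset(manifest)
        assert len(back) == len(small_dataset)
        for a, b in zip(small_dataset, back):
            assert a.record_id == b.record_id
            assert a.subject_id == b.subject_id
            assert a.label == b.label
            # %.17g text roundtrip is exact for doubles
            np.testing.assert_array_equal(a.data, b.data)

    def test_manifest_order_preserved(self, small_dataset, tmp_path):
        manifest = write_dataset(small_dataset, tmp_path)
        ids = [r.record_id for r in read_dataset(manifest)]
        assert ids == [r.record_id for r in small_dataset]

    def test_wrong_channel_count_names_record(self, small_dataset, tmp_path):
        subset = small_dataset[:2] + small_dataset[-2:]
        manifest = write_dataset(subset, tmp_path)
        bad = subset[0].record_id
        np.savetxt(tmp_path / "records" / f"{bad}.txt", np.zeros((13, 512)), delimiter=",")
        with pytest.raises(ValueError, match=bad):
            read_dataset(manifest)

    def test_missing_record_file_names_path(self, small_dataset, tmp_path):
        subset = small_dataset[:2] + small_dataset[-2:]
        manifest = write_dataset(subset, tmp_path)
        (tmp_path / "records" / f"{subset[1].record_id}.txt").unlink()
        with pytest.raises(FileNotFoundError, match=subset[1].record_id):
            read_dataset(manifest)

    def test_unknown_label_in_manifest(self, small_dataset, tmp_path):
        manifest = write_dataset(small_dataset[:2] + small_dataset[-2:], tmp_path)
        df = pd.read_csv(manifest)
        df.loc[0, "label"] = "unsure"
        df.to_csv(manifest, index=False)
        with pytest.raises(ValueError):
            read_dataset(manifest)

    def test_single_class_manifest_rejected(self, small_dataset, tmp_path):
        healthy_only = [r for r in small_dataset if r.label == 1][:4]
        manifest = write_dataset(healthy_only, tmp_path)
        with pytest.raises(ValueError, match="both classes"):
            read_dataset(manifest)


class TestRecordValidation:
    def test_shape_enforced(self):
        rec = EEGRecord("r1", "s1", 1, np.zeros((14, 100)))
        with pytest.raises(ValueError, match="r1"):
            rec.validate()

    def test_non_finite_rejected(self):
        data = np.zeros((14, 512))
        data[3, 5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            EEGRecord("r2", "s1", 1, data).validate()


def _small_fm(rng, n=3, d=40):
    cols = [FeatureColumn(level=i % 19, extractor="tmp" if i % 2 else "stat", index=i) for i in range(d)]
    return FeatureMatrix(
        values=rng.normal(size=(n, d)) * 1e3,
        columns=cols,
        record_ids=[f"r{i}" for i in range(n)],
        subject_ids=[f"s{i // 2}" for i in range(n)],
        labels=np.array([1, 2, 1][:n]),
    )


class TestFeatureMatrixIO:
    def test_roundtrip_preserves_values_and_metadata(self, rng, tmp_path):
        fm = _small_fm(rng)
        path = tmp_path / "fm.csv"
        write_feature_matrix(fm, path)
        back = read_feature_matrix(path)
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert back.columns == fm.columns
        assert back.record_ids == fm.record_ids
        assert back.subject_ids == fm.subject_ids
        np.testing.assert_array_equal(back.labels, fm.labels)

    def test_empty_matrix_rejected(self, rng, tmp_path):
        fm = _small_fm(rng)
        fm.values = fm.values[:0]
        fm.record_ids, fm.subject_ids, fm.labels = [], [], np.array([], dtype=int)
        with pytest.raises(ValueError, match="no records"):
            write_feature_matrix(fm, tmp_path / "empty.csv")

    def test_malformed_header_rejected(self, rng, tmp_path):
        fm = _small_fm(rng)
        path = tmp_path / "fm.csv"
        write_feature_matrix(fm, path)
        text = path.read_text().replace("L1:tmp:1", "garbage")
        path.write_text(text)
        with pytest.raises(ValueError, match="malformed"):
            read_feature_matrix(path)

    def test_metadata_column_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="column metadata"):
            FeatureMatrix(
                values=rng.normal(size=(2, 3)),
                columns=[FeatureColumn(0, "tmp", 0)],
                record_ids=["a", "b"],
                subject_ids=["s", "s"],
                labels=np.array([1, 2]),
            )


class TestConfig:
    def test_key_value_format(self, tmp_path):
        p = tmp_path / "run.cfg"
        p.write_text("Q = 4\nr = 3.0\nJ = 17  # levels\ncv_scheme = loso\n")
        cfg = load_config(p)
        assert cfg == {"Q": 4, "r": 3.0, "J": 17, "cv_scheme": "loso"}

    def test_yaml_format(self, tmp_path):
        p = tmp_path / "synth.yaml"
        p.write_text("seed: 3\nn_subjects_per_class: 2\n")
        assert load_config(p) == {"seed": 3, "n_subjects_per_class": 2}

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("Q 4\n")
        with pytest.raises(ValueError, match="key = value"):
            load_config(p)
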