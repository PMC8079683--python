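import numpy as np
import pandas as pd
import pytest
from PIL import Image

from radcal import data_io
from radcal.data_io import (
    Manifest, ManifestError, apply_augmentation_plan, augment_image,
    batch_stream, default_batch_size, load_manifest, preprocess_image,
    sample_augmentation_plan, scan_mura_tree, write_manifest,
)


def _write_csv(path, rows):
    header = "image_id,path,patient_id,study_id,region,label,split\n"
    path.write_text(header + "\n".join(rows) + "\n")
    return path


class TestLoadManifest:
    def test_counts_direct(self, tmp_path):
        p = _write_csv(tmp_path / "m.csv", [
            "i1,a.png,p1,s1,Elbow,0,train",
            "i2,b.png,p1,s2,Elbow,1,train",
            "i3,c.png,p2,s3,Wrist,1,train",
        ])
        m = load_manifest(p)
        assert m.counts() == (2, 1)

    def test_bad_label_cites_row(self, tmp_path):
        rows = [f"i{k},x{k}.png,p{k},s{k},Elbow,0,train" for k in range(4)]
        rows.append("i9,y.png,p9,s9,Elbow,2,train")
        p = _write_csv(tmp_path / "m.csv", rows)
        with pytest.raises(ManifestError, match="row 5"):
            load_manifest(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("image_id,path,patient_id,study_id,region,label\ni,a,p,s,Elbow,0\n")
        with pytest.raises(ManifestError, match="split"):
            load_manifest(p)

    def test_duplicate_image_id(self, tmp_path):
        p = _write_csv(tmp_path / "m.csv", [
            "i1,a.png,p1,s1,Elbow,0,train",
            "i1,b.png,p1,s1,Elbow,0,train",
        ])
        with pytest.raises(ManifestError, match="duplicate image_id"):
            load_manifest(p)

    def test_published_elbow_train_counts(self, tmp_path):
        # 1734 abnormal / 2584 normal, as in the public benchmark's table
        rows = [f"a{k},a{k}.png,p{k},s{k},Elbow,1,train" for k in range(1734)]
        rows += [f"n{k},n{k}.png,q{k},t{k},Elbow,0,train" for k in range(2584)]
        m = load_manifest(_write_csv(tmp_path / "m.csv", rows))
        assert m.counts(split="train", region="Elbow") == (1734, 2584)

    def test_round_trip(self, tmp_path, small_dataset):
        out = tmp_path / "rt.csv"
        write_manifest(small_dataset.manifest, out)
        again = load_manifest(out)
        pd.testing.assert_frame_equal(again.df, small_dataset.manifest.df)

    def test_inconsistent_study_rejected(self, tmp_path):
        p = _write_csv(tmp_path / "m.csv", [
            "i1,a.png,p1,s1,Elbow,0,train",
            "i2,b.png,p1,s1,Elbow,1,train",  # same study, other label
        ])
        with pytest.raises(ManifestError, match="s1"):
            load_manifest(p)


class TestScanMuraTree:
    def _make_tree(self, root, entries):
        for rel in entries:
            p = root / rel
            p.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(p)

    def test_positive_parse(self, tmp_path):
        self._make_tree(tmp_path, ["train/XR_ELBOW/patient001/study1_positive/image1.png"])
        m = scan_mura_tree(tmp_path)
        r = m.records[0]
        assert (r.region, r.label, r.split) == ("Elbow", 1, "train")

    def test_negative_parse(self, tmp_path):
        self._make_tree(tmp_path, ["valid/XR_WRIST/patient002/study2_negative/image1.png"])
        m = scan_mura_tree(tmp_path)
        assert m.records[0].label == 0
        assert m.records[0].split == "validation"

    def test_two_studies_two_views(self, tmp_path):
        self._make_tree(tmp_path, [
            "train/XR_HAND/patient001/study1_positive/image1.png",
            "train/XR_HAND/patient001/study1_positive/image2.png",
            "train/XR_HAND/patient002/study1_negative/image1.png",
            "train/XR_HAND/patient002/study1_negative/image2.png",
        ])
        m = scan_mura_tree(tmp_path)
        assert len(m) == 4
        assert len(m.studies()) == 2

    def test_weird_suffix_skipped(self, tmp_path, caplog):
        self._make_tree(tmp_path, ["train/XR_HAND/patient001/study1_unsure/image1.png"])
        with caplog.at_level("WARNING"):
            m = scan_mura_tree(tmp_path)
        assert len(m) == 0
        assert "neither" in caplog.text

    def test_unknown_region(self, tmp_path):
        self._make_tree(tmp_path, ["train/XR_KNEE/patient001/study1_positive/image1.png"])
        with pytest.raises(ManifestError, match="XR_KNEE"):
            scan_mura_tree(tmp_path)
        assert len(scan_mura_tree(tmp_path, on_unknown_region="skip")) == 0


class TestPreprocess:
    def test_255_maps_to_1(self):
        out = preprocess_image(np.full((10, 10), 255.0))
        assert out.shape == (256, 256)
        assert np.allclose(out, 1.0)

    def test_0_maps_to_0(self):
        assert np.allclose(preprocess_image(np.full((300, 300), 0.0)), 0.0)

    def test_resize_shape(self):
        out = preprocess_image(np.random.default_rng(0).integers(
            0, 256, (512, 132)).astype(float))
        assert out.shape == (256, 256)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_idempotent(self, rng):
        once = preprocess_image(rng.integers(0, 256, (100, 80)).astype(float))
        np.testing.assert_array_equal(preprocess_image(once), once)

    def test_constant_stays_constant(self):
        out = preprocess_image(np.full((40, 60), 128.0))
        assert np.allclose(out, 128.0 / 255.0)

    def test_out_of_range_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            out = preprocess_image(np.full((4, 4), 300.0))
        assert np.allclose(out, 1.0)
        assert "clamp" in caplog.text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((0, 0)))


class TestAugment:
    def test_deterministic(self, rng):
        img = np.random.default_rng(0).random((32, 32))
        a = augment_image(img, np.random.default_rng(7))
        b = augment_image(img, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_hflip_involution(self):
        img = np.random.default_rng(0).random((16, 16))
        np.testing.assert_array_equal(
            apply_augmentation_plan(apply_augmentation_plan(img, ["hflip"]), ["hflip"]),
            img)

    def test_sampler_monte_carlo(self):
        rng = np.random.default_rng(123)
        ks = []
        for _ in range(1000):
            plan = sample_augmentation_plan(rng)
            ks.append(len(plan))
            names = [p if isinstance(p, str) else p[0] for p in plan]
            assert len(set(names)) == len(names)  # without replacement
            for p in plan:
                if not isinstance(p, str):
                    assert -30.0 <= p[1] <= 30.0
        assert set(ks) == {1, 2, 3}

    def test_range_preserved(self, rng):
        img = np.random.default_rng(1).random((20, 20))
        for _ in range(50):
            out = augment_image(img, rng)
            assert out.shape == img.shape
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestBatchStream:
    def test_batch_sizes(self, small_dataset, rng):
        m = small_dataset.manifest.subset(region="Elbow")
        ten = Manifest(m.subset(split="train").df.head(10))
        sizes = [len(y) for _, y in batch_stream(ten, 3, rng, split="train",
                                                 image_size=32)]
        assert sizes == [3, 3, 3, 1]

    def test_same_seed_same_order(self, small_dataset):
        m = small_dataset.manifest
        a = [y for _, y in batch_stream(m, 16, np.random.default_rng(5),
                                        split="train", image_size=32)]
        b = [y for _, y in batch_stream(m, 16, np.random.default_rng(5),
                                        split="train", image_size=32)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_epoch_label_coverage(self, small_dataset, rng):
        m = small_dataset.manifest
        got = np.concatenate([y for _, y in batch_stream(
            m, 7, rng, split="train", image_size=32)])
        want = m.subset(split="train").df["label"].to_numpy()
        assert sorted(got) == sorted(want)

    def test_empty_split_rejected(self, manifest_factory, rng):
        m = manifest_factory([("i1", "a.png", "p", "s", "Elbow", 0, "test")])
        with pytest.raises(ManifestError):
            next(batch_stream(m, 2, rng, split="train"))

    def test_default_batch_sizes(self):
        assert default_batch_size("convnet") == 32
        assert default_batch_size("resnet") == 32
        assert default_batch_size("densenet") == 16
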