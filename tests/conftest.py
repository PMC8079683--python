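import numpy as np
import pandas as pd
import pytest

from radcal.data_io import Manifest
from radcal.synthetic import GeneratorConfig, RegionSignalSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Two-region 32px synthetic dataset shared by IO/training tests."""
    cfg = GeneratorConfig(
        (RegionSignalSpec("Elbow", "bright_implant", snr=5.0),
         RegionSignalSpec("Wrist", "line_discontinuity", snr=5.0)),
        split_counts={"train": (30, 30), "validation": (20, 20), "test": (25, 25)},
        image_size=32, seed=3)
    return generate_dataset(cfg, tmp_path_factory.mktemp("smallds"))


@pytest.fixture()
def manifest_factory():
    """Build an in-memory Manifest from compact row tuples."""
    def make(rows):
        df = pd.DataFrame(rows, columns=["image_id", "path", "patient_id",
                                         "study_id", "region", "label", "split"])
        return Manifest(df)
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
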