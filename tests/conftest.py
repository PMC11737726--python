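import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import coopvox as cv
from coopvox import classifier as cl
from coopvox import pipeline as pl

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_clean():
    """Clean desk-scale dataset (300 clips) with raw MFE features."""
    clips, manifest = cv.generate_clips(cv.MINI_COMPOSITION, seed=11)
    x = pl.featurize_clips(clips, pl.RunConfig(), apply_denoise=False)
    return {
        "clips": clips,
        "manifest": manifest,
        "x": x,
        "labels": manifest["label"].to_numpy(),
        "is_train": (manifest["split"] == "train").to_numpy(),
    }


@pytest.fixture(scope="session")
def trained_mini_model(mini_clean):
    """The CNN trained on the clean desk-scale dataset."""
    d = mini_clean
    tr = d["is_train"]
    model = cl.build_model(
        cl.ModelConfig(input_shape=tuple(d["x"].shape[1:])), seed=11)
    return cl.train(model, d["x"][tr], d["labels"][tr],
                    d["x"][~tr], d["labels"][~tr],
                    cl.TrainConfig(epochs=30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
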