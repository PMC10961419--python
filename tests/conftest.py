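import numpy as np
import pytest

from remshuffle.backbone import build_model, tiny_preset
from remshuffle.synth import easy_spec, generate_arrays
from remshuffle.training import TrainConfig, train


@pytest.fixture(scope="session")
def easy_dataset():
    """The default easy 4-class synthetic dataset (seed 0)."""
    xtr, ytr, xte, yte, order = generate_arrays(easy_spec(seed=0))
    return {"xtr": xtr, "ytr": ytr, "xte": xte, "yte": yte, "classes": order}


@pytest.fixture(scope="session")
def sanity_run(easy_dataset):
    """The learning-sanity experiment: desk-scale model with all REM features
    trained for 10 epochs on the easy synthetic set at the standard
    hyperparameters.  Shared across tests (one run per session).
    """
    d = easy_dataset
    model = build_model(tiny_preset(num_classes=4, input_size=64), seed=0)
    untrained_acc = float(np.mean(model.predict(d["xte"]) == d["yte"]))
    cfg = TrainConfig(epochs=10, seed=0)
    history = train(model, (d["xtr"], d["ytr"]), (d["xte"], d["yte"]), cfg)
    return {"model": model, "history": history, "config": cfg,
            "untrained_accuracy": untrained_acc, **d}
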