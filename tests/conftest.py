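import numpy as np
import pytest

from roca import synth, sketchnet


@pytest.fixture(scope="session")
def tiny_trained():
    """A small classifier trained briefly on a small synthetic set.

    Deliberately scaled down (32 px input, one fire module, 60 drawings,
    6 epochs) so unit tests of the classify/evaluate/checkpoint paths stay
    fast; the full-scale training run lives in the acceptance suite.
    """
    pairs = synth.generate_labeled_dataset(20, 0.5, seed=42)
    # thicker strokes: at 32 px the default 2 px line nearly vanishes
    spec = sketchnet.PreprocessSpec(out_size=32, stroke_thickness=6)
    x, labels = sketchnet.drawings_to_arrays(pairs, spec)
    config = sketchnet.NetConfig(input_size=32, stem_channels=8,
                                 fire_specs=((4, 8, 8),), pool_after=(0,), seed=1)
    model = sketchnet.build_model(config)
    clf, report = sketchnet.train(model, x, labels,
                                  sketchnet.TrainSpec(epochs=30, batch_size=8,
                                                      seed=2, learning_rate=3e-3),
                                  preprocess=spec)
    return clf, report, pairs
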