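"""Shared fixtures: one synthetic field and one trained classifier per session.

The heavy artefacts (a 500-head overflowed field, its calibrated raster and a
classifier trained + localisation-refined on it) are built once and reused by
the detection, sizing and CLI tests.
"""

import numpy as np
import pytest

from lettucescan.calibration import calibrate
from lettucescan.classifier import (ModelConfig, build_model, online_update,
                                    train)
from lettucescan.detection import select_overlap_param
from lettucescan.synthetic_field import (FieldSpec, generate_field,
                                         generate_localisation_patches,
                                         generate_patch_dataset)


@pytest.fixture(scope="session")
def field_bundle():
    """(spec, raw image, truth, calibrated image) for a 500-head field."""
    spec = FieldSpec.for_count(500, overflow=True, seed=7)
    img, truth = generate_field(spec)
    return spec, img, truth, calibrate(img)


@pytest.fixture(scope="session")
def trained_model(field_bundle):
    """Classifier trained on the session field, plus its base history."""
    _spec, _img, truth, cal = field_bundle
    cfg = ModelConfig(seed=7)
    patches = generate_patch_dataset(cal, truth, 2000, seed=7)
    model, base_history = train(build_model(cfg), patches, cfg)
    base = (list(base_history.train_acc), list(base_history.val_acc),
            base_history.stopping_epoch)
    extra = generate_localisation_patches(cal, truth, 1000, seed=8)
    online_update(model, extra, cfg)
    return model, base


@pytest.fixture(scope="session")
def overlap_thresh(trained_model, field_bundle):
    """NMS threshold selected on the session field's ground truth."""
    model, _ = trained_model
    _spec, _img, truth, cal = field_bundle
    return select_overlap_param(model, [(cal, truth)])


@pytest.fixture(scope="session")
def weights_file(trained_model, tmp_path_factory):
    from lettucescan.classifier import save_model
    model, _ = trained_model
    path = tmp_path_factory.mktemp("weights") / "model.npz"
    save_model(model, path)
    return path
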