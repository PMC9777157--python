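"""Shared fixtures: phantom datasets and a small trained base CNN.

Everything is generated programmatically at test time; no stored fixtures.
The session-scoped trained model is intentionally small (70 images, a few
epochs) - enough signal for the seeded regression assertions downstream.
"""

from __future__ import annotations

import numpy as np
import pytest

from oagrade import cnn, phantom, preprocess

SESSION_SEED = 11


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """Small on-disk phantom dataset: 12 images per grade, default noise."""
    out = tmp_path_factory.mktemp("phantoms")
    dataset = phantom.generate_dataset([12] * 5, seed=SESSION_SEED, out_dir=out)
    return out, dataset


@pytest.fixture(scope="session")
def split_arrays(phantom_dir):
    """Preprocessed arrays split into train/valid/test (stratified, seeded)."""
    out, dataset = phantom_dir
    split = preprocess.holdout_split(
        dataset, preprocess.SplitSpec(seed=SESSION_SEED)
    )
    raw = phantom.load_images(split, out)
    x = preprocess.preprocess_stack(raw)
    tags = np.array([r.split for r in split.records])
    grades = split.grades
    data = {"split": split}
    for tag in ("train", "valid", "test"):
        mask = tags == tag
        data[f"x_{tag}"] = x[mask]
        data[f"y_{tag}"] = grades[mask]
    return data


@pytest.fixture(scope="session")
def trained_model(split_arrays):
    """Base CNN trained briefly on the session phantoms (seeded)."""
    model = cnn.build_base_cnn(5, seed=SESSION_SEED)
    config = cnn.TrainConfig(
        epochs=4, batch_size=32, chunk_size=16, seed=SESSION_SEED
    )
    history = cnn.train(
        model,
        split_arrays["x_train"],
        split_arrays["y_train"],
        config,
        x_valid=split_arrays["x_valid"],
        y_valid=split_arrays["y_valid"],
    )
    return model, history
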