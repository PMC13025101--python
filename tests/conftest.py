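"""Shared fixtures.

The trained models are expensive, so they are built once per session:
``model2d`` at the full benchmark scale used by the acceptance criteria
(64 spectra x 256 peaks, ~2e5 resampled cross-objectives), and quick
reduced models for the 3D pipeline contract tests.
"""

import numpy as np
import pytest

from p3nmr.benchmarks import (bench_grid_2d, bench_grid_3d, train_2d_model,
                              train_projection_model, train_3d_model)
from p3nmr.network import TrainConfig


@pytest.fixture(scope="session")
def model2d():
    """Benchmark-scale 2D model (the one the acceptance criteria grade)."""
    cfg = TrainConfig(learning_rate=3e-3, lr_schedule="cosine", batch_size=4096,
                      max_epochs=75, patience=75, recalibrate_to_ratio=0.01,
                      seed=1)
    model, history = train_2d_model(seed=1, n_spectra=64, n_total=200_000,
                                    config=cfg)
    model.train_meta["history"] = history
    return model


@pytest.fixture(scope="session")
def quick_train_config():
    return TrainConfig(learning_rate=3e-3, lr_schedule="cosine", batch_size=4096,
                       max_epochs=30, patience=30, recalibrate_to_ratio=0.01,
                       seed=2)


@pytest.fixture(scope="session")
def proj_model(quick_train_config):
    """Reduced-scale skyline-projection model (bimodal noise corpus)."""
    model, _ = train_projection_model(seed=2, n_spectra=12, n_total=30_000,
                                      config=quick_train_config)
    return model


@pytest.fixture(scope="session")
def model3d(quick_train_config):
    """Reduced-scale 3D model (Cauchy-Gaussian mixture corpus)."""
    model, _ = train_3d_model(seed=2, n_spectra=6, n_total=30_000,
                              config=quick_train_config)
    return model
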