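"""Shared fixtures: one default synthetic run reused across test modules."""

import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hexspot import (
    PipelineConfig,
    SyntheticConfig,
    evaluate_spots,
    generate_hex_microarray,
    run_pipeline,
)

warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def hex_case():
    """Default hexagonal microarray (8x20, d=14, 2% missing, 5% weak, seed 42)."""
    cfg = SyntheticConfig()
    image, truth = generate_hex_microarray(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def pipeline_run(hex_case):
    """Full pipeline result on the default image."""
    _, image, _ = hex_case
    return run_pipeline(image)


@pytest.fixture(scope="session")
def quality(hex_case, pipeline_run):
    cfg, _, truth = hex_case
    return evaluate_spots(pipeline_run.spots, truth.spots, spot_diameter=cfg.spot_diameter)


@pytest.fixture(scope="session")
def wide_amplitude_run():
    """160 spots with amplitudes over a 20-fold range (intensity-fidelity case)."""
    cfg = SyntheticConfig(
        seed=7,
        spot_amplitude_range=(3000.0, 60000.0),
        weak_fraction=0.0,
        missing_fraction=0.0,
        noise_sigma=0.02 * 60000.0,
    )
    image, truth = generate_hex_microarray(cfg)
    result = run_pipeline(image)
    report = evaluate_spots(result.spots, truth.spots, spot_diameter=cfg.spot_diameter)
    return cfg, truth, result, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
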