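"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexnet import (
    ConditionSpec,
    ExpressionMatrix,
    ModuleSpec,
    SampleMetadata,
    SyntheticConfig,
    TFSetSpec,
    generate,
)

#: short half-log dose grid used by the small fixtures (molar)
SMALL_DOSES = (0.0,) + tuple(float(1e-9 * 10 ** (0.5 * k)) for k in range(11))


def small_config(seed: int = 0, **kwargs) -> SyntheticConfig:
    """A fast 3-module design (~500 genes, 24 samples) for unit tests."""
    defaults = dict(
        seed=seed,
        conditions=(ConditionSpec("estrogen", SMALL_DOSES, 2),),
        modules=(
            ModuleSpec(60, 0.8, 0.7, "monotonic"),
            ModuleSpec(60, 0.8, -0.7, "monotonic"),
            ModuleSpec(60, 0.8, 0.0, "null"),
        ),
        background_genes=320,
        tf_sets=(TFSetSpec(0, 0.5, 30), TFSetSpec(1, 0.5, 30)),
    )
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config(seed=0))


@pytest.fixture(scope="session")
def default_dataset():
    """The benchmark design: 5 modules x 100 genes, 1500 background, 36 samples."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture()
def tiny_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(
        rng.normal(5, 1, size=(12, 8)),
        index=[f"G{i}" for i in range(12)],
        columns=[f"S{j}" for j in range(8)],
    )
    return ExpressionMatrix(frame)


@pytest.fixture()
def tiny_metadata(tiny_expression) -> SampleMetadata:
    doses = [0.0, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3]
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": tiny_expression.sample_ids,
                "condition": ["estrogen"] * 8,
                "dose_molar": doses,
                "replicate": [1] * 8,
            }
        )
    )
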