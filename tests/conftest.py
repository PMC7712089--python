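import numpy as np
import pytest

from glvenrich import (
    DiscrepancyParams,
    EnrichedModel,
    GeneratorConfig,
    GLVModel,
    sample_detailed_model,
    subsample_partial_model,
)

# The fixed two-species showcase system and its one-species reduction.
POC_A = np.array([[-3.0, -1.0], [-1.0, -2.0]])
POC_R = np.array([5.0, 3.0])


@pytest.fixture(scope="session")
def poc_detailed() -> GLVModel:
    return GLVModel(A=POC_A, r=POC_R)


@pytest.fixture(scope="session")
def poc_partial(poc_detailed) -> GLVModel:
    return subsample_partial_model(poc_detailed, 1)


@pytest.fixture(scope="session")
def logistic_enriched() -> EnrichedModel:
    """One-species system x' = x - x^2 - 0.5|x'|."""
    return EnrichedModel(
        partial=GLVModel(A=np.array([[-1.0]]), r=np.array([1.0])),
        disc=DiscrepancyParams(delta0=np.array([0.0]), delta1=np.array([-0.5])),
    )


@pytest.fixture(scope="session")
def random_models() -> list[GLVModel]:
    """100 generator draws with varied sizes, shared across property tests."""
    rng = np.random.default_rng(20251001)
    out = []
    for _ in range(100):
        S = int(rng.integers(2, 9))
        seed = int(rng.integers(0, 2**31 - 1))
        out.append(sample_detailed_model(GeneratorConfig(S=S, seed=seed)))
    return out
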