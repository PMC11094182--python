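import numpy as np
import pandas as pd
import pytest

from mutlike import (
    PipelineConfig,
    SimulationConfig,
    generate_cohort,
    normalize,
    run_full_pipeline,
)

# study-scale conditions: 400 samples, 2000 genes, 50-gene planted program,
# 9% mutants, 10% of wild-type planted mutant-like, 1.5 log2-unit effect
REFERENCE_CONFIG = SimulationConfig(seed=11)

SMALL_CONFIG = SimulationConfig(
    n_samples=120,
    n_genes=300,
    n_program_genes=30,
    n_drugs=10,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_zscore(small_cohort):
    expr, *_ = small_cohort
    return normalize(expr)


@pytest.fixture(scope="session")
def reference_cohort():
    return generate_cohort(REFERENCE_CONFIG)


@pytest.fixture(scope="session")
def reference_report(reference_cohort):
    """Full pipeline on the study-scale cohort, shared across tests."""
    expr, ann, drugs, _ = reference_cohort
    cfg = PipelineConfig(seed=11, signature_n_iter=100)
    return run_full_pipeline(expr, ann, drugsA=drugs, config=cfg)


def jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a | b) else 1.0
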