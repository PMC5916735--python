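import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stickleseq as ss

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def uniform_annotation():
    """300 genes placed uniformly on one 10 Mb chromosome."""
    spec = ss.GenomeSpec(("chr1",), (10_000_000,), (300,), seed=100)
    return ss.simulate_annotation(spec)


@pytest.fixture(scope="session")
def small_genome():
    """~300 genes across the 21 scaled chromosomes."""
    spec = ss.scaled_genome_spec(300, seed=1)
    return spec, ss.simulate_annotation(spec)


@pytest.fixture(scope="session")
def de_run():
    """A full simulate + DE run at study-regime parameters, 2,000 genes."""
    ann = ss.simulate_annotation(ss.scaled_genome_spec(2000, seed=20))
    spec = dataclasses.replace(ss.ExpressionSpec(), seed=21)
    matrix, truth = ss.simulate_counts(ann, spec)
    result = ss.de_analysis(matrix)
    return ann, spec, matrix, truth, result


@pytest.fixture
def toy_matrix():
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 100, 5],
            "s2": [12, 1, 90, 6],
            "s3": [50, 2, 80, 0],
            "s4": [45, 0, 95, 1],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    group = pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
    return ss.CountMatrix(counts, group)
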