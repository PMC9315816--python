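"""Shared fixtures: one session-scoped synthetic universe and cohort.

The default simulation design is the package's study-condition default
(47 normal + 90 CNV subjects, 400-gene universe, planted causal pathway
of 20 genes); generating it once keeps the suite fast while every test
still exercises real generated data.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cnvcircuits.core import ExpressionBundle
from cnvcircuits.simulate import (
    SimulationDesign,
    generate_cohort,
    generate_universe,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    return SimulationDesign(rng_seed=7)


@pytest.fixture(scope="session")
def universe(design):
    return generate_universe(design)


@pytest.fixture(scope="session")
def cohort(design, universe):
    return generate_cohort(design, universe.annotation, universe.causal_genes)


def build_bundle(gene_values, samples):
    """Small hand-built expression bundle.

    gene_values: dict gene -> list of values (one per sample)
    samples: list of (sample_id, region_code, age_value, age_unit)
    """
    ids = [s[0] for s in samples]
    matrix = pd.DataFrame(
        {sid: [gene_values[g][i] for g in gene_values] for i, sid in enumerate(ids)},
        index=list(gene_values),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "region_code": [s[1] for s in samples],
            "age_value": [s[2] for s in samples],
            "age_unit": [s[3] for s in samples],
        }
    ).set_index("sample_id")
    return ExpressionBundle(matrix=matrix, sample_meta=meta)


@pytest.fixture
def tiny_bundle():
    rng = np.random.default_rng(0)
    samples = []
    k = 0
    for region in ("ACC", "STR", "Amy"):
        for age, unit in ((8.0, "pcw"), (20.0, "pcw"), (30.0, "pcw"), (365.0, "postnatal_days")):
            for _ in range(2):
                k += 1
                samples.append((f"S{k:03d}", region, age, unit))
    genes = {f"T{i}": list(np.round(rng.uniform(1, 100, len(samples)), 3)) for i in range(6)}
    return build_bundle(genes, samples)
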