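"""Shared fixtures: one default synthetic study, computed once per session."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutlike.cohort import classify_cohort, derive_signature_from_cohorts
from mutlike.datatypes import AnalysisConfig
from mutlike.simulate import simulate_gene_sets, simulate_two_cohorts

STUDY_SEED = 0


@pytest.fixture(scope="session")
def two_cohorts():
    """Two default synthetic cohorts sharing a planted 100-gene program."""
    return simulate_two_cohorts(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def signature(two_cohorts):
    """Signature derived from the two default cohorts."""
    pairs = [(expr, clin) for expr, clin, _ in two_cohorts]
    return derive_signature_from_cohorts(pairs)


@pytest.fixture(scope="session")
def panel(two_cohorts, signature):
    """Fig-1B-like panel: signature + 30 program subsets + 34 decoys."""
    expr = two_cohorts[0][0]
    return simulate_gene_sets(
        n_decoys=34,
        planted=signature.signature,
        gene_universe=expr.gene_ids,
        seed=STUDY_SEED + 1,
        n_program_subsets=30,
    )


@pytest.fixture(scope="session")
def classified(two_cohorts, panel):
    """Full subgroup call on the first default cohort, plus its truth."""
    expr, clin, truth = two_cohorts[0]
    config = AnalysisConfig(bootstrap_b=500, seed=STUDY_SEED)
    result = classify_cohort(expr, clin, panel, config=config)
    return result, truth


@pytest.fixture()
def small_expr():
    """Tiny deterministic expression matrix for unit tests."""
    from mutlike.datatypes import ExpressionMatrix

    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{i}" for i in range(8)]
    return ExpressionMatrix(
        pd.DataFrame(rng.lognormal(3, 1, size=(30, 8)), index=genes, columns=samples),
        scale="linear",
    )
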