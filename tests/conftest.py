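import numpy as np
import pandas as pd
import pytest

from senosig.io import ClinicalTable, ExpressionMatrix
from senosig.signature import GeneWeightTable
from senosig.simulate import (
    SimulationConfig,
    simulate_clinical_covariates,
    simulate_cohort,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            [[100.0, 200.0], [300.0, 50.0], [120.0, 80.0]],
            index=["s1", "s2", "s3"],
            columns=["MKI67", "CDKN1A"],
        )
    )


@pytest.fixture
def tiny_clin() -> ClinicalTable:
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "time": [12.0, 30.0, 48.0],
                "event": [1, 0, 1],
            }
        )
    )


def fixed_weight_table(genes, weights) -> GeneWeightTable:
    rows = [
        {
            "gene_id": g,
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "weight": w,
            "source": "fixed",
            "note": "",
        }
        for g, w in zip(genes, weights)
    ]
    return GeneWeightTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def effect_cohort():
    """Three simulated datasets of 150 samples sharing 40+40 effect genes."""
    cfg = SimulationConfig(n_samples=(150, 150, 150), seed=42)
    expr, clin, truth = simulate_cohort(cfg)
    clin = simulate_clinical_covariates(clin, eta=truth.eta, seed=43)
    return expr, clin, truth
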