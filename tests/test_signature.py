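"""Directional gene screen and weighted-mean scoring."""

import numpy as np
import pandas as pd
import pytest

from conftest import fixed_weight_table
from senosig.io import ExpressionMatrix, GeneListEntry, ValidationError
from senosig.signature import (
    GeneWeightTable,
    load_fixed_signature,
    score_samples,
    screen_genes,
)
from senosig.survival import SurvivalData


def risk_cohort(n=200, seed=0):
    """Two informative genes (one risk, one protective) and one constant."""
    rng = np.random.default_rng(seed)
    risk = rng.normal(size=n)
    prot = rng.normal(size=n)
    t = rng.exponential(1 / np.exp(1.2 * risk - 1.2 * prot)) + 1e-9
    expr = ExpressionMatrix(
        pd.DataFrame(
            {
                "RISK": 500 + 100 * risk,
                "PROT": 500 + 100 * prot,
                "FLAT": np.full(n, 42.0),
            },
            index=[f"s{i}" for i in range(n)],
        )
    )
    return expr, SurvivalData(t, np.ones(n, int))


def test_screen_assigns_directional_weights():
    expr, surv = risk_cohort()
    table = screen_genes(expr, surv).data.set_index("gene_id")
    assert table.loc["RISK", "hr"] > 1 and table.loc["RISK", "weight"] == 1
    assert table.loc["PROT", "hr"] < 1 and table.loc["PROT", "weight"] == -1
    assert table.loc["FLAT", "weight"] == 0
    assert table.loc["FLAT", "note"] == "constant"


def test_screen_weight_signs_invariant_to_affine_transform():
    expr, surv = risk_cohort(seed=3)
    shifted = ExpressionMatrix(expr.data * 7.5 + 1000.0)
    w1 = screen_genes(expr, surv).data.set_index("gene_id")["weight"]
    w2 = screen_genes(shifted, surv).data.set_index("gene_id")["weight"]
    pd.testing.assert_series_equal(w1, w2)


def test_screen_standardization_does_not_flip_signs():
    expr, surv = risk_cohort(seed=4)
    raw = screen_genes(expr, surv, standardize=False).data.set_index("gene_id")
    std = screen_genes(expr, surv, standardize=True).data.set_index("gene_id")
    pd.testing.assert_series_equal(raw["weight"], std["weight"])


def test_screen_median_split_variant_agrees_in_direction():
    expr, surv = risk_cohort(seed=5)
    table = screen_genes(expr, surv, median_split=True).data.set_index("gene_id")
    assert table.loc["RISK", "weight"] == 1
    assert table.loc["PROT", "weight"] == -1


def test_screen_alignment_mismatch():
    expr, surv = risk_cohort()
    with pytest.raises(ValidationError):
        screen_genes(expr, SurvivalData(surv.time[:-1], surv.event[:-1]))


def test_score_is_weighted_mean():
    expr = ExpressionMatrix(
        pd.DataFrame({"A": [800.0, 100.0], "B": [200.0, 100.0]},
                     index=["s1", "s2"])
    )
    weights = fixed_weight_table(["A", "B"], [1, -1])
    scores = score_samples(expr, weights)
    assert scores["s1"] == pytest.approx((800 - 200) / 2) == 300.0
    assert scores["s2"] == pytest.approx(0.0)  # cancellation at equal expression
    all_plus = fixed_weight_table(["A", "B"], [1, 1])
    assert score_samples(expr, all_plus)["s1"] == pytest.approx(500.0)


def test_score_linearity_and_gene_order_invariance():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.lognormal(5, 1, (10, 6)),
                      index=[f"s{i}" for i in range(10)],
                      columns=list("abcdef"))
    w = fixed_weight_table(list("abcdef"), [1, -1, 1, -1, 1, -1])
    s1 = score_samples(ExpressionMatrix(df), w)
    s2 = score_samples(ExpressionMatrix(df[list("fedcba")]), w)
    pd.testing.assert_series_equal(s1, s2)
    s3 = score_samples(ExpressionMatrix(df * 3.0), w)
    assert np.allclose(s3, 3.0 * s1)


def test_score_skips_absent_genes_and_requires_one():
    expr = ExpressionMatrix(
        pd.DataFrame({"A": [1.0, 2.0]}, index=["s1", "s2"])
    )
    weights = fixed_weight_table(["A", "MISSING"], [1, -1])
    scores = score_samples(expr, weights)  # MISSING skipped
    assert scores["s2"] == pytest.approx(2.0)
    only_missing = fixed_weight_table(["X", "Y"], [1, 1])
    with pytest.raises(ValidationError):
        score_samples(expr, only_missing)


def test_load_fixed_signature():
    entries = [GeneListEntry("A", fixed_weight=1),
               GeneListEntry("B", fixed_weight=1),
               GeneListEntry("C", fixed_weight=-1)]
    table = load_fixed_signature(entries)
    assert len(table) == 3
    assert set(table.data["source"]) == {"fixed"}
    with pytest.raises(ValidationError):
        load_fixed_signature([GeneListEntry("A")])  # no weight
    with pytest.raises(ValidationError):
        load_fixed_signature(
            [GeneListEntry("A", fixed_weight=1), GeneListEntry("A", fixed_weight=1)]
        )


def test_weight_table_consistency_enforced():
    bad = pd.DataFrame(
        [{"gene_id": "A", "hr": 2.0, "ci_low": 1.0, "ci_high": 4.0,
          "p": 0.01, "weight": -1, "source": "fitted"}]
    )
    with pytest.raises(ValidationError, match="inconsistent"):
        GeneWeightTable(bad)


def test_weight_table_tsv_round_trip(tmp_path):
    table = fixed_weight_table(["A", "B"], [1, -1])
    path = tmp_path / "w.tsv"
    table.to_tsv(path)
    back = GeneWeightTable.from_tsv(path)
    pd.testing.assert_frame_equal(
        back.data[["gene_id", "weight", "source"]],
        table.data[["gene_id", "weight", "source"]],
    )
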