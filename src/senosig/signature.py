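"""Signature construction: per-gene directional Cox screen and sign-weighted
mean scoring.

Each gene is screened individually with a univariate Cox model on its
(optionally per-gene standardized) expression; the gene enters the signature
with weight +1 when its hazard ratio exceeds 1 (higher expression, worse
outcome) and -1 when the HR lies in (0, 1).  The signature score of a sample
is the mean of weight x expression over the weighted genes, so high scores
aggregate risk-associated expression.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneListEntry, ValidationError
from .survival import (
    DegenerateDataError,
    SurvivalData,
    _RiskSetIndex,
    cox_fit,
)

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ("gene_id", "hr", "ci_low", "ci_high", "p", "weight", "source")


class GeneWeightTable:
    """Per-gene screen results and the resulting +/-1 weights.

    ``source`` is ``fitted`` for screened genes (weight derived from the HR
    direction) or ``fixed`` for weights supplied by an external gene list,
    in which case hr/ci/p are null.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy().reset_index(drop=True)
        missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"weight table missing columns {missing}")
        dup = df["gene_id"][df["gene_id"].duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate gene ids in weight table: {list(dup)}")
        if not df["weight"].isin([-1, 0, 1]).all():
            raise ValidationError("weights must be in {-1, 0, +1}")
        if not df["source"].isin(["fitted", "fixed"]).all():
            raise ValidationError("source must be 'fitted' or 'fixed'")
        fitted = df[df["source"] == "fitted"]
        hr = fitted["hr"].to_numpy(dtype=float)
        w = fitted["weight"].to_numpy()
        ok = np.where(np.isnan(hr), w == 0, w == np.sign(np.log(np.where(hr > 0, hr, 1.0))))
        if not ok.all():
            bad = fitted["gene_id"].iloc[int(np.flatnonzero(~ok)[0])]
            raise ValidationError(
                f"weight inconsistent with HR direction for gene {bad!r}"
            )
        fixed = df[df["source"] == "fixed"]
        if not fixed["weight"].isin([-1, 1]).all():
            raise ValidationError("fixed weights must be +/-1")
        self.data = df[list(WEIGHT_COLUMNS) + [c for c in df.columns if c not in WEIGHT_COLUMNS]]

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def nonzero(self) -> pd.DataFrame:
        return self.data[self.data["weight"] != 0]

    def weights(self) -> pd.Series:
        """gene_id -> weight, nonzero entries only."""
        nz = self.nonzero()
        return pd.Series(nz["weight"].to_numpy(), index=nz["gene_id"], name="weight")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "GeneWeightTable":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nz = self.data["weight"] != 0
        return (
            f"GeneWeightTable({len(self)} genes, "
            f"{int((self.data['weight'] == 1).sum())} risk / "
            f"{int((self.data['weight'] == -1).sum())} protective)"
        )


def screen_genes(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    standardize: bool = True,
    median_split: bool = False,
) -> GeneWeightTable:
    """Univariate Cox screen of every gene; weight by HR direction.

    ``standardize`` fits each gene on its z-scored expression (the weight
    sign is invariant to this, the reported HR becomes per-SD and hence
    comparable across genes).  ``median_split`` instead dichotomizes each
    gene at its median — a cruder screen kept behind a flag.

    Genes that cannot be fitted (constant expression, non-convergence) get
    weight 0 with the reason recorded in the ``note`` column.
    """
    if expr.n_samples != surv.n:
        raise ValidationError(
            f"expression has {expr.n_samples} samples but survival has {surv.n}"
        )
    index = _RiskSetIndex(surv)
    values = expr.data.to_numpy()
    rows = []
    n_skipped = 0
    for j, gene in enumerate(expr.gene_ids):
        x = values[:, j]
        note = ""
        if np.ptp(x) == 0:
            rows.append(_zero_row(gene, "constant"))
            n_skipped += 1
            continue
        if median_split:
            x = (x > np.median(x)).astype(float)
            if np.ptp(x) == 0:
                rows.append(_zero_row(gene, "constant after median split"))
                n_skipped += 1
                continue
        elif standardize:
            x = (x - x.mean()) / x.std()
        try:
            res = cox_fit(x.reshape(-1, 1), surv, names=[gene], _index=index)[0]
        except DegenerateDataError as exc:
            rows.append(_zero_row(gene, str(exc)))
            n_skipped += 1
            continue
        if not res.converged:
            rows.append(_zero_row(gene, res.message or "no convergence"))
            n_skipped += 1
            continue
        weight = 1 if res.hr > 1 else (-1 if res.hr < 1 else 0)
        rows.append(
            {
                "gene_id": gene,
                "hr": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "weight": weight,
                "source": "fitted",
                "note": note,
            }
        )
    if n_skipped:
        logger.info("screen_genes: %d gene(s) assigned weight 0 (unfittable)", n_skipped)
    return GeneWeightTable(pd.DataFrame(rows))


def _zero_row(gene: str, reason: str) -> dict:
    return {
        "gene_id": gene,
        "hr": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p": np.nan,
        "weight": 0,
        "source": "fitted",
        "note": reason,
    }


def score_samples(expr: ExpressionMatrix, weights: GeneWeightTable) -> pd.Series:
    """Signature score per sample: mean over weighted genes of
    weight x expression.

    Genes in the weight table but absent from the matrix are skipped (with a
    logged count); scoring fails if no weighted gene is present.
    """
    w = weights.weights()
    usable = w[w.index.isin(expr.gene_ids)]
    skipped = len(w) - len(usable)
    if len(usable) == 0:
        raise ValidationError("no weighted signature gene present in the matrix")
    if skipped:
        logger.warning("score_samples: %d signature gene(s) absent, skipped", skipped)
    sub = expr.data[usable.index]
    scores = sub.mul(usable, axis=1).sum(axis=1) / len(usable)
    scores.name = "score"
    return scores


def load_fixed_signature(entries: Sequence[GeneListEntry]) -> GeneWeightTable:
    """Build a weight table from an externally supplied gene/weight list
    (e.g. a published supplementary signature table)."""
    rows = []
    for entry in entries:
        if entry.fixed_weight is None:
            raise ValidationError(f"gene {entry.gene_id!r} has no fixed weight")
        rows.append(
            {
                "gene_id": entry.gene_id,
                "hr": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "weight": entry.fixed_weight,
                "source": "fixed",
                "note": "",
            }
        )
    if not rows:
        raise ValidationError("empty signature gene list")
    return GeneWeightTable(pd.DataFrame(rows))
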