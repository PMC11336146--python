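"""Model/Results facade over the signature pipeline.

:class:`SenescenceSignatureModel` is constructed from an expression matrix
and a clinical table (plus, optionally, a fixed published signature);
``fit()`` runs screen -> score -> quartile-bounded cutoff scan -> KM and
returns a :class:`SignatureResults` carrying the estimates, their
uncertainties and a ``summary()`` table, with per-dataset replication and
paired multivariate models as methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis as _analysis
from .analysis import (
    CohortReport,
    DatasetResult,
    PairedCoxResult,
    dataset_results_frame,
    paired_results_frame,
)
from .cutoff import CutoffScanResult, scan_profile
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneListEntry,
    read_clinical,
    read_expression,
    read_gene_list,
)
from .signature import GeneWeightTable, load_fixed_signature, screen_genes
from .survival import CoxResult, KMCurve, SurvivalData


class SenescenceSignatureModel:
    """Prognostic gene-signature model for right-censored cohort data.

    Parameters
    ----------
    expression
        Normalized samples x genes intensities.
    clinical
        Follow-up time (months), event indicator, dataset ids, covariates.
    fixed_signature
        Optional externally fixed gene/weight list; when given the per-gene
        screen is skipped and these weights are used as-is.
    standardize_screen
        Screen each gene on its z-scored expression (default); the weight
        signs are invariant to this choice.
    median_split_screen
        Dichotomize each gene at its median in the screen instead of using
        the continuous value.
    scan_test
        Per-cutoff test: ``"cox"`` (Wald, default) or ``"logrank"``.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: ClinicalTable,
        fixed_signature: Optional[Sequence[GeneListEntry]] = None,
        standardize_screen: bool = True,
        median_split_screen: bool = False,
        scan_test: str = "cox",
        q_low: float = 0.25,
        q_high: float = 0.75,
        min_group: Optional[int] = None,
    ):
        self.expression, self.clinical = _analysis.align(expression, clinical)
        self.fixed_signature = fixed_signature
        self.standardize_screen = standardize_screen
        self.median_split_screen = median_split_screen
        self.scan_test = scan_test
        self.q_low = q_low
        self.q_high = q_high
        self.min_group = min_group

    @classmethod
    def from_files(
        cls,
        expression_path,
        clinical_path,
        gene_list_path=None,
        orientation: str = "samples_by_genes",
        vocabulary=None,
        columns=None,
        **kwargs,
    ) -> "SenescenceSignatureModel":
        expr = read_expression(expression_path, orientation)
        clin = read_clinical(clinical_path, vocabulary, columns)
        fixed = read_gene_list(gene_list_path) if gene_list_path else None
        if fixed is not None and all(e.fixed_weight is None for e in fixed):
            # a plain gene list restricts the screened genes instead
            keep = [e.gene_id for e in fixed if e.gene_id in set(expr.gene_ids)]
            expr = ExpressionMatrix(expr.data[keep])
            fixed = None
        return cls(expr, clin, fixed_signature=fixed, **kwargs)

    def fit(self) -> "SignatureResults":
        surv = SurvivalData.from_clinical(self.clinical)
        if self.fixed_signature is not None:
            weights = load_fixed_signature(self.fixed_signature)
        else:
            weights = screen_genes(
                self.expression,
                surv,
                standardize=self.standardize_screen,
                median_split=self.median_split_screen,
            )
        report = _analysis.analyze_cohort(
            self.expression,
            self.clinical,
            weights,
            q_low=self.q_low,
            q_high=self.q_high,
            min_group=self.min_group,
            test=self.scan_test,
        )
        return SignatureResults(self, weights, report)


@dataclass
class SignatureResults:
    """Fitted signature: weights, scores, cutoff scan and survival contrast."""

    model: SenescenceSignatureModel
    weights: GeneWeightTable
    report: CohortReport

    # -- convenience accessors -------------------------------------------
    @property
    def scores(self) -> pd.Series:
        return self.report.scores

    @property
    def scan(self) -> CutoffScanResult:
        return self.report.scan

    @property
    def cox(self) -> CoxResult:
        return self.report.cox

    @property
    def km_low(self) -> KMCurve:
        return self.report.km_low

    @property
    def km_high(self) -> KMCurve:
        return self.report.km_high

    @property
    def hr(self) -> float:
        return self.report.cox.hr

    @property
    def p(self) -> float:
        return self.report.cox.p

    def scan_profile(self) -> pd.DataFrame:
        return scan_profile(self.report.scan)

    # -- downstream analyses ---------------------------------------------
    def per_dataset(
        self,
        min_n: int = 30,
        min_events: int = 10,
        use_global_cutoff: bool = False,
    ) -> tuple[list[DatasetResult], list[tuple[str, str]]]:
        cutoff = self.scan.selected_cutoff if use_global_cutoff else None
        return _analysis.per_dataset(
            self.model.expression,
            self.model.clinical,
            self.weights,
            min_n=min_n,
            min_events=min_events,
            q_low=self.model.q_low,
            q_high=self.model.q_high,
            min_group=self.model.min_group,
            test=self.model.scan_test,
            global_cutoff=cutoff,
        )

    def paired_multivariate(
        self, covariate_name: str, encodings=None
    ) -> PairedCoxResult:
        return _analysis.paired_multivariate(
            self.scores, self.model.clinical, covariate_name,
            self.scan.selected_cutoff, encodings,
        )

    def paired_multivariate_all(self, covariates=None, encodings=None):
        return _analysis.paired_multivariate_all(
            self.scores, self.model.clinical, self.scan.selected_cutoff,
            covariates, encodings,
        )

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        c = self.cox
        scan = self.scan
        w = self.weights.data
        lines = [
            "Senescence-signature survival analysis",
            "=" * 54,
            f"samples: {self.report.n}    events: {self.report.events}",
            f"signature genes: {len(w)} "
            f"(+1: {int((w['weight'] == 1).sum())}, "
            f"-1: {int((w['weight'] == -1).sum())}, "
            f"0: {int((w['weight'] == 0).sum())})",
            "",
            "cutoff scan (between score quartiles)",
            f"  scanned cutoffs : {len(scan.table)}",
            f"  selected cutoff : {scan.selected_cutoff:.6g}",
            f"  HR range        : {scan.hr_range[0]:.3g} - {scan.hr_range[1]:.3g}",
            "",
            "high vs low signature at the selected cutoff",
            f"  HR = {c.hr:.2f}, 95% CI = {c.ci_low:.2f}-{c.ci_high:.2f}, "
            f"p = {c.format_p()}",
            f"  FDR-adjusted minimum p = {scan.selected_p_adj:.2e}",
            f"  log-rank: chi2 = {self.report.logrank.chi_square:.2f}, "
            f"p = {self.report.logrank.p:.2e}",
        ]
        return "\n".join(lines)

    def plot_km(self, path, annotate: bool = True):
        from .plotting import render_km

        c = self.cox
        annotation = (
            f"HR = {c.hr:.2f} ({c.ci_low:.2f}-{c.ci_high:.2f})\np = {c.format_p()}"
            if annotate
            else None
        )
        return render_km(
            {"low signature": self.km_low, "high signature": self.km_high},
            path,
            annotation=annotation,
        )

    def plot_scan(self, path):
        from .plotting import render_scan_profile

        return render_scan_profile(self.scan, path)
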