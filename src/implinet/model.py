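"""Model/Results facade for the differential-coexpression signature analysis.

``DifferentialCoexpressionModel`` bundles a training cohort (expression +
clinical), an optional independent test cohort and the hub gene list;
``fit()`` runs screening, per-group implication-network construction,
differential extraction, cross-cohort validation and all-hub signature
selection, returning a ``DifferentialCoexpressionResults`` with the
intermediate objects, a ``summary()`` table and evaluation helpers
(annotation precision, permutation FDR, subsampling stability, prognostic
risk modelling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clinical as clin
from . import evaluation as ev
from . import screening as scr
from .differential import (
    DifferentialEdgeSet,
    SignatureResult,
    differential_edges,
    select_signature,
    validate_edges,
)
from .rules import ImplicationNetwork, build_network, dichotomize

__all__ = ["DifferentialCoexpressionModel", "DifferentialCoexpressionResults"]

logger = logging.getLogger(__name__)


class DifferentialCoexpressionModel:
    """Smoking-associated differential implication-network model.

    Parameters
    ----------
    train_expr : genes x samples log2 expression of the training cohort.
    train_clinical : table indexed by sample with at least a ``smoker``
        column (1 = ever-smoker, 0 = never); ``surv_months``/``event``
        enable the survival screen.  Samples with missing smoking status are
        excluded from screening and network construction.
    hubs : the signaling-pathway anchor genes; signature genes must acquire
        a group-specific edge to every one of them.
    test_expr, test_clinical : optional independent cohort used to validate
        differential edges (dichotomized with the training means).
    """

    def __init__(
        self,
        train_expr: pd.DataFrame,
        train_clinical: pd.DataFrame,
        hubs: Sequence[str],
        test_expr: Optional[pd.DataFrame] = None,
        test_clinical: Optional[pd.DataFrame] = None,
        alpha: float = 0.05,
        screen: bool = True,
        quantile_normalize: bool = True,
        screen_fdr: bool = False,
    ) -> None:
        missing = [h for h in hubs if h not in train_expr.index]
        if missing:
            raise KeyError(f"hub gene(s) absent from training expression: {missing}")
        self.hubs = tuple(hubs)
        self.alpha = float(alpha)
        self.screen = bool(screen)
        self.screen_fdr = bool(screen_fdr)
        self.train_expr = (
            scr.quantile_normalize(train_expr) if quantile_normalize else train_expr.copy()
        )
        self.train_clinical = train_clinical
        if test_expr is not None:
            self.test_expr = (
                scr.quantile_normalize(test_expr) if quantile_normalize else test_expr.copy()
            )
        else:
            self.test_expr = None
        self.test_clinical = test_clinical

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _smoking_groups(clinical: pd.DataFrame, columns) -> pd.Series:
        groups = clinical["smoker"].reindex(columns)
        n_missing = int(groups.isna().sum())
        if n_missing:
            logger.info("excluding %d sample(s) with unknown smoking status", n_missing)
        return groups.dropna().astype(int)

    def fit(self) -> "DifferentialCoexpressionResults":
        groups = self._smoking_groups(self.train_clinical, self.train_expr.columns)
        expr = self.train_expr.loc[:, groups.index]

        survival_results = smoking_results = None
        if self.screen:
            has_surv = {"surv_months", "event"} <= set(self.train_clinical.columns)
            if not has_surv:
                raise ValueError(
                    "screening requires surv_months/event clinical columns; "
                    "pass screen=False to skip"
                )
            survival_results = scr.cox_screen(
                expr,
                self.train_clinical["surv_months"],
                self.train_clinical["event"],
                alpha=self.alpha,
                fdr=self.screen_fdr,
            )
            survival_pass = [r.gene_id for r in survival_results if r.passed]
            smoking_results = scr.ttest_screen(
                expr.loc[survival_pass], groups, alpha=self.alpha, fdr=self.screen_fdr
            )
            smoking_pass = [r.gene_id for r in smoking_results if r.passed]
        else:
            survival_pass = list(expr.index)
            smoking_pass = list(expr.index)
        candidates = scr.assemble_candidates(
            survival_pass, smoking_pass, self.hubs, expr_genes=expr.index
        )

        cand_expr = expr.loc[list(candidates.candidates)]
        training_means = cand_expr.mean(axis=1)
        states = dichotomize(cand_expr, training_means)
        net_smoker = build_network(
            states.loc[:, (groups == 1).to_numpy()], alpha=self.alpha, group="smoker"
        )
        net_nonsmoker = build_network(
            states.loc[:, (groups == 0).to_numpy()], alpha=self.alpha, group="nonsmoker"
        )
        diff = differential_edges(net_smoker, net_nonsmoker)

        validated = diff
        test_groups = None
        if self.test_expr is not None:
            if self.test_clinical is None:
                raise ValueError("a test cohort needs its clinical table")
            overlap = set(self.train_expr.columns) & set(self.test_expr.columns)
            if overlap:
                raise ValueError(
                    f"training and test cohorts share sample IDs: {sorted(overlap)[:5]}"
                )
            test_groups = self._smoking_groups(self.test_clinical, self.test_expr.columns)
            validated = validate_edges(
                diff,
                self.test_expr.loc[list(candidates.candidates), test_groups.index],
                test_groups,
                training_means,
                self.alpha,
            )
        signature = select_signature(validated, self.hubs)
        return DifferentialCoexpressionResults(
            model=self,
            candidates=candidates,
            survival_screen=survival_results,
            smoking_screen=smoking_results,
            training_means=training_means,
            train_groups=groups,
            test_groups=test_groups,
            net_smoker=net_smoker,
            net_nonsmoker=net_nonsmoker,
            differential=diff,
            validated=validated,
            signature=signature,
        )


@dataclass
class DifferentialCoexpressionResults:
    """Fitted differential-network analysis with evaluation helpers."""

    model: DifferentialCoexpressionModel
    candidates: scr.CandidateSet
    survival_screen: Optional[list]
    smoking_screen: Optional[list]
    training_means: pd.Series
    train_groups: pd.Series
    test_groups: Optional[pd.Series]
    net_smoker: ImplicationNetwork
    net_nonsmoker: ImplicationNetwork
    differential: DifferentialEdgeSet
    validated: DifferentialEdgeSet
    signature: SignatureResult

    # -- evaluation --------------------------------------------------------

    def signature_network_pairs(self) -> list:
        return sorted(self.signature.network_edges())

    def evaluate(self, annotations: ev.AnnotationCollection) -> ev.EdgeLabelSummary:
        """TP/FP/ND precision of the validated signature network."""
        return ev.evaluate_network(self.signature_network_pairs(), annotations)

    def permutation_fdr(
        self,
        annotations: ev.AnnotationCollection,
        n_perm: int = 1000,
        seed: int = 0,
        gene_set: str = "all",
    ) -> ev.FdrResult:
        """Permutation FDR over the test cohort (requires one).

        ``gene_set='all'`` permutes over the full expression matrix (the
        default: the null edge universe is every gene pair); ``'candidates'``
        restricts to the screened network genes.
        """
        if self.model.test_expr is None:
            raise ValueError("permutation FDR needs an independent test cohort")
        genes = (
            list(self.model.train_expr.index)
            if gene_set == "all"
            else list(self.candidates.candidates)
        )
        return ev.permutation_fdr(
            self.model.train_expr.loc[genes, self.train_groups.index],
            self.train_groups,
            self.model.test_expr.loc[genes, self.test_groups.index],
            self.test_groups,
            hubs=self.model.hubs,
            annotations=annotations,
            n_perm=n_perm,
            alpha=self.model.alpha,
            seed=seed,
        )

    def stability(
        self, subset_fraction: float = 0.8, n_iter: int = 100, seed: int = 0
    ) -> ev.StabilityResult:
        """Training-subsample stability of the validated signature network."""
        if self.model.test_expr is None:
            raise ValueError("stability needs an independent test cohort")
        genes = list(self.candidates.candidates)
        return ev.stability(
            self.model.train_expr.loc[genes, self.train_groups.index],
            self.train_groups,
            self.model.test_expr.loc[genes, self.test_groups.index],
            self.test_groups,
            hubs=self.model.hubs,
            subset_fraction=subset_fraction,
            n_iter=n_iter,
            alpha=self.model.alpha,
            seed=seed,
        )

    # -- prognosis ---------------------------------------------------------

    def fit_risk_model(self, cohort: str = "train") -> clin.RiskModel:
        """Cox risk model over the signature genes with a frozen 3-year-ROC
        threshold, fitted on the training cohort."""
        genes = list(self.signature.genes)
        if not genes:
            raise ValueError("empty signature; no risk model to fit")
        expr = self.model.train_expr.loc[genes, self.train_groups.index]
        surv = self.model.train_clinical["surv_months"]
        event = self.model.train_clinical["event"]
        rm = clin.fit_cox_risk_model(expr, surv, event, genes, training_cohort=cohort)
        scores = rm.score(expr)
        threshold, _ = clin.select_cutoff_3yr_roc(scores, surv, event)
        return rm.with_threshold(threshold)

    # -- reporting ---------------------------------------------------------

    def counts(self) -> dict:
        return dict(
            n_train_samples=int(len(self.train_groups)),
            n_train_smokers=int((self.train_groups == 1).sum()),
            n_survival_pass=(
                sum(r.passed for r in self.survival_screen)
                if self.survival_screen is not None else None
            ),
            n_smoking_pass=(
                sum(r.passed for r in self.smoking_screen)
                if self.smoking_screen is not None else None
            ),
            n_candidates=len(self.candidates),
            n_edges_smoker=len(self.net_smoker),
            n_edges_nonsmoker=len(self.net_nonsmoker),
            n_differential=self.differential.n_edges,
            n_type_changed=len(self.differential.type_changed),
            n_validated=self.validated.n_edges,
            n_signature_smoker=len(self.signature.smoker_genes),
            n_signature_nonsmoker=len(self.signature.nonsmoker_genes),
        )

    def summary(self) -> str:
        c = self.counts()
        lines = [
            "Differential implication-network analysis",
            "=" * 41,
            f"training samples              {c['n_train_samples']} "
            f"({c['n_train_smokers']} smokers)",
        ]
        if c["n_survival_pass"] is not None:
            lines.append(f"survival screen (Cox p<{self.model.alpha})    {c['n_survival_pass']}")
            lines.append(f"smoking screen (t-test p<{self.model.alpha})  {c['n_smoking_pass']}")
        lines += [
            f"network genes (incl. {len(self.model.hubs)} hubs)   {c['n_candidates']}",
            f"edges: smoker net             {c['n_edges_smoker']}",
            f"edges: non-smoker net         {c['n_edges_nonsmoker']}",
            f"differential edges            {c['n_differential']} "
            f"(+{c['n_type_changed']} type-changed)",
            f"validated edges               {c['n_validated']}",
            f"signature genes               {len(self.signature.genes)} "
            f"({c['n_signature_smoker']} smoker / {c['n_signature_nonsmoker']} non-smoker)",
        ]
        if self.signature.genes:
            lines.append("  " + ", ".join(self.signature.genes))
        return "\n".join(lines)
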