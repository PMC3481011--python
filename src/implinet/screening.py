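"""Candidate-gene screening: normalization, survival and smoking screens.

The screening order is fixed: a univariate Cox screen over the whole gene
set first, then a smoker-vs-non-smoker Welch t-test screen restricted to the
survival survivors, then assembly of the candidates together with the hub
(signaling-pathway) genes, which enter the network stage regardless of
whether they pass either screen.  Neither screen applies a multiplicity
correction by default; an optional Benjamini-Hochberg flag is exposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sps

__all__ = [
    "ScreenResult",
    "CandidateSet",
    "quantile_normalize",
    "cox_screen",
    "ttest_screen",
    "assemble_candidates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenResult:
    gene_id: str
    statistic: float
    p_value: float
    direction: int
    passed: bool
    testable: bool = True


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean order-statistic distribution.

    Ranks within each column are preserved; tied values receive the mean of
    their tied order statistics.  A single-column matrix is returned
    unchanged with a warning.  Missing values are not handled here — drop or
    impute by gene median beforehand.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    if matrix.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(mean_sorted)
        assigned[order] = mean_sorted
        # average over ties so equal inputs map to equal outputs
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cox_screen(
    expr: pd.DataFrame,
    surv_months: pd.Series,
    event: pd.Series,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[ScreenResult]:
    """Univariate Cox proportional-hazards screen, one Wald test per gene.

    Each gene's continuous expression is the single covariate.  Genes with
    p < alpha are flagged; constant genes are excluded as non-testable with a
    log entry.  Raw p-values by default; ``fdr=True`` flags by
    Benjamini-Hochberg adjusted p instead.
    """
    surv = surv_months.reindex(expr.columns).astype(float)
    ev = event.reindex(expr.columns).astype(int)
    if surv.isna().any() or ev.isna().any():
        raise ValueError("survival columns must cover every sample")
    if int(ev.sum()) < 2:
        raise ValueError("Cox screen needs at least two events")
    results: list[ScreenResult] = []
    base = pd.DataFrame({"time": surv.to_numpy(), "event": ev.to_numpy()})
    fitter = CoxPHFitter()
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.info("cox_screen: gene %s is constant; excluded", gene)
            results.append(ScreenResult(gene, float("nan"), float("nan"), 0, False, False))
            continue
        df = base.copy()
        df["x"] = x
        try:
            fitter.fit(df, duration_col="time", event_col="event")
        except Exception:  # convergence failure on a pathological gene
            logger.warning("cox_screen: fit failed for gene %s; excluded", gene)
            results.append(ScreenResult(gene, float("nan"), float("nan"), 0, False, False))
            continue
        z = float(fitter.summary.loc["x", "z"])
        p = float(fitter.summary.loc["x", "p"])
        results.append(ScreenResult(gene, z, p, int(np.sign(z)), p < alpha))
    return _apply_fdr(results, alpha) if fdr else results


def _apply_fdr(results: list[ScreenResult], alpha: float) -> list[ScreenResult]:
    testable = [r for r in results if r.testable and np.isfinite(r.p_value)]
    if not testable:
        return results
    adj = sps.false_discovery_control([r.p_value for r in testable])
    adj_map = {r.gene_id: q for r, q in zip(testable, adj)}
    return [
        ScreenResult(
            r.gene_id, r.statistic, r.p_value, r.direction,
            r.testable and adj_map.get(r.gene_id, 1.0) < alpha, r.testable,
        )
        for r in results
    ]


def ttest_screen(
    expr: pd.DataFrame,
    group: pd.Series,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[ScreenResult]:
    """Two-sided Welch t-test per gene between two sample groups.

    ``group`` is binary over samples (1 = smoker).  Zero-variance genes with
    equal group means are reported with p = 1 by convention.
    """
    g = group.reindex(expr.columns)
    if g.isna().any():
        raise ValueError("group labels must cover every sample")
    mask = g.astype(int).to_numpy() == 1
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least two samples")
    a = expr.loc[:, mask].to_numpy(dtype=float)
    b = expr.loc[:, ~mask].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    results = []
    for gene, t, pv, da, db in zip(
        expr.index, stat, p, a.mean(axis=1), b.mean(axis=1)
    ):
        if np.isnan(t):  # zero variance in both groups
            t, pv = 0.0, 1.0
        results.append(
            ScreenResult(gene, float(t), float(pv), int(np.sign(da - db)), pv < alpha)
        )
    return _apply_fdr(results, alpha) if fdr else results


@dataclass
class CandidateSet:
    """Candidate genes for network construction, with provenance flags."""

    candidates: tuple[str, ...]
    hubs: tuple[str, ...]
    survival_pass: frozenset
    smoking_pass: frozenset

    def provenance(self, gene: str) -> dict:
        return dict(
            survival=gene in self.survival_pass,
            smoking=gene in self.smoking_pass,
            hub=gene in self.hubs,
        )

    def __len__(self) -> int:
        return len(self.candidates)


def assemble_candidates(
    survival_pass: Sequence[str],
    smoking_pass: Sequence[str],
    hubs: Sequence[str],
    expr_genes: Optional[Sequence[str]] = None,
) -> CandidateSet:
    """Candidates = (survival survivors that also pass the smoking screen)
    plus the hub genes, which are always included."""
    if expr_genes is not None:
        missing = [h for h in hubs if h not in set(expr_genes)]
        if missing:
            raise KeyError(f"hub gene(s) absent from expression matrix: {missing}")
    screened = set(survival_pass) & set(smoking_pass)
    if not screened:
        warnings.warn("no gene passed both screens; candidates are the hubs only")
    ordered = sorted(screened | set(hubs))
    logger.info(
        "assemble_candidates: %d screened + %d hubs -> %d candidates",
        len(screened), len(hubs), len(ordered),
    )
    return CandidateSet(
        candidates=tuple(ordered),
        hubs=tuple(hubs),
        survival_pass=frozenset(survival_pass),
        smoking_pass=frozenset(smoking_pass),
    )


def screen_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Screen results as a TSV-ready data frame."""
    return pd.DataFrame(
        [
            dict(
                gene_id=r.gene_id, statistic=r.statistic, p=r.p_value,
                direction=r.direction, pass_flag=int(r.passed),
                testable=int(r.testable),
            )
            for r in results
        ]
    )
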