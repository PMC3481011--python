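"""Prognostic and diagnostic use of a gene signature.

Prognosis: the signature genes are fitted jointly into a Cox proportional-
hazards model on the training cohort; the linear predictor is each patient's
risk score.  The score threshold is chosen on the 3-year ROC curve (death
within 36 months as the outcome, Youden-optimal cutoff) and frozen together
with the coefficients, so test cohorts are stratified without re-estimating
any parameter.  Stratified groups are compared with Kaplan-Meier curves and
the log-rank test, and the dichotomized risk group enters a multivariate Cox
model next to the usual clinicopathological covariates.

Diagnosis: a k-nearest-neighbour classifier (k=1, Euclidean distance on
per-gene standardized values) separates cancer from normal samples on the
signature genes; performance is reported as accuracy and as the odds ratio
of the predicted risk with a Woolf logit confidence interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "RiskModel",
    "HazardTable",
    "ConfusionTable",
    "fit_cox_risk_model",
    "select_cutoff_3yr_roc",
    "km_logrank",
    "multivariate_cox",
    "prognostic_factor_table",
    "group_association_test",
    "knn_train_predict",
    "diagnosis_odds_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskModel:
    """Frozen per-gene Cox coefficients plus a risk-score threshold."""

    genes: tuple[str, ...]
    coefficients: tuple[float, ...]
    threshold: Optional[float] = None
    training_cohort: str = ""

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Linear predictor sum_i beta_i * x_i per sample (columns)."""
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise KeyError(f"expression matrix lacks signature genes: {missing}")
        beta = np.asarray(self.coefficients)
        x = expr.loc[list(self.genes)].to_numpy(dtype=float)
        return pd.Series(beta @ x, index=expr.columns, name="risk_score")

    def risk_group(self, expr: pd.DataFrame) -> pd.Series:
        """1 = high risk (score >= threshold)."""
        if self.threshold is None:
            raise ValueError("risk model has no frozen threshold; select a cutoff first")
        return (self.score(expr) >= self.threshold).astype(int)

    def with_threshold(self, threshold: float) -> "RiskModel":
        return replace(self, threshold=float(threshold))

    # -- plain-text serialization (one gene per line) ----------------------
    def to_text(self) -> str:
        lines = [f"# risk model ({self.training_cohort})"]
        lines.append(f"threshold\t{'' if self.threshold is None else repr(self.threshold)}")
        for g, b in zip(self.genes, self.coefficients):
            lines.append(f"{g}\t{b!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RiskModel":
        lines = [l for l in text.splitlines() if l.strip()]
        cohort = lines[0].lstrip("# ").replace("risk model (", "").rstrip(")")
        _, thr = lines[1].split("\t")
        genes, coefs = [], []
        for line in lines[2:]:
            g, b = line.split("\t")
            genes.append(g)
            coefs.append(float(b))
        return cls(
            genes=tuple(genes),
            coefficients=tuple(coefs),
            threshold=float(thr) if thr else None,
            training_cohort=cohort,
        )


def fit_cox_risk_model(
    expr: pd.DataFrame,
    surv_months: pd.Series,
    event: pd.Series,
    genes: Optional[Sequence[str]] = None,
    training_cohort: str = "",
    l2: float = 0.0,
) -> RiskModel:
    """Multivariable Cox partial-likelihood fit of the signature genes.

    ``l2`` adds a tiny ridge penalty for collinear signatures; it is off by
    default and a collinearity-driven failure is reported as an error.
    """
    genes = tuple(genes) if genes is not None else tuple(expr.index)
    ev = event.reindex(expr.columns).astype(int)
    if int(ev.sum()) < 1:
        raise ValueError("Cox risk model needs at least one event")
    df = pd.DataFrame(
        {g: expr.loc[g].to_numpy(dtype=float) for g in genes}
    )
    df["time"] = surv_months.reindex(expr.columns).to_numpy(dtype=float)
    df["event"] = ev.to_numpy()
    fitter = CoxPHFitter(penalizer=l2)
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise RuntimeError(
            f"Cox risk model failed to converge (possibly collinear genes): {exc}"
        ) from exc
    return RiskModel(
        genes=genes,
        coefficients=tuple(float(fitter.params_[g]) for g in genes),
        training_cohort=training_cohort,
    )


def select_cutoff_3yr_roc(
    scores: pd.Series,
    surv_months: pd.Series,
    event: pd.Series,
    horizon_months: float = 36.0,
) -> tuple[float, float]:
    """Risk-score cutoff maximizing the Youden index on the 3-year ROC curve.

    The binary outcome is death within ``horizon_months``; samples censored
    before the horizon are excluded from the ROC construction.  Ties on the
    Youden index resolve to the lower threshold.  Returns (threshold, AUC);
    a near-chance AUC is flagged with a warning because the chosen cutoff is
    then unstable.
    """
    t = surv_months.reindex(scores.index).astype(float)
    e = event.reindex(scores.index).astype(int)
    died_early = (t <= horizon_months) & (e == 1)
    known = died_early | (t > horizon_months)
    y = died_early[known].astype(int)
    s = scores[known].astype(float)
    if y.nunique() < 2:
        raise ValueError("3-year outcome has a single class; cannot build a ROC curve")
    if s.nunique() < 2:
        raise ValueError("all risk scores are equal; no cutoff exists")
    fpr, tpr, thresholds = roc_curve(y.to_numpy(), s.to_numpy())
    youden = tpr - fpr
    best = youden == youden.max()
    threshold = float(thresholds[best].min())
    if not np.isfinite(threshold):  # roc_curve's sentinel top threshold
        threshold = float(s.max())
    auc = float(np.trapezoid(tpr, fpr))
    if auc < 0.55:
        warnings.warn(
            f"risk score barely separates 3-year outcomes (AUC={auc:.2f}); "
            "the selected cutoff is unstable"
        )
    return threshold, auc


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    group_sizes: dict[str, int]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, curve in self.curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=name)
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


def km_logrank(
    scores: pd.Series,
    threshold: float,
    surv_months: pd.Series,
    event: pd.Series,
) -> KMResult:
    """Kaplan-Meier curves of the threshold-defined groups plus log-rank test."""
    s = scores.astype(float)
    high = s >= threshold
    t = surv_months.reindex(s.index).astype(float)
    e = event.reindex(s.index).astype(int)
    if high.all() or (~high).all():
        raise ValueError("threshold puts every sample into one risk group")
    curves = {}
    for name, mask in (("low", ~high), ("high", high)):
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask], label=name)
        curves[name] = pd.DataFrame(
            {
                "time": km.survival_function_.index.to_numpy(dtype=float),
                "survival": km.survival_function_[name].to_numpy(dtype=float),
            }
        )
    lr = logrank_test(t[high], t[~high], e[high], e[~high])
    return KMResult(
        curves=curves,
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        group_sizes={"low": int((~high).sum()), "high": int(high.sum())},
    )


@dataclass
class HazardTable:
    """Per-covariate hazard ratios with 95% CIs from a multivariate Cox fit."""

    table: pd.DataFrame  # index covariate; columns p, hr, ci_low, ci_high
    coding: dict[str, str]
    flags: tuple[str, ...] = ()


_STAGE_LEVELS = ("I", "II", "III")
_DIFF_LEVELS = ("well", "moderate", "poor")


def _clinical_design(covariates: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Covariate coding: gender male=1; age dichotomized at 60; tumor
    differentiation and stage as treatment-coded categoricals (well / stage I
    reference)."""
    design = pd.DataFrame(index=covariates.index)
    coding: dict[str, str] = {}
    if "gender" in covariates:
        design["gender_male"] = covariates["gender"].astype(int)
        coding["gender_male"] = "1 = male"
    if "age" in covariates:
        design["age_gt60"] = (covariates["age"].astype(float) > 60).astype(int)
        coding["age_gt60"] = "1 = older than 60"
    if "differentiation" in covariates:
        for level in _DIFF_LEVELS[1:]:
            design[f"diff_{level}"] = (covariates["differentiation"] == level).astype(int)
            coding[f"diff_{level}"] = f"1 = {level}ly differentiated (ref: well)"
    if "stage" in covariates:
        for level in _STAGE_LEVELS[1:]:
            design[f"stage_{level}"] = (covariates["stage"] == level).astype(int)
            coding[f"stage_{level}"] = f"1 = stage {level} (ref: stage I)"
    return design, coding


def multivariate_cox(
    risk_group: Optional[pd.Series],
    covariates: pd.DataFrame,
    surv_months: pd.Series,
    event: pd.Series,
) -> HazardTable:
    """Multivariate Cox fit of clinical covariates, optionally with the
    dichotomized signature risk group as an additional binary covariate."""
    design, coding = _clinical_design(covariates)
    if risk_group is not None:
        design["risk_score_group"] = risk_group.reindex(design.index).astype(int)
        coding["risk_score_group"] = "1 = high signature risk score"
    flags = []
    dropped = []
    arr = design.to_numpy(dtype=float)
    for i, col in enumerate(design.columns):
        if np.ptp(arr[:, i]) == 0:
            dropped.append(col)
    if dropped:
        flags.append(f"constant covariates dropped: {dropped}")
        design = design.drop(columns=dropped)
    corr = np.corrcoef(design.to_numpy(dtype=float), rowvar=False)
    if design.shape[1] > 1 and np.any(np.abs(corr - np.eye(len(corr))) > 0.999):
        flags.append("collinear covariates detected")
    df = design.copy()
    df["time"] = surv_months.reindex(design.index).astype(float)
    df["event"] = event.reindex(design.index).astype(int)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise RuntimeError(f"multivariate Cox failed: {exc}") from exc
    summ = fitter.summary
    table = pd.DataFrame(
        {
            "p": summ["p"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
        }
    )
    return HazardTable(table=table, coding=coding, flags=tuple(flags))


def prognostic_factor_table(
    risk_group: pd.Series,
    covariates: pd.DataFrame,
    surv_months: pd.Series,
    event: pd.Series,
) -> dict[str, HazardTable]:
    """The standard two-fit report: clinical covariates alone, then the same
    model with the dichotomized signature risk group added."""
    return {
        "without_risk_score": multivariate_cox(None, covariates, surv_months, event),
        "with_risk_score": multivariate_cox(risk_group, covariates, surv_months, event),
    }


def group_association_test(
    risk_group: pd.Series, categorical: pd.Series
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) of risk group vs a
    categorical label such as smoking status or cessation."""
    tab = pd.crosstab(risk_group, categorical)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any() or tab.size < 4:
        raise ValueError("degenerate contingency margins")
    chi2, p, _, expected = sps.chi2_contingency(tab.to_numpy(), correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expected counts below 5; p-value is approximate")
    return float(chi2), float(p)


def knn_train_predict(
    train_expr: pd.DataFrame,
    train_labels: pd.Series,
    test_expr: pd.DataFrame,
    test_labels: Optional[pd.Series] = None,
    k: int = 1,
    standardize: bool = True,
) -> tuple[pd.Series, Optional[float]]:
    """k-nearest-neighbour diagnosis on the signature genes.

    Features are per-gene standardized with the *training* mean and SD
    (frozen, reused on the test set).  Returns predictions and, when test
    labels are supplied, the accuracy.
    """
    if k > train_expr.shape[1]:
        raise ValueError("k exceeds the number of training samples")
    X = train_expr.to_numpy(dtype=float).T
    Xt = test_expr.loc[train_expr.index].to_numpy(dtype=float).T
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        Xt = (Xt - mu) / sd
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    clf.fit(X, train_labels.reindex(train_expr.columns).astype(int).to_numpy())
    pred = pd.Series(clf.predict(Xt), index=test_expr.columns, name="predicted")
    acc = None
    if test_labels is not None:
        acc = float((pred == test_labels.reindex(pred.index).astype(int)).mean())
    return pred, acc


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 diagnosis confusion counts."""

    a: int  # predicted positive, truly positive
    b: int  # predicted positive, truly negative
    c: int  # predicted negative, truly positive
    d: int  # predicted negative, truly negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, pred: pd.Series, truth: pd.Series) -> "ConfusionTable":
        p = pred.astype(int)
        t = truth.reindex(p.index).astype(int)
        return cls(
            a=int(((p == 1) & (t == 1)).sum()),
            b=int(((p == 1) & (t == 0)).sum()),
            c=int(((p == 0) & (t == 1)).sum()),
            d=int(((p == 0) & (t == 0)).sum()),
        )


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # Haldane-Anscombe +0.5 applied


def diagnosis_odds_ratio(c: ConfusionTable) -> OddsRatioResult:
    """OR = ad/bc with the Woolf logit 95% CI and a two-sided Wald p.

    Zero cells receive the Haldane-Anscombe +0.5 correction (flagged).
    """
    cells = np.array([c.a, c.b, c.c, c.d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, cc, d = cells
    or_ = (a * d) / (b * cc)
    se = float(np.sqrt((1 / cells).sum()))
    log_or = float(np.log(or_))
    lo, hi = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    p = float(2 * sps.norm.sf(abs(log_or) / se))
    return OddsRatioResult(float(or_), float(lo), float(hi), p, corrected)
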