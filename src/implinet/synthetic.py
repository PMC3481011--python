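"""Synthetic cohorts with planted implication structure.

The generator plants, at the dichotomized-state level, a smoker-specific
implication-rule structure between a handful of signature genes and a set of
hub (signaling-pathway) genes, then maps states to log2 expression as
``mu_g + delta * state + noise``.  A shared per-sample latent state drives
the hub genes in every sample; smoker-planted signature genes follow that
latent state only in smoker samples (non-smoker-planted genes only in
non-smokers), which is exactly the group-specific coexpression the
differential-network pipeline is designed to find.  Planted genes addition-
ally carry a smoker/non-smoker mean shift (so they pass a differential-
expression screen) and a proportional-hazards survival effect through their
states.  Background genes are mutually independent coin-flip states.

Everything is driven by one master seed; named substreams keep each
component reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import AnnotationCollection
from .rules import RULE_ORDER

__all__ = [
    "SurvivalParams",
    "CohortConfig",
    "TruthRecord",
    "plant_rule_states",
    "generate_expression_cohort",
    "generate_survival",
    "simulate_survival",
    "generate_diagnosis_cohort",
    "generate_truth_annotations",
    "imbalanced_smoking_preset",
]

# default rule types cycled over the smoker-planted genes
_DEFAULT_SMOKER_RULES = ("EQV", "NEQV", "EQV", "EQV", "NEQV", "EQV")

_STREAMS = {
    "latent": 1, "hubs": 2, "smoker": 3, "nonsmoker": 4, "background": 5,
    "expression": 6, "clinical": 7, "survival": 8, "diagnosis": 9,
    "annotations": 10,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


def _gene_baselines(genes: Sequence[str], lo: float, hi: float) -> np.ndarray:
    """Per-gene baseline log2 means, a stable property of the gene name.

    Baselines deliberately do not depend on the cohort seed: two cohorts
    generated with different seeds share gene-wise expression levels, the
    way train and test cohorts profiled on one platform do, so training
    reference means remain meaningful on a test cohort.
    """
    u = np.array(
        [zlib.crc32(g.encode()) / 0xFFFFFFFF for g in genes], dtype=float
    )
    return lo + (hi - lo) * u


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential proportional-hazards survival with simple censoring.

    ``baseline_hazard`` is the per-month event rate at risk 0;
    ``log_hr_per_risk_unit`` scales the planted risk score; censoring is
    administrative at ``censoring_horizon`` months plus, with probability
    ``censoring_rate`` per subject, independent uniform dropout before the
    event.
    """

    baseline_hazard: float = 0.03
    log_hr_per_risk_unit: float = 1.0
    censoring_horizon: float = 60.0
    censoring_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring_horizon must be positive")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_smokers: int = 150
    n_nonsmokers: int = 150
    n_background_genes: int = 200
    n_hubs: int = 6
    planted_smoker_genes: int = 6
    planted_nonsmoker_genes: int = 1
    violation_rate: float = 0.02
    effect_size_delta: float = 1.5
    smoking_shift: float = 1.5
    noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (5.0, 9.0)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    planted_rule_types: Optional[tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_smokers", "n_nonsmokers", "n_background_genes", "n_hubs",
            "planted_smoker_genes", "planted_nonsmoker_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_smokers + self.n_nonsmokers == 0:
            raise ValueError("cohort must contain at least one sample")
        total_genes = (
            self.n_background_genes + self.n_hubs
            + self.planted_smoker_genes + self.planted_nonsmoker_genes
        )
        if total_genes == 0:
            raise ValueError("cohort must contain at least one gene")
        if not 0 <= self.violation_rate < 0.5:
            raise ValueError("violation_rate must lie in [0, 0.5)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.planted_rule_types is not None:
            unknown = set(self.planted_rule_types) - set(RULE_ORDER)
            if unknown:
                raise ValueError(f"unknown planted rule types: {sorted(unknown)}")


def imbalanced_smoking_preset(**overrides) -> CohortConfig:
    """Preset with the heavily imbalanced 149/20 smoker/non-smoker split
    typical of published lung-cancer training cohorts."""
    base = CohortConfig(n_smokers=149, n_nonsmokers=20)
    return replace(base, **overrides)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a generated cohort: what was planted, and where."""

    hub_genes: tuple[str, ...]
    smoker_signature: tuple[str, ...]
    nonsmoker_signature: tuple[str, ...]
    #: planted rule type per (signature_gene, hub_gene) ordered pair
    rule_types: Mapping[tuple[str, str], str]
    #: per-gene log-hazard increment of the "up" state
    survival_effects: Mapping[str, float]

    def __post_init__(self) -> None:
        planted = set(self.smoker_signature) | set(self.nonsmoker_signature)
        if planted & set(self.hub_genes):
            raise ValueError("planted signature genes must be disjoint from hubs")
        for pair, rule in self.rule_types.items():
            if rule not in RULE_ORDER:
                raise ValueError(f"unknown rule type {rule!r} for pair {pair}")

    @property
    def signature_genes(self) -> tuple[str, ...]:
        return self.smoker_signature + self.nonsmoker_signature


def _states_from_latent(
    z: np.ndarray, rule_type: str, rng: np.random.Generator, violation: float
) -> np.ndarray:
    """Antecedent states A such that (A, z) satisfies ``rule_type`` A -> B=z.

    Off-premise cells receive independent coin flips; a fraction ~violation
    of samples is afterwards flipped into the rule's error region.
    """
    n = z.size
    u = rng.random(n) < 0.5
    m = rng.random(n) < 0.7
    if rule_type == "EQV":
        a = z.copy()
    elif rule_type == "NEQV":
        a = 1 - z
    elif rule_type == "IMP":          # A=1 forces z=1
        a = z & m
    elif rule_type == "IMPNOT":       # A=1 forces z=0
        a = (1 - z) & m
    elif rule_type == "NOTIMP":       # A=0 forces z=1
        a = (1 - z) | (z & u)
    elif rule_type == "NOTIMPNOT":    # A=0 forces z=0
        a = z | ((1 - z) & u & m)
    else:
        raise ValueError(f"unknown rule type {rule_type!r}")
    a = a.astype(np.int8)
    if violation > 0:
        a = np.where(rng.random(n) < violation, 1 - a, a)
    return a


def plant_rule_states(
    rule_type: str, n: int, violation_rate: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a pair of binary state vectors satisfying one rule A -> B.

    The antecedent marginal is ~0.5 and the rule's error cell(s) carry an
    expected fraction ~``violation_rate`` of the samples.  With zero
    violation the error cells are exactly empty.
    """
    if rule_type not in RULE_ORDER:
        raise ValueError(f"unknown rule type {rule_type!r}; expected one of {RULE_ORDER}")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng([int(seed) % (2**31), 101])
    a = (rng.random(n) < 0.5).astype(np.int8)
    u = (rng.random(n) < 0.5).astype(np.int8)
    if rule_type == "EQV":
        b = a.copy()
        if violation_rate > 0:
            b = np.where(rng.random(n) < violation_rate, 1 - b, b)
    elif rule_type == "NEQV":
        b = 1 - a
        if violation_rate > 0:
            b = np.where(rng.random(n) < violation_rate, 1 - b, b)
    else:
        antecedent = {"IMP": 1, "IMPNOT": 1, "NOTIMP": 0, "NOTIMPNOT": 0}[rule_type]
        forced = {"IMP": 1, "IMPNOT": 0, "NOTIMP": 1, "NOTIMPNOT": 0}[rule_type]
        on_premise = a == antecedent
        b = np.where(on_premise, forced, u).astype(np.int8)
        if violation_rate > 0:
            # only premise samples can land in the single error cell; flipping
            # them at rate 2v puts expected total mass v in that cell
            flip = on_premise & (rng.random(n) < min(1.0, 2.0 * violation_rate))
            b = np.where(flip, 1 - b, b)
    return a, b


def _gene_names(config: CohortConfig) -> tuple[list, list, list, list]:
    smoker = [f"SMK{i + 1:02d}" for i in range(config.planted_smoker_genes)]
    nonsmoker = [f"NSM{i + 1:02d}" for i in range(config.planted_nonsmoker_genes)]
    hubs = [f"HUB{i + 1:02d}" for i in range(config.n_hubs)]
    background = [f"BG{i + 1:03d}" for i in range(config.n_background_genes)]
    return smoker, nonsmoker, hubs, background


def _make_truth(config: CohortConfig) -> TruthRecord:
    smoker, nonsmoker, hubs, _ = _gene_names(config)
    rule_cycle = config.planted_rule_types or _DEFAULT_SMOKER_RULES
    rule_types: dict[tuple[str, str], str] = {}
    for i, g in enumerate(smoker):
        rule = rule_cycle[i % len(rule_cycle)]
        for h in hubs:
            rule_types[(g, h)] = rule
    for g in nonsmoker:
        for h in hubs:
            rule_types[(g, h)] = "EQV"
    # Survival effects align with each gene's latent orientation so the
    # group-wise marginal associations add instead of cancelling; the lone
    # non-smoker gene carries a larger own effect because it cannot share
    # the hub latent factor's signal across half the cohort.
    positive = {"EQV", "IMP", "NOTIMPNOT"}
    effects: dict[str, float] = {}
    for g in smoker:
        rule = rule_types[(g, hubs[0])] if hubs else "EQV"
        effects[g] = 0.65 if rule in positive else -0.65
    for g in nonsmoker:
        effects[g] = 2.0
    return TruthRecord(
        hub_genes=tuple(hubs),
        smoker_signature=tuple(smoker),
        nonsmoker_signature=tuple(nonsmoker),
        rule_types=rule_types,
        survival_effects=effects,
    )


def generate_expression_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (expression genes x samples, clinical table, truth record).

    Expression is on a log2-like scale.  Smoker samples come first in the
    column order; the clinical table's ``smoker`` column is authoritative.
    """
    truth = _make_truth(config)
    smoker_genes, nonsmoker_genes, hubs, background = _gene_names(config)
    ns, nn = config.n_smokers, config.n_nonsmokers
    n = ns + nn
    if n == 0:
        raise ValueError("cohort must contain at least one sample")
    is_smoker = np.r_[np.ones(ns, dtype=bool), np.zeros(nn, dtype=bool)]
    v = config.violation_rate

    z = (_rng(config.seed, "latent").random(n) < 0.5).astype(np.int8)

    states: dict[str, np.ndarray] = {}
    rng_h = _rng(config.seed, "hubs")
    for h in hubs:
        s = z.copy()
        if v > 0:
            s = np.where(rng_h.random(n) < v, 1 - s, s)
        states[h] = s.astype(np.int8)

    rng_s = _rng(config.seed, "smoker")
    for g in smoker_genes:
        rule = truth.rule_types[(g, hubs[0])] if hubs else "EQV"
        a = _states_from_latent(z, rule, rng_s, v)
        rand = (rng_s.random(n) < 0.5).astype(np.int8)
        states[g] = np.where(is_smoker, a, rand).astype(np.int8)

    rng_n = _rng(config.seed, "nonsmoker")
    for g in nonsmoker_genes:
        rule = truth.rule_types[(g, hubs[0])] if hubs else "EQV"
        a = _states_from_latent(z, rule, rng_n, v)
        rand = (rng_n.random(n) < 0.5).astype(np.int8)
        states[g] = np.where(~is_smoker, a, rand).astype(np.int8)

    rng_b = _rng(config.seed, "background")
    for g in background:
        states[g] = (rng_b.random(n) < 0.5).astype(np.int8)

    genes = smoker_genes + nonsmoker_genes + hubs + background
    state_mat = np.vstack([states[g] for g in genes])

    rng_e = _rng(config.seed, "expression")
    lo, hi = config.baseline_mean_range
    mu = _gene_baselines(genes, lo, hi)
    expr = (
        mu[:, None]
        + config.effect_size_delta * state_mat
        + rng_e.normal(0.0, config.noise_sd, size=state_mat.shape)
    )
    # planted genes are additionally mean-shifted in their own group so a
    # smoker-vs-non-smoker differential screen can find them
    for g in smoker_genes:
        expr[genes.index(g)] += config.smoking_shift * is_smoker
    for g in nonsmoker_genes:
        expr[genes.index(g)] += config.smoking_shift * (~is_smoker)

    samples = [f"S{i + 1:04d}" for i in range(n)]
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    states_df = pd.DataFrame(state_mat, index=genes, columns=samples)

    rng_c = _rng(config.seed, "clinical")
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "smoker": is_smoker.astype(int),
            "stage": rng_c.choice(["I", "II", "III"], size=n, p=[0.6, 0.25, 0.15]),
            "age": np.round(rng_c.normal(65, 10, size=n)).astype(int),
            "gender": rng_c.integers(0, 2, size=n),
            "cancer": np.ones(n, dtype=int),
        }
    ).set_index("sample_id", drop=False)
    surv = generate_survival(
        clinical, truth, config.survival, config.seed, states=states_df
    )
    clinical["surv_months"] = surv["surv_months"]
    clinical["event"] = surv["event"]
    # keep the dichotomized truth available to tests without recomputation
    clinical.attrs["states"] = states_df
    return expr_df, clinical, truth


def simulate_survival(
    risk: np.ndarray, params: SurvivalParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard ``baseline * exp(log_hr * risk)``.

    Subjects are administratively censored at the horizon; with probability
    ``censoring_rate`` a subject instead drops out at a uniform time before
    its (horizon-truncated) event.
    """
    risk = np.asarray(risk, dtype=float)
    hazard = params.baseline_hazard * np.exp(params.log_hr_per_risk_unit * risk)
    if np.any(hazard <= 0):
        raise ValueError("hazard must be positive for every subject")
    t_event = rng.exponential(1.0 / hazard)
    horizon = params.censoring_horizon
    time = np.minimum(t_event, horizon)
    event = t_event <= horizon
    dropout = rng.random(risk.size) < params.censoring_rate
    if dropout.any():
        t_drop = rng.uniform(0.0, np.maximum(time, 1e-9))
        time = np.where(dropout, t_drop, time)
        event = event & ~dropout
    return time, event.astype(int)


def generate_survival(
    clinical: pd.DataFrame,
    truth: TruthRecord,
    params: SurvivalParams,
    seed: int,
    states: Optional[pd.DataFrame] = None,
    risk: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Survival columns for a cohort, driven by the planted per-gene effects.

    The per-sample risk is ``sum_g effect_g * (state_g - 0.5)`` over the
    planted genes; an explicit ``risk`` vector overrides it.
    """
    if risk is None:
        if states is None:
            raise ValueError("either states or an explicit risk vector is required")
        effects = pd.Series(dict(truth.survival_effects), dtype=float)
        missing = effects.index.difference(states.index)
        if len(missing):
            raise KeyError(f"states matrix lacks planted genes: {list(missing)}")
        sub = states.loc[effects.index].to_numpy(dtype=float) - 0.5
        risk = effects.to_numpy() @ sub
    rng = _rng(seed, "survival")
    time, event = simulate_survival(np.asarray(risk, dtype=float), params, rng)
    return pd.DataFrame(
        {"surv_months": time, "event": event}, index=clinical.index
    )


def generate_diagnosis_cohort(
    config: CohortConfig,
    seed: int,
    truth: Optional[TruthRecord] = None,
    n_samples: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cancer/normal cohort: signature genes mean-shifted in cancer samples.

    Returns (expression genes x samples, binary labels with 1 = cancer).
    Half the samples (rounded down) are cancerous; assignment order is
    shuffled deterministically from the seed.
    """
    if truth is None:
        truth = _make_truth(config)
    if n_samples is None:
        n_samples = config.n_smokers + config.n_nonsmokers
    if n_samples < 2:
        raise ValueError("diagnosis cohort needs at least two samples")
    smoker_genes, nonsmoker_genes, hubs, background = _gene_names(config)
    genes = smoker_genes + nonsmoker_genes + hubs + background
    signature = set(truth.signature_genes)
    rng = _rng(seed, "diagnosis")
    labels = np.zeros(n_samples, dtype=int)
    labels[: n_samples // 2] = 1
    rng.shuffle(labels)
    lo, hi = config.baseline_mean_range
    mu = _gene_baselines(genes, lo, hi)
    expr = mu[:, None] + rng.normal(0.0, config.noise_sd, (len(genes), n_samples))
    for i, g in enumerate(genes):
        if g in signature:
            expr[i] += config.effect_size_delta * labels
    samples = [f"D{i + 1:04d}" for i in range(n_samples)]
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    return expr_df, pd.Series(labels, index=samples, name="cancer")


def generate_truth_annotations(
    truth: TruthRecord,
    n_decoy_sets: int = 0,
    seed: int = 0,
    genes: Optional[Sequence[str]] = None,
    pair_sharing_rate: float = 0.1,
    unannotated_fraction: float = 0.0,
    decoy_set_size: int = 8,
) -> AnnotationCollection:
    """Annotation collection whose truth matches the planted network.

    Every planted (signature, hub) pair shares a two-gene set; every other
    annotated pair is declared an interaction with probability
    ``pair_sharing_rate``, so a random annotated non-planted pair is a true
    positive at exactly that rate.  A fraction ``unannotated_fraction`` of
    genes is left entirely out of the annotated universe (their edges label
    as ND).  Optional decoy sets of random genes add correlated sharing on
    top of the pairwise rate.
    """
    if not truth.rule_types and not truth.hub_genes:
        raise ValueError("truth record is empty")
    rng = _rng(seed, "annotations")
    if genes is None:
        genes = list(truth.hub_genes) + list(truth.signature_genes)
    genes = list(dict.fromkeys(genes))
    n_un = int(round(unannotated_fraction * len(genes)))
    unannotated = set(rng.choice(genes, size=n_un, replace=False)) if n_un else set()
    annotated = [g for g in genes if g not in unannotated]

    gene_sets: dict[str, frozenset] = {}
    planted_pairs = set()
    for (g, h) in truth.rule_types:
        planted_pairs.add(frozenset((g, h)))
        if g not in unannotated and h not in unannotated:
            gene_sets[f"PLANTED_{g}_{h}"] = frozenset((g, h))
    # singleton membership puts every annotated gene into the universe
    for g in annotated:
        gene_sets[f"ANN_{g}"] = frozenset((g,))
    for d in range(n_decoy_sets):
        size = min(decoy_set_size, len(annotated))
        if size >= 2:
            members = rng.choice(annotated, size=size, replace=False)
            gene_sets[f"DECOY_{d + 1:03d}"] = frozenset(members)

    interactions: set[frozenset] = set()
    if pair_sharing_rate > 0 and len(annotated) >= 2:
        arr = np.array(annotated)
        iu = np.triu_indices(len(arr), k=1)
        draw = rng.random(iu[0].size) < pair_sharing_rate
        for ia, ib in zip(iu[0][draw], iu[1][draw]):
            pair = frozenset((arr[ia], arr[ib]))
            if pair not in planted_pairs:
                interactions.add(pair)
    return AnnotationCollection(gene_sets=gene_sets, interactions=interactions)
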