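"""Evaluation of coexpression networks against annotation collections.

Edges are labeled TP (the pair shares any annotated gene set or has a known
interaction), FP (both genes annotated but share nothing) or ND
(non-discriminatory: at least one gene outside the annotated universe).
Network precision is TP/(TP+FP) and the q-value FP/(TP+FP) over the labeled
(non-ND) edges.  A permutation FDR shuffles the test cohort's smoking labels
and averages the q-values of the re-validated differential edge sets; a
subsampling stability measures how much of the original signature network is
retrieved from random subsets of the training samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationCollection",
    "EdgeLabelSummary",
    "label_edge",
    "summarize_labels",
    "evaluate_network",
    "FdrResult",
    "permutation_fdr",
    "StabilityResult",
    "stability",
]


@dataclass
class AnnotationCollection:
    """Named gene sets plus pairwise interactions.

    All set-like sources (positional, curated, motif, computational, GO) are
    ingested uniformly as named gene sets; protein-protein style interactions
    as unordered pairs.  The annotated universe is the union of all genes
    appearing in any source.
    """

    gene_sets: dict[str, frozenset] = field(default_factory=dict)
    interactions: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.gene_sets = {k: frozenset(v) for k, v in self.gene_sets.items()}
        self.interactions = {frozenset(p) for p in self.interactions}
        for p in self.interactions:
            if len(p) != 2:
                raise ValueError("interactions must be pairs of two distinct genes")
        self._membership: dict[str, set[str]] = {}
        for name, members in self.gene_sets.items():
            for g in members:
                self._membership.setdefault(g, set()).add(name)
        self._universe = set(self._membership)
        for p in self.interactions:
            self._universe.update(p)

    @property
    def universe(self) -> set:
        return self._universe

    def shares_set(self, a: str, b: str) -> bool:
        sa = self._membership.get(a)
        sb = self._membership.get(b)
        return bool(sa and sb and (sa & sb))

    def has_interaction(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.interactions


def label_edge(pair: Sequence[str], annotations: AnnotationCollection) -> str:
    """Label one gene pair: 'TP', 'FP' or 'ND'."""
    a, b = pair
    if a not in annotations.universe or b not in annotations.universe:
        return "ND"
    if annotations.has_interaction(a, b) or annotations.shares_set(a, b):
        return "TP"
    return "FP"


@dataclass(frozen=True)
class EdgeLabelSummary:
    """TP/FP/ND counts with network precision and q-value."""

    tp: int
    fp: int
    nd: int

    @property
    def defined(self) -> bool:
        return self.tp + self.fp > 0

    @property
    def network_precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.defined else float("nan")

    @property
    def q_value(self) -> float:
        return self.fp / (self.tp + self.fp) if self.defined else float("nan")

    @property
    def n_edges(self) -> int:
        return self.tp + self.fp + self.nd


def summarize_labels(labels: Iterable[str]) -> EdgeLabelSummary:
    counts = {"TP": 0, "FP": 0, "ND": 0}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown edge label {lab!r}")
        counts[lab] += 1
    return EdgeLabelSummary(tp=counts["TP"], fp=counts["FP"], nd=counts["ND"])


def evaluate_network(
    pairs: Iterable[Sequence[str]], annotations: AnnotationCollection
) -> EdgeLabelSummary:
    """Label every edge of a network and summarize."""
    return summarize_labels(label_edge(p, annotations) for p in pairs)


# ---------------------------------------------------------------------------
# Permutation FDR and subsampling stability.  Both re-use the training
# differential edge set and the frozen training reference means.
# ---------------------------------------------------------------------------


def _split_groups(expr: pd.DataFrame, groups: pd.Series):
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("group labels must cover every sample")
    g = groups.astype(int).to_numpy()
    return expr.loc[:, g == 1], expr.loc[:, g == 0]


def _train_differential(train_expr: pd.DataFrame, train_groups: pd.Series, alpha: float):
    """Group networks and differential edges on the training cohort."""
    from .differential import differential_edges
    from .rules import build_network, dichotomize

    means = train_expr.mean(axis=1)
    states = dichotomize(train_expr, means)
    smoker_expr, nonsmoker_expr = _split_groups(states, train_groups)
    net_s = build_network(smoker_expr, alpha=alpha, group="smoker")
    net_n = build_network(nonsmoker_expr, alpha=alpha, group="nonsmoker")
    return differential_edges(net_s, net_n), means


@dataclass
class FdrResult:
    fdr: float
    q_values: tuple[float, ...]
    n_empty: int
    n_perm: int

    @property
    def defined(self) -> bool:
        return len(self.q_values) > 0


def permutation_fdr(
    train_expr: pd.DataFrame,
    train_groups: pd.Series,
    test_expr: pd.DataFrame,
    test_groups: pd.Series,
    hubs: Sequence[str] = (),
    annotations: Optional[AnnotationCollection] = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> FdrResult:
    """FDR of the validated differential network under label permutation.

    The training differential edge set and the training reference means are
    computed once.  For each permutation the test cohort's smoker labels are
    shuffled, the cross-cohort validation is re-run against the permuted
    groups, surviving edges are labeled against the annotations and the
    q-value recorded.  The FDR is the mean q-value; permutations whose
    validated set has no labeled (non-ND) edge contribute nothing and are
    counted in ``n_empty``.
    """
    from .differential import validate_edges

    if annotations is None:
        raise ValueError("an AnnotationCollection is required")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    diff, means = _train_differential(train_expr, train_groups, alpha)
    rng = np.random.default_rng(int(seed) % (2**31))
    labels = test_groups.reindex(test_expr.columns).astype(int).to_numpy()
    qs: list[float] = []
    n_empty = 0
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(labels), index=test_expr.columns)
        validated = validate_edges(diff, test_expr, perm, means, alpha)
        summary = evaluate_network(
            (p for p, _, _ in validated.all_pairs()), annotations
        )
        if summary.defined:
            qs.append(summary.q_value)
        else:
            n_empty += 1
    fdr = float(np.mean(qs)) if qs else float("nan")
    return FdrResult(fdr=fdr, q_values=tuple(qs), n_empty=n_empty, n_perm=n_perm)


@dataclass
class StabilityResult:
    stability: float
    per_iteration: tuple[float, ...]
    n_reference_edges: int

    @property
    def defined(self) -> bool:
        return self.n_reference_edges > 0


def _validated_edge_ids(train_expr, train_groups, test_expr, test_groups, alpha):
    """(pair, group) ids of the validated differential edges for one training set."""
    from .differential import validate_edges

    diff, means = _train_differential(train_expr, train_groups, alpha)
    validated = validate_edges(diff, test_expr, test_groups, means, alpha)
    return {(pair, grp) for pair, grp, _ in validated.all_pairs()}


def stability(
    train_expr: pd.DataFrame,
    train_groups: pd.Series,
    test_expr: pd.DataFrame,
    test_groups: pd.Series,
    hubs: Sequence[str] = (),
    subset_fraction: float = 0.8,
    n_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> StabilityResult:
    """Subsampling stability of the validated differential coexpression set.

    The reference relations are the validated differential edges derived
    from the full training data.  Each iteration subsamples the training
    cohort without replacement within each smoking group (preserving the
    group ratio), re-runs dichotomization, network construction,
    differential extraction and validation against the full test cohort,
    and records the fraction of reference relations retrieved.  Returns the
    mean fraction plus per-iteration values for plotting.
    """
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must lie in (0, 1]")
    groups = train_groups.reindex(train_expr.columns).astype(int)
    reference = _validated_edge_ids(
        train_expr, groups, test_expr, test_groups, alpha
    )
    if not reference:
        return StabilityResult(float("nan"), (), 0)
    rng = np.random.default_rng(int(seed) % (2**31))
    cols = np.asarray(train_expr.columns)
    smoker_cols = cols[groups.to_numpy() == 1]
    nonsmoker_cols = cols[groups.to_numpy() == 0]
    fractions: list[float] = []
    for _ in range(n_iter):
        pick: list = []
        for pool in (smoker_cols, nonsmoker_cols):
            k = int(round(subset_fraction * len(pool)))
            if k < 2:
                raise ValueError("subset keeps fewer than two samples in a group")
            pick.extend(rng.choice(pool, size=k, replace=False))
        sub = train_expr.loc[:, [c for c in train_expr.columns if c in set(pick)]]
        current = _validated_edge_ids(
            sub, groups.loc[sub.columns], test_expr, test_groups, alpha
        )
        fractions.append(len(reference & current) / len(reference))
    return StabilityResult(
        stability=float(np.mean(fractions)),
        per_iteration=tuple(fractions),
        n_reference_edges=len(reference),
    )
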