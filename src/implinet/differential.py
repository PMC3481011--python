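"""Differential network extraction, cross-cohort validation and signature
selection.

A differential component is a gene-pair relation present in one smoking
group's network and absent (any rule type) in the other's.  Pairs carrying
edges of different rule types in both groups are reported separately as
"type changed" and excluded from signature selection.  Signature genes are
the non-hub genes whose group-specific differential edges reach every hub.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .rules import (
    RULE_ORDER,
    ImplicationNetwork,
    RuleStats,
    _rule_arrays,
    _rule_tests,
    dichotomize,
)

__all__ = [
    "DifferentialEdgeSet",
    "SignatureResult",
    "differential_edges",
    "validate_edges",
    "select_signature",
    "check_rule_consistency",
]

Pair = tuple[str, str]


@dataclass
class DifferentialEdgeSet:
    """Group-specific and type-changed gene-pair relations."""

    smoker_specific: dict[Pair, RuleStats] = field(default_factory=dict)
    nonsmoker_specific: dict[Pair, RuleStats] = field(default_factory=dict)
    type_changed: dict[Pair, tuple[RuleStats, RuleStats]] = field(default_factory=dict)
    alpha: float = 0.05
    genes: tuple[str, ...] = ()
    #: populated by validate_edges: pair -> reason an edge was dropped
    dropped: dict[Pair, str] = field(default_factory=dict)

    def group_edges(self, group: str) -> dict[Pair, RuleStats]:
        if group == "smoker":
            return self.smoker_specific
        if group == "nonsmoker":
            return self.nonsmoker_specific
        raise KeyError(group)

    @property
    def n_edges(self) -> int:
        return len(self.smoker_specific) + len(self.nonsmoker_specific)

    def all_pairs(self) -> list[tuple[Pair, str, RuleStats]]:
        out = [(p, "smoker", s) for p, s in self.smoker_specific.items()]
        out += [(p, "nonsmoker", s) for p, s in self.nonsmoker_specific.items()]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                gene_a=p[0], gene_b=p[1], group=grp, rule=s.rule_type,
                precision=s.precision, scope=s.scope,
                z_precision=s.z_precision, p_precision=s.p_precision,
            )
            for p, grp, s in self.all_pairs()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_a", "gene_b", "group", "rule", "precision", "scope",
                "z_precision", "p_precision",
            ],
        ).sort_values(["group", "gene_a", "gene_b"], ignore_index=True)


def differential_edges(
    net_smoker: ImplicationNetwork,
    net_nonsmoker: ImplicationNetwork,
    treat_type_change_as_differential: bool = False,
) -> DifferentialEdgeSet:
    """Compare two group networks built over the same gene universe.

    By default differential means strict presence/absence: a pair carrying
    edges of *different* rule types in both groups is reported separately in
    ``type_changed`` and excluded from the group-specific sets.  With
    ``treat_type_change_as_differential=True`` such pairs are additionally
    entered into both group-specific sets (each with its own group's rule),
    the looser reading under which a changed relation also counts as
    group-specific signal.
    """
    if net_smoker.genes != net_nonsmoker.genes:
        raise ValueError("networks were built over different gene universes")
    if net_smoker.alpha != net_nonsmoker.alpha:
        raise ValueError("networks were built at different alpha levels")
    diff = DifferentialEdgeSet(alpha=net_smoker.alpha, genes=net_smoker.genes)
    for pair, stats in net_smoker.edges.items():
        other = net_nonsmoker.edges.get(pair)
        if other is None:
            diff.smoker_specific[pair] = stats
        elif other.rule_type != stats.rule_type:
            diff.type_changed[pair] = (stats, other)
            if treat_type_change_as_differential:
                diff.smoker_specific[pair] = stats
                diff.nonsmoker_specific[pair] = other
    for pair, stats in net_nonsmoker.edges.items():
        if pair not in net_smoker.edges:
            diff.nonsmoker_specific[pair] = stats
    return diff


def _pair_tables(states: pd.DataFrame, pairs: Sequence[Pair]):
    """Stacked 2x2 counts for selected (gene_a, gene_b) pairs."""
    S = states.to_numpy().astype(np.int8)
    index = {g: i for i, g in enumerate(states.index)}
    ia = np.array([index[a] for a, _ in pairs])
    ib = np.array([index[b] for _, b in pairs])
    A = S[ia]
    B = S[ib]
    n11 = np.sum((A == 1) & (B == 1), axis=1)
    n10 = np.sum((A == 1) & (B == 0), axis=1)
    n01 = np.sum((A == 0) & (B == 1), axis=1)
    n00 = np.sum((A == 0) & (B == 0), axis=1)
    return n11, n10, n01, n00


def _rule_significance(states, pairs, alpha, min_scope=0.0):
    """(6 x pairs) per-rule significance plus per-rule stats for given pairs."""
    n, V, K, scope, premise = _rule_arrays(*_pair_tables(states, pairs))
    nabla, z_prec, p_prec, z_scope, p_scope, defined = _rule_tests(
        n, V, K, scope, premise, min_scope
    )
    sig = defined & (nabla > 0) & (p_prec < alpha) & (p_scope < alpha)
    return sig


def validate_edges(
    diff: DifferentialEdgeSet,
    test_expr: pd.DataFrame,
    test_groups: pd.Series,
    training_means: pd.Series,
    alpha: Optional[float] = None,
) -> DifferentialEdgeSet:
    """Keep differential edges that replicate in an independent test cohort.

    The test cohort is dichotomized with the *training* reference means.  An
    edge from group G survives iff its rule type is significant in the test
    cohort's group G and no rule is significant for that pair in the other
    test group (it stays group-specific).  Dropped edges carry a reason code
    in ``result.dropped``.
    """
    alpha = diff.alpha if alpha is None else alpha
    groups = test_groups.reindex(test_expr.columns)
    if groups.isna().any():
        raise ValueError("test_groups must cover every test sample")
    states = dichotomize(test_expr, training_means)
    out = DifferentialEdgeSet(alpha=alpha, genes=diff.genes)
    for grp, other in (("smoker", "nonsmoker"), ("nonsmoker", "smoker")):
        edges = diff.group_edges(grp)
        if not edges:
            continue
        in_grp = states.loc[:, (groups == (1 if grp == "smoker" else 0)).to_numpy()]
        in_other = states.loc[:, (groups == (0 if grp == "smoker" else 1)).to_numpy()]
        if in_grp.shape[1] == 0 or in_other.shape[1] == 0:
            raise ValueError(f"empty test group while validating {grp} edges")
        pairs = list(edges)
        sig_same = _rule_significance(in_grp, pairs, alpha)
        sig_other = _rule_significance(in_other, pairs, alpha)
        for j, pair in enumerate(pairs):
            rule_idx = RULE_ORDER.index(edges[pair].rule_type)
            if not sig_same[rule_idx, j]:
                out.dropped[pair] = f"{grp}:not_significant_in_test"
            elif sig_other[:, j].any():
                out.dropped[pair] = f"{grp}:not_specific_in_test"
            else:
                out.group_edges(grp)[pair] = edges[pair]
    return out


@dataclass
class SignatureResult:
    """Genes coexpressed with every hub in a group-specific differential set."""

    smoker_genes: tuple[str, ...]
    nonsmoker_genes: tuple[str, ...]
    hubs: tuple[str, ...]
    #: selected gene -> its justifying hub edges (pair, rule stats)
    justification: Mapping[str, tuple[tuple[Pair, RuleStats], ...]]
    #: per-gene hub adjacency counts (diagnostic, includes non-selected genes)
    adjacency_counts: Mapping[str, int]

    @property
    def genes(self) -> tuple[str, ...]:
        return self.smoker_genes + self.nonsmoker_genes

    def network_edges(self) -> dict[Pair, tuple[str, RuleStats]]:
        """The signature subnetwork: every justifying (gene, hub) edge."""
        edges: dict[Pair, tuple[str, RuleStats]] = {}
        for g in self.smoker_genes:
            for pair, stats in self.justification[g]:
                edges[pair] = ("smoker", stats)
        for g in self.nonsmoker_genes:
            for pair, stats in self.justification[g]:
                edges[pair] = ("nonsmoker", stats)
        return edges

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for grp, genes in (("smoker", self.smoker_genes), ("nonsmoker", self.nonsmoker_genes)):
            for g in genes:
                for (a, b), stats in self.justification[g]:
                    hub = b if a == g else a
                    rows.append(
                        dict(gene=g, group=grp, hub=hub, rule=stats.rule_type,
                             precision=stats.precision, p_precision=stats.p_precision)
                    )
        return pd.DataFrame(
            rows, columns=["gene", "group", "hub", "rule", "precision", "p_precision"]
        )


def select_signature(
    diff: DifferentialEdgeSet, hubs: Sequence[str]
) -> SignatureResult:
    """Select genes with a group-specific differential edge to every hub.

    Hubs themselves are never signature genes.  ``adjacency_counts`` reports
    how close every differential gene came, which diagnoses empty results.
    """
    hubs = tuple(hubs)
    hub_set = set(hubs)
    adjacency: dict[str, int] = {}
    selected: dict[str, list] = {"smoker": [], "nonsmoker": []}
    justification: dict[str, tuple] = {}
    for grp in ("smoker", "nonsmoker"):
        edges = diff.group_edges(grp)
        per_gene: dict[str, list] = {}
        for (a, b), stats in edges.items():
            for g, h in ((a, b), (b, a)):
                if g not in hub_set and h in hub_set:
                    per_gene.setdefault(g, []).append(((a, b), stats))
        for g, hub_edges in per_gene.items():
            n_hub = len({(b if a == g else a) for (a, b), _ in hub_edges})
            adjacency[g] = max(adjacency.get(g, 0), n_hub)
            if n_hub == len(hubs) and len(hubs) > 0:
                selected[grp].append(g)
                justification[g] = tuple(sorted(hub_edges, key=lambda e: e[0]))
    return SignatureResult(
        smoker_genes=tuple(sorted(selected["smoker"])),
        nonsmoker_genes=tuple(sorted(selected["nonsmoker"])),
        hubs=hubs,
        justification=justification,
        adjacency_counts=adjacency,
    )


#: NNK-style observed-change confirmation table.  A rule is confirmed when the
#: observed direction of change of both genes is consistent with it; an
#: unchanged gene confirms nothing.
_CONFIRMATIONS: Mapping[str, tuple[tuple[str, str], ...]] = {
    "EQV": (("up", "up"), ("down", "down")),
    "NEQV": (("up", "down"), ("down", "up")),
    "IMP": (("up", "up"),),
    "IMPNOT": (("up", "down"),),
    "NOTIMP": (("down", "up"),),
    "NOTIMPNOT": (("down", "down"),),
}

_CHANGE_TOKENS = ("up", "down", "none")


def check_rule_consistency(
    rule_type: str, observed_change_a: str, observed_change_b: str
) -> bool:
    """Is an observed pair of expression changes consistent with a rule?"""
    if rule_type not in RULE_ORDER:
        raise ValueError(f"unknown rule type {rule_type!r}")
    for token in (observed_change_a, observed_change_b):
        if token not in _CHANGE_TOKENS:
            raise ValueError(
                f"unknown change token {token!r}; expected one of {_CHANGE_TOKENS}"
            )
    return (observed_change_a, observed_change_b) in _CONFIRMATIONS[rule_type]
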