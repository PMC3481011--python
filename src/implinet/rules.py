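"""Prediction-logic implication rules between dichotomized gene pairs.

Six rule types relate two binary expression states A and B (1 = expression
above the training-set mean, "up"; 0 = at or below, "down"):

====================  =========================  ==================
token                 reading                    error cell(s) (A,B)
====================  =========================  ==================
``EQV``               A <=> B                    (1,0), (0,1)
``NEQV``              A <=> not B                (1,1), (0,0)
``IMP``               A => B                     (1,0)
``IMPNOT``            A => not B                 (1,1)
``NOTIMP``            not A => B                 (0,0)
``NOTIMPNOT``         not A => not B             (0,1)
====================  =========================  ==================

For a rule with error-cell set E over a 2x2 table of N samples, the
observed error rate is ``V = sum_E n_ij / N`` and the expected error rate
under marginal independence is ``K = sum_E p_i. * p_.j``.  The rule's
precision ("del") is ``nabla = 1 - V/K``; its scope U is the fraction of
samples to which the premise applies (the antecedent marginal for the four
directional rules, 1 for the two equivalences).  Precision is tested with a
one-sided z treating the error count as Binomial(N, K) under independence::

    z = (N*K - N*V) / sqrt(N*K*(1-K))

This estimator family is a reconstruction of the classical prediction-logic
del analysis; the exact formulas used by historical implication-induction
software are unpublished, so the package documents its own definitions (see
docs/methods.md) rather than asserting equivalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RULE_ORDER",
    "RULE_SYMBOLS",
    "ERROR_CELLS",
    "ContingencyTable",
    "RuleStats",
    "ImplicationNetwork",
    "dichotomize",
    "contingency",
    "rule_statistics",
    "induce_relation",
    "induce_relation_many",
    "permutation_pvalue",
    "build_network",
    "pearson_network",
]

# Selection priority on precision ties: equivalences first, then the fixed
# directional order.
RULE_ORDER: tuple[str, ...] = ("EQV", "NEQV", "IMP", "IMPNOT", "NOTIMP", "NOTIMPNOT")

RULE_SYMBOLS: Mapping[str, str] = {
    "EQV": "A<=>B",
    "NEQV": "A<=>~B",
    "IMP": "A=>B",
    "IMPNOT": "A=>~B",
    "NOTIMP": "~A=>B",
    "NOTIMPNOT": "~A=>~B",
}

ERROR_CELLS: Mapping[str, tuple[tuple[int, int], ...]] = {
    "EQV": ((1, 0), (0, 1)),
    "NEQV": ((1, 1), (0, 0)),
    "IMP": ((1, 0),),
    "IMPNOT": ((1, 1),),
    "NOTIMP": ((0, 0),),
    "NOTIMPNOT": ((0, 1),),
}

#: antecedent state for the directional rules (None for equivalences)
_ANTECEDENT: Mapping[str, Optional[int]] = {
    "EQV": None,
    "NEQV": None,
    "IMP": 1,
    "IMPNOT": 1,
    "NOTIMP": 0,
    "NOTIMPNOT": 0,
}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 joint counts of dichotomized states for an ordered pair (A, B)."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        counts = (self.n11, self.n10, self.n01, self.n00)
        if any(c < 0 for c in counts):
            raise ValueError("contingency counts must be non-negative")
        if sum(counts) <= 0:
            raise ValueError("contingency table must contain at least one sample")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_vectors(cls, a: Sequence[int], b: Sequence[int]) -> "ContingencyTable":
        return contingency(a, b)

    def as_array(self) -> np.ndarray:
        return np.array([[self.n00, self.n01], [self.n10, self.n11]])


@dataclass(frozen=True)
class RuleStats:
    """Scope/precision statistics of one implication rule on one table."""

    rule_type: str
    scope: float
    precision: float
    error_rate: float          # observed V
    expected_error_rate: float  # K under independence
    z_precision: float
    p_precision: float
    z_scope: float
    p_scope: float
    n: int
    defined: bool = True

    @property
    def symbol(self) -> str:
        return RULE_SYMBOLS[self.rule_type]

    def is_significant(self, alpha: float = 0.05) -> bool:
        return (
            self.defined
            and self.precision > 0
            and self.p_precision < alpha
            and self.p_scope < alpha
        )


def contingency(a: Sequence[int], b: Sequence[int]) -> ContingencyTable:
    """Tally the 2x2 table of two equal-length binary vectors."""
    a_arr = np.asarray(a).astype(bool)
    b_arr = np.asarray(b).astype(bool)
    if a_arr.shape != b_arr.shape or a_arr.ndim != 1:
        raise ValueError("state vectors must be 1-D and of equal length")
    if a_arr.size == 0:
        raise ValueError("state vectors must be non-empty")
    n11 = int(np.sum(a_arr & b_arr))
    n10 = int(np.sum(a_arr & ~b_arr))
    n01 = int(np.sum(~a_arr & b_arr))
    n00 = int(np.sum(~a_arr & ~b_arr))
    return ContingencyTable(n11, n10, n01, n00)


def dichotomize(expr: pd.DataFrame, reference_means: pd.Series) -> pd.DataFrame:
    """Binarize a genes x samples matrix against per-gene reference means.

    State 1 means strictly above the reference mean ("up"); values at or
    below the mean, including exact ties, map to 0.  The reference means must
    come from the designated training samples and are reused unchanged when
    dichotomizing test cohorts.
    """
    missing = expr.index.difference(reference_means.index)
    if len(missing) > 0:
        raise KeyError(f"no reference mean for genes: {sorted(missing)[:5]}")
    means = reference_means.loc[expr.index]
    return expr.gt(means, axis=0)


# ---------------------------------------------------------------------------
# Vectorized rule arithmetic.  All scalar entry points delegate here.
# ---------------------------------------------------------------------------


def _rule_arrays(n11, n10, n01, n00):
    """Per-rule V, K, scope and premise counts for stacked tables.

    Inputs are broadcastable count arrays; outputs have a leading axis of
    length six ordered as RULE_ORDER.
    """
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    n = n11 + n10 + n01 + n00
    with np.errstate(invalid="ignore", divide="ignore"):
        pa1 = (n11 + n10) / n
        pb1 = (n11 + n01) / n
    pa0 = 1.0 - pa1
    pb0 = 1.0 - pb1

    cell = {(1, 1): n11, (1, 0): n10, (0, 1): n01, (0, 0): n00}
    marg = {(1, 1): pa1 * pb1, (1, 0): pa1 * pb0, (0, 1): pa0 * pb1, (0, 0): pa0 * pb0}

    V = np.empty((6,) + n.shape)
    K = np.empty_like(V)
    scope = np.empty_like(V)
    premise = np.empty_like(V)
    for i, rule in enumerate(RULE_ORDER):
        cells = ERROR_CELLS[rule]
        with np.errstate(invalid="ignore", divide="ignore"):
            V[i] = sum(cell[c] for c in cells) / n
        K[i] = sum(marg[c] for c in cells)
        ant = _ANTECEDENT[rule]
        if ant is None:
            scope[i] = 1.0
            premise[i] = n
        elif ant == 1:
            scope[i] = pa1
            premise[i] = n11 + n10
        else:
            scope[i] = pa0
            premise[i] = n01 + n00
    return n, V, K, scope, premise


def _rule_tests(n, V, K, scope, premise, min_scope: float = 0.0):
    """Precision/scope z statistics and p-values for stacked rule arrays."""
    with np.errstate(invalid="ignore", divide="ignore"):
        nabla = 1.0 - V / K
        z_prec = (n * K - n * V) / np.sqrt(n * K * (1.0 - K))
    defined = (K > 0) & (K < 1)
    nabla = np.where(defined, nabla, np.nan)
    z_prec = np.where(defined, z_prec, np.nan)
    p_prec = np.where(defined, sps.norm.sf(z_prec), np.nan)

    if min_scope > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            z_scope = (premise - n * min_scope) / np.sqrt(n * min_scope * (1 - min_scope))
        p_scope = sps.norm.sf(z_scope)
    else:
        # With a zero minimum the scope test is structural: any non-empty
        # premise passes; an empty premise cannot.
        z_scope = np.where(premise > 0, np.inf, 0.0)
        p_scope = np.where(premise > 0, 0.0, 0.5)
    return nabla, z_prec, p_prec, z_scope, p_scope, defined


def rule_statistics(
    table: ContingencyTable, rule_type: str, min_scope: float = 0.0
) -> RuleStats:
    """Scope/precision statistics for one rule on one contingency table.

    When the expected error rate K is zero (a degenerate marginal) the
    precision is undefined and the rule is returned flagged non-significant.
    """
    if rule_type not in RULE_ORDER:
        raise ValueError(f"unknown rule type {rule_type!r}; expected one of {RULE_ORDER}")
    i = RULE_ORDER.index(rule_type)
    n, V, K, scope, premise = _rule_arrays(table.n11, table.n10, table.n01, table.n00)
    nabla, z_prec, p_prec, z_scope, p_scope, defined = _rule_tests(
        n, V, K, scope, premise, min_scope
    )
    return RuleStats(
        rule_type=rule_type,
        scope=float(scope[i]),
        precision=float(nabla[i]),
        error_rate=float(V[i]),
        expected_error_rate=float(K[i]),
        z_precision=float(z_prec[i]),
        p_precision=float(p_prec[i]),
        z_scope=float(z_scope[i]),
        p_scope=float(p_scope[i]),
        n=table.n,
        defined=bool(defined[i]),
    )


def permutation_pvalue(
    a: Sequence[int],
    b: Sequence[int],
    rule_type: str,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical one-sided p for a rule's error count under label permutation.

    The second vector is permuted relative to the first; the p-value is the
    (add-one smoothed) fraction of permutations whose error count is at most
    the observed one.  This is the model-free reference the analytic z
    approximates.
    """
    if rule_type not in RULE_ORDER:
        raise ValueError(f"unknown rule type {rule_type!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_arr = np.asarray(a).astype(bool)
    b_arr = np.asarray(b).astype(int)
    cells = ERROR_CELLS[rule_type]

    def err_count(bmat: np.ndarray) -> np.ndarray:
        total = np.zeros(bmat.shape[:-1], dtype=int)
        for ca, cb in cells:
            mask = a_arr == bool(ca)
            total = total + np.sum(bmat[..., mask] == cb, axis=-1)
        return total

    obs = int(err_count(b_arr[None, :])[0])
    order = np.argsort(rng.random((n_perm, b_arr.size)), axis=1)
    perm_err = err_count(b_arr[order])
    return (1 + int(np.sum(perm_err <= obs))) / (1 + n_perm)


def _select(
    n11, n10, n01, n00, alpha: float, min_scope: float = 0.0
):
    """Vectorized rule selection: index of the chosen rule per table (-1 none).

    Among rules significant at ``alpha`` (precision and scope) with positive
    precision, the maximum-precision rule wins; exact ties go to the earlier
    entry of RULE_ORDER, i.e. equivalences are preferred.
    """
    n, V, K, scope, premise = _rule_arrays(n11, n10, n01, n00)
    nabla, z_prec, p_prec, z_scope, p_scope, defined = _rule_tests(
        n, V, K, scope, premise, min_scope
    )
    sig = defined & (nabla > 0) & (p_prec < alpha) & (p_scope < alpha)
    cand = np.where(sig, nabla, -np.inf)
    best_idx = np.full(np.shape(n), -1, dtype=int)
    best_val = np.full(np.shape(n), -np.inf)
    for i in range(6):  # earlier rules win ties because comparison is strict
        take = cand[i] > best_val
        best_val = np.where(take, cand[i], best_val)
        best_idx = np.where(take, i, best_idx)
    stats = dict(
        nabla=nabla, z_prec=z_prec, p_prec=p_prec, z_scope=z_scope,
        p_scope=p_scope, V=V, K=K, scope=scope, n=n, sig=sig,
    )
    return best_idx, stats


def _stats_at(stats, i: int, h: int) -> RuleStats:
    """Materialize a RuleStats from stacked arrays at rule i, table position h."""

    def pick(name: str) -> float:
        return float(np.asarray(stats[name][i]).ravel()[h])

    return RuleStats(
        rule_type=RULE_ORDER[i],
        scope=pick("scope"),
        precision=pick("nabla"),
        error_rate=pick("V"),
        expected_error_rate=pick("K"),
        z_precision=pick("z_prec"),
        p_precision=pick("p_prec"),
        z_scope=pick("z_scope"),
        p_scope=pick("p_scope"),
        n=int(np.asarray(stats["n"]).ravel()[h]),
        defined=True,
    )


def induce_relation(
    a: Sequence[int],
    b: Sequence[int],
    alpha: float = 0.05,
    min_scope: float = 0.0,
) -> Optional[RuleStats]:
    """Derive the best significant implication rule between two state vectors.

    All six rules are evaluated on the joint 2x2 table; rules whose precision
    and scope are both significant at ``alpha`` (one-sided z-tests) with
    positive precision are kept, and the maximum-precision keeper is
    returned (equivalence preferred on exact ties).  Returns ``None`` when no
    rule qualifies, in particular for degenerate all-0/all-1 vectors.
    """
    t = contingency(a, b)
    return induce_from_table(t, alpha=alpha, min_scope=min_scope)


def induce_from_table(
    table: ContingencyTable, alpha: float = 0.05, min_scope: float = 0.0
) -> Optional[RuleStats]:
    idx, stats = _select(
        np.array([table.n11]), np.array([table.n10]),
        np.array([table.n01]), np.array([table.n00]),
        alpha, min_scope,
    )
    i = int(idx[0])
    if i < 0:
        return None
    return _stats_at(stats, i, 0)


def induce_relation_many(
    a_mat: np.ndarray,
    b_mat: np.ndarray,
    alpha: float = 0.05,
    min_scope: float = 0.0,
):
    """Rule induction over many pairs at once.

    ``a_mat`` and ``b_mat`` are (pairs x samples) binary arrays; row i of each
    forms one pair.  Returns ``(selected, sig)`` where ``selected`` is an int
    array of chosen rule indices into RULE_ORDER (-1 for none) and ``sig`` is
    the (6 x pairs) boolean per-rule significance matrix.
    """
    a_arr = np.asarray(a_mat).astype(bool)
    b_arr = np.asarray(b_mat).astype(bool)
    n11 = np.sum(a_arr & b_arr, axis=1)
    n10 = np.sum(a_arr & ~b_arr, axis=1)
    n01 = np.sum(~a_arr & b_arr, axis=1)
    n00 = np.sum(~a_arr & ~b_arr, axis=1)
    idx, stats = _select(n11, n10, n01, n00, alpha, min_scope)
    return idx, stats["sig"]


@dataclass
class ImplicationNetwork:
    """Per-group coexpression network: unordered gene pair -> selected rule.

    Pair keys are ``(gene_a, gene_b)`` tuples in the matrix's gene order;
    the stored rule is oriented A -> B with A the first gene of the key.
    """

    group: str
    genes: tuple[str, ...]
    alpha: float
    edges: dict[tuple[str, str], RuleStats] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def has_pair(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.edges

    def rule_for(self, a: str, b: str) -> Optional[RuleStats]:
        return self.edges.get(self._key(a, b))

    def _key(self, a: str, b: str) -> tuple[str, str]:
        ia, ib = self.genes.index(a), self.genes.index(b)
        return (a, b) if ia <= ib else (b, a)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                gene_a=a, gene_b=b, rule=s.rule_type, scope=s.scope,
                precision=s.precision, z_precision=s.z_precision,
                p_precision=s.p_precision, z_scope=s.z_scope, p_scope=s.p_scope,
            )
            for (a, b), s in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_a", "gene_b", "rule", "scope", "precision",
                "z_precision", "p_precision", "z_scope", "p_scope",
            ],
        )


def build_network(
    states: pd.DataFrame,
    alpha: float = 0.05,
    group: str = "",
    min_scope: float = 0.0,
) -> ImplicationNetwork:
    """Induce implication rules over all unordered gene pairs of a state matrix.

    ``states`` is genes x samples, boolean or 0/1.  Exactly k(k-1)/2 pairs are
    evaluated; each stored edge carries the selected rule oriented from the
    lower-index gene to the higher-index gene.
    """
    genes = tuple(states.index)
    if len(genes) < 2:
        raise ValueError("network construction needs at least two genes")
    S = states.to_numpy().astype(np.int64)
    ones = np.ones_like(S)
    c11 = S @ S.T
    c10 = S @ (ones - S).T
    c01 = c10.T
    c00 = (ones - S) @ (ones - S).T
    iu = np.triu_indices(len(genes), k=1)
    idx, stats = _select(c11[iu], c10[iu], c01[iu], c00[iu], alpha, min_scope)
    net = ImplicationNetwork(group=group, genes=genes, alpha=alpha)
    hits = np.nonzero(idx >= 0)[0]
    for h in hits:
        i = int(idx[h])
        a, b = genes[iu[0][h]], genes[iu[1][h]]
        net.edges[(a, b)] = _stats_at(stats, i, int(h))
    return net


def pearson_network(
    expr: pd.DataFrame, alpha: float = 0.05, group: str = ""
) -> pd.DataFrame:
    """Comparator network: edges are significant Pearson correlations.

    Returns a data frame with one row per significant unordered pair
    (gene_a, gene_b, r, p, sign).  Zero-variance genes are skipped with a
    warning.  Provided for side-by-side reporting only; it carries no rule
    types.
    """
    if expr.shape[1] < 3:
        raise ValueError("Pearson comparator needs at least three samples")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"skipping {int((~keep).sum())} zero-variance gene(s) in Pearson comparator"
        )
    genes = expr.index[keep]
    vals = vals[keep]
    n = vals.shape[1]
    r = np.corrcoef(vals)
    iu = np.triu_indices(len(genes), k=1)
    rv = np.clip(r[iu], -0.9999999999, 0.9999999999)
    tstat = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    mask = p < alpha
    return pd.DataFrame(
        dict(
            gene_a=np.asarray(genes)[iu[0][mask]],
            gene_b=np.asarray(genes)[iu[1][mask]],
            r=rv[mask],
            p=p[mask],
            sign=np.sign(rv[mask]).astype(int),
        )
    )
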