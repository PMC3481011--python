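"""Unit and property tests for the prediction-logic rule machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from implinet.rules import (
    ERROR_CELLS,
    RULE_ORDER,
    ContingencyTable,
    build_network,
    contingency,
    dichotomize,
    induce_from_table,
    induce_relation,
    induce_relation_many,
    pearson_network,
    permutation_pvalue,
    rule_statistics,
)

tables = st.tuples(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
).filter(lambda t: sum(t) > 0)


class TestContingency:
    def test_enumeration(self):
        t = contingency([1, 1, 0, 0], [1, 0, 1, 0])
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 1, 1)

    def test_identical_vectors(self):
        t = contingency([1, 0], [1, 0])
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 0, 0, 1)

    def test_counts_conserve_length(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 2, 1000), rng.integers(0, 2, 1000)
        assert contingency(a, b).n == 1000

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contingency([1, 0], [1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestRuleStatistics:
    def test_directional_rule_hand_arithmetic(self):
        s = rule_statistics(ContingencyTable(40, 10, 10, 40), "IMP")
        assert s.error_rate == pytest.approx(0.10)
        assert s.expected_error_rate == pytest.approx(0.25)
        assert s.precision == pytest.approx(0.6)
        assert s.scope == pytest.approx(0.5)
        assert s.z_precision == pytest.approx(15 / np.sqrt(18.75), abs=1e-9)
        assert s.p_precision == pytest.approx(2.66e-4, rel=0.01)

    def test_equivalence_rule_hand_arithmetic(self):
        s = rule_statistics(ContingencyTable(45, 5, 5, 45), "EQV")
        assert s.error_rate == pytest.approx(0.10)
        assert s.expected_error_rate == pytest.approx(0.50)
        assert s.precision == pytest.approx(0.8)
        assert s.z_precision == pytest.approx(8.0)

    def test_exact_independence_is_null(self):
        for rule in RULE_ORDER:
            s = rule_statistics(ContingencyTable(25, 25, 25, 25), rule)
            assert s.precision == pytest.approx(0.0)
            assert s.z_precision == pytest.approx(0.0)
            assert s.p_precision == pytest.approx(0.5)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            rule_statistics(ContingencyTable(1, 1, 1, 1), "XOR")

    def test_degenerate_marginal_flagged_undefined(self):
        # all A=1: the NOTIMP premise never fires and K=0 for A-premise rules
        s = rule_statistics(ContingencyTable(5, 5, 0, 0), "NOTIMP")
        assert not s.defined
        assert not s.is_significant()

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_precision_one_iff_empty_error_cells(self, counts):
        t = ContingencyTable(*counts)
        cells = dict(zip([(1, 1), (1, 0), (0, 1), (0, 0)], counts))
        for rule in RULE_ORDER:
            s = rule_statistics(t, rule)
            if not s.defined:
                continue
            empty = all(cells[c] == 0 for c in ERROR_CELLS[rule])
            assert (s.precision == pytest.approx(1.0)) == empty

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_equivalence_rules_symmetric_in_a_and_b(self, counts):
        n11, n10, n01, n00 = counts
        swapped = ContingencyTable(n11, n01, n10, n00)  # A <-> B transposes 10/01
        for rule in ("EQV", "NEQV"):
            s1 = rule_statistics(ContingencyTable(*counts), rule)
            s2 = rule_statistics(swapped, rule)
            for field in ("precision", "z_precision", "scope"):
                v1, v2 = getattr(s1, field), getattr(s2, field)
                assert (np.isnan(v1) and np.isnan(v2)) or v1 == pytest.approx(v2)

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_complement_relabeling_maps_rules(self, counts):
        # relabeling B -> not B turns A=>B into A=>not B with identical stats
        n11, n10, n01, n00 = counts
        flipped = ContingencyTable(n10, n11, n00, n01)
        s1 = rule_statistics(ContingencyTable(*counts), "IMP")
        s2 = rule_statistics(flipped, "IMPNOT")
        for field in ("precision", "z_precision", "error_rate", "expected_error_rate"):
            v1, v2 = getattr(s1, field), getattr(s2, field)
            assert (np.isnan(v1) and np.isnan(v2)) or v1 == pytest.approx(v2)


class TestInduceRelation:
    def test_equivalence_wins_on_symmetric_table(self):
        assert induce_from_table(ContingencyTable(45, 5, 5, 45)).rule_type == "EQV"

    def test_directional_perfect_rule_beats_equivalence(self):
        # B = A or noise: A=>B has empty error cell (precision 1) while the
        # equivalence pays for the noisy half
        sel = induce_from_table(ContingencyTable(50, 0, 25, 25))
        assert sel.rule_type == "IMP"
        assert sel.precision == pytest.approx(1.0)

    def test_independence_yields_no_rule(self):
        assert induce_from_table(ContingencyTable(25, 25, 25, 25)) is None

    def test_degenerate_vectors_yield_none(self):
        assert induce_relation(np.ones(50), np.zeros(50)) is None
        assert induce_relation(np.ones(50), np.ones(50)) is None

    def test_selected_rule_maximizes_precision_over_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.multinomial(80, rng.dirichlet(np.ones(4)))
            t = ContingencyTable(*counts)
            sel = induce_from_table(t, alpha=0.05)
            stats = [rule_statistics(t, r) for r in RULE_ORDER]
            sig = [s for s in stats if s.is_significant(0.05)]
            if sel is None:
                assert not sig
            else:
                best = max(s.precision for s in sig)
                assert sel.precision == pytest.approx(best)
                # ties prefer the earlier (equivalence-first) rule
                first = next(s for s in sig if s.precision == pytest.approx(best))
                assert sel.rule_type == first.rule_type


class TestDichotomize:
    def test_tie_at_mean_maps_down(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        states = dichotomize(expr, pd.Series({"g": 2.0}))
        assert states.loc["g"].tolist() == [False, False, True]

    def test_constant_gene_all_down(self):
        expr = pd.DataFrame([[2.0, 2.0]], index=["g"], columns=list("ab"))
        assert not dichotomize(expr, pd.Series({"g": 2.0})).loc["g"].any()

    def test_training_means_differ_from_test_means(self):
        # a test cohort shifted upward stays mostly "up" under training means
        expr = pd.DataFrame([[5.0, 6.0, 7.0]], index=["g"], columns=list("abc"))
        train_states = dichotomize(expr, pd.Series({"g": 2.0}))
        test_states = dichotomize(expr, pd.Series({"g": expr.loc["g"].mean()}))
        assert train_states.loc["g"].all()
        assert not test_states.loc["g"].all()

    def test_missing_reference_mean_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["a"])
        with pytest.raises(KeyError):
            dichotomize(expr, pd.Series({"other": 0.0}))


class TestBuildNetwork:
    def test_pair_count_is_k_choose_2(self):
        rng = np.random.default_rng(1)
        states = pd.DataFrame(
            rng.integers(0, 2, (6, 300)).astype(bool),
            index=[f"g{i}" for i in range(6)],
        )
        net = build_network(states)
        # no direct pair count is exposed; instead the planted-free network
        # stays near-empty and never exceeds the pair count
        assert len(net) <= 15

    def test_planted_equivalence_detected_with_full_precision(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 400)
        states = pd.DataFrame([a, a, rng.integers(0, 2, 400)], index=["x", "y", "z"])
        net = build_network(states.astype(bool))
        edge = net.rule_for("x", "y")
        assert edge is not None and edge.rule_type == "EQV"
        assert edge.precision == pytest.approx(1.0)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            build_network(pd.DataFrame([[1, 0]], index=["g"]))

    def test_matches_scalar_induction(self):
        rng = np.random.default_rng(3)
        states = pd.DataFrame(
            rng.integers(0, 2, (5, 120)).astype(bool),
            index=list("abcde"),
        )
        net = build_network(states, alpha=0.3)
        genes = list(states.index)
        for i, ga in enumerate(genes):
            for gb in genes[i + 1:]:
                scalar = induce_relation(
                    states.loc[ga].to_numpy(), states.loc[gb].to_numpy(), alpha=0.3
                )
                edge = net.rule_for(ga, gb)
                if scalar is None:
                    assert edge is None
                else:
                    assert edge is not None
                    assert edge.rule_type == scalar.rule_type
                    assert edge.precision == pytest.approx(scalar.precision)


class TestTypeIControl:
    def test_per_rule_false_positive_rate_bounded(self):
        rng = np.random.default_rng(11)
        n_pairs, n = 2000, 300
        a = rng.random((n_pairs, n)) < 0.5
        b = rng.random((n_pairs, n)) < 0.5
        _, sig = induce_relation_many(a, b, alpha=0.05)
        rates = sig.mean(axis=1)
        assert (rates <= 0.07).all()


class TestPearsonComparator:
    def test_perfect_correlation_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        expr = pd.DataFrame([x, x], index=["a", "b"])
        edges = pearson_network(expr)
        assert len(edges) == 1
        assert edges["r"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_null_edge_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(46, 200)))
        expr.index = [f"g{i}" for i in range(46)]
        edges = pearson_network(expr, alpha=0.05)
        n_pairs = 46 * 45 / 2  # 1035 pairs
        assert 0.02 < len(edges) / n_pairs < 0.08

    def test_zero_variance_gene_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            [np.ones(50), rng.normal(size=50), rng.normal(size=50)],
            index=["flat", "a", "b"],
        )
        with pytest.warns(UserWarning):
            edges = pearson_network(expr)
        assert "flat" not in set(edges["gene_a"]) | set(edges["gene_b"])

    def test_detects_planted_pair_alongside_implication_network(self):
        rng = np.random.default_rng(7)
        state = rng.integers(0, 2, 300)
        expr = pd.DataFrame(
            [
                5 + 1.5 * state + rng.normal(0, 0.3, 300),
                6 + 1.5 * state + rng.normal(0, 0.3, 300),
                7 + rng.normal(0, 0.3, 300),
            ],
            index=["a", "b", "z"],
        )
        pears = pearson_network(expr)
        assert {"a", "b"} in [set(r) for r in pears[["gene_a", "gene_b"]].to_numpy()]
        net = build_network(dichotomize(expr, expr.mean(axis=1)))
        assert net.rule_for("a", "b") is not None


class TestPermutationOracle:
    def test_permutation_p_small_for_strong_equivalence(self):
        a = np.r_[np.ones(45), np.ones(5), np.zeros(5), np.zeros(45)]
        b = np.r_[np.ones(45), np.zeros(5), np.ones(5), np.zeros(45)]
        p = permutation_pvalue(a, b, "EQV", n_perm=2000, seed=1)
        assert p < 0.01

    def test_equivalence_rule_z_tracks_permutation_null_balanced_marginals(self):
        # with ~balanced marginals the Binomial(N, K) variance of the
        # equivalence error count matches the permutation variance, so the z
        # p-value is calibrated there (unbalanced tables drift; see docs)
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(12):
            n = 60
            a = (rng.random(n) < 0.5).astype(int)
            b = np.where(rng.random(n) < 0.7, a, (rng.random(n) < 0.5).astype(int))
            t = contingency(a, b)
            s = rule_statistics(t, "EQV")
            p_perm = permutation_pvalue(a, b, "EQV", n_perm=4000, seed=rng)
            diffs.append(abs(s.p_precision - p_perm))
        assert np.median(diffs) < 0.03
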