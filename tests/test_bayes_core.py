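import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuralsampling.bayes_core import (
    BayesNet,
    BayesNetError,
    Evidence,
    assignment_index,
    exact_posterior,
    factorize,
    index_assignment,
    joint_table,
    log_odds,
    log_odds_weights_mb,
    markov_blanket,
    posterior_marginals,
    read_bn,
    write_bn,
)
from conftest import all_states, enumeration_conditional, make_random_net


class TestStructure:
    def test_markov_blanket_examples(self, fig1):
        assert markov_blanket(fig1, "S") == {"Re", "Sh", "Co"}
        assert markov_blanket(fig1, "Co") == {"S"}
        assert markov_blanket(fig1, "Re") == {"S", "Sh"}

    def test_markov_blanket_matches_bruteforce_definition(self):
        net = make_random_net(5, 8)
        for node in net.nodes:
            expected = set(net.parents[node])
            for child in net.nodes:
                if node in net.parents[child]:
                    expected.add(child)
                    expected |= set(net.parents[child])
            expected.discard(node)
            assert markov_blanket(net, node) == expected

    def test_unknown_node_raises(self, fig1):
        with pytest.raises(KeyError):
            markov_blanket(fig1, "nope")

    def test_cyclic_graph_rejected(self):
        with pytest.raises(BayesNetError, match="cyclic"):
            BayesNet(["A", "B"], {"A": ["B"], "B": ["A"]},
                     {"A": [0.5, 0.5], "B": [0.5, 0.5]})

    def test_deterministic_cpt_rejected(self):
        with pytest.raises(BayesNetError, match="deterministic"):
            BayesNet(["A"], {}, {"A": [1.0]})

    def test_assignment_index_roundtrip(self):
        for m in (1, 2, 3, 5):
            for idx in range(2 ** m):
                assert assignment_index(index_assignment(idx, m)) == idx


class TestFactorize:
    def test_fig1_factor_scopes(self, fig1):
        fs = factorize(fig1)
        scopes = sorted(tuple(f.scope) for f in fs.factors)
        assert scopes == sorted(
            [("Re",), ("S",), ("Sh", "Re", "S"), ("Co", "S")]
        )

    def test_single_isolated_node_unary_prior(self):
        net = BayesNet(["A"], {}, {"A": [0.3]})
        fs = factorize(net)
        assert len(fs.factors) == 1
        assert np.allclose(fs.factors[0].table, [0.7, 0.3])

    @pytest.mark.parametrize("seed,n", [(0, 4), (1, 5), (2, 6)])
    def test_factor_product_equals_joint_and_normalizes(self, seed, n):
        net = make_random_net(seed, n)
        fs = factorize(net)
        total = 0.0
        for state in all_states(net):
            prod = fs.unnormalized(state)
            assert prod == pytest.approx(net.joint_prob(state), abs=1e-14)
            total += prod
        assert total == pytest.approx(1.0, abs=1e-10)


class TestExactPosterior:
    def test_prior_of_re_is_half(self, fig1):
        assert exact_posterior(fig1, Evidence({}), "Re") == pytest.approx(0.5)

    def test_explaining_away_frozen_values(self, fig1):
        # frozen from an independent 16-state hand enumeration
        assert exact_posterior(
            fig1, Evidence({"Sh": 1, "Co": 1}), "Re"
        ) == pytest.approx(0.255, abs=1e-12)
        assert exact_posterior(
            fig1, Evidence({"Sh": 1, "Co": 1}), "S"
        ) == pytest.approx(0.85, abs=1e-12)
        assert exact_posterior(
            fig1, Evidence({"Sh": 1, "Co": 0}), "Re"
        ) == pytest.approx(0.745, abs=1e-12)

    def test_query_on_evidence_node_returns_indicator(self, asia):
        assert exact_posterior(asia, Evidence({"X": 1}), "X") == 1.0
        assert exact_posterior(asia, Evidence({"X": 0}), "X") == 0.0

    def test_marginals_sum_rule(self, asia):
        ev = Evidence({"A": 1, "D": 1})
        for rv in asia.nodes:
            p1 = exact_posterior(asia, ev, rv)
            assert 0.0 <= p1 <= 1.0

    def test_invariant_under_renaming(self, fig1):
        mapping = {"Re": "n1", "S": "n2", "Sh": "n3", "Co": "n4"}
        renamed = BayesNet(
            [mapping[n] for n in fig1.nodes],
            {mapping[n]: [mapping[p] for p in fig1.parents[n]] for n in fig1.nodes},
            {mapping[n]: fig1.cpt[n] for n in fig1.nodes},
        )
        a = exact_posterior(fig1, Evidence({"Sh": 1, "Co": 1}), "Re")
        b = exact_posterior(renamed, Evidence({"n3": 1, "n4": 1}), "n1")
        assert a == pytest.approx(b, abs=1e-15)


class TestLogOdds:
    def test_symmetric_cpt_gives_zero(self):
        net = BayesNet(["A", "B"], {"B": ["A"]}, {"A": [0.5], "B": [0.5, 0.5]})
        assert log_odds(net, "B", {"A": 1}) == pytest.approx(0.0)

    @pytest.mark.parametrize("netname", ["fig1", "asia"])
    def test_log_odds_equals_full_joint_conditional(self, netname, request):
        net = request.getfixturevalue(netname)
        for state in all_states(net):
            for node in net.nodes:
                rest = {k: v for k, v in state.items() if k != node}
                p1 = enumeration_conditional(net, node, rest)
                lo = log_odds(net, node, rest)
                assert lo == pytest.approx(
                    math.log(p1 / (1 - p1)), abs=1e-12
                ), (node, rest)

    def test_weights_table_reproduces_log_odds(self, fig1):
        for node in fig1.nodes:
            mb = sorted(markov_blanket(fig1, node), key=fig1.index)
            table = log_odds_weights_mb(fig1, node)
            assert len(table) == 2 ** len(mb)
            for x, w in table.items():
                vals = index_assignment(x, len(mb))
                assert w == pytest.approx(
                    log_odds(fig1, node, dict(zip(mb, vals))), abs=1e-14
                )

    def test_incomplete_blanket_raises(self, fig1):
        with pytest.raises(BayesNetError, match="incomplete"):
            log_odds(fig1, "S", {"Re": 1})

    def test_markov_blanket_property(self):
        # conditioning on the blanket equals conditioning on everything
        net = make_random_net(11, 6)
        for state in all_states(net):
            for node in net.nodes:
                mb = markov_blanket(net, node)
                rest = {k: v for k, v in state.items() if k != node}
                blanket_only = {k: v for k, v in rest.items() if k in mb}
                assert log_odds(net, node, blanket_only) == pytest.approx(
                    log_odds(net, node, rest), abs=1e-12
                )


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 10 ** 6), n=st.integers(2, 6))
def test_joint_table_matches_pointwise_product(seed, n):
    net = make_random_net(seed, n)
    table = joint_table(net)
    assert table.sum() == pytest.approx(1.0, abs=1e-10)
    for state in all_states(net):
        idx = assignment_index([state[r] for r in net.nodes])
        assert table[idx] == pytest.approx(net.joint_prob(state), abs=1e-14)


class TestIO:
    def test_json_roundtrip_bit_exact(self, asia, tmp_path):
        p = tmp_path / "asia.json"
        write_bn(asia, p)
        again = read_bn(p)
        assert again == asia
        write_bn(again, tmp_path / "asia2.json")
        assert (tmp_path / "asia2.json").read_text() == p.read_text()

    def test_asia_structure(self, asia):
        assert asia.nodes == ("A", "S", "T", "C", "B", "X", "D")
        edges = {(p, c) for c in asia.nodes for p in asia.parents[c]}
        assert edges == {
            ("A", "T"), ("S", "C"), ("S", "B"),
            ("T", "X"), ("C", "X"),
            ("T", "D"), ("C", "D"), ("B", "D"),
        }

    def test_bif_roundtrip_same_joint(self, fig1, tmp_path):
        p = tmp_path / "fig1.bif"
        write_bn(fig1, p)
        again = read_bn(p)
        assert np.allclose(joint_table(again), joint_table(fig1), atol=1e-15)

    def test_malformed_json_names_problem(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"nodes": ["A"], "parents": {"A": []}, "cpt": {}}')
        with pytest.raises(BayesNetError):
            read_bn(p)

    def test_non_binary_bif_rejected(self, tmp_path):
        p = tmp_path / "tri.bif"
        p.write_text(
            "variable A {\n  type discrete [ 3 ] { 0, 1, 2 };\n}\n"
            "probability ( A ) {\n  table 0.3, 0.3, 0.4;\n}\n"
        )
        with pytest.raises(BayesNetError, match="binary"):
            read_bn(p)


def test_posterior_marginals_matches_exact_posterior(asia):
    ev = Evidence({"A": 1, "D": 1})
    pm = posterior_marginals(asia, ev)
    for rv in asia.nodes:
        assert pm[rv] == pytest.approx(exact_posterior(asia, ev, rv), abs=1e-13)
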