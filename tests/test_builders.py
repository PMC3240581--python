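import json
import math

import numpy as np
import pytest

from neuralsampling.bayes_core import BayesNet, BayesNetError, factorize, log_odds
from neuralsampling.builders import (
    BuilderParams,
    NetworkSpec,
    build,
    build_ideal,
    build_impl1,
    build_impl2,
    build_impl3,
    build_impl4,
    build_impl5,
)
from conftest import all_states, make_random_net

ALL_IMPLS = ["ideal", "2", "3", "4", "5"]


class TestCounts:
    def test_ideal_fig1_is_four_principals_no_aux(self, fig1):
        spec = build_ideal(fig1)
        assert len(spec.neurons_with_role("principal")) == 4
        assert len(spec.neurons_with_role("auxiliary")) == 0

    def test_impl1_fig1_units(self, fig1):
        spec = build_impl1(fig1)
        # 4 principals for the RVs plus 8 principals for the lifted
        # auxiliary RVs of the single three-way factor
        roles = [n for n in spec.neurons if n.role == "principal"]
        assert len(roles) == 12
        assert sum(1 for n in roles if n.rv is not None) == 4

    def test_impl2_counts_are_two_to_the_blanket(self, fig1, asia):
        for net, expected in [
            (fig1, {"Re": 4, "S": 8, "Sh": 4, "Co": 2}),
            (asia, {"A": 2, "S": 4, "T": 32, "C": 32, "B": 16, "X": 4, "D": 8}),
        ]:
            spec = build_impl2(net)
            assert {rv: spec.aux_count(rv) for rv in net.nodes} == expected

    def test_impl3_branches_match_impl2_aux(self, fig1, asia):
        for net in (fig1, asia):
            s2, s3 = build_impl2(net), build_impl3(net)
            for rv in net.nodes:
                assert s3.branch_count(rv) == s2.aux_count(rv)

    def test_impl5_fig1_group_sizes(self, fig1):
        spec = build_impl5(fig1)
        sizes = sorted(spec.branch_group_sizes("S").values())
        assert sizes == [2, 4]  # three-way factor and the contour factor
        assert sorted(spec.branch_group_sizes("Re").values()) == [4]

    def test_impl4_aux_counts_and_bound(self, fig1, asia):
        for net in (fig1, asia):
            s2, s4 = build_impl2(net), build_impl4(net)
            factors = factorize(net)
            for rv in net.nodes:
                expect = sum(
                    2 ** (f.order - 1)
                    for f in factors.factors_containing(rv)
                    if f.order > 1
                )
                assert s4.aux_count(rv) == expect
                assert s4.aux_count(rv) <= s2.aux_count(rv)

    def test_blanket_cap_suggests_factorized_constructions(self):
        net = make_random_net(21, 8)
        with pytest.raises(BayesNetError, match="impl4"):
            build_impl2(net, BuilderParams(mb_cap=1))


class TestNCCAudit:
    @pytest.mark.parametrize("impl", ALL_IMPLS)
    @pytest.mark.parametrize("netname", ["fig1", "asia"])
    def test_steady_state_potential_equals_log_odds(self, impl, netname, request):
        net = request.getfixturevalue(netname)
        spec = build(net, impl)
        factors = factorize(net)
        for state in all_states(net):
            for rv in net.nodes:
                u = spec.principal_potential(rv, state)
                assert u == pytest.approx(
                    log_odds(factors, rv, state), abs=1e-9
                ), (impl, rv, state)

    @pytest.mark.parametrize("impl", ALL_IMPLS)
    def test_audit_on_random_nets(self, impl):
        for seed in (31, 32):
            net = make_random_net(seed, 5)
            spec = build(net, impl)
            factors = factorize(net)
            for state in all_states(net):
                for rv in net.nodes:
                    assert spec.principal_potential(rv, state) == pytest.approx(
                        log_odds(factors, rv, state), abs=1e-9
                    )

    def test_single_node_prior_log_odds(self):
        net = BayesNet(["A"], {}, {"A": [0.3]})
        for impl in ALL_IMPLS:
            spec = build(net, impl)
            assert spec.principal_potential("A", {"A": 0}) == pytest.approx(
                math.log(0.3 / 0.7), abs=1e-12
            )

    def test_impl1_unit_potential_is_boltzmann(self, fig1):
        spec = build_impl1(fig1)
        bp = spec.meta["boltzmann"]
        state = {u: (1 if i % 3 == 0 else 0) for i, u in enumerate(bp.units)}
        y = np.array([state[u] for u in bp.units], dtype=float)
        for i, u in enumerate(bp.units):
            assert spec.unit_potential(u, state) == pytest.approx(
                float(bp.b[i] + bp.W[i] @ y)
            )


class TestStructure:
    def test_exactly_one_principal_per_rv(self, asia):
        for impl in ALL_IMPLS:
            spec = build(asia, impl)
            assert set(spec.principal_of) == set(asia.nodes)

    def test_impl2_wiring_sign_pattern(self, fig1):
        spec = build_impl2(fig1)
        for aux in spec.aux_of_node("Re"):
            inputs = dict(spec.meta["aux_inputs"][aux.id])
            mb = spec.meta["mb"]["Re"]
            from neuralsampling.bayes_core import index_assignment

            vals = dict(zip(mb, index_assignment(aux.assignment, len(mb))))
            for rv, w in inputs.items():
                assert (w > 0) == (vals[rv] == 1)

    def test_impl2_unique_matching_aux_above_threshold(self, fig1):
        # for every joint state, the most-driven auxiliary of each node is
        # the one whose assignment matches the blanket, by a clear margin
        spec = build_impl2(fig1)
        from neuralsampling.bayes_core import assignment_index

        for state in all_states(fig1):
            for rv in fig1.nodes:
                mb = spec.meta["mb"][rv]
                want = assignment_index([state[r] for r in mb])
                drives = {
                    a.assignment: spec._aux_drive(a, state)
                    for a in spec.aux_of_node(rv)
                }
                best = max(drives, key=drives.get)
                assert best == want
                for x, d in drives.items():
                    if x != want:
                        assert d < drives[want] - 5.0

    def test_branch_selectivity_conditions_hold(self, asia):
        for impl in ("3", "5"):
            spec = build(asia, impl)
            for br in spec.branches:
                exc = [w for _, w in br.synapses if w > 0]
                total = br.tonic + sum(exc)
                assert total >= br.theta - 1e-9
                for w in exc:
                    assert total - w < br.theta
                for w in [w for _, w in br.synapses if w < 0]:
                    assert total + w < br.theta
                assert br.beta >= 0.0

    def test_lateral_pools_cover_all_aux(self, asia):
        spec = build_impl2(asia)
        pooled = {m for p in spec.pools for m in p.members}
        assert pooled == {a.id for a in spec.neurons_with_role("auxiliary")}

    def test_explicit_interneurons_flag(self, fig1):
        spec = build_impl2(fig1, BuilderParams(explicit_interneurons=True))
        assert len(spec.neurons_with_role("interneuron")) > 0

    def test_unknown_impl_rejected(self, fig1):
        with pytest.raises(BayesNetError, match="unknown implementation"):
            build(fig1, "7")


class TestSerialization:
    @pytest.mark.parametrize("impl", ["ideal", "1", "2", "3", "4", "5"])
    def test_json_roundtrip_preserves_potentials(self, fig1, impl, tmp_path):
        spec = build(fig1, impl)
        path = tmp_path / f"{impl}.json"
        spec.to_json(path)
        again = NetworkSpec.from_json(path)
        assert again.impl == spec.impl
        assert len(again.neurons) == len(spec.neurons)
        state = dict(zip(fig1.nodes, (1, 0, 1, 1)))
        if impl == "1":
            bp = spec.meta["boltzmann"]
            full = {u: (1 if i % 2 else 0) for i, u in enumerate(bp.units)}
            assert again.unit_potential("Re", full) == pytest.approx(
                spec.unit_potential("Re", full)
            )
        else:
            for rv in fig1.nodes:
                assert again.principal_potential(rv, state) == pytest.approx(
                    spec.principal_potential(rv, state), abs=1e-12
                )

    def test_roundtrip_is_stable_json(self, fig1, tmp_path):
        spec = build(fig1, "2")
        d1 = spec.to_dict()
        d2 = NetworkSpec.from_dict(json.loads(json.dumps(d1))).to_dict()
        assert json.dumps(d1, sort_keys=True) == json.dumps(d2, sort_keys=True)
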