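"""Compile a Bayesian network into spiking-network blueprints.

Six constructions are provided, all guaranteeing — by construction, and
audited exhaustively in the tests — that the steady-state potential
delivered to each principal neuron equals the conditional log-odds of its
RV given the current state of the rest of the network (the neural
computability condition, NCC):

``ideal``
    Principal neurons only; the potential is the blanket log-odds table
    itself.  This is the ideal version of constructions 2–5 (rectangular
    PSPs, no delays) and is what the engine simulates in ideal mode.
``impl1``
    The lifted pairwise Boltzmann network: one principal neuron per
    original RV and per auxiliary RV, with ±M couplings standing in for the
    hard constraints.  Its principals satisfy the NCC in the *expanded*
    distribution.
``impl2``
    Markov-blanket expansion with auxiliary point neurons: per node one
    auxiliary neuron per blanket assignment x, direct excitatory input
    (weight w_exc) from blanket principals that are 1 in x, inhibition
    (modeled as negative weight, standing for an interneuron) from those
    that are 0, bias w_x − N1(x)·w_exc, lateral inhibition pool enforcing
    at most one auxiliary spike per τ, and a strong drive onto the
    principal.
``impl3``
    Markov-blanket expansion on dendrites: one multi-compartment principal
    per node with a branch per blanket assignment (strength w_x + C, soma
    rest −C), same input wiring as impl2 but onto branches.
``impl4`` / ``impl5``
    Factorized expansion: per factor J containing the node, one auxiliary
    neuron (impl4: synapse efficacy w_{x,J} + γ onto a dedicated branch,
    with a shunting interneuron per branch) or one dendritic branch
    (impl5: amplitude w_{x,J} + γ) per assignment x to the factor's other
    RVs; soma bias −K·γ with K the number of factors containing the node.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .bayes_core import (
    BayesNet,
    BayesNetError,
    FactorSet,
    assignment_index,
    index_assignment,
    factorize,
    factor_log_odds_weights,
    log_odds_weights_mb,
    markov_blanket,
)
from . import expansion as _exp

__all__ = [
    "BuilderParams",
    "NeuronSpec",
    "BranchSpec",
    "ConnectionSpec",
    "PoolSpec",
    "NetworkSpec",
    "build_ideal",
    "build_impl1",
    "build_impl2",
    "build_impl3",
    "build_impl4",
    "build_impl5",
    "build",
]


@dataclass
class BuilderParams:
    """Tunables shared by the constructions.

    ``w_exc_margin``: the strong excitatory weight onto an auxiliary neuron
    is w_exc = margin + max_x |w_x| per node — an additive selectivity
    margin rather than a multiplicative rule, so that with non-rectangular
    PSPs the margin (which multiplies kernel fluctuations) stays bounded.
    ``mb_cap``: refuse blankets larger than this (resource blow-up);
    ``explicit_interneurons``: instantiate inhibitory interneuron units
    instead of representing them as sign-flipped direct connections.
    """

    mb_cap: int = 12
    w_exc_margin: float = 10.0
    branch_theta: float = 1.0
    drive_weight: float = 100.0
    principal_rest_bias: float = -50.0
    explicit_interneurons: bool = False
    coupling_M: float | None = None  # impl1; None -> the 10x rule


@dataclass
class NeuronSpec:
    id: str
    role: str  # principal | auxiliary | interneuron | lateral-pool
    model: str = "point"  # point | multi
    bias: float = 0.0
    rv: str | None = None  # for principals
    node: str | None = None  # owning node for auxiliaries / pools
    group: str | None = None  # factor key (impl4/5) or "mb"
    assignment: int | None = None


@dataclass
class BranchSpec:
    owner: str  # principal neuron id
    group: str
    assignment: int
    synapses: list  # [(pre_id, weight)]
    theta: float
    beta: float
    tonic: float = 0.0


@dataclass
class ConnectionSpec:
    pre: str
    post: str
    weight: float
    delay: float = 0.0
    target: str = "soma"  # soma | branch:<index>


@dataclass
class PoolSpec:
    """Lateral-inhibition pool: at most one member spike per τ."""

    node: str
    members: list
    inhibitor: str | None = None


class NetworkSpec:
    """A compiled spiking network plus the bookkeeping the engine needs."""

    def __init__(
        self,
        impl: str,
        net: BayesNet,
        params: BuilderParams,
        neurons: list[NeuronSpec],
        connections: list[ConnectionSpec],
        branches: list[BranchSpec],
        pools: list[PoolSpec],
        meta: dict,
    ):
        self.impl = impl
        self.net = net
        self.params = params
        self.neurons = neurons
        self.connections = connections
        self.branches = branches
        self.pools = pools
        self.meta = meta
        self._by_id = {n.id: n for n in neurons}
        self.principal_of = {n.rv: n.id for n in neurons if n.role == "principal" and n.rv}

    # -- lookups -----------------------------------------------------------

    def neuron(self, nid: str) -> NeuronSpec:
        return self._by_id[nid]

    def neurons_with_role(self, role: str) -> list[NeuronSpec]:
        return [n for n in self.neurons if n.role == role]

    def aux_of_node(self, node: str) -> list[NeuronSpec]:
        return [n for n in self.neurons if n.role == "auxiliary" and n.node == node]

    def branches_of(self, rv: str) -> list[BranchSpec]:
        pid = self.principal_of[rv]
        return [b for b in self.branches if b.owner == pid]

    def aux_count(self, node: str) -> int:
        return len(self.aux_of_node(node))

    def branch_count(self, rv: str) -> int:
        return len(self.branches_of(rv))

    def branch_group_sizes(self, rv: str) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for b in self.branches_of(rv):
            sizes[b.group] = sizes.get(b.group, 0) + 1
        return sizes

    def aux_group_sizes(self, node: str) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for a in self.aux_of_node(node):
            sizes[a.group] = sizes.get(a.group, 0) + 1
        return sizes

    # -- steady-state NCC surface -----------------------------------------

    def principal_potential(self, rv: str, state: Mapping[str, int]) -> float:
        """Deterministic steady-state potential at the principal of ``rv``.

        Reconstructed from the stored structure (biases, synaptic weights,
        branch strengths) under the steady-state reading of the dynamics:
        every principal whose RV is 1 emits an uninterrupted rectangular
        PSP, shunting has removed stale EPSPs, and for point-neuron
        constructions the firing probability of the principal is that of
        its most-driven auxiliary.
        """
        if self.impl == "ideal":
            u = self.meta["lr_const"][rv]
            for rest, table in self.meta["factor_lr"][rv]:
                u += table[assignment_index([state[r] for r in rest])]
            return float(u)
        if self.impl == "impl1":
            raise BayesNetError(
                "impl1 principals satisfy the NCC in the expanded distribution; "
                "use unit_potential on the full (z, x) state"
            )
        if self.impl == "impl2":
            return max(
                self._aux_drive(a, state) for a in self.aux_of_node(rv)
            )
        if self.impl == "impl3":
            pid = self.principal_of[rv]
            u = self.neuron(pid).bias
            for br in self.branches_of(rv):
                if self._branch_activation(br, state) >= br.theta - _THETA_TOL:
                    u += br.beta
            return float(u)
        if self.impl == "impl4":
            pid = self.principal_of[rv]
            u = self.neuron(pid).bias
            for group, aux_list in self._groups(rv).items():
                best = max(aux_list, key=lambda a: self._aux_drive(a, state))
                u += self.meta["aux_syn"][best.id]
            return float(u)
        if self.impl == "impl5":
            pid = self.principal_of[rv]
            u = self.neuron(pid).bias
            for br in self.branches_of(rv):
                if self._branch_activation(br, state) >= br.theta - _THETA_TOL:
                    u += br.beta
            return float(u)
        raise BayesNetError(f"unknown implementation {self.impl!r}")

    def _groups(self, node: str) -> dict[str, list[NeuronSpec]]:
        groups: dict[str, list[NeuronSpec]] = {}
        for a in self.aux_of_node(node):
            groups.setdefault(a.group, []).append(a)
        return groups

    def _aux_drive(self, aux: NeuronSpec, state: Mapping[str, int]) -> float:
        u = aux.bias
        for c in self.meta["aux_inputs"][aux.id]:
            pre_rv, w = c
            u += w * state[pre_rv]
        return u

    def unit_potential(self, unit: str, full_state: Mapping[str, int]) -> float:
        """impl1: Boltzmann potential b_k + Σ W_kj y_j over (z, x)."""
        if self.impl != "impl1":
            raise BayesNetError("unit_potential is only defined for impl1")
        bp: _exp.BoltzmannParams = self.meta["boltzmann"]
        i = bp.units.index(unit)
        y = np.array([full_state[u] for u in bp.units], dtype=float)
        return float(bp.b[i] + bp.W[i] @ y)

    def potential_mb_table(self, rv: str) -> tuple[tuple[str, ...], np.ndarray]:
        """(blanket order, table over blanket assignments) of the structural
        steady-state potential — the engine's ideal-mode lookup."""
        mb = self.meta["mb"][rv]
        table = np.empty(2 ** len(mb))
        base = {r: 0 for r in self.net.nodes}
        for x in range(2 ** len(mb)):
            st = dict(base)
            st.update(zip(mb, index_assignment(x, len(mb))))
            table[x] = self.principal_potential(rv, st)
        return mb, table

    def _branch_activation(self, br: BranchSpec, state: Mapping[str, int]) -> float:
        a = br.tonic
        for pre_id, w in br.synapses:
            pre = self.neuron(pre_id)
            a += w * state[pre.rv]
        return a

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        from .bayes_core import _net_to_dict

        return {
            "impl": self.impl,
            "net": _net_to_dict(self.net),
            "params": asdict(self.params),
            "neurons": [asdict(n) for n in self.neurons],
            "connections": [asdict(c) for c in self.connections],
            "branches": [asdict(b) for b in self.branches],
            "pools": [asdict(p) for p in self.pools],
            "meta": _meta_to_jsonable(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        from .bayes_core import _net_from_dict

        net = _net_from_dict(d["net"])
        params = BuilderParams(**d["params"])
        spec = cls(
            d["impl"],
            net,
            params,
            [NeuronSpec(**n) for n in d["neurons"]],
            [ConnectionSpec(**c) for c in d["connections"]],
            [BranchSpec(**b) for b in d["branches"]],
            [PoolSpec(**p) for p in d["pools"]],
            _meta_from_jsonable(d["meta"], net, params),
        )
        return spec

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _meta_to_jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if k == "boltzmann":
            bp = v
            out[k] = {
                "units": list(bp.units),
                "W": bp.W.tolist(),
                "b": bp.b.tolist(),
                "M": bp.M,
                "n_principal": bp.n_principal,
            }
        elif k in ("w_mb",):
            out[k] = {rv: t.tolist() for rv, t in v.items()}
        elif k == "factor_lr":
            out[k] = {
                rv: [[list(rest), t.tolist()] for rest, t in lst]
                for rv, lst in v.items()
            }
        elif k == "mb":
            out[k] = {rv: list(t) for rv, t in v.items()}
        elif k == "aux_inputs":
            out[k] = {a: [[rv, w] for rv, w in lst] for a, lst in v.items()}
        else:
            out[k] = v
    return out


def _meta_from_jsonable(d: dict, net: BayesNet, params: BuilderParams) -> dict:
    meta: dict = {}
    for k, v in d.items():
        if k == "boltzmann":
            meta[k] = _exp.BoltzmannParams(
                units=tuple(v["units"]),
                W=np.asarray(v["W"]),
                b=np.asarray(v["b"]),
                M=v["M"],
                n_principal=v["n_principal"],
            )
        elif k == "w_mb":
            meta[k] = {rv: np.asarray(t) for rv, t in v.items()}
        elif k == "factor_lr":
            meta[k] = {
                rv: [(tuple(rest), np.asarray(t)) for rest, t in lst]
                for rv, lst in v.items()
            }
        elif k == "mb":
            meta[k] = {rv: tuple(t) for rv, t in v.items()}
        elif k == "aux_inputs":
            meta[k] = {a: [(rv, w) for rv, w in lst] for a, lst in v.items()}
        else:
            meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _blankets(net: BayesNet, cap: int) -> dict[str, tuple[str, ...]]:
    out = {}
    for n in net.nodes:
        mb = tuple(sorted(markov_blanket(net, n), key=net.index))
        if len(mb) > cap:
            raise BayesNetError(
                f"Markov blanket of {n!r} has {len(mb)} RVs (cap {cap}); "
                "consider the factorized constructions (impl4/impl5)"
            )
        out[n] = mb
    return out


def _w_mb_tables(net: BayesNet) -> dict[str, np.ndarray]:
    out = {}
    for n in net.nodes:
        w = log_odds_weights_mb(net, n)
        out[n] = np.array([w[x] for x in range(len(w))])
    return out


def _w_exc(params: BuilderParams, w_table: np.ndarray) -> float:
    """Strong excitatory weight onto auxiliary neurons.

    Must exceed the spread of the log-odds coefficients so that one missing
    or wrong input outweighs any coefficient difference between auxiliary
    neurons; the additive margin is what suppresses mismatched auxiliaries.
    """
    return params.w_exc_margin + float(w_table.max() - w_table.min())


#: absolute slack for branch-threshold comparisons (θ/n weights re-summed)
_THETA_TOL = 1e-9


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_ideal(net: BayesNet, params: BuilderParams | None = None) -> NetworkSpec:
    """Principal-only sampler whose potential is the conditional log-odds.

    The log-odds is held as its factorized expansion (one log-ratio table
    per factor containing the node, plus the constant from unary factors),
    which stays tractable for arbitrarily large Markov blankets.  No
    blanket-size cap applies: this builder allocates no per-assignment
    resources.
    """
    params = params or BuilderParams()
    mb = {
        n: tuple(sorted(markov_blanket(net, n), key=net.index)) for n in net.nodes
    }
    _, groups, const = _factor_groups(net)
    factor_lr = {
        rv: [(rest, table) for _, rest, table in groups[rv]] for rv in net.nodes
    }
    neurons = [
        NeuronSpec(id=f"nu[{rv}]", role="principal", rv=rv) for rv in net.nodes
    ]
    meta = {"mb": mb, "factor_lr": factor_lr, "lr_const": const}
    return NetworkSpec("ideal", net, params, neurons, [], [], [], meta)


def build_impl1(net: BayesNet, params: BuilderParams | None = None) -> NetworkSpec:
    """Lifted-Boltzmann network (principal neurons for z and for every
    auxiliary RV; inhibitory paths as negative direct weights)."""
    params = params or BuilderParams()
    exp = _exp.expand(factorize(net))
    bp = _exp.boltzmann_params(exp, M=params.coupling_M)
    neurons = []
    for i, unit in enumerate(bp.units):
        is_z = i < bp.n_principal
        neurons.append(
            NeuronSpec(
                id=f"nu[{unit}]",
                role="principal",
                rv=unit if is_z else None,
                node=None if is_z else unit,
                bias=float(bp.b[i]),
            )
        )
    connections = []
    n = len(bp.units)
    for i in range(n):
        for j in range(i + 1, n):
            if bp.W[i, j] != 0.0:
                w = float(bp.W[i, j])
                connections.append(
                    ConnectionSpec(f"nu[{bp.units[i]}]", f"nu[{bp.units[j]}]", w)
                )
                connections.append(
                    ConnectionSpec(f"nu[{bp.units[j]}]", f"nu[{bp.units[i]}]", w)
                )
    meta = {"boltzmann": bp, "expanded_rvs": list(exp.all_rvs)}
    return NetworkSpec("impl1", net, params, neurons, connections, [], [], meta)


def _mb_wiring(
    mb: tuple[str, ...], x: int
) -> list[tuple[str, int]]:
    """[(blanket rv, required value)] for assignment index x."""
    vals = index_assignment(x, len(mb))
    return list(zip(mb, vals))


def build_impl2(net: BayesNet, params: BuilderParams | None = None) -> NetworkSpec:
    """Markov-blanket expansion with auxiliary point neurons."""
    params = params or BuilderParams()
    mb = _blankets(net, params.mb_cap)
    w_mb = _w_mb_tables(net)
    neurons, connections, pools = [], [], []
    aux_inputs: dict[str, list[tuple[str, float]]] = {}
    w_exc_by_node = {}
    for rv in net.nodes:
        neurons.append(NeuronSpec(id=f"nu[{rv}]", role="principal", rv=rv,
                                  bias=params.principal_rest_bias))
    for rv in net.nodes:
        blanket = mb[rv]
        w = w_mb[rv]
        w_exc = _w_exc(params, w)
        w_exc_by_node[rv] = w_exc
        members = []
        for x in range(2 ** len(blanket)):
            n1 = sum(index_assignment(x, len(blanket)))
            aid = f"alpha[{rv}]{x:0{max(len(blanket), 1)}b}" if blanket else f"alpha[{rv}]"
            bias = float(w[x]) - n1 * w_exc
            neurons.append(
                NeuronSpec(id=aid, role="auxiliary", node=rv, group="mb",
                           assignment=x, bias=bias)
            )
            inputs = []
            for b_rv, req in _mb_wiring(blanket, x):
                weight = w_exc if req == 1 else -w_exc
                if req == 0 and params.explicit_interneurons:
                    iid = f"I[{aid}|{b_rv}]"
                    neurons.append(NeuronSpec(id=iid, role="interneuron", node=rv))
                    connections.append(ConnectionSpec(f"nu[{b_rv}]", iid, w_exc))
                    connections.append(ConnectionSpec(iid, aid, -w_exc))
                else:
                    connections.append(ConnectionSpec(f"nu[{b_rv}]", aid, weight))
                inputs.append((b_rv, weight))
            connections.append(ConnectionSpec(aid, f"nu[{rv}]", params.drive_weight))
            aux_inputs[aid] = inputs
            members.append(aid)
        lid = f"L[{rv}]"
        neurons.append(NeuronSpec(id=lid, role="lateral-pool", node=rv))
        for m in members:
            connections.append(ConnectionSpec(m, lid, params.drive_weight))
            connections.append(ConnectionSpec(lid, m, -params.drive_weight))
        pools.append(PoolSpec(node=rv, members=members, inhibitor=lid))
    meta = {
        "mb": mb,
        "w_mb": w_mb,
        "aux_inputs": aux_inputs,
        "w_exc": w_exc_by_node,
    }
    return NetworkSpec("impl2", net, params, neurons, connections, [], pools, meta)


def build_impl3(net: BayesNet, params: BuilderParams | None = None) -> NetworkSpec:
    """Markov-blanket expansion on dendritic branches."""
    params = params or BuilderParams()
    mb = _blankets(net, params.mb_cap)
    w_mb = _w_mb_tables(net)
    theta = params.branch_theta
    neurons, branches = [], []
    connections: list[ConnectionSpec] = []
    shifts = {}
    for rv in net.nodes:
        blanket = mb[rv]
        w = w_mb[rv]
        C = 1.0 + float(np.abs(w).max())
        shifts[rv] = C
        pid = f"nu[{rv}]"
        neurons.append(
            NeuronSpec(id=pid, role="principal", rv=rv, model="multi", bias=-C)
        )
        for x in range(2 ** len(blanket)):
            wiring = _mb_wiring(blanket, x)
            n_direct = sum(1 for _, req in wiring if req == 1)
            syn = []
            for b_rv, req in wiring:
                weight = theta / n_direct if req == 1 else -theta
                syn.append((f"nu[{b_rv}]", weight))
                connections.append(
                    ConnectionSpec(f"nu[{b_rv}]", pid, weight,
                                   target=f"branch:{len(branches)}")
                )
            branches.append(
                BranchSpec(
                    owner=pid, group="mb", assignment=x, synapses=syn,
                    theta=theta, beta=float(w[x]) + C,
                    tonic=theta if n_direct == 0 else 0.0,
                )
            )
    meta = {"mb": mb, "w_mb": w_mb, "shift_C": shifts}
    return NetworkSpec("impl3", net, params, neurons, connections, branches, [], meta)


def _factor_groups(net: BayesNet) -> tuple[FactorSet, dict[str, list], dict[str, float]]:
    """Per node: [(group key, rest scope, w table over rest assignments)].

    A factor whose scope is the node alone contributes a *constant* to the
    node's log-odds; those constants are returned separately (folded into
    the soma bias) instead of spending an auxiliary group on them.
    """
    factors = factorize(net)
    groups: dict[str, list] = {n: [] for n in net.nodes}
    const: dict[str, float] = {n: 0.0 for n in net.nodes}
    for fi, f in enumerate(factors.factors):
        for rv in f.scope:
            rest = tuple(r for r in f.scope if r != rv)
            all_w = factor_log_odds_weights(factors, rv)
            if not rest:
                const[rv] += all_w[((), 0)]
                continue
            table = np.empty(2 ** len(rest))
            for x in range(2 ** len(rest)):
                table[x] = all_w[(rest, x)]
            groups[rv].append((f"f{fi}[{','.join(f.scope)}]", rest, table))
    return factors, groups, const


def build_impl4(net: BayesNet, params: BuilderParams | None = None) -> NetworkSpec:
    """Factorized expansion with auxiliary neurons and dedicated branches."""
    params = params or BuilderParams()
    mb = _blankets(net, params.mb_cap)
    w_mb = _w_mb_tables(net)
    _, groups, const = _factor_groups(net)
    gamma = 1.0 + max(
        (float(np.abs(t).max()) for lst in groups.values() for _, _, t in lst),
        default=0.0,
    )
    neurons, connections, branches, pools = [], [], [], []
    aux_inputs: dict[str, list[tuple[str, float]]] = {}
    aux_syn: dict[str, float] = {}
    for rv in net.nodes:
        K_k = len(groups[rv])
        pid = f"nu[{rv}]"
        neurons.append(
            NeuronSpec(id=pid, role="principal", rv=rv, model="multi",
                       bias=-K_k * gamma + const[rv])
        )
    for rv in net.nodes:
        pid = f"nu[{rv}]"
        for gkey, rest, table in groups[rv]:
            w_exc = params.w_exc_margin + float(np.abs(table).max())
            members = []
            for x in range(2 ** len(rest)):
                aid = f"alpha[{rv}|{gkey}]{x:0{max(len(rest), 1)}b}" if rest else f"alpha[{rv}|{gkey}]"
                n1 = sum(index_assignment(x, len(rest)))
                neurons.append(
                    NeuronSpec(id=aid, role="auxiliary", node=rv, group=gkey,
                               assignment=x, bias=-n1 * w_exc)
                )
                inputs = []
                for b_rv, req in zip(rest, index_assignment(x, len(rest))):
                    weight = w_exc if req == 1 else -w_exc
                    connections.append(ConnectionSpec(f"nu[{b_rv}]", aid, weight))
                    inputs.append((b_rv, weight))
                aux_inputs[aid] = inputs
                eff = float(table[x]) + gamma
                aux_syn[aid] = eff
                bidx = len(branches)
                branches.append(
                    BranchSpec(owner=pid, group=gkey, assignment=x,
                               synapses=[(aid, eff)], theta=params.branch_theta,
                               beta=eff)
                )
                connections.append(
                    ConnectionSpec(aid, pid, eff, target=f"branch:{bidx}")
                )
                # shunting interneuron: wired from all other auxiliaries of
                # the group, clears the stale EPSP on this branch
                iid = f"I[{aid}]"
                neurons.append(NeuronSpec(id=iid, role="interneuron", node=rv,
                                          group=gkey))
                connections.append(ConnectionSpec(iid, pid, -eff,
                                                  target=f"branch:{bidx}"))
                members.append(aid)
            for aid in members:
                for other in members:
                    if other != aid:
                        connections.append(
                            ConnectionSpec(other, f"I[{aid}]", params.drive_weight)
                        )
            pools.append(PoolSpec(node=rv, members=members, inhibitor=None))
    meta = {
        "mb": mb,
        "w_mb": w_mb,
        "gamma": gamma,
        "aux_inputs": aux_inputs,
        "aux_syn": aux_syn,
    }
    return NetworkSpec("impl4", net, params, neurons, connections, branches,
                       pools, meta)


def build_impl5(net: BayesNet, params: BuilderParams | None = None) -> NetworkSpec:
    """Factorized expansion with groups of dendritic branches."""
    params = params or BuilderParams()
    mb = _blankets(net, params.mb_cap)
    w_mb = _w_mb_tables(net)
    _, groups, const = _factor_groups(net)
    gamma = 1.0 + max(
        (float(np.abs(t).max()) for lst in groups.values() for _, _, t in lst),
        default=0.0,
    )
    theta = params.branch_theta
    neurons, connections, branches = [], [], []
    for rv in net.nodes:
        K_k = len(groups[rv])
        pid = f"nu[{rv}]"
        neurons.append(
            NeuronSpec(id=pid, role="principal", rv=rv, model="multi",
                       bias=-K_k * gamma + const[rv])
        )
    for rv in net.nodes:
        pid = f"nu[{rv}]"
        for gkey, rest, table in groups[rv]:
            for x in range(2 ** len(rest)):
                wiring = list(zip(rest, index_assignment(x, len(rest))))
                n_direct = sum(1 for _, req in wiring if req == 1)
                syn = []
                for b_rv, req in wiring:
                    weight = theta / n_direct if req == 1 else -theta
                    syn.append((f"nu[{b_rv}]", weight))
                    connections.append(
                        ConnectionSpec(f"nu[{b_rv}]", pid, weight,
                                       target=f"branch:{len(branches)}")
                    )
                branches.append(
                    BranchSpec(owner=pid, group=gkey, assignment=x,
                               synapses=syn, theta=theta,
                               beta=float(table[x]) + gamma,
                               tonic=theta if n_direct == 0 else 0.0)
                )
    meta = {"mb": mb, "w_mb": w_mb, "gamma": gamma}
    return NetworkSpec("impl5", net, params, neurons, connections, branches,
                       [], meta)


_BUILDERS = {
    "ideal": build_ideal,
    "1": build_impl1,
    "2": build_impl2,
    "3": build_impl3,
    "4": build_impl4,
    "5": build_impl5,
    "impl1": build_impl1,
    "impl2": build_impl2,
    "impl3": build_impl3,
    "impl4": build_impl4,
    "impl5": build_impl5,
}


def build(net: BayesNet, impl: str, params: BuilderParams | None = None) -> NetworkSpec:
    """Dispatch on implementation name: ideal, 1–5."""
    try:
        builder = _BUILDERS[str(impl)]
    except KeyError:
        raise BayesNetError(
            f"unknown implementation {impl!r}; choose ideal or 1-5"
        ) from None
    return builder(net, params)
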