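"""Bayesian networks over binary random variables and exact inference by enumeration.

This module provides the probabilistic backbone for the spiking-network
samplers: a :class:`BayesNet` container for directed graphical models over
binary RVs, its factor-graph view (:class:`FactorSet`), Markov blankets,
exact posteriors by brute-force enumeration (feasible for the network sizes
considered here, K <= ~22), and the conditional log-odds

    log [ P(z_k = 1 | rest) / P(z_k = 0 | rest) ]

that every neural construction must deliver to the membrane potential of the
principal neuron representing ``z_k`` (the neural computability condition).

Assignment indexing convention
------------------------------
An assignment ``(v_1, ..., v_m)`` to an ordered list of RVs is mapped to the
integer ``sum_j v_j * 2**(m-1-j)``, i.e. lexicographic order with the first
RV as the most significant bit.  Every probability table in this package
(CPTs, factor tables, blanket log-odds tables) is indexed this way.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "CPT_EPS",
    "BayesNet",
    "Factor",
    "FactorSet",
    "Evidence",
    "BayesNetError",
    "assignment_index",
    "index_assignment",
    "markov_blanket",
    "factorize",
    "joint_table",
    "exact_posterior",
    "posterior_marginals",
    "log_odds",
    "log_odds_weights_mb",
    "factor_log_odds_weights",
    "read_bn",
    "write_bn",
]

#: CPT entries are validated to lie in [CPT_EPS, 1 - CPT_EPS].  Strictly
#: non-deterministic links keep every log-odds finite and make the sampling
#: Markov chain irreducible (the ASIA network is used in a modified form for
#: exactly this reason).
CPT_EPS = 1e-6


class BayesNetError(ValueError):
    """Raised for malformed networks, tables or evidence."""


def assignment_index(values: Sequence[int]) -> int:
    """Map a 0/1 assignment tuple to its table index (first RV = MSB)."""
    idx = 0
    for v in values:
        idx = (idx << 1) | int(v)
    return idx


def index_assignment(idx: int, m: int) -> tuple[int, ...]:
    """Inverse of :func:`assignment_index` for ``m`` variables."""
    return tuple((idx >> (m - 1 - j)) & 1 for j in range(m))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Evidence:
    """A partial assignment of observed values to a subset of RVs."""

    assignments: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "assignments", dict(self.assignments))
        for rv, v in self.assignments.items():
            if v not in (0, 1):
                raise BayesNetError(f"evidence value for {rv!r} must be 0 or 1, got {v!r}")

    def validate(self, net: "BayesNet") -> None:
        unknown = set(self.assignments) - set(net.nodes)
        if unknown:
            raise BayesNetError(f"evidence refers to unknown RVs: {sorted(unknown)}")

    def __getitem__(self, rv: str) -> int:
        return self.assignments[rv]

    def __contains__(self, rv: str) -> bool:
        return rv in self.assignments

    def items(self):
        return self.assignments.items()

    def __len__(self) -> int:
        return len(self.assignments)


class BayesNet:
    """A Bayesian network over binary RVs.

    Parameters
    ----------
    nodes:
        Ordered RV names; the order fixes bit positions in joint-state
        enumeration.
    parents:
        Map node -> ordered tuple of parent names.
    cpt:
        Map node -> array of ``P(node = 1 | parent assignment)`` with
        ``2**len(parents)`` entries, indexed by :func:`assignment_index`
        over the parent tuple.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        parents: Mapping[str, Sequence[str]],
        cpt: Mapping[str, Sequence[float]],
    ):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise BayesNetError("duplicate node names")
        self.parents: dict[str, tuple[str, ...]] = {
            n: tuple(parents.get(n, ())) for n in self.nodes
        }
        self.cpt: dict[str, np.ndarray] = {}
        for n in self.nodes:
            for p in self.parents[n]:
                if p not in set(self.nodes):
                    raise BayesNetError(f"node {n!r} has unknown parent {p!r}")
            table = np.asarray(cpt.get(n), dtype=float)
            want = 2 ** len(self.parents[n])
            if table is None or table.ndim != 1 or table.size != want:
                raise BayesNetError(
                    f"CPT for node {n!r} must have {want} entries "
                    f"(one per parent assignment)"
                )
            if np.any(table < CPT_EPS) or np.any(table > 1.0 - CPT_EPS):
                raise BayesNetError(
                    f"CPT for node {n!r} has entries outside "
                    f"[{CPT_EPS}, {1 - CPT_EPS}]; deterministic links are not allowed"
                )
            self.cpt[n] = table
        extra = set(cpt) - set(self.nodes)
        if extra:
            raise BayesNetError(f"CPT given for unknown nodes: {sorted(extra)}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise BayesNetError(f"parent structure is cyclic: {cycle}")

    # -- structure ---------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for n, ps in self.parents.items():
            g.add_edges_from((p, n) for p in ps)
        return g

    def children(self, node: str) -> tuple[str, ...]:
        self._check(node)
        return tuple(n for n in self.nodes if node in self.parents[n])

    def index(self, node: str) -> int:
        self._check(node)
        return self.nodes.index(node)

    def _check(self, node: str) -> None:
        if node not in self.parents:
            raise KeyError(f"unknown node {node!r}")

    @property
    def K(self) -> int:
        return len(self.nodes)

    # -- probabilities -----------------------------------------------------

    def node_prob(self, node: str, value: int, state: Mapping[str, int]) -> float:
        """``P(node = value | parent values taken from state)``."""
        idx = assignment_index([state[p] for p in self.parents[node]])
        p1 = float(self.cpt[node][idx])
        return p1 if value == 1 else 1.0 - p1

    def joint_prob(self, state: Mapping[str, int]) -> float:
        return math.prod(self.node_prob(n, state[n], state) for n in self.nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BayesNet):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.parents == other.parents
            and all(np.array_equal(self.cpt[n], other.cpt[n]) for n in self.nodes)
        )

    def __repr__(self) -> str:
        ne = sum(len(p) for p in self.parents.values())
        return f"BayesNet(K={self.K}, edges={ne})"


@dataclass(frozen=True)
class Factor:
    """A nonnegative factor over an ordered subset of RVs."""

    scope: tuple[str, ...]
    table: np.ndarray  # shape (2**len(scope),)

    def __post_init__(self):
        object.__setattr__(self, "scope", tuple(self.scope))
        t = np.asarray(self.table, dtype=float)
        if t.shape != (2 ** len(self.scope),):
            raise BayesNetError(
                f"factor over {self.scope} needs {2 ** len(self.scope)} values"
            )
        object.__setattr__(self, "table", t)

    @property
    def order(self) -> int:
        return len(self.scope)

    def value(self, state: Mapping[str, int]) -> float:
        return float(self.table[assignment_index([state[r] for r in self.scope])])


@dataclass
class FactorSet:
    """A factorized distribution p(z) ∝ ∏_I f_I(z_I) over binary RVs."""

    rvs: tuple[str, ...]
    factors: list[Factor] = field(default_factory=list)

    def __post_init__(self):
        self.rvs = tuple(self.rvs)
        covered: set[str] = set()
        for f in self.factors:
            unknown = set(f.scope) - set(self.rvs)
            if unknown:
                raise BayesNetError(f"factor scope has unknown RVs {sorted(unknown)}")
            covered |= set(f.scope)
        missing = set(self.rvs) - covered
        if missing:
            raise BayesNetError(f"RVs appear in no factor: {sorted(missing)}")

    def validate_positive(self) -> None:
        for f in self.factors:
            if np.any(f.table <= 0.0):
                raise BayesNetError(
                    f"factor over {f.scope} has a non-positive entry; "
                    "all factor values must be strictly positive"
                )

    def unnormalized(self, state: Mapping[str, int]) -> float:
        return math.prod(f.value(state) for f in self.factors)

    def factors_containing(self, rv: str) -> list[Factor]:
        return [f for f in self.factors if rv in f.scope]


# ---------------------------------------------------------------------------
# Structure queries
# ---------------------------------------------------------------------------


def markov_blanket(net: BayesNet, node: str) -> set[str]:
    """Parents, children and co-parents of ``node`` (excluding the node)."""
    net._check(node)
    mb: set[str] = set(net.parents[node])
    for child in net.children(node):
        mb.add(child)
        mb.update(net.parents[child])
    mb.discard(node)
    return mb


def factorize(net: BayesNet) -> FactorSet:
    """The defining factorization: one factor per node over {node} ∪ parents.

    The factor scope is ordered ``(node, *parents)`` and its table holds
    ``P(node = v | parent assignment)``, so the product over factors equals
    the joint probability for every complete state.
    """
    factors = []
    for n in net.nodes:
        scope = (n,) + net.parents[n]
        m = len(scope)
        table = np.empty(2 ** m)
        for idx in range(2 ** m):
            vals = index_assignment(idx, m)
            p1 = net.cpt[n][assignment_index(vals[1:])]
            table[idx] = p1 if vals[0] == 1 else 1.0 - p1
        factors.append(Factor(scope, table))
    return FactorSet(net.nodes, factors)


# ---------------------------------------------------------------------------
# Exact inference by enumeration
# ---------------------------------------------------------------------------


def joint_table(net: BayesNet) -> np.ndarray:
    """The full joint ``p(z)`` over all ``2**K`` states (vectorized).

    State index uses :func:`assignment_index` over ``net.nodes``.
    """
    K = net.K
    if K > 22:
        raise BayesNetError(f"enumeration over 2**{K} states refused (K > 22)")
    idx = np.arange(2 ** K, dtype=np.int64)
    bit = {n: (idx >> (K - 1 - i)) & 1 for i, n in enumerate(net.nodes)}
    p = np.ones(2 ** K)
    for n in net.nodes:
        pidx = np.zeros(2 ** K, dtype=np.int64)
        for par in net.parents[n]:
            pidx = (pidx << 1) | bit[par]
        p1 = net.cpt[n][pidx]
        p *= np.where(bit[n] == 1, p1, 1.0 - p1)
    return p


def _evidence_mask(net: BayesNet, ev: Evidence) -> np.ndarray:
    K = net.K
    idx = np.arange(2 ** K, dtype=np.int64)
    mask = np.ones(2 ** K, dtype=bool)
    for rv, v in ev.items():
        i = net.index(rv)
        mask &= ((idx >> (K - 1 - i)) & 1) == v
    return mask


def exact_posterior(net: BayesNet, ev: Evidence, query: str) -> float:
    """``P(query = 1 | ev)`` by summation over all completions."""
    ev.validate(net)
    net._check(query)
    if query in ev:
        return float(ev[query])
    p = joint_table(net)
    mask = _evidence_mask(net, ev)
    z = p[mask].sum()
    if z <= 0.0:
        raise BayesNetError(f"evidence {dict(ev.items())} has zero probability")
    i = net.index(query)
    idx = np.arange(2 ** net.K, dtype=np.int64)
    one = mask & (((idx >> (net.K - 1 - i)) & 1) == 1)
    return float(p[one].sum() / z)


def posterior_marginals(net: BayesNet, ev: Evidence) -> dict[str, float]:
    """``P(rv = 1 | ev)`` for every RV in one enumeration pass."""
    ev.validate(net)
    p = joint_table(net)
    mask = _evidence_mask(net, ev)
    z = p[mask].sum()
    if z <= 0.0:
        raise BayesNetError(f"evidence {dict(ev.items())} has zero probability")
    idx = np.arange(2 ** net.K, dtype=np.int64)
    out = {}
    for i, rv in enumerate(net.nodes):
        if rv in ev:
            out[rv] = float(ev[rv])
        else:
            one = mask & (((idx >> (net.K - 1 - i)) & 1) == 1)
            out[rv] = float(p[one].sum() / z)
    return out


# ---------------------------------------------------------------------------
# Log-odds (the quantity the NCC pins to the membrane potential)
# ---------------------------------------------------------------------------


def log_odds(
    model: BayesNet | FactorSet, node: str, blanket_state: Mapping[str, int]
) -> float:
    """log P(node=1 | blanket) / P(node=0 | blanket).

    ``blanket_state`` must assign every RV in the Markov blanket of ``node``
    (for a :class:`FactorSet`: every RV sharing a factor with ``node``);
    additional assignments are ignored.  Because each factor containing the
    node depends, apart from the node, only on blanket RVs, the log-odds is
    the sum over those factors of ``log f(node=1, ·) - log f(node=0, ·)``.
    """
    factors = factorize(model) if isinstance(model, BayesNet) else model
    if node not in factors.rvs:
        raise KeyError(f"unknown node {node!r}")
    needed: set[str] = set()
    for f in factors.factors_containing(node):
        needed |= set(f.scope)
    needed.discard(node)
    missing = needed - set(blanket_state)
    if missing:
        raise BayesNetError(
            f"blanket assignment for {node!r} is incomplete: missing {sorted(missing)}"
        )
    state = dict(blanket_state)
    total = 0.0
    for f in factors.factors_containing(node):
        state[node] = 1
        hi = f.value(state)
        state[node] = 0
        lo = f.value(state)
        total += math.log(hi) - math.log(lo)
    return total


def log_odds_weights_mb(net: BayesNet, node: str) -> dict[int, float]:
    """Blanket log-odds table: assignment index x of MB(node) -> w_x.

    The Markov blanket is enumerated in ``net.nodes`` order; ``w_x`` is the
    log-odds of ``node`` given blanket assignment ``x``.  These are the
    membrane-potential coefficients used by the Markov-blanket constructions
    (one auxiliary neuron or dendritic branch per blanket assignment).
    """
    mb = sorted(markov_blanket(net, node), key=net.index)
    factors = factorize(net)
    out = {}
    for x in range(2 ** len(mb)):
        vals = index_assignment(x, len(mb))
        out[x] = log_odds(factors, node, dict(zip(mb, vals)))
    return out


def factor_log_odds_weights(
    factors: FactorSet, node: str
) -> dict[tuple[tuple[str, ...], int], float]:
    """Per-factor log-odds coefficients for the factorized expansion.

    For each factor J containing ``node`` and each assignment x to the other
    RVs of J, the coefficient ``w_{x,J} = log f_J(node=1, x) / f_J(node=0, x)``.
    Summing the coefficients of the currently matching assignment of every
    factor reproduces :func:`log_odds`.  Keys are ``(scope_without_node, x)``.
    """
    if node not in factors.rvs:
        raise KeyError(f"unknown node {node!r}")
    out = {}
    for f in factors.factors_containing(node):
        rest = tuple(r for r in f.scope if r != node)
        for x in range(2 ** len(rest)):
            state = dict(zip(rest, index_assignment(x, len(rest))))
            state[node] = 1
            hi = f.value(state)
            state[node] = 0
            lo = f.value(state)
            out[(rest, x)] = math.log(hi) - math.log(lo)
    return out


# ---------------------------------------------------------------------------
# I/O: canonical JSON dialect and a minimal BIF dialect
# ---------------------------------------------------------------------------
#
# JSON schema (canonical, bit-exact round trip):
# {
#   "nodes": ["A", "B", ...],
#   "parents": {"B": ["A"], ...},
#   "cpt": {"B": {"0": 0.2, "1": 0.7}, ...}
# }
# CPT rows are keyed by the parent assignment bit-string, first parent =
# most significant (leftmost) bit; values are P(node = 1 | parents).


def _net_to_dict(net: BayesNet) -> dict:
    cpt = {}
    for n in net.nodes:
        m = len(net.parents[n])
        cpt[n] = {
            format(i, f"0{m}b") if m else "": float(net.cpt[n][i])
            for i in range(2 ** m)
        }
    return {
        "nodes": list(net.nodes),
        "parents": {n: list(net.parents[n]) for n in net.nodes},
        "cpt": cpt,
    }


def _net_from_dict(d: Mapping) -> BayesNet:
    try:
        nodes = list(d["nodes"])
        parents = {n: list(d["parents"].get(n, [])) for n in nodes}
        cpt = {}
        for n in nodes:
            rows = d["cpt"][n]
            m = len(parents[n])
            table = np.empty(2 ** m)
            for key, v in rows.items():
                idx = int(key, 2) if key else 0
                table[idx] = float(v)
            if len(rows) != 2 ** m:
                raise BayesNetError(
                    f"node {n!r}: expected {2 ** m} CPT rows, got {len(rows)}"
                )
            cpt[n] = table
    except KeyError as e:
        raise BayesNetError(f"malformed network file: missing {e}") from e
    return BayesNet(nodes, parents, cpt)


_BIF_NAME = r"[A-Za-z_][A-Za-z0-9_.-]*"


def _bif_parse(text: str) -> BayesNet:
    """Parse the subset of the BIF interchange dialect used for binary RVs."""
    text = re.sub(r"//[^\n]*", "", text)
    nodes: list[str] = []
    for m in re.finditer(
        rf"variable\s+({_BIF_NAME})\s*\{{(.*?)\}}", text, re.S
    ):
        name, body = m.group(1), m.group(2)
        tm = re.search(r"type\s+discrete\s*\[\s*(\d+)\s*\]", body)
        if not tm or tm.group(1) != "2":
            raise BayesNetError(f"variable {name!r} is not binary in BIF file")
        nodes.append(name)
    parents: dict[str, list[str]] = {n: [] for n in nodes}
    cpt: dict[str, np.ndarray] = {}
    for m in re.finditer(
        rf"probability\s*\(\s*({_BIF_NAME})\s*(?:\|([^)]*))?\)\s*\{{(.*?)\}}",
        text,
        re.S,
    ):
        child = m.group(1)
        if child not in parents:
            raise BayesNetError(f"probability block for unknown variable {child!r}")
        ps = [p.strip() for p in (m.group(2) or "").split(",") if p.strip()]
        parents[child] = ps
        body = m.group(3)
        table = np.empty(2 ** len(ps))
        if not ps:
            tm = re.search(r"table\s+([^;]+);", body)
            if not tm:
                raise BayesNetError(f"missing table for root variable {child!r}")
            vals = [float(v) for v in tm.group(1).split(",")]
            table[0] = vals[1]  # states are declared as (0, 1); P(child=1)
        else:
            seen = 0
            for rm in re.finditer(r"\(([^)]*)\)\s*([^;]+);", body):
                key = [int(v) for v in rm.group(1).split(",")]
                vals = [float(v) for v in rm.group(2).split(",")]
                table[assignment_index(key)] = vals[1]
                seen += 1
            if seen != 2 ** len(ps):
                raise BayesNetError(
                    f"node {child!r}: expected {2 ** len(ps)} CPT rows, got {seen}"
                )
        cpt[child] = table
    missing = [n for n in nodes if n not in cpt]
    if missing:
        raise BayesNetError(f"BIF file lacks probability blocks for {missing}")
    return BayesNet(nodes, parents, cpt)


def _bif_format(net: BayesNet) -> str:
    lines = ["network unnamed {", "}"]
    for n in net.nodes:
        lines += [
            f"variable {n} {{",
            "  type discrete [ 2 ] { 0, 1 };",
            "}",
        ]
    for n in net.nodes:
        ps = net.parents[n]
        head = n if not ps else f"{n} | {', '.join(ps)}"
        lines.append(f"probability ( {head} ) {{")
        if not ps:
            p1 = float(net.cpt[n][0])
            lines.append(f"  table {1.0 - p1!r}, {p1!r};")
        else:
            for i in range(2 ** len(ps)):
                vals = index_assignment(i, len(ps))
                p1 = float(net.cpt[n][i])
                key = ", ".join(str(v) for v in vals)
                lines.append(f"  ({key}) {1.0 - p1!r}, {p1!r};")
        lines.append("}")
    return "\n".join(lines) + "\n"


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("json", "bif"):
            raise BayesNetError(f"unknown dialect {dialect!r}")
        return dialect
    return "bif" if path.suffix.lower() == ".bif" else "json"


def read_bn(path: str | Path, dialect: str | None = None) -> BayesNet:
    """Read a network from a JSON (canonical) or BIF file."""
    path = Path(path)
    text = path.read_text()
    if _infer_dialect(path, dialect) == "bif":
        return _bif_parse(text)
    try:
        d = json.loads(text)
    except json.JSONDecodeError as e:
        raise BayesNetError(f"{path} is not valid JSON: {e}") from e
    return _net_from_dict(d)


def write_bn(net: BayesNet, path: str | Path, dialect: str | None = None) -> None:
    """Write a network; the JSON dialect round-trips bit-exactly."""
    path = Path(path)
    if _infer_dialect(path, dialect) == "bif":
        path.write_text(_bif_format(net))
    else:
        path.write_text(json.dumps(_net_to_dict(net), indent=1, sort_keys=False))
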