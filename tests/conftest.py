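import itertools

import numpy as np
import pytest

from neuralsampling.bayes_core import BayesNet
from neuralsampling.genfix import fixture_asia, fixture_explaining_away


@pytest.fixture(scope="session")
def fig1():
    return fixture_explaining_away()


@pytest.fixture(scope="session")
def asia():
    return fixture_asia()


def make_random_net(seed: int, n_nodes: int, max_parents: int = 3) -> BayesNet:
    """Small random DAG with Beta(1,1) CPTs (ordered: parents precede)."""
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(n_nodes)]
    parents = {}
    cpt = {}
    for j, name in enumerate(names):
        k = int(rng.integers(0, min(j, max_parents) + 1))
        ps = sorted(rng.choice(j, size=k, replace=False)) if k else []
        parents[name] = [names[i] for i in ps]
        p = rng.uniform(0.02, 0.98, size=2 ** k)
        cpt[name] = p
    return BayesNet(names, parents, cpt)


def all_states(net: BayesNet):
    for vals in itertools.product([0, 1], repeat=net.K):
        yield dict(zip(net.nodes, vals))


def expandable_nets(start_seed: int, count: int, max_bits: int = 20):
    """Small random nets whose pairwise lift stays enumerable (z plus
    auxiliary bits <= max_bits); deterministic given start_seed."""
    from neuralsampling.bayes_core import factorize

    out = []
    seed = start_seed
    while len(out) < count:
        net = make_random_net(seed, 3 + seed % 2, max_parents=2)
        fs = factorize(net)
        bits = net.K + sum(2 ** f.order for f in fs.factors if f.order > 2)
        if bits <= max_bits:
            out.append(net)
        seed += 1
    return out


def enumeration_conditional(net: BayesNet, node: str, rest: dict) -> float:
    """Brute-force P(node=1 | all other RVs) from the joint — the
    independent oracle used against the factor-based log-odds."""
    num = den = 0.0
    for v in (0, 1):
        state = dict(rest)
        state[node] = v
        p = net.joint_prob(state)
        if v == 1:
            num = p
        else:
            den = p
    return num / (num + den)
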