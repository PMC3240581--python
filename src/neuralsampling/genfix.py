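"""Study networks and the random Bayesian-network generator.

Three networks drive the simulation studies:

* the 4-node "explaining away" network from visual perception (relative
  reflectance Re, 3D shape S, shading Sh, contour Co), with the symmetric
  conditional tables that make a cylindrical-contour percept explain away a
  reflectance step;
* a modified ASIA diagnosis network (7 nodes; the deterministic
  "tuberculosis or cancer" collider of the classical network is eliminated so
  that every link is strictly stochastic and the sampler's chain stays
  irreducible);
* randomly generated connected DAGs from an ordered edge-toggle MCMC whose
  stationary law is uniform over connected DAGs with a bounded in-degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bayes_core import CPT_EPS, BayesNet, Evidence

__all__ = [
    "fixture_explaining_away",
    "fixture_asia",
    "GeneratorConfig",
    "generate_random_bn",
    "random_net_with_evidence",
    "run_experiment",
]


def fixture_explaining_away() -> BayesNet:
    """The 4-node explaining-away network (Re, S, Sh, Co).

    Priors P(Re=1) = P(S=1) = 0.5.  The shading Sh is explained by a
    reflectance step or a cylindrical 3D shape but not both at once
    (P(Sh=1|Re,S) = 0.15, 0.85, 0.85, 0.15 over (Re,S) = 00, 01, 10, 11),
    and the contour follows the shape softly (P(Co=1|S) = 0.15 / 0.85).
    """
    return BayesNet(
        nodes=["Re", "S", "Sh", "Co"],
        parents={"Sh": ["Re", "S"], "Co": ["S"]},
        cpt={
            "Re": [0.5],
            "S": [0.5],
            "Sh": [0.15, 0.85, 0.85, 0.15],
            "Co": [0.15, 0.85],
        },
    )


def fixture_asia() -> BayesNet:
    """The modified 7-node ASIA network.

    Nodes: A (visit to Asia), S (smoker), T (tuberculosis), C (lung cancer),
    B (bronchitis), X (positive chest x-ray), D (dyspnoea).  Edges
    A→T, S→C, S→B, (T,C)→X, (T,C,B)→D.  The "tuberculosis or cancer"
    variable of the classical network is folded into the CPTs of X and D
    so that no link is deterministic.
    """
    return BayesNet(
        nodes=["A", "S", "T", "C", "B", "X", "D"],
        parents={
            "T": ["A"],
            "C": ["S"],
            "B": ["S"],
            "X": ["T", "C"],
            "D": ["T", "C", "B"],
        },
        cpt={
            "A": [0.01],
            "S": [0.5],
            # P(T=1|A): A=0 -> 0.01, A=1 -> 0.05
            "T": [0.01, 0.05],
            # P(C=1|S): S=0 -> 0.01, S=1 -> 0.10
            "C": [0.01, 0.10],
            # P(B=1|S): S=0 -> 0.3, S=1 -> 0.6
            "B": [0.3, 0.6],
            # P(X=1|T,C) over (T,C) = 00, 01, 10, 11
            "X": [0.05, 0.98, 0.98, 0.98],
            # P(D=1|T,C,B) over (T,C,B) = 000..111
            "D": [0.1, 0.8, 0.7, 0.9, 0.7, 0.9, 0.7, 0.9],
        },
    )


# ---------------------------------------------------------------------------
# Random connected ordered DAGs via edge-toggle MCMC
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Settings of the ordered edge-toggle MCMC over connected DAGs.

    The chain preserves a fixed node ordering (edges only run from lower to
    higher index, so acyclicity is structural), keeps the underlying
    undirected graph connected, and caps the number of parents per node.
    CPT rows are drawn from a symmetric Dirichlet (Beta for binary RVs).
    """

    n_nodes: int = 20
    max_in_degree: int = 8
    iterations: int = 500_000
    seed: int = 0
    dirichlet_alpha: float = 1.0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.max_in_degree < 1:
            raise ValueError("max_in_degree must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _is_connected(adj: list[set[int]], n: int) -> bool:
    seen = [False] * n
    stack = [0]
    seen[0] = True
    count = 1
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                count += 1
                stack.append(v)
    return count == n


def random_dag_edges(cfg: GeneratorConfig, rng: np.random.Generator) -> set[tuple[int, int]]:
    """Run the edge-toggle MCMC and return the edge set (i, j) with i < j.

    Starts from the path graph (node i+1 parented by node i).  At each
    iteration a random ordered pair is chosen; an existing edge is removed
    if the network stays connected, a missing edge is added if the child
    stays within the in-degree cap.
    """
    n = cfg.n_nodes
    edges: set[tuple[int, int]] = {(i, i + 1) for i in range(n - 1)}
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    in_deg = [0] * n
    for _, j in edges:
        in_deg[j] += 1

    # draw pairs in bulk; i < j uniformly over all ordered pairs
    pair_count = n * (n - 1) // 2
    draws = rng.integers(0, pair_count, size=cfg.iterations)
    pairs = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            pairs.append((i, j))
    for d in draws:
        i, j = pairs[d]
        if (i, j) in edges:
            adj[i].discard(j)
            adj[j].discard(i)
            if _is_connected(adj, n):
                edges.discard((i, j))
                in_deg[j] -= 1
            else:
                adj[i].add(j)
                adj[j].add(i)
        else:
            if in_deg[j] < cfg.max_in_degree:
                edges.add((i, j))
                adj[i].add(j)
                adj[j].add(i)
                in_deg[j] += 1
    return edges


def generate_random_bn(cfg: GeneratorConfig) -> BayesNet:
    """Generate a connected random Bayesian network with random CPTs."""
    rng = np.random.default_rng(cfg.seed)
    edges = random_dag_edges(cfg, rng)
    n = cfg.n_nodes
    names = [f"N{i + 1:02d}" for i in range(n)]
    parents = {
        names[j]: [names[i] for i in range(j) if (i, j) in edges] for j in range(n)
    }
    a = cfg.dirichlet_alpha
    cpt = {}
    for j, name in enumerate(names):
        rows = 2 ** len(parents[name])
        p = rng.beta(a, a, size=rows)
        cpt[name] = np.clip(p, CPT_EPS, 1.0 - CPT_EPS)
    return BayesNet(names, parents, cpt)


def random_net_with_evidence(
    seed: int, n_clamped: int = 8, cfg: GeneratorConfig | None = None
) -> tuple[BayesNet, Evidence]:
    """A generated 20-node network plus evidence on its lower layer.

    Clamps a random subset of ``n_clamped`` nodes drawn from the high-index
    (downstream) half of the ordering to a random assignment, emulating
    observations entering at the bottom of the causal hierarchy.
    """
    if cfg is None:
        cfg = GeneratorConfig(seed=seed, iterations=20_000)
    else:
        cfg = GeneratorConfig(
            n_nodes=cfg.n_nodes,
            max_in_degree=cfg.max_in_degree,
            iterations=cfg.iterations,
            seed=seed,
            dirichlet_alpha=cfg.dirichlet_alpha,
        )
    net = generate_random_bn(cfg)
    rng = np.random.default_rng(seed + 1)
    lower = list(net.nodes[cfg.n_nodes // 2:])
    chosen = rng.choice(len(lower), size=n_clamped, replace=False)
    ev = Evidence({lower[i]: int(rng.integers(0, 2)) for i in sorted(chosen)})
    return net, ev


# ---------------------------------------------------------------------------
# Experiment orchestration (the three simulation studies)
# ---------------------------------------------------------------------------


def run_experiment(name: str, overrides: dict | None = None, outdir: str | Path = "results"):
    """Run one of the three packaged simulation studies and write a report.

    ``sim1`` compares the lifted-Boltzmann sampler with the ideal
    log-odds sampler on the explaining-away network; ``sim2`` runs the
    auxiliary-neuron network on ASIA with three EPSP shapes; ``sim3`` runs
    the ideal sampler on a generated 20-node network with lower-layer
    evidence, for absolute and relative refractoriness.

    Returns the report dict (also written as JSON, with KL traces as CSV).
    """
    from . import experiments

    runner = {
        "sim1": experiments.sim1,
        "sim2": experiments.sim2,
        "sim3": experiments.sim3,
    }.get(name)
    if runner is None:
        raise ValueError(f"unknown experiment {name!r}; choose sim1, sim2 or sim3")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = runner(overrides or {}, outdir)
    (outdir / f"{name}_report.json").write_text(json.dumps(report, indent=1))
    return report
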