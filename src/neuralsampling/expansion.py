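"""Lifting higher-order factors to a pairwise Boltzmann model with auxiliary RVs.

Any factorized distribution p(z) ∝ ∏_I f_I(z_I) over binary RVs can be
written as the marginal of a second-order (pairwise) Boltzmann distribution
q(z, x) over the original RVs plus auxiliary RVs: each factor of order >= 3
gets one auxiliary RV X_{I,x} per assignment x to its scope, hard pairwise
constraint factors force X_{I,x} = 1 to imply z_I = x, and a unary factor on
X_{I,x} carries the (rescaled) factor value.  Marginalizing the auxiliaries
out recovers p exactly: for fixed z the auxiliaries of factor I contribute
1 (all-zero configuration) + (λ_I f_I(z_I) − 1) (the single matching
auxiliary on), i.e. λ_I f_I(z_I).

The all-zero auxiliary configuration is compatible with every z, which is
what keeps the single-flip Markov chain over non-forbidden states connected
(irreducible) despite the deterministic constraints.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .bayes_core import (
    BayesNetError,
    Factor,
    FactorSet,
    index_assignment,
)

__all__ = [
    "AuxiliaryRV",
    "ExpandedDistribution",
    "BoltzmannParams",
    "expand",
    "boltzmann_params",
    "check_irreducible",
    "boltzmann_joint",
    "gibbs_sample",
    "IrreducibilityReport",
]

#: Per-factor rescaling: λ = LAMBDA_MARGIN / min_x f(x), so the smallest
#: lifted unary value λf(x) − 1 equals LAMBDA_MARGIN − 1.  The default 2
#: makes every unary value >= 1 (every auxiliary RV is actively used to
#: represent its assignment, with bias log(λf − 1) >= 0); any value > 1
#: keeps log(λf − 1) finite and leaves the marginal over auxiliaries exact.
LAMBDA_MARGIN = 2.0


@dataclass(frozen=True)
class AuxiliaryRV:
    """One auxiliary RV: ``factor`` (index into higher-order factors),
    ``assignment`` (index over the factor scope) and its unary value
    ``λ f(assignment) − 1``."""

    name: str
    factor: int
    assignment: int
    unary: float


@dataclass
class ExpandedDistribution:
    """The lifted pairwise model q(z, x).

    ``pass_factors`` are the original factors of order <= 2 (unchanged);
    ``higher_factors`` the original factors of order >= 3 (kept for
    reference); ``aux`` the auxiliary RVs; ``constraints`` the hard pairwise
    {0,1} factors as triples ``(aux_name, rv, required_value)`` meaning the
    factor is 0 iff aux = 1 and rv != required_value.
    """

    rvs: tuple[str, ...]
    pass_factors: list[Factor]
    higher_factors: list[Factor]
    lambdas: list[float]
    aux: list[AuxiliaryRV]
    constraints: list[tuple[str, str, int]]

    @property
    def aux_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.aux)

    @property
    def all_rvs(self) -> tuple[str, ...]:
        return self.rvs + self.aux_names

    def n_aux_for_factor(self, i: int) -> int:
        return sum(1 for a in self.aux if a.factor == i)

    # -- enumeration -------------------------------------------------------

    def joint_weights(self) -> np.ndarray:
        """Unnormalized q over all 2**(K+A) states of (z, x).

        State index uses the package bit convention over ``all_rvs``
        (first RV = most significant bit).  Forbidden states get weight 0.
        """
        names = self.all_rvs
        n = len(names)
        if n > 22:
            raise BayesNetError(f"enumeration over 2**{n} states refused (n > 22)")
        pos = {r: i for i, r in enumerate(names)}
        idx = np.arange(2 ** n, dtype=np.int64)
        bit = lambda r: (idx >> (n - 1 - pos[r])) & 1  # noqa: E731
        w = np.ones(2 ** n)
        for f in self.pass_factors:
            fidx = np.zeros(2 ** n, dtype=np.int64)
            for r in f.scope:
                fidx = (fidx << 1) | bit(r)
            w *= f.table[fidx]
        for a in self.aux:
            w *= np.where(bit(a.name) == 1, a.unary, 1.0)
        allowed = np.ones(2 ** n, dtype=bool)
        for aux_name, rv, req in self.constraints:
            allowed &= ~((bit(aux_name) == 1) & (bit(rv) != req))
        return np.where(allowed, w, 0.0)

    def allowed_mask(self) -> np.ndarray:
        return self.joint_weights() > 0.0

    def marginal_over_aux(self) -> np.ndarray:
        """q marginalized over auxiliaries: unnormalized weights over the
        2**K principal states, normalized to sum to 1."""
        K = len(self.rvs)
        A = len(self.aux)
        w = self.joint_weights().reshape(2 ** K, 2 ** A)
        m = w.sum(axis=1)
        return m / m.sum()


def expand(factors: FactorSet) -> ExpandedDistribution:
    """Lift ``factors`` to a pairwise model with auxiliary RVs."""
    factors.validate_positive()
    pass_factors: list[Factor] = []
    higher: list[Factor] = []
    for f in factors.factors:
        (pass_factors if f.order <= 2 else higher).append(f)
    lambdas: list[float] = []
    aux: list[AuxiliaryRV] = []
    constraints: list[tuple[str, str, int]] = []
    for i, f in enumerate(higher):
        lam = LAMBDA_MARGIN / float(f.table.min())
        lambdas.append(lam)
        m = f.order
        for x in range(2 ** m):
            name = f"aux[{','.join(f.scope)}]={x:0{m}b}"
            unary = lam * float(f.table[x]) - 1.0
            aux.append(AuxiliaryRV(name, i, x, unary))
            vals = index_assignment(x, m)
            for rv, v in zip(f.scope, vals):
                constraints.append((name, rv, v))
    return ExpandedDistribution(
        rvs=factors.rvs,
        pass_factors=pass_factors,
        higher_factors=higher,
        lambdas=lambdas,
        aux=aux,
        constraints=constraints,
    )


# ---------------------------------------------------------------------------
# Boltzmann parameterization
# ---------------------------------------------------------------------------


@dataclass
class BoltzmannParams:
    """Parameters of p(y) ∝ exp(y'Wy/2 + b'y) over ``units``.

    W is symmetric with zero diagonal; the deterministic constraints of the
    lifted model appear as finite couplings of magnitude ``M`` standing in
    for the ±∞ ideal.
    """

    units: tuple[str, ...]
    W: np.ndarray
    b: np.ndarray
    M: float
    n_principal: int

    def __post_init__(self):
        n = len(self.units)
        if self.W.shape != (n, n) or self.b.shape != (n,):
            raise BayesNetError("inconsistent Boltzmann parameter shapes")
        if not np.allclose(self.W, self.W.T) or np.any(np.diag(self.W) != 0.0):
            raise BayesNetError("W must be symmetric with zero diagonal")


def default_coupling(exp: ExpandedDistribution) -> float:
    """The 10x rule: ten times the largest factor value of the lifted model."""
    vals = [1.0]
    vals += [float(f.table.max()) for f in exp.pass_factors]
    vals += [a.unary for a in exp.aux]
    return 10.0 * max(vals)


def boltzmann_params(exp: ExpandedDistribution, M: float | None = None) -> BoltzmannParams:
    """Compile the lifted model into pairwise Boltzmann weights and biases.

    Auxiliary X_{I,x} couples with +M to every principal that is 1 in its
    assignment x and with −M to every principal that is 0 in it; its bias is
    ``log(λf(x) − 1) − N1(x)·M`` (N1 = number of ones in x), so that the
    exact constraint factors are recovered in the M → ∞ limit.  Factors of
    order <= 2 pass through via the standard log-parameterization.
    """
    if M is None:
        M = default_coupling(exp)
    max_unary_mag = max((abs(math.log(a.unary)) for a in exp.aux), default=0.0)
    if M <= max_unary_mag:
        raise BayesNetError(
            f"coupling M={M:.3g} must exceed the largest unary log-factor "
            f"magnitude {max_unary_mag:.3g}"
        )
    units = exp.all_rvs
    pos = {r: i for i, r in enumerate(units)}
    n = len(units)
    W = np.zeros((n, n))
    b = np.zeros(n)
    for f in exp.pass_factors:
        t = np.log(f.table)
        if f.order == 1:
            b[pos[f.scope[0]]] += t[1] - t[0]
        else:
            i, j = pos[f.scope[0]], pos[f.scope[1]]
            W[i, j] += t[3] + t[0] - t[1] - t[2]
            W[j, i] = W[i, j]
            b[i] += t[2] - t[0]  # scope[0]=1, scope[1]=0
            b[j] += t[1] - t[0]
    for a in exp.aux:
        ai = pos[a.name]
        scope = exp.higher_factors[a.factor].scope
        vals = index_assignment(a.assignment, len(scope))
        n1 = sum(vals)
        for rv, v in zip(scope, vals):
            zi = pos[rv]
            W[ai, zi] += M if v == 1 else -M
            W[zi, ai] = W[ai, zi]
        b[ai] += math.log(a.unary) - n1 * M
    return BoltzmannParams(units=units, W=W, b=b, M=M, n_principal=len(exp.rvs))


def boltzmann_joint(params: BoltzmannParams) -> np.ndarray:
    """Exact Boltzmann probabilities over all 2**n unit states."""
    n = len(params.units)
    if n > 22:
        raise BayesNetError(f"enumeration over 2**{n} states refused (n > 22)")
    idx = np.arange(2 ** n, dtype=np.int64)
    S = np.empty((2 ** n, n))
    for i in range(n):
        S[:, i] = (idx >> (n - 1 - i)) & 1
    e = 0.5 * np.einsum("si,ij,sj->s", S, params.W, S) + S @ params.b
    e -= e.max()
    w = np.exp(e)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Irreducibility check
# ---------------------------------------------------------------------------


@dataclass
class IrreducibilityReport:
    connected: bool
    n_allowed: int
    n_reachable: int
    n_bits: int

    def __bool__(self) -> bool:
        return self.connected


def check_irreducible(exp: ExpandedDistribution) -> IrreducibilityReport:
    """BFS over non-forbidden (z, x) states under single-variable flips.

    The chain is irreducible iff the non-forbidden states form a single
    connected component; connectivity under symmetric single flips also
    implies that the all-zero auxiliary configuration is reachable from
    every state.
    """
    exp.rvs and None  # noqa: B018 (touch)
    n = len(exp.all_rvs)
    if n > 22:
        raise BayesNetError(
            f"state space 2**{n} exceeds the 2**22 irreducibility-check cap"
        )
    for a in exp.aux:
        if a.unary <= 0.0:
            raise BayesNetError(f"auxiliary {a.name!r} has non-positive value")
    allowed = np.asarray(exp.allowed_mask())
    n_allowed = int(allowed.sum())
    start = 0  # all-zero state is always allowed (aux all zero)
    if not allowed[start]:
        raise BayesNetError("all-zero state unexpectedly forbidden")
    seen = np.zeros(allowed.size, dtype=bool)
    seen[start] = True
    q = deque([start])
    flips = [1 << k for k in range(n)]
    reach = 1
    while q:
        s = q.popleft()
        for f in flips:
            t = s ^ f
            if allowed[t] and not seen[t]:
                seen[t] = True
                reach += 1
                q.append(t)
    return IrreducibilityReport(
        connected=(reach == n_allowed),
        n_allowed=n_allowed,
        n_reachable=reach,
        n_bits=n,
    )


# ---------------------------------------------------------------------------
# Reference sampler (independent of the spiking engine)
# ---------------------------------------------------------------------------


def gibbs_sample(
    params: BoltzmannParams,
    sweeps: int,
    seed: int,
    burn_in: int = 0,
    clamp: dict[int, int] | None = None,
) -> np.ndarray:
    """Single-site systematic-scan Gibbs sampling of the Boltzmann model.

    Returns the occupancy (mean value) of every unit over the kept sweeps.
    ``clamp`` maps unit index -> pinned value.  This reference sampler keeps
    the expansion testable independently of the spiking dynamics.
    """
    rng = np.random.default_rng(seed)
    n = len(params.units)
    y = rng.integers(0, 2, size=n).astype(float)
    clamp = clamp or {}
    for i, v in clamp.items():
        y[i] = v
    free = [i for i in range(n) if i not in clamp]
    W = params.W
    b = params.b
    counts = np.zeros(n)
    u = rng.random(size=(sweeps, len(free)))
    for s in range(sweeps):
        for k, i in enumerate(free):
            ui = b[i] + W[i] @ y
            y[i] = 1.0 if u[s, k] < 1.0 / (1.0 + math.exp(-ui)) else 0.0
        if s >= burn_in:
            counts += y
    return counts / max(sweeps - burn_in, 1)
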