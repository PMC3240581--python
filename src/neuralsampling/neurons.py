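"""Stochastic spike-response neurons: PSP kernels, refractoriness, dendrites.

The sampling theory needs neurons whose instantaneous firing probability
density is exp(u(t)) (in units of 1/τ) outside the refractory period, where
u is the membrane potential in log-odds units.  In discrete time with step
Δt and an absolute refractory period τ = N·Δt this becomes the per-step
firing probability σ(u − log N), which makes the induced Markov chain over
(state, refractory-counter) leave the target distribution exactly invariant.

For a *relative* refractory mechanism, readiness to fire is modulated by a
function g(s) of the time s since the last spike (g(0) = 0, g(s) = 1 for
s >= τ), the hazard is g(s)·f(u)/τ, and f is defined implicitly by the
requirement that an isolated neuron at constant u occupies state 1 with
odds exp(u).  :func:`solve_f_from_g` solves that renewal self-consistency
numerically; for the absolute profile it reduces to f(u) = exp(u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PSPKernel",
    "rectangular_kernel",
    "alpha_kernel",
    "plateau_kernel",
    "make_kernel",
    "kernel_eval",
    "RefractoryProfile",
    "absolute_profile",
    "relative_profile",
    "FiringFunction",
    "solve_f_from_g",
    "absolute_fire_prob",
    "fire_step",
    "PointNeuron",
    "membrane_potential",
    "Branch",
    "MultiCompartmentNeuron",
    "soma_voltage",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PSP kernels
# ---------------------------------------------------------------------------

ALPHA_SCALE = 2.3  # peak amplitude of the alpha EPSP
ALPHA_CUTOFF = 0.05  # tail truncation level


@dataclass(frozen=True)
class PSPKernel:
    """A causal PSP time course ε(s); ε(s) = 0 for s < 0."""

    shape: str  # rectangular | alpha | plateau
    tau: float  # window length τ (ms)
    params: tuple[tuple[str, float], ...] = ()

    def param(self, name: str) -> float:
        return dict(self.params)[name]

    def __call__(self, s):
        return kernel_eval(self, s)

    @property
    def support(self) -> float:
        """Length of the interval on which the kernel can be nonzero."""
        if self.shape == "alpha":
            return self.param("s_end")
        return self.tau


def rectangular_kernel(tau: float = 20.0) -> PSPKernel:
    """The theoretically optimal PSP: 1 on [0, τ), 0 elsewhere."""
    return PSPKernel("rectangular", tau)


def _alpha_crossings(scale: float, level: float = 1.0) -> tuple[float, float]:
    """(x1, x2): points (in units of τ_α) where scale·x·e^(1-x) crosses
    ``level`` on the way up and down; requires scale > level."""
    def h(x):
        return scale * x * math.exp(1.0 - x) - level

    return brentq(h, 1e-6, 1.0), brentq(h, 1.0, 60.0)


def alpha_kernel(
    tau: float = 20.0,
    tau_alpha: float | None = None,
    scale: float = ALPHA_SCALE,
    cutoff: float = ALPHA_CUTOFF,
) -> PSPKernel:
    """Alpha-shaped EPSP scale·(s/τ_α)·exp(1 − s/τ_α), peak ``scale`` at τ_α.

    By default τ_α is calibrated so that the span [t1, t2] on which the
    kernel exceeds the unit (rectangular) amplitude equals τ: the EPSP is
    then "effectively on" for one nominal window length, with a graded rise
    before t1 and a tail after t2.  The tail is truncated where it falls
    below ``cutoff``.
    """
    x1, x2 = _alpha_crossings(scale, 1.0)
    if tau_alpha is None:
        tau_alpha = tau / (x2 - x1)
    target = cutoff / scale

    def h(x):
        return x * math.exp(1.0 - x) - target

    x_end = brentq(h, 1.0, 60.0)
    return PSPKernel(
        "alpha",
        tau,
        (
            ("tau_alpha", float(tau_alpha)),
            ("scale", float(scale)),
            ("s_end", float(x_end * tau_alpha)),
        ),
    )


def plateau_kernel(tau: float = 20.0, rise: float = 2.0, fall: float = 5.0) -> PSPKernel:
    """Plateau EPSP: linear rise, hold at 1, quarter-sine fall; support [0, τ)."""
    if rise + fall > tau:
        raise ConfigError("plateau rise + fall must not exceed tau")
    return PSPKernel("plateau", tau, (("rise", float(rise)), ("fall", float(fall))))


def make_kernel(name: str, tau: float = 20.0, **kw) -> PSPKernel:
    try:
        factory = {
            "rectangular": rectangular_kernel,
            "alpha": alpha_kernel,
            "plateau": plateau_kernel,
        }[name]
    except KeyError:
        raise ConfigError(f"unknown kernel shape {name!r}") from None
    return factory(tau, **kw)


def kernel_eval(kernel: PSPKernel, s):
    """Evaluate ε(s); accepts scalars or arrays."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    if kernel.shape == "rectangular":
        out = np.where((s >= 0.0) & (s < kernel.tau), 1.0, 0.0)
    elif kernel.shape == "alpha":
        ta = kernel.param("tau_alpha")
        val = kernel.param("scale") * (s / ta) * np.exp(1.0 - s / ta)
        out = np.where((s >= 0.0) & (s < kernel.param("s_end")), val, 0.0)
    elif kernel.shape == "plateau":
        rise, fall, tau = kernel.param("rise"), kernel.param("fall"), kernel.tau
        val = np.ones_like(s)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(s < rise, s / rise, val)
            val = np.where(
                s >= tau - fall, np.sin(0.5 * np.pi * (tau - s) / fall), val
            )
        out = np.where((s >= 0.0) & (s < tau), val, 0.0)
    else:  # pragma: no cover
        raise ConfigError(f"unknown kernel shape {kernel.shape!r}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Refractory mechanisms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RefractoryProfile:
    """Readiness-to-fire function g on [0, τ]: g(0)=0, g(s)=1 for s >= τ."""

    kind: str  # absolute | relative
    tau: float
    g: Callable[[float], float] = field(compare=False, default=None)

    def g_eval(self, s):
        s = np.asarray(s, dtype=float)
        if self.kind == "absolute":
            out = np.where(s >= self.tau, 1.0, 0.0)
        else:
            out = np.clip(self.g(np.minimum(s, self.tau)), 0.0, 1.0)
            out = np.where(s >= self.tau, 1.0, out)
        return float(out) if out.ndim == 0 else out


def absolute_profile(tau: float = 20.0) -> RefractoryProfile:
    return RefractoryProfile("absolute", tau)


def relative_profile(
    tau: float = 20.0, g: Callable | None = None
) -> RefractoryProfile:
    """Relative refractoriness; default readiness ramp g(s) = (s/τ)²."""
    if g is None:
        t = tau

        def g(s):
            return (np.asarray(s) / t) ** 2

    return RefractoryProfile("relative", tau, g)


# ---------------------------------------------------------------------------
# Solving the firing function f from g
# ---------------------------------------------------------------------------


@dataclass
class FiringFunction:
    """Tabulated f(u) with linear interpolation of log f in u."""

    u_grid: np.ndarray
    log_f: np.ndarray
    profile: RefractoryProfile
    dt: float | None
    residual: float

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        lo, hi = self.u_grid[0], self.u_grid[-1]
        # linear extrapolation of log f (slope -> 1 in both tails)
        out = np.interp(u, self.u_grid, self.log_f)
        out = np.where(u < lo, self.log_f[0] + (u - lo), out)
        out = np.where(u > hi, self.log_f[-1] + (u - hi), out)
        f = np.exp(out)
        return float(f) if f.ndim == 0 else f


def _odds_continuous(f: float, profile: RefractoryProfile, grid: np.ndarray) -> float:
    """Stationary odds P(z=1)/P(z=0) of the renewal process with hazard
    g(s)·f/τ, where z = 1 for τ after each spike (continuous time)."""
    tau = profile.tau
    # midpoint rule for the readiness integral: exact for the absolute
    # profile, whose jump sits exactly at s = tau
    gm = profile.g_eval(0.5 * (grid[1:] + grid[:-1]))
    G = np.concatenate([[0.0], np.cumsum(gm * np.diff(grid))])
    S = np.exp(-(f / tau) * G)
    e1 = np.trapezoid(S, grid)
    if S[-1] == 0.0:
        return math.inf
    with np.errstate(over="ignore"):
        e0 = S[-1] * tau / f
    if e0 == 0.0:
        return math.inf
    with np.errstate(over="ignore"):
        out = float(e1 / e0)
    return out


def _odds_discrete(f: float, profile: RefractoryProfile, dt: float) -> float:
    """Same stationary odds for the discrete-time chain with per-step hazard
    min(g(j·Δt)·f·Δt/τ, 1)."""
    tau = profile.tau
    n = int(round(tau / dt))
    h = np.minimum(profile.g_eval(np.arange(1, n + 1) * dt) * f * dt / tau, 1.0)
    S = np.concatenate([[1.0], np.cumprod(1.0 - h)])  # S[j] = P(no spike in 1..j)
    e1 = S[:n].sum()
    hc = min(f * dt / tau, 1.0)
    e0 = S[n] / hc if hc > 0 else math.inf
    if e0 == 0.0:
        return math.inf
    return e1 / e0


def solve_f_from_g(
    profile: RefractoryProfile,
    dt: float | None = None,
    u_grid: np.ndarray | None = None,
    tol: float = 1e-10,
    n_quad: int = 801,
) -> FiringFunction:
    """Solve the renewal self-consistency for the firing function f(u).

    For each u on the grid, finds f such that an isolated neuron with
    constant potential u and hazard g(s)·f/τ has stationary occupancy odds
    exp(u).  With ``dt=None`` the continuous-time process is solved (for the
    absolute profile this gives f(u) = exp(u) exactly); with a concrete
    ``dt`` the discrete simulation chain is solved, making the simulated
    single-neuron occupancy exact at that step size.
    """
    if profile.kind == "relative" and profile.g is None:
        raise ConfigError("relative profile requires a readiness function g")
    if dt is not None and not dt < profile.tau:
        raise ConfigError("dt must be smaller than tau")
    if u_grid is None:
        u_grid = np.linspace(-12.0, 12.0, 241)
    grid = np.linspace(0.0, profile.tau, n_quad)

    def odds(f: float) -> float:
        if dt is None:
            return _odds_continuous(f, profile, grid)
        return _odds_discrete(f, profile, dt)

    log_f = np.empty_like(u_grid)
    worst = 0.0
    for i, u in enumerate(u_grid):
        target = math.exp(u)

        def h(lf):
            return math.log(odds(math.exp(lf))) - u

        lo, hi = u - 30.0, u + 5.0
        tries = 0
        while h(hi) < 0.0:
            hi += 5.0
            tries += 1
            if tries > 40:
                raise ConfigError(
                    f"firing-function solve did not bracket at u={u:.3g} "
                    f"(residual {h(hi):.3g})"
                )
        lf = brentq(h, lo, hi, xtol=1e-13, rtol=8.9e-16)
        log_f[i] = lf
        worst = max(worst, abs(math.log(odds(math.exp(lf))) - u))
    if worst > max(tol, 1e-8):
        raise ConfigError(
            f"firing-function solve residual {worst:.3g} exceeds tolerance"
        )
    return FiringFunction(np.asarray(u_grid, float), log_f, profile, dt, worst)


# ---------------------------------------------------------------------------
# Per-step firing rule
# ---------------------------------------------------------------------------


def absolute_fire_prob(u, n_steps: int):
    """σ(u − log N): per-step firing probability of a free neuron with an
    absolute refractory period of N steps."""
    x = np.asarray(u, dtype=float) - math.log(n_steps)
    p = 1.0 / (1.0 + np.exp(-x))
    return float(p) if p.ndim == 0 else p


def fire_step(
    u: float,
    steps_since_spike: int,
    profile: RefractoryProfile,
    dt: float,
    rng: np.random.Generator,
    f: FiringFunction | None = None,
) -> bool:
    """One discrete-time firing decision.

    ``steps_since_spike`` counts steps since the last spike (use a large
    value if the neuron never fired).  Absolute case: no spike while
    s·Δt < τ, otherwise probability σ(u − log(τ/Δt)).  Relative case:
    probability min(g(s·Δt)·f(u)·Δt/τ, 1).
    """
    if not dt < profile.tau:
        raise ConfigError("dt must be smaller than tau")
    n = int(round(profile.tau / dt))
    if profile.kind == "absolute":
        if steps_since_spike < n:
            return False
        p = absolute_fire_prob(u, n)
    else:
        if f is None:
            raise ConfigError("relative profile requires a solved firing function")
        g = profile.g_eval(steps_since_spike * dt)
        p = min(g * f(u) * dt / profile.tau, 1.0)
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# Point and multi-compartment potentials
# ---------------------------------------------------------------------------


@dataclass
class PointNeuron:
    """A point neuron: u(t) = b + Σ_i w_i · ε_i(t − t̂_i − d_i)."""

    bias: float
    connections: list[tuple[str, float, PSPKernel, float]] = field(default_factory=list)
    refractory: RefractoryProfile = field(default_factory=absolute_profile)


def _last_spike_before(times: Sequence[float], t: float) -> float | None:
    last = None
    for ts in times:
        if ts <= t:
            last = ts
        else:
            break
    return last


def membrane_potential(
    neuron: PointNeuron, spikes: Mapping[str, Sequence[float]], t: float
) -> float:
    """Potential at time t from the last spike of each presynaptic source."""
    u = neuron.bias
    for source, w, kernel, delay in neuron.connections:
        last = _last_spike_before(spikes.get(source, ()), t)
        if last is not None:
            u += w * kernel_eval(kernel, t - last - delay)
    return u


@dataclass
class Branch:
    """A dendritic branch: thresholded regenerative unit.

    Contribution to the soma is β·H(A − θ) + c·A where A is the summed
    synaptic drive plus any tonic drive.  ``tonic`` supplies a constant
    activation for branches that encode the all-zero input assignment
    (which receive only inhibitory synapses and must be active by default).
    """

    synapses: list[tuple[str, float]]
    theta: float
    beta: float
    kernel: PSPKernel
    tonic: float = 0.0
    passive: float = 0.0  # attenuation c of the passive component

    def __post_init__(self):
        if self.theta <= 0.0:
            raise ConfigError("branch threshold must be positive")
        if self.beta < 0.0:
            raise ConfigError("branch strength must be nonnegative")

    def activation(self, spikes: Mapping[str, Sequence[float]], t: float) -> float:
        a = self.tonic
        for source, w in self.synapses:
            last = _last_spike_before(spikes.get(source, ()), t)
            if last is not None:
                a += w * kernel_eval(self.kernel, t - last)
        return a

    def validate_selectivity(self) -> None:
        """Synaptic weights must be conjunctive: the full matching pattern
        crosses θ, but no proper subset of the excitatory inputs does, and
        any single inhibitory input vetoes the spike."""
        exc = [w for _, w in self.synapses if w > 0]
        inh = [w for _, w in self.synapses if w < 0]
        total = self.tonic + sum(exc)
        if total < self.theta:
            raise ConfigError("full matching input fails to cross the branch threshold")
        for w in exc:
            if total - w >= self.theta:
                raise ConfigError(
                    "a branch fires without one of its excitatory inputs"
                )
        for w in inh:
            if total + w >= self.theta:
                raise ConfigError("an inhibitory input fails to veto the branch")


@dataclass
class MultiCompartmentNeuron:
    """Soma potential = rest + Σ_E [β_E·H(A_E − θ_E) + c·A_E]."""

    rest: float
    branches: list[Branch] = field(default_factory=list)
    refractory: RefractoryProfile = field(default_factory=absolute_profile)


def soma_voltage(
    neuron: MultiCompartmentNeuron, spikes: Mapping[str, Sequence[float]], t: float
) -> float:
    u = neuron.rest
    for br in neuron.branches:
        a = br.activation(spikes, t)
        if a >= br.theta:
            u += br.beta
        u += br.passive * a
    return u
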