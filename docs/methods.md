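# Methods

## Model

The target is a distribution p(z) over binary RVs z = (z_1 … z_K) given by
a Bayesian network: p(z) = ∏_k p(z_k | z_{pa(k)}), every CPT entry strictly
inside (0, 1) (validated to [1e-6, 1−1e-6]).  Non-degenerate tables are a
correctness requirement, not a convenience: a deterministic link makes the
sampling chain reducible, which is why the classical ASIA network is used
in a modified form with its deterministic or-node folded into the CPTs of
its children.

Sampling interprets spikes as samples: principal neuron ν_k fires ⇒
z_k = 1 for the window (t, t + τ].  With an absolute refractory period of
τ and firing density exp(u_k)/τ outside it, the network state follows a
non-reversible Markov chain whose stationary distribution marginalizes to
p(z), provided the NCC holds: u_k equals the log-odds of z_k given the
current state of the other RVs.

### Discrete-time chain

The engine simulates the discrete chain with step Δt and N = τ/Δt.  Each
neuron carries the time since its last spike; a neuron is free when that
age is ≥ N, and a free neuron fires with probability σ(u − log N).  Within
a time step neurons are updated **sequentially in node order**, each
reading the latest state of the others.  Each per-neuron update leaves the
joint distribution over (states, refractory phases) exactly invariant, so
the composition does too: the chain has no O(Δt) bias, and long-run
occupancies match exact enumeration to Monte-Carlo error (the test suite
checks 3-SE agreement on 4-, 7- and 20-node networks).  A random-scan
(asynchronous) variant was evaluated and rejected: refractory windows then
expire between a neuron's updates, deflating occupancies by O(Δt/τ).

Defaults: Δt = 1 ms, τ = 20 ms.  τ only sets the time scale; Δt must
divide τ.

### Relative refractoriness

A readiness function g(s) (g(0) = 0, g(s) = 1 for s ≥ τ; default the ramp
g(s) = (s/τ)², configurable) modulates the hazard g(s)·f(u)/τ.  f is not
free: it is pinned by the renewal self-consistency that an isolated neuron
at constant u occupies state 1 with odds e^u.  `solve_f_from_g` solves this
by root-finding on a grid of u (continuous-time form, which reduces to
f = e^u for the absolute profile, or the discrete-time form matched to the
simulation step, which makes the simulated single-neuron occupancy exact).
In a network the relative-refractory sampler is only locally correct — the
derivation holds for a frozen environment — and is assessed empirically.

## The five constructions

All constructions are compiled by `builders` into a `NetworkSpec` whose
structural steady-state potential is audited exhaustively against
enumeration log-odds (≤ 1e-9) on every fixture.

* **Lifting (impl1).**  Factors of order ≥ 3 get one auxiliary RV per
  scope assignment; constraints become couplings ±M between the auxiliary
  and the scope RVs, with auxiliary bias log(λf(x) − 1) − N1(x)·M.  Finite
  M stands in for the ±∞ ideal; default M = 10 × the largest lifted factor
  value.  The rescaling constant is λ = 2 / min_x f(x): the smallest
  lifted unary value is then exactly 1, so every auxiliary RV actively
  represents its assignment and all unary log-values are ≥ 0.  (The
  near-minimal alternative λ ≈ 1/min f makes the minimum-assignment
  auxiliary inert — unary value ~0, bias → −∞ — and with it the lifted
  chain loses the auxiliary-locking slowdown that distinguishes it from
  the direct NCC samplers.)  Marginal equality over the auxiliaries is
  exact for any admissible λ and is tested by enumeration; irreducibility
  of the single-flip chain over non-forbidden states is checked by BFS.
* **Blanket expansion (impl2/impl3).**  Per node, 2^{|MB|} auxiliary
  neurons (or branches).  Strong excitatory weight w_exc = 10 +
  (max_x w_x − min_x w_x) per node: the additive margin (10) is the
  suppression of a mismatched auxiliary in log-odds units, and it must be
  added to the *spread* of the coefficients, not their magnitude, because
  a mismatched auxiliary competes with its own bias advantage.  Auxiliary
  bias w_x − N1(x)·w_exc; a lateral-inhibition pool per node enforces at
  most one auxiliary spike per τ (hard constraint in the engine, with a
  uniform tie-break among simultaneous would-be spikers, and a structural
  inhibitory unit recorded in the spec); the principal fires in the same
  time step as its auxiliary.  Dendritic branches use threshold θ = 1,
  direct weights θ/n per matching input, −θ from each inhibitory input,
  and strength β_x = w_x + C with C = 1 + max_x |w_x| subtracted at the
  soma.  A branch encoding the all-zero assignment receives only
  inhibition and carries a tonic drive θ so that it is active by default.
* **Factorized expansion (impl4/impl5).**  Per factor containing the node,
  2^{|scope|−1} auxiliaries/branches with coefficients w_{x,J}; per-branch
  amplitudes w_{x,J} + γ with γ = 1 + max |w_{x,J}|, soma bias −K_k·γ.
  Factors whose scope is the node alone (a root's own prior) contribute a
  constant log-odds term and are folded into the soma bias rather than
  being given a one-unit group; this matches the published resource counts
  and keeps the factorized counts never larger than the blanket counts.

## Biological mode

Implemented for the point-neuron constructions; the dendritic
constructions run in ideal mode only (their biological fidelity would add
shunting dynamics that none of the verification targets exercise).
Membrane potentials are sums of weighted PSP kernels of the presynaptic
spike trains (last spike per synapse); the lateral pool is blocked for
τ − Δt after an auxiliary spike so that a sustained state can refire
seamlessly; evidence is injected as ±50 log-odds units of driving current
on the clamped principal (amplitudes not critical — anything ≫ max |w_x|
pins the state).

Kernels (all causal, engine evaluates the phase from the step after the
spike):

* rectangular — 1 on [0, τ); the theoretically optimal shape, for which
  biological mode coincides with the ideal chain;
* alpha — 2.3·(s/τ_α)·e^{1−s/τ_α}, truncated where the tail falls below
  0.05.  τ_α defaults to τ/(x₂−x₁) where x₁, x₂ are the points where the
  curve crosses the unit amplitude, i.e. the EPSP exceeds the rectangular
  level for exactly one window length;
* plateau — linear rise (2 ms), hold at 1, quarter-sine fall (5 ms),
  support τ.

The strong detection synapses onto auxiliary neurons are modeled at their
saturation ceiling: delivered drive is w·min(ε, 1).  This is the graded
version of the construction's binary gate — the weight encodes *whether*
an input is present, the kernel *when*.  Without the ceiling, a
supra-unit kernel multiplied by the (necessarily large) detection weight
saturates every pool and the network collapses to the all-ones state;
with it, the residual sampling error comes from the rise and tail of the
kernel, giving the observed ordering of the summed KL floor on the ASIA
task: rectangular ~0.007, plateau ~0.04, alpha ~0.12 at 10 s.

## Analysis

Marginals are estimated as time-averages of z_k; clamped RVs are excluded.
KL traces use cumulative-from-start estimates (floored at 1e-9) and binary
KL(correct ‖ estimate) per query RV, optionally summed; a sliding-window
rate estimate is available through the raster export.  Convergence time is
the first time the trial-averaged summed KL falls below a threshold and
stays below — by default for 100 ms; the comparison study uses the
strictest persistence (below through the end of the evidence segment,
right-censored at the segment length), which proved the most stable
against trial noise, with threshold 0.1 over the two query RVs (above the
1/t noise floor that cumulative estimators reach within a 3 s segment).

State extraction from rasters reproduces the chain's internal state
exactly except for the initial window, whose state was set before any
recorded spike (a < 2τ/duration boundary effect).

## Synthetic networks

The generator emulates "arbitrary, less structured" Bayesian networks: an
edge-toggle MCMC over graphs with a fixed node ordering (edges only from
lower to higher index), connectivity of the undirected skeleton preserved,
in-degree capped (default 8), started from the path graph.  Its stationary
law is uniform over the valid graphs, verified by exhaustive enumeration
and a chi-square test at 3 nodes.  CPT rows are symmetric-Dirichlet
(Beta(1,1)) draws clipped to the admissible range.  Defaults follow the
large-network study: 20 nodes, cap 8, 500000 iterations; evidence enters
as a random assignment to 8 nodes drawn from the downstream half of the
ordering.  What these networks do not emulate: real-world CPT structure
(context-specific independence, near-deterministic links), so passing
tests certify the sampling machinery, not robustness to extreme
conditional probabilities beyond the clipped range.

## Known limitations

* Resource counts grow exponentially with blanket/factor sizes; the
  builders refuse blankets beyond a cap (default 12) and point to the
  factorized constructions.  Learned, approximate realizations are out of
  scope.
* Multinomial RVs (winner-take-all population codes) are not supported.
* The convergence-time ratio between the lifted and the ideal sampler
  measures ~5× under this package's defaults; its value depends strongly
  on the rescaling constant λ, which the underlying construction leaves
  open (larger λ slows the lifted chain without bound).
* Exact oracles require enumeration and stop at ~22 RVs.
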