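# Methods

## Model

The simulator tracks an effectively infinite ensemble of neuronal circuits
that share one topology (an undirected simple graph on *n* neuronal loci)
but differ in spiking pattern. Under the product-measure assumption — loci
statistically independent across the ensemble, the analogue of
Hardy–Weinberg — the ensemble state is the firing-probability vector
ρ ∈ [0,1]ⁿ plus a directed weight matrix φ supported on the topology
(φᵢⱼ and φⱼᵢ evolve independently even though the graph is undirected).

With X̄ⱼ = 2ρⱼ − 1, the coupled ODE system is

* mean activity: Yᵢ = Σⱼ φᵢⱼ X̄ⱼ (variance and correlation terms of the
  input are neglected; only mean weights are tracked);
* switching probability: Mᵢ = ½·exp(−Yᵢ²). This is an even function of the
  activity: a neuron driven hard either way is frozen in its state, while a
  naive neuron (Y ≈ 0) switches at ~½. The even form is required by the
  stabilizing-landscape behaviour — loci that are selected *off* must also
  be stabilized by learning (negative input freezes them silent); a form
  monotone in signed Y would leave silent loci maximally noisy and the
  target census could never lock in;
* firing probabilities: dρᵢ/dt = ρᵢ(1−ρᵢ)·sᵢ + Mᵢ(1−2ρᵢ). The switching
  term is the symmetric-mutation limit of the master equation
  dρᵢ/dt = A⁺(1−ρᵢ) − A⁻ρᵢ with A⁺ = A⁻ = Mᵢ: it vanishes at ρ = ½,
  relaxes toward ½ at rate Mᵢ, and disappears when learning drives M → 0;
* weights: Oja's rule dφᵢⱼ/dt = λ·Yᵢ·(X̄ⱼ − Yᵢφᵢⱼ), Hebbian covariance
  growth with Euclidean normalization — the incoming weight norm of a
  driven neuron converges to 1. Weights between co-silent neurons grow
  positive, which acts as inhibition of the pair by the active rest.

### Selection backends

`selection_coefficients` supplies the first-order differential that the
integrator uses by default:

* directional landscape, gradient S (scalar or per-locus): sᵢ = Sᵢ;
* stabilizing landscape W = exp(−β(T−Ω)²), Ω = number of firing neurons:
  sᵢ = β[2(T − Ω̄) + (2ρᵢ − 1)], the gradient of −β[(T−Ω̄)² + Var Ω] with
  Ω̄ = Σρⱼ and Var Ω = Σρⱼ(1−ρⱼ).

The variance gradient (the `include_variance` flag, default on) is the
disruptive term that polarizes loci to 0/1; without it the symmetric
dynamics have no force that singles out exactly T active loci, so the
census behaviour fixes the default. At a polarized equilibrium with M → 0
the only consistent configurations have Ω̄ within ±½ of T, i.e. exactly T
(the nearest integer) loci on — which is why the census is so robust across
seeds.

An exact backend computes the replicator term ρ(1−ρ)(W_on − W_off)/W̄ from
the conditional expectations E[W | xᵢ = ±1] under the product measure, via
the O(n²) on-count convolution (Poisson-binomial). It is the oracle for the
first-order form (their difference vanishes ∝ β as β → 0) and supplies
exact ensemble mean fitness for trajectories and the structural loop. The
directional landscape is normalized as W = exp(S(Ω−n)) so that W ∈ (0,1]
and "relative fitness" is well defined at any S and n.

### Numerical integration

`solve_ivp` (LSODA, rtol 1e-8 / atol 1e-10) over t = 10 000 time units by
default, which is past convergence for all standard configurations; output
times are log-spaced because the dynamics unfold on log time (selective
amplification ~1/S, learning plateau ~1/λ − 1/S, final convergence).
Initial conditions are U[0, 0.01] for every ρᵢ and every directed weight.
The boundary ρ ∈ {0,1} is protected by zeroing outward flow within solver
tolerance; trajectories additionally clip to [0,1] at output. The final
rate-infinity-norm is reported as a convergence diagnostic; exceeding the
tolerance flags the trajectory rather than raising. A fixed-step Euler
re-integration written directly from the equations (`fixtures.euler_oracle`)
cross-validates the solver to 1e-4.

## Synaptic information

The information content of synapse (i, j) is the mutual information between
the two binary neuron states. Conditioning protocol: clamp neuron j on
(ρⱼ → 1) or off (ρⱼ → 0), recompute only the activity — hence the
conditioned switching probability Mᵢ|ⱼ — with all weights frozen and all
other loci at their ensemble values, and relax locus i alone to its nearest
equilibrium (dense sign-scan plus Brent root-finding; the stabilizing
variance term admits several roots and the relaxation starts from the
current state, so the nearest attracting root is the relevant one). The two
conditional firing probabilities and the marginal ρⱼ assemble the joint
table; because conditioning acts only through the activity, φᵢⱼ = 0 gives
identical conditionals and H ≡ 0 exactly, to machine precision.

The cheap path (`mutual_information_approx`) is the closed-form quadratic
expansion of the same computation: the conditional activity shift ±φᵢⱼ
moves Mᵢ by ΔM, the equilibrium responds with gain dρ*/dM from the implicit
derivative of the locus rate, and for weakly coupled binary variables
H ≈ ρⱼ(1−ρⱼ)·Δρ²/(2 ln2 ρᵢ(1−ρᵢ)) bits. It is O(1), proportional to φ²
for small weights (H(2φ)/H(φ) → 4), exactly zero at φ = 0, suppressed when
the focal neuron spikes randomly (M → ½ ⇒ ΔM → 0), and agrees with the
exact path to a few percent in the small-weight regime. Units default to
bits (switchable to nats); the structural loop consumes this path.

Because Oja normalization spreads a unit incoming norm over however many
synapses a neuron has, per-synapse weights — and with them per-synapse
information — are systematically larger in sparse circuits than in fully
connected ones (star vs complete: mean |φ| 0.72 vs 0.45 at n = 6).

## Structural synaptic plasticity

One circuit modification is attempted per Metropolis step (the `joint`
scheduling variant, which applies a synaptogenesis draw plus a full
independent disbanding sweep per proposal, is retained as an option but has
a built-in densification bias — one guaranteed addition per step against
removals gated by R(H) — that no acceptance tilt can counter):

* with probability u (default 0.01) a random rewire: one existing edge and
  one missing edge exchanged uniformly (edge count preserved);
* otherwise a fair coin between
  * synaptogenesis: one unconnected pair drawn with probability ∝ ρᵢρⱼ
    (co-firing pairs favoured; uniform fallback when all ρ vanish), and
  * disbanding: one edge uniformly at random, removed with probability
    R(H) = r_max·exp(−γH), H the synapse's information (mean of the two
    directed assessments). Defaults r_max = 1 (a synapse carrying no
    information is removed whenever attempted) and γ = 50 bit⁻¹. R gives
    informative synapses a proposal-side advantage; at near-deterministic
    equilibria every H → 0 and protection of load-bearing synapses falls
    to the fitness comparison itself, which is the dominant force.

After rewiring, weights are reset to fresh U[0, 0.01] values by default
(`reset-all`; keeping surviving weights and randomizing only new ones is the
alternative policy, and either may also reset ρ), the learning dynamics are
re-equilibrated on the proposal, and the cost-penalized mean fitness
W = W̄·exp(−k·d) (k ≥ 0 per synapse, d edges) enters the acceptance rule.

Acceptance is Metropolis on the fitness ratio: accept with probability
min(1, W_new/W_old), i.e. exp(ln W_new − ln W_old). The additive form
exp(W_new − W_old) is available (`acceptance="literal-exp"`) but is not the
default: with W ∈ (0,1] crushed by the cost factor, its exponent goes to
zero for every move at high cost, the chain accepts everything and drifts
dense — the opposite of the observed cost response. The ratio form keeps
discrimination on all scales, and with it the sweep over k ∈
{0.01, 0.1, 0.5, 1.0} produces monotonically thinning stationary networks,
near-optimal dense solutions at low cost and sparse, sometimes disconnected
circuits at k ~ 1.

A symmetric single-edge-toggle Metropolis sampler (`sample_topologies`) with
a user-supplied fitness table provides the exact stationary reference
π(G) ∝ exp(W(G)) used to validate the acceptance rule; the full proposal
kernel above is deliberately asymmetric (Hebbian-informed) and is not
expected to satisfy detailed balance with respect to that target.

## Selection strength and learnt weights

At the fully learnt symmetric equilibrium the Euclidean normalization pins
the incoming weight norm to 1, so the equilibrium mean |φ| is 1/√(n−1)
regardless of the selection gradient — the dependence of learnt weights on
S is expressed along the *asymptotic approach*: stronger selection
polarizes the ensemble earlier (amplification time ~1/S) and larger |X̄|
drives weight growth at rate ~λ‖X̄‖², so at any fixed horizon weights rank
with S. The selection-strength sweep therefore measures |φ| at the standard
t = 10⁴ horizon with slow learning (λ = 1e-4, n = 12), where every
condition lies in or near that regime; the rank correlation is then strong
and positive (Spearman ρ_s ≈ 0.97, p ≈ 7e-15 in the test configuration).
The learnt *equilibrium point* of ρ is independent of λ, as the suite
checks separately.

## Study conditions and problem sizes

Standard configurations follow the printed settings: the directional
comparison and stabilizing census use n = 20, S = 5 (β = S/2T), λ = 0.001,
complete topology, U[0, 0.01] initial conditions, t = 10 000, with 20 seeds
for the census; the cost sweep uses n = 10, T = 7, S = 10, λ = 0.01. Chain
lengths and replicate counts in the test suite are desk-scaled (220
Metropolis steps × 3 replicates per cost with an 800-time-unit inner
horizon, from an ER(0.5) start so low- and high-cost chains approach their
stationary densities from mid-range); the defaults in `SSPParams`
(2000 steps, inner horizon 2000) are sized for standalone studies. Small
fully connected systems (n ≤ 6) polarize only when β is large enough for
the disruptive variance term to beat residual switching (the tiny-census
test uses β = 2), because the maximal activity — and hence the minimal
switching probability — scales with √(n−1).

## What the tests do and do not show

All inputs are generated by the model itself; there is no external data.
The suite validates the mathematical contracts (oracle enumeration,
independent Euler integration, bisection roots, entropy decompositions,
binomial/χ² nulls) and the qualitative phenomena at desk scale. It does not
address spike-level stochasticity, finite circuit numbers (drift), the
physiological copying mechanism between circuits, or any claim about real
brains; the time unit is abstract. Equation forms follow the contracts
stated above; alternative switching or disbanding forms with the same
monotonicity and boundary behaviour would reproduce the same qualitative
results.

## Known limitations

* The mean-field activity neglects input variance and correlations; for
  very sparse graphs with few active neighbours this underestimates
  fluctuation effects.
* The conditional-information protocol relaxes a single locus; joint
  conditioning of larger sets (whole-network information measures) is out
  of scope.
* Metropolis fitness evaluations are stochastic through the weight-reset
  policy; a chain can linger on a luckily evaluated state. The reported
  stationary summaries average the final 50 recorded steps over replicates
  to damp this.
* The quadratic information approximation degrades for |φ| ≳ 0.5 and very
  polarized states (it remains a valid ranking, which is all the
  disbanding rule needs).
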