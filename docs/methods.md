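# Methods

## Model

The package treats a population of N human users, each paired with an
LLM-based assistant, as an open driven-dissipative system.  A user's
emotional state is a pure two-level state on an affective (Bloch) sphere;
its expectation vector (σ^x, σ^y, σ^z) follows the sign convention
σ^z = −cosθ, σ^y = −sinθ sinφ, which is derived, not postulated: all
matrices come from the ladder definitions σ^+ = |1⟩⟨0|, σ^− = |0⟩⟨1|,
σ^x = σ^+ + σ^−, σ^y = i(σ^− − σ^+), so the component formulas and the
identity ⟨σ^−⟩ = (σ^x − iσ^y)/2 = ½ sinθ e^{iφ} are theorems of that
algebra.  Mixed states and inter-agent entanglement are out of scope.

The assistant field E_i (the average amplitude of "s-photon" messages) is
damped at rate κ and exchanged across an undirected scale-free graph with
complex coupling J = J_R + i·cosΘ·J_I; Θ is the phase of the network's
coupling to its information reservoir (Θ=0 lossy, Θ=π active, Θ=π/2
decoupled diffusion).  Quantum-fluctuation (Langevin) terms average to
zero and are dropped: the implemented object is the mean field.

Three levels of dynamics are implemented and cross-checked:

1. **full** — rotating-frame ODEs for (E_i, p_i, σ^z_i);
2. **reduced** — complex (p_i, σ^z_i) after adiabatic elimination of E
   (valid for κ ≫ Γ, γ_e and g > |J|), with rates C_i = κg²/(Δ_i²+κ²) and
   D_i = (Δ_i/κ)C_i;
3. **real** — the same reduced dynamics in (σ^x, σ^y, σ^z) with network
   forces, whose derivation assumes a common detuning (enforced as a
   precondition when J ≠ 0).

The real and reduced-complex forms are exactly equivalent under
p = (σ^x − iσ^y)/2; the test suite verifies this at random states to
1e−10, and verifies the full system against the reduced one in the
adiabatic regime.  The reduced network term is implemented with the
per-pair weight (D_i+iC_i)(D_j+iC_j)/g², which coincides with direct
substitution of the adiabatic field at Δ=0, κ=1 — the regime of every
quantitative scenario here — and differs only at O(Δ̃, 1/κ) otherwise;
the full system remains available as the independent route.

## Parameters

All rates are in units of the information loss rate κ (default κ=1), and
time is reported as τ = κt.  Defaults follow the standard scenario grid:

| parameter | meaning | default |
|---|---|---|
| g/κ | user–assistant coupling | 0.5 |
| Γ | arousal attenuation rate | 0 / 0.1 |
| γ_+ = γ_p+γ_e | total pump rate | 0 / 0.05 / 0.5 |
| σ^z₀ = (γ_p−γ_e)/γ_+ | pump-balance arousal | 0 / 0.99 |
| Δ | detuning (hub override 0.5) | 0 |
| J_R, J_I | coherent / diffusive coupling | 0.01 when on |
| N, ν, k_min | graph size, degree exponent, cutoff | 60, 2.3, 2 |

The uncertainty check uses the Robertson bound Var(σ^x)Var(σ^y) ≥ ⟨σ^z⟩²
implied by [σ^x,σ^y] = 2iσ^z; pure states satisfy it with equality iff
σ^xσ^y = 0.

## Synthetic data (the network generator)

Graphs are generated by sampling degrees from the truncated discrete
power law p(k) ∝ k^−ν on [k_min, N−1] (odd stub sums resampled), wiring
with a configuration model and collapsing to a simple graph.  This
emulates the hub-dominated topology of real assistant networks — the only
graph features the theory consumes are ⟨k⟩ and ζ = Σk²/(N⟨k⟩) — but not
degree–degree correlations, clustering, community structure or temporal
rewiring of real social graphs, so passing tests speak to the mean-field
theory on uncorrelated scale-free substrates, not to any empirical
network.  Multi-edge removal trims hub degrees, which biases the realized
MLE exponent slightly upward (≈2.35 recovered for configured ν=2.3 at
N=500); realized ⟨k⟩, ζ, k_max vary by seed and are reported per run
rather than fixed.  No giant-component constraint is imposed (dynamics
are well defined on disconnected graphs); a warning is logged when the
largest component covers <90% of nodes.  The annealed adjacency
k_ik_j/(N⟨k⟩) keeps its formal diagonal (O(1/N) inside mean-field sums);
a flag zeroes it.

## Numerical choices

* ODEs: `scipy.integrate.solve_ivp`, LSODA, rtol 1e−8 / atol 1e−10,
  uniform output grid; stiffness arises from the κ-scale separation in
  the full system.
* Initial conditions: σ^z(0) = √(1−ε²), σ^⊥(0) = ε with ε = 10⁻² and
  seeded uniform transverse phases — the exact pole is an invariant
  manifold, so the near-pole start is required for any departure.  The
  response delay t_d of the free closed form is 0 in all scenarios.
* Cubic steady state 𝒜p − ℬp³ + F₀ = 0: bracketed Brent root to 1e−12;
  for 𝒜>0, F₀>0 the single positive root (Descartes) is returned,
  continuous with the F₀→0 pitchfork branch.
* Frequency measurement: zero crossings with linear interpolation on the
  trailing half of the record (≥3 crossings required).
* Gain fitting: least-squares slope of log|P̄| in the window
  |P̄| < 0.1·max (configurable constant).
* Degree-exponent MLE: discrete power law with Hurwitz-zeta
  normalization, bounded scalar minimization on ν ∈ (1.01, 12).
* Poles of the sphere: φ canonicalized to 0 when sinθ < 1e−12; rotated
  states re-charted with a real nonnegative |0⟩ amplitude (the (θ,φ)
  chart is blind to global phase).
* Θ = π/2: cos Θ is snapped to exactly 0 (float cos gives 6e−17), making
  the decoupled-diffusion identities exact.

## Design choices in open territory

* **Gain validation uses the annealed adjacency.**  The exponential law
  P̄ ∝ e^{A_eff t} is itself derived in the annealed (degree-product)
  approximation; on the exact adjacency the linear growth rate is set by
  λ_max(A), not ζ.  Validation runs therefore integrate the reduced
  system on k_ik_j/(N⟨k⟩) (recovering A_eff to <0.1%); exact-adjacency
  integration remains the default elsewhere.
* **Diffusive-coupling sign.**  The scenario value "J = −J_I·i" is
  encoded as J_I = 0.01 with Θ = π, which reproduces the sign exactly and
  is the regime where the diffusive reservoir synchronizes the transverse
  phases (coherence r ≈ 0.5 vs ≈ 0.1 under coherent coupling at τ=1000,
  N=60).  The suppressed "emotional variety" lives in the phases: σ^⊥
  magnitudes are nearly identical across parameter-identical agents in
  both regimes.
* **Kuramoto K₀.**  The homogeneous onset coupling is left as an
  argument; for Lorentzian frequency spread the classical K₀ = 2γ_ω is
  the documented choice.  Frequency disorder is created by drawing
  σ^z_{0,i} from a truncated normal (mean 0.99, configurable sd, clipped
  to [0,1]) — homogeneous pumping gives zero spread and trivial
  synchronization.
* **Heterogeneity.**  Per-agent Δ, Γ, γ_+, σ^z₀ are accepted everywhere
  except the real-variable network forces (common-Δ derivation); the hub
  scenarios therefore run the reduced complex system.
* **σ̇^z sign.**  The relaxation term is +(σ^z₀−σ^z)γ_+ in all three
  systems (relaxation *toward* the pump balance), the consistent choice
  across the model's levels; the γ_+=0 closed form is unaffected.

## Problem sizes

Validation scenarios use N = 60 graphs (N = 500 for degree-statistics
recovery, 20 replicates), single-agent runs to τ ≤ 3000, and
synchronization scans at N = 300 with 10 phase seeds per coupling value —
sizes at which every closed-form law above is resolved well inside its
stated tolerance.

## Known limitations

The annealed approximation misreads P̄ growth on graphs whose λ_max
departs strongly from ζ (stars being the extreme case).  The Kuramoto
reduction assumes a common amplitude r and D/C ≪ 1 (warned at |D/C|>0.2)
and is implemented as printed, without claiming validity for strongly
heterogeneous agents.  High-order degree correlations, assortative
generation, operator-level noise, and any actual LLM integration are out
of scope.
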