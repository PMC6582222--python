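# Methods

## Scope and model chain

The package implements the computation chain that turns per-step free
energies of a stepwise reaction mechanism into kinetics and composed
free-energy profiles, and the simulation chain that produces such free
energies from nonequilibrium pulling work. The concrete system it ships
data for is the adenine→guanine transition (deamination → oxidation →
amination, pathways A/B × C × D/E), in gas and aqueous phase at 298.15 K.

The chain has four largely independent stages:

1. **TST kinetics** (`smdfe.kinetics`). For a step with activation free
   energy ΔG‡ and reaction free energy ΔG (kcal·mol⁻¹, both relative to the
   step's own reactant level):

   K = e^(−ΔG/RT), k_f = (k_B·T/h)·e^(−ΔG‡/RT), ΔG‡_rev = ΔG‡ − ΔG,
   k_r from ΔG‡_rev, τ = 1/k_r.

   Constants are the 2019 SI exact values (k_B = 1.380649·10⁻²³ J·K⁻¹,
   h = 6.62607015·10⁻³⁴ J·s) and R = 1.9872041·10⁻³ kcal·mol⁻¹·K⁻¹. The
   transmission coefficient is fixed at 1; no tunneling or variational
   corrections. Barriers in this system span |ΔG| up to ~80 kcal·mol⁻¹ and
   the derived quantities span ~10⁻⁵⁵…10⁺⁴⁴, so all arithmetic is done in
   log₁₀ space and exponentiated last; K is formed as 10^(log k_f − log k_r)
   so detailed balance holds to rounding. Negative forward or reverse
   barriers (possible after composition or rounding) emit
   `NegativeBarrierWarning` rather than failing.

2. **Profile composition** (`smdfe.profiles`). A profile over n steps has
   2n+1 alternating stationary/transition levels, cumulative from the first
   reactant: TS_i = (previous stationary) + ΔG‡(i), next stationary =
   (previous stationary) + ΔG(i). A pathway concatenates process profiles,
   offsetting each by the level already reached. Global activation energy =
   maximum cumulative TS level; global reaction energy = final level; the
   rate-determining transition state is the argmax (ties broken by earliest
   occurrence, for deterministic output). Process-level kinetics are
   recomputed from the composed ΔG‡/ΔG — no steady-state or master-equation
   kinetics. Values are kept at full precision internally and rounded only
   for display, because the shipped tables' own 0.01 kcal·mol⁻¹ rounding
   already produces visible inconsistencies.

3. **Jarzynski estimation** (`smdfe.jarzynski`). Given works W_i from
   repeated pulls between the same two restrained equilibrium states,
   ΔG = −RT·ln[(1/N)·Σ e^(−W_i/RT)], evaluated via log-sum-exp (stable for
   |W| up to 10⁴ kcal·mol⁻¹). The estimate is bounded above by ⟨W⟩ (Jensen)
   and biased high at finite N. Complements: the second-cumulant estimate
   ⟨W⟩ − s²/(2RT) with the unbiased (n−1) variance, exact in the Gaussian
   (near-equilibrium) limit; a percentile bootstrap (default B = 1000,
   2.5/97.5 percentiles — percentile rather than BCa for simplicity and
   determinism); and a subsample bias curve. All randomness passes through
   one integer seed; there is no global random state. A caveat the test
   suite quantifies: the percentile interval of the exponential estimator
   undercovers slightly (measured 88.5% ± 1.6% at N = 1000 for Gaussian
   works of variance 2RT, essentially all misses caused by the finite-N
   bias sitting above the truth), while the bias-free cumulant estimator
   attains its nominal 95%.

4. **Steered Langevin engine** (`smdfe.engine`). Point particles with
   pairwise LJ(12-6-1) interactions U = A/r¹² − B/r⁶ + C·q_i·q_j/r
   (C = 332.0636 kcal·Å·mol⁻¹·e⁻², the AMBER convention), optional harmonic
   bonds k(r−r₀)² and angles k(θ−θ₀)², direct sums with no cutoff and no
   periodicity; bonded 1-2 and 1-3 pairs are excluded from the nonbonded
   sum. Units: Å, fs, amu, kcal·mol⁻¹. Integrator: BAOAB Langevin
   splitting (exact on harmonic modes, excellent configurational sampling
   at moderate dt); defaults dt = 0.5 fs, γ = 1 ps⁻¹. Fixed atoms are
   implemented by a zero inverse mass. The moving restraint is
   V = ½k(ξ − λ(t))² on a distance or distance-difference coordinate
   ξ, with λ strictly linear in t. Work is accumulated per schedule step as
   ΔW = −k·(ξ − λ_mid)·Δλ with ξ at the moment the restraint centre moves —
   exact for stepwise switching of the restraint, second-order in Δλ as a
   quadrature of ∫(∂V/∂λ)dλ. Ensemble replicas draw per-replica seeds from
   a master `numpy.random.SeedSequence`, so ensembles are reproducible and
   replicas statistically independent. Trajectories that leave |x| > 10⁶ Å
   or go non-finite raise `IntegrationError` naming the step (checked every
   64 steps to keep the hot loop cheap).

Structure I/O (`smdfe.structures`) reads and writes standard XYZ (count
line, comment, `element x y z`), with parse errors carrying line numbers,
and produces interatomic-distance reports. Published geometry narratives
label atoms (O21, C6, H23…) rather than indexing them, so a `label,index`
CSV sidecar (1-based) maps labels to file positions; the mapping is the
user's responsibility because the deposited structures carry no canonical
ordering.

## The shipped tables and their internal consistency

`smdfe.synth.paper_tables()` packages the per-step, per-process and global
activation/reaction free energies of the A→G transition in both phases
(16 labeled rows each), together with the published derived columns
(K, k_f, τ) and per-quantity consistency flags. The ΔG columns are treated
as primary and K/k/τ as derived, since the table formulas declare them so.
Recomputing the derived columns from the ΔG columns reproduces the large
majority within the tolerance that 0.01 kcal·mol⁻¹ rounding propagated
through exp(ΔG/RT) allows (≈5% on K, ≈15% on k and τ, which pass through
the larger ΔG‡). A minority of printed values are internally inconsistent
with their own row's ΔG values (for example a lifetime whose printed
exponent disagrees by ten orders of magnitude with the row's reverse
barrier, or a step rate constant that duplicates its process row); these
carry `False` flags and a note saying what the printed number appears to
be. They are reproduced in the fixture verbatim, not corrected.

Two composition-level quirks are worth knowing. Process rows list as τ the
lifetime of the species the process ends in, i.e. the final step's τ; for
the oxidation and amination processes this coincides algebraically with
1/k_r of the process-level barriers (the process ΔG‡ comes from the second
transition state), for the deamination processes it does not. And the
deamination step rows carry ~0.08 kcal·mol⁻¹ of accumulated rounding
relative to their process row, so `ace_pathway` composes the global pathway
from process-level values by default (`level="process"`); this reproduces
the tabulated global activation energies (74.15 gas, 72.88 solution) to
±0.01 kcal·mol⁻¹, with step-level composition available for full-resolution
profiles.

## Synthetic data and benchmarks: what they do and do not show

`GaussianWorkSpec` draws i.i.d. normal works; its implied free energy
μ − σ²/(2RT) is the exact Jarzynski limit for a Gaussian work distribution
and anchors the estimator tests. Real pulling-work distributions are only
asymptotically Gaussian (slow pulling); the generator does not emulate the
skewed, heavy-tailed distributions of fast pulls, so Gaussian-based
passes say nothing about far-from-equilibrium estimation.

`gen_pull_benchmark` builds two few-atom systems pulled along
ξ = d(p,a₁) − d(p,a₂) between two fixed anchors 7 Å apart:

* **flat** — the mobile particle is bound to both anchors by identical
  harmonic bonds; the system is mirror-symmetric, and the pull window
  (λ: −2 → +2 Å) is symmetric, so ΔF = 0 exactly. (A bare 3-D *distance*
  coordinate would not be flat: its phase-space Jacobian contributes
  −2RT·ln λ.)
* **two_state** — LJ wells of unequal depth (ε = 3.0 vs 1.2 kcal·mol⁻¹,
  r_min = 2.5 Å) on the two anchors; pulling drags the particle from the
  deep to the shallow well. Because a distance-difference isosurface is an
  unbounded hyperboloid, the restrained ensembles would be delocalized
  without confinement; a weak spherical cage bond to a fixed centre atom
  (k = 0.5 kcal·mol⁻¹·Å⁻², r₀ = 1 Å — zero energy at both on-axis wells,
  so it does not bias either endpoint) keeps them localized. The exact
  endpoint ΔF (quadrature of the restrained Boltzmann weight over
  cylindrical (z, ρ), 2801×961 grid) is 1.4606 kcal·mol⁻¹ and was
  cross-checked against an independent 3-D Monte-Carlo integration
  (1.477 ± 0.011).

The default two-state protocol (k = 15 kcal·mol⁻¹·Å⁻², 12 000 steps of
1 fs, γ = 1 ps⁻¹, 1000 equilibration steps) was chosen by a pull-speed
ladder against the exact oracle: it is the speed at which the exponential
estimator's finite-sample bias falls below the statistical width of a
200-pull bootstrap interval, i.e. the near-equilibrium regime the
estimator assumes. Faster protocols on the same system demonstrate,
deliberately, the monotone growth of dissipated work with pulling speed.

These benchmarks validate the mechanics of the chain — forces against
finite differences, symplectic energy conservation in the γ = 0 limit,
equipartition under the thermostat, work bookkeeping against closed forms,
estimator against exact ΔF. They are not a model of the real
nucleobase–water–formic-acid system: no QM, no explicit solvent, no
electrostatics beyond fixed point charges, three atoms instead of dozens.
The shipped A→G energetics enter the pipeline as data, not as simulation
output.

## Numerical choices and degenerate inputs

* Temperature defaults to 298.15 K everywhere; T ≤ 0 is a domain error in
  every thermodynamic formula (the engine alone accepts T = 0 as the
  deterministic limit of the thermostat).
* Empty step lists compose to a domain error; an empty kinetics table
  annotates to an empty table (exit 0 on the CLI).
* Coincident atoms in a nonbonded pair or a reaction coordinate are domain
  errors (the potential and the gradient are singular there).
* Derived table columns are formatted as 3-significant-digit scientific
  notation, mirroring the source tables; full precision is kept internally.
* Profile serialization (`profile_to_table`/`profile_from_table`) is
  lossless and round-trips exactly.

## Known limitations

* TST with unit transmission coefficient: rates for barriers of
  60–80 kcal·mol⁻¹ are formal numbers (10⁻⁴⁰ s⁻¹ scale); their value is in
  ranking steps and phases, not absolute prediction.
* The percentile bootstrap does not correct the exponential estimator's
  bias; for fast pulls the interval can sit entirely above the true ΔG.
  The cumulant estimator is the better-calibrated diagnostic near
  equilibrium.
* The engine is a direct-sum, no-cutoff toy: cost grows quadratically with
  atoms and it is intended for ≲10 atoms.
* One-sided (forward-only) estimation only; no Crooks/BAR, no stiff-spring
  PMF deconvolution.
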