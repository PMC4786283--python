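# Methods

This note documents the modeling conventions, defaults and numerical
choices behind the package, and what its tests do and do not establish.

## Normalized model

A network is a stoichiometric matrix `S` (metabolites × reactions, integer
entries), a reversibility flag and a kind tag per reaction, and a strictly
positive reference flux `vref` with `S·vref = 0`.  Concentrations are
normalized to the reference steady state, x̄ᵢ = Xᵢ/Xᵢ,ss, so the reference
state is the all-ones vector and every affinity constant appears only as
the dimensionless ratio K̄ = K_m/X_ss.  Time is in normalized units (the
reference output flux is O(1)); nothing in the package converts to minutes
or molar.

Rate laws (common modular form):

* irreversible enzymatic, substrates s with multiplicity n_s:

  v = V·∏ₛ(x̄ₛ/K̄ₛ)^{n_s} / [∏ₛ(1+x̄ₛ/K̄ₛ)^{n_s} + Σ_I x̄_I/K̄i_I]

  The inhibitor sum implements competitive inhibition; with two substrates
  this is exactly the random-order bi-substrate glucokinase equation, with
  the G6P term adding one unit to the free-enzyme denominator term.

* reversible enzymatic:

  v = V·[∏ₛ(x̄ₛ/K̄ₛ)^{n_s} − γ·∏ₚ(x̄ₚ/K̄ₚ)^{n_p}]
      / [∏ₛ(1+x̄ₛ/K̄ₛ)^{n_s} + ∏ₚ(1+x̄ₚ/K̄ₚ)^{n_p} − 1 + inhibition]

  Instead of sampling an equilibrium constant directly, each reversible
  reaction carries a reference driving-force ratio ρ ∈ (0,1) and
  γ = ρ·∏ₛK̄ₛ^{-n_s}/∏ₚK̄ₚ^{-n_p}, so the reverse term is exactly ρ times
  the forward term at x̄ = 1.  This guarantees positive net reference flux
  for every draw with no rejection step.  ρ = 1 − thermodynamic
  displacement; ρ → 0 is the irreversible limit.

* `input_exchange`: v = V (a constant-rate feed — perturbing "IN" is
  exactly perturbing the feed rate); `output_exchange`:
  v = V·(x̄/K̄)/(1+x̄/K̄), an irreversible saturable sink.

V_max is never free in constrained mode: V = vref·D(1)/N(1) per reaction,
which makes x̄ = 1 a fixed point to machine precision and is idempotent.

## Sampling

Defaults (the study conditions): K̄ ~ U(0.1, 10) per reaction–metabolite
pair; ρ ~ U(0, 1); K̄i ~ U(0.1, 10); ensembles of n = 1000 with three
replicates for headline fractions.  Unconstrained mode additionally draws
V_max log-uniformly over a 100-fold band centered on the reference flux
(vref·10^U(−1,1)); the band's center is a convention choice — the
reference value is the only distinguished scale in the normalized model —
and its consequences are discussed under Limitations.  Alternative schemes
`all-uniform` and `all-log-uniform` apply one distribution family to every
parameter for sensitivity checks.

Reaction groups (the two phosphoketolase activities at weights ¼ Fpk :
¾ Xpk) receive a single random magnitude split by weight, and continuation
perturbs all group members jointly, so total group activity is one
variable.

Reproducibility: one root seed; each draw gets a `SeedSequence` child
stream, with separate substreams per parameter class so that networks
differing only in a regulation edge draw identical K̄, ρ and V_max under
the same seed — regulated-vs-unregulated comparisons are exactly paired.
Discarded (unstable) constrained draws are counted, so the intrinsic
stable fraction is a by-product of ensemble construction.

## Stability and steady states

Jacobians are central finite differences of S·v(x̄) with step
h = 10⁻⁶·max(x̄ⱼ, 1); the rate laws are smooth rational functions, so this
carries ~8 significant digits (an analytic cross-check for the
Michaelis–Menten sink is in the tests).  Conserved pools (ATP+ADP,
NAD(P)+NAD(P)H, and the MCC sugar-phosphate carrier pool, which is
conserved even in continuous operation) produce exact zero eigenvalues
that say nothing about dynamics: classification excludes up to one
eigenvalue per conserved pool with |Re| < 10⁻⁷ and calls the point stable
iff the remaining leading real part is below −10⁻⁷.  A zero mode *not*
licensed by a conservation law counts as not stable.

Steady states are located by damped Newton iteration on a square system
combining a maximal independent subset of the metabolite balances
(column-pivoted QR row selection) with the conservation constraints
mᵀ(x − x₀) = 0; iterates are clipped at zero with step damping.  On Newton
failure the state is relaxed by stiff integration (LSODA, rtol 10⁻⁸,
atol 10⁻¹⁰) to t = 10⁴ and re-polished.  Convergence means
‖S·v‖∞ < 10⁻⁹; non-convergence is reported honestly in the record, never
raised.  Note that with conserved pools the solution depends on the pool
totals implied by x₀.

## Continuation

Fold grids default to 41 log-spaced points on [0.1, 10] containing 1.0
exactly.  From fold 1 outward in each direction the target V_max is
multiplied, the steady state warm-started from the previous fold, and
stability re-classified; the branch terminates at the first unstable or
lost (non-converged) fold and the boundary is bisected to 10⁻³ in fold.
Unstable branches are not tracked (no pseudo-arclength); "unstable" and
"lost" both end a branch, the latter typically meaning the productive
branch has vanished at a saddle-node.  A dense-grid scan oracle in the
tests confirms bisection folds to within one fine-grid step.

## Batch and fed-batch

Batch conversion sets every exchange V_max to zero (reactions are kept for
bookkeeping), starts all species at their reference value except the
substrate, charged at 200× by default (a convention signifying a single
up-front charge; the value is a config knob and other choices work), and
integrates until the substrate falls below 1% of its charge or t = 10⁴.
Production bookkeeping is mode-independent: production rate = net
formation rate of the product species plus any export flux; cumulative
product = reactor accumulation plus exported amount.  A production
plateau is declared where the rate stays within ±2% of its local mean
over a sliding window of 10% of the run duration; bifurcated runs never
flatten, which is the time-domain signature of a lost pseudo-steady state.
Fed-batch keeps the input exchange on a piecewise-constant multiplier
schedule with the output exchange off; the initial state is x̄ = 1 for all
species (an approximation — real priming proportions are assay-specific).

The unconstrained productivity classifier integrates the continuous system
from x̄ = 1 (LSODA, rtol 10⁻⁶, atol 10⁻⁹, expanding windows to t = 10⁴
with early exit once flat) and calls a member productive iff
‖dx̄/dt‖∞ < 10⁻⁶ at the endpoint and the output flux exceeds 1% of the
reference output flux.  Both tolerances are conventions for "reached a
non-trivial steady state".

## Built-in systems

All eight systems are reconstructed from published pathway descriptions
(schematics, enzyme lists, and the three reversibility rules: ATP-dependent
kinases, strongly exergonic steps (≲ −20 kJ/mol), and decarboxylations are
irreversible) and are tagged `provenance: text-reconstruction`.  Reference
fluxes are the unique (up to the documented phosphoketolase split)
steady-state flux mode normalized to the feed.  Exact facts checked by
arithmetic on the fixtures: MCC converts 2 CH₂O to 1 acetyl-phosphate
(100% carbon); EMP glycolysis makes +2 ATP per glucose ahead of its ATP
drain; the GapN-based chimeric glycolysis is exactly ATP- and NADH-
balanced; the isoprene route converts 3 glucose to 2 isoprene and is
ATP-balanced, with 21 perturbable activities (20 enzymes + feed).  The
mevalonate-route lumping of the isoprene reconstruction (AtoB, HMGS, HMGR,
MK, PMK, MDC, IDI, IspS) is one defensible reading of a 21-variable
system, not a transcription of a published parameter table.

## What the synthetic systems do and do not show

The generator emulates the *structure* of these cell-free systems —
stoichiometry, cofactor coupling, reversibility pattern, reference flux —
with kinetics sampled from broad parameter-free priors.  Passing tests
therefore demonstrate properties of network structure under the stated
rate-law convention, not predictions fitted to any assay: absolute
stable/productive percentages are convention-dependent wherever the
leading eigenvalue is marginal, while orderings and qualitative profile
shapes (which enzyme destabilizes in which direction) are robust across
every convention variant we probed.

## Known limitations

* **Marginal modes make MCC percentages convention-sensitive.**  The MCC
  carrier pool induces a near-zero slow mode; its sign — hence the
  stable fraction of the Xpk-only variant (~9–13% here) and the
  mixed-variant fraction (~91–95%) — shifts substantially under equally
  defensible choices of reversible-denominator form and ρ/K_eq sampling.
  The robust finding is ordinal: the Xpk-only cycle is by far the least
  intrinsically stable system, and most systems hold ≳95–100%.
* **Unconstrained productivity is dominated by capacity coincidences.**
  With every V_max centered on its reference flux, a ~20-enzyme pathway
  almost never satisfies all capacity constraints simultaneously, so the
  measured productive fractions for the isoprene system are near zero and
  the stabilizing effect of glucokinase regulation (which operates by
  damping transient ATP overdraw) is not resolved from a fully primed
  initial state.  Anchoring the random band on the constraint-solved
  V_max raises the fraction to ~10% (each enzyme then carries its natural
  (K̄+1)-fold headroom); we report the centered-on-reference convention
  and flag both numbers as reconstruction-dependent.
* **Batch pseudo-steady agreement is a branch property.**  Charging the
  substrate raises the effective uptake saturation by (1+K̄_substrate);
  members near their bifurcation relax onto a degraded lower-flux
  attractor whose plateau does not match the reference continuous flux.
  Agreement within 5% is demonstrated for branch-retaining members.
* No Hopf/limit-cycle classification (only the sign of the leading real
  part), no multistability enumeration, no SBML import, no thermodynamic
  feasibility analysis beyond the reversibility flags.
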