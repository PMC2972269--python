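# Methods

## Discrete dynamics

Networks are deterministic synchronous Boolean systems: every node
carries one truth table over its ordered inputs, and all nodes update
simultaneously from the time-t state with unit time step.  Truth-table
rows are enumerated with the declared inputs most-significant-first,
from all-zeros (row 0 / line 1) to all-ones; "line 14" of a four-input
table is therefore the input pattern 1101.  Asynchronous and stochastic
update schemes are out of scope.

States are packed into integers (node 0 in the most significant bit),
so integer order equals lexicographic order of the bit vectors.
Exhaustive attractor search builds the full successor table and applies
pointer doubling (f^(2^N) by N squarings); every state's terminal cycle
is then extracted by walking the successor map, and attractors are
canonicalised by rotating the cycle to start at its smallest state.
The exhaustive mode is capped at N = 24 (~16.7M states, configurable);
beyond that, seeded uniform sampling of initial states with
per-trajectory visited-state hashing is used, which detects cycles of
any period.  Basin counts always sum to the number of explored initial
states.

Clamping (the mutant mechanism) holds a node at a constant: it
overrides the node's rule at every step *and* replaces the node's value
in the initial condition, so basin statistics of a clamped model are
taken over the clamp-consistent representatives of all initial states.

## The single-cell SCN rule set

The exact published truth tables of the original study are not
distributed with it; the rules here are a reconstruction constrained to
reproduce the documented attractor tables, basin structure and mutant
behaviours, and the package validates those constraints in its test
suite rather than claiming bit-level identity.  Two reconstruction
choices deserve note:

* **WOX5 self-maintenance.**  A symmetric synchronous mutual repression
  between WOX5 and MGP (or CLEX) would oscillate with period 2.  The
  WOX5 rule therefore carries a self-maintenance disjunct
  (`... AND (NOT MGP OR WOX5)`), which removes the two-cycle while
  preserving the mutual-exclusion steady states.  This makes WOX5 a
  five-input rule (2^5 truth-table rows), which the rule-flip totals
  reflect: Σ 2^(k_n) = 69 for A/A′ and 101 for B/B′.
* **CLEX regulation.**  Nothing constrains the single-cell CLEX rule
  except its attractor pattern (on in CEI, off in QC and CEpI, bistable
  in vascular initials); `SHR AND NOT WOX5 AND (MGP OR CLEX)` is the
  minimal rule with that behaviour.

SCR keeps a declared four-input table (SHR, SCR, JKD, MGP) in every
variant so that A/A′ and B/B′ differ in exactly one output bit.

## Perturbation analyses

*Mutants* clamp one gene per run.  *Rule flips* invert one truth-table
output bit at a time (restoring it afterwards) and compare the
exhaustive attractor **state set** to the wild type — basin sizes do
not enter the classification.  Fractions of attractor-preserving flips
are reported per variant; no external reference value exists for the
reconstructed tables, so the suite asserts structural properties (flip
count, null-flip invariance, fraction strictly inside (0,1)).

*Derrida maps* sample, per initial Hamming distance d, pairs formed by
flipping exactly d distinct seeded-random bits of a uniform random
state, advance both one synchronous step, and record the mean
normalised distance (default 10,000 pairs per class).  The SCN variants
track the identity line within 0.1 for normalised distances ≤ 0.2, the
usual signature of near-critical dynamics.

The engine is cross-validated on the NK random-network ensemble
(inputs without replacement, independent output bias p).  For that
ensemble the exact one-step expectation is
2p(1−p)·[1 − C(N−d,K)/C(N,K)]; the familiar annealed formula
2p(1−p)·[1 − (1−d/N)^K] is its large-N limit.  The cross-validation
compares empirical means against the exact form (3-standard-error
criterion across 100 networks at N = 30, K = 2, p = 0.5) because at
10^4 pairs per class the finite-size gap between the two closed forms
is already resolvable at d = 1.

## Continuous conversion

Each node k becomes dX_k/dt = f[w_k(X)] − γ_k X_k with
f(w) = 1/(1+exp[−h(w − w_thr)]).  The input function w_k is the fuzzy
(Gödel) rendering of the node's rule — AND→min, OR→max, NOT→1−x,
constants→0/1 — which maps [0,1]^N into [0,1] and coincides with the
Boolean rule on corners; rules defined only as tables use their minterm
DNF.  The rendering is a swappable choice; a product algebra would give
the same corner behaviour but different interior geometry.  Defaults
h = 50, γ_k = 1, w_thr = 1/2; steady-state residual tolerance 1e−8;
duplicate roots merged within 1e−4 (sup-norm); `solve_ivp` (LSODA,
rtol 1e−8) for single trajectories and a fixed-step RK4 lockstep
integrator (dt = 0.02, stable since |∂f/∂w| ≤ h/4) for large ensembles
where only the terminal state matters.

Steady states are found by polishing with a Newton–hybrid root finder
from (i) all Boolean corners after a short forward relaxation (which
lands on the stable states), (ii) the cube centre, and (iii) pairwise
midpoints of the roots found so far — midpoint seeds go straight to the
root finder because forward flow would slide off the very saddles they
target.  Stability is classified from central-difference Jacobian
eigenvalue real parts (threshold 1e−6) and corroborated by seeded
perturbed-restart trials; a root is matched to a Boolean attractor only
when it lies within 0.05 (sup-norm) of that corner.

At h = 50 the stable steady states of all four variants round exactly
to their discrete attractor sets, and the count is unchanged across
h ∈ [20, 200].  The A-family models carry an unstable steady state
between CEI and QC with MGP = WOX5 = 1/2 — an exact consequence of the
min/max rendering: at that point w_MGP = 1 − X_WOX5 and
w_WOX5 = max(1 − X_MGP, X_WOX5) both equal the threshold 1/2.
Perturbed restarts (±30% multiplicative, so zero coordinates stay zero)
from that state settle at CEI or QC only.  The fuzzy rendering also
produces unstable roots on *other* basin boundaries — e.g. X_SHR = 1/2
from the autonomous SHR self-copy equation, and a MGP=WOX5=CLEX=1/2
state in the B family — which is inherent to any sigmoidal rendering of
self-sustaining rules; the discrete/continuous correspondence claims
here concern the stable states plus the specifically located CEI/QC
saddle, and steady states are therefore selected by location, not by
count.

## The coupled spatial model

Four positional cells (V, C, Q, E) each run model B′; the only
topological change is that SCR cannot be transcribed in V.  SHR@V,
auxin@V and auxin@C are clamped on, SCR@V off.  Mobility terms
(adjacency V–C, V–Q, C–Q, Q–E, fixed throughout) enter the rules of the
four mobile species only: SHR moves from a neighbour where it is
present and SCR absent; auxin flows acropetally V/C→Q→E; WOX5 represses
Aux/IAA locally (the activator arm) and activates CLEX in every cell
except the QC; CLEX inhibits WOX5 through an OR over all four cells
(the long-range inhibitor arm); CLEX is structurally silent in the QC.
All 40 variables update synchronously, movement terms reading time-t
values.

Because SCR requires itself, simulations use an initialisation
convention: non-clamped SCR variables are forced on at t = 0 and t = 1
and then released — the Boolean stand-in for basal SCR expression.
Under it, seeded sampling of initial states (100,000 by default; the
2^40 space is beyond explicit enumeration) always reaches one global
fixed point with V=vascular, C=CEI, Q=QC, E=CEpI; without it SCR never
bootstraps, which is reported as a prediction-relevant behaviour, not a
bug.  Spatial mutants clamp one gene in all four cells and by default
merge the attractor sets obtained under both convention settings (the
CEpI-plus-ectopic-SHR outcome of the SHR gain exists only when SCR may
start off); any comparison against the wild type is made under a single
convention on both sides, since the convention-off regime is massively
multistable for mutant and wild type alike.  The continuous spatial
check integrates the 40-variable ODE from seeded random interior points
with SCR levels started at 1 and verifies that every run rounds to the
discrete global attractor.

## Synthetic data

The NK generator draws, per node, K distinct inputs (self-inputs
allowed) and an independent Bernoulli(p) output column, from an
explicit integer seed; identical seeds give identical networks.  It
emulates the degree-regular, statistically homogeneous ensembles used
for criticality analysis and deliberately does **not** emulate real
GRN features — scale-free degrees, canalysing functions, correlated
rules — so passing the ensemble checks validates the *engine*, not any
biological claim.  All stochastic operations in the package take
explicit seeds; there is no hidden global RNG state.

## Problem sizes and defaults

Exhaustive analyses run over 512 (A/A′) and 1024 (B/B′) states; rule
flips re-enumerate the full space per flip (69/101 flips).  Derrida
curves use 10,000 pairs per distance class; the ensemble
cross-validation uses 100 networks × 100 pairs per class.  Saddle
stability uses 1000 restarts.  Spatial uniqueness uses 100,000 sampled
initial states, spatial mutants 20,000 per convention, and the
continuous spatial check 100 starts.  The pipeline's defaults scale the
spatial sample to 10,000 for interactive runs; all sizes are arguments.

## Known limitations

* The rule set is a constrained reconstruction, not the published
  truth tables; quantities that depend on the literal tables (e.g. the
  published rule-flip percentages) are not reproduced, only their
  structural properties.
* Graded auxin levels, auxin transport/PIN gradients, cell division
  and growth, and dynamically emerging (rather than pre-specified)
  mobility are not modelled.
* The Boolean-limit equivalence is verified at finite steepness
  (h = 50); it is a numerical observation here, not a proof, and the
  continuous systems possess additional interior saddles by
  construction.
* Global-attractor uniqueness of the meta-GRN is established by
  sampling, not enumeration of all 2^40 states.
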