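# rootscn

Dynamic gene-regulatory-network (GRN) models of the *Arabidopsis
thaliana* root stem-cell niche (SCN): a synchronous Boolean engine, four
alternative single-cell SCN models, mutant / rule-perturbation /
Derrida robustness analyses, a logistic-ODE continuous counterpart, and
a four-cell coupled spatial meta-GRN with mobile regulators.

## The scientific problem

The root tip of *A. thaliana* harbours a stem-cell niche: a quiescent
centre (QC) of rarely dividing organiser cells surrounded by initials
that found the root's cell lineages — vascular initials,
cortex/endodermis initials (CEI) and columella/epidermis initials
(CEpI).  Two molecular modules pattern the niche: the SHR/SCR radial
module (SHR, SCR, JKD, MGP) and the auxin readout pathway (auxin ⊣
Aux/IAA ⊣ ARF → PLT), linked through WOX5, the QC identity gene.  This
package asks, with executable models, whether the known interactions
suffice to recover the observed cell-type expression profiles, how
robust those profiles are, and whether cell-to-cell movement of a few
regulators can pattern the whole niche from arbitrary initial
conditions.

## The models

Each gene is a Boolean variable updated synchronously,

x_n(t+1) = F_n(x_{n₁}(t), …, x_{n_k}(t)),

so every trajectory in the finite state space Ω = 2^N ends in an
attractor — a fixed point or cycle — identified with a cell type's
expression profile.  Four rule-set variants are shipped: in models
**A/A′** WOX5 and MGP repress each other; in **B/B′** WOX5 is instead
repressed by the hypothetical CLE-like gene *CLEX* (a tenth node).  The
primed variants flip a single SCR truth-table bit (line 14: SHR=1,
SCR=1, JKD=0, MGP=1), making SCR transcription independent of JKD.
Mutants are simulated by clamping a node to 0 (loss) or 1 (gain) from
t = 0 onward.

The continuous counterpart replaces each rule by
dX_k/dt = f[w_k(X)] − γ_k X_k with the logistic activation
f(w) = 1/(1+exp[−h(w − w_thr)]) and a fuzzy rendering of the rule
(AND→min, OR→max, NOT→1−x); defaults h = 50, γ = 1, w_thr = 1/2.  The
spatial model couples four copies of model B′ (cells V, C, Q, E — one
per attractor) through mobility-augmented rules for SHR, auxin, WOX5
and CLEX, realising a local-activator (WOX5) / long-range-inhibitor
(CLEX) motif.

## Worked example

```python
from rootscn import build_scn_model, find_attractors, to_continuous, find_steady_states
from rootscn.models import reference_profiles, label_attractors

model = build_scn_model("A")                      # 9 nodes, 512 states
aset = label_attractors(find_attractors(model), reference_profiles("A"), model)
for a, basin in zip(aset.attractors, aset.basin_counts):
    print(f"{a.label:<10}", "".join(map(str, a.states[0])), f"basin={basin}")

steady = find_steady_states(to_continuous(model, h=50.0))
print("stable steady states:", sum(1 for s in steady if s.stable))
```

prints

```
CEpI       111000000 basin=256
vascular   111010000 basin=160
QC         111011101 basin=42
CEI        111011110 basin=54
stable steady states: 4
```

Reading: exhaustive search over all 512 initial states finds exactly
four fixed points, matching the QC, vascular, CEI and CEpI expression
profiles (node order PLT, auxin, ARF, Aux/IAA, SHR, SCR, JKD, MGP,
WOX5).  Exactly half the state space (256 states — those starting with
SHR off) drains into CEpI.  The ODE version recovers the same four
profiles as its stable steady states; between CEI and QC it also has an
unstable steady state with MGP and WOX5 at half activation (0.5), from
which perturbed trajectories fall to either CEI or QC.

The same analyses are available from the shell:

```sh
scn attractors --variant B_prime
scn mutants --variant B_prime --out mutants.csv
scn derrida --variant A --pairs 10000 --seed 42 --out curve.csv
scn continuous --variant A --h 50 --out steady_states.json
scn spatial --samples 100000 --seed 7 --out pattern.json
scn pipeline --variant B_prime --seed 1 --out-dir results/
```

## Layout

| module | contents |
| --- | --- |
| `rootscn.network` | synchronous Boolean engine: rules, clamping, trajectories, exhaustive/sampled attractor and basin analysis |
| `rootscn.expr` / `rootscn.io` | rule expression dialect, truth-table TSV dialect, SBML-qual export |
| `rootscn.models` | the four SCN variants, reference profiles, validation, PINX/QC46 marker extension |
| `rootscn.perturbation` | mutant clamps, single-output rule-flip scan, Derrida map |
| `rootscn.continuous` | logistic-ODE conversion, steady states, stability analysis |
| `rootscn.spatial` | the 40-variable four-cell meta-GRN, spatial mutants, continuous spatial check |
| `rootscn.synthetic` | seeded NK random Boolean networks and closed-form Derrida oracles |
| `rootscn.cli` | the `scn` command-line tool and the reproducible pipeline |

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
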