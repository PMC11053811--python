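# demicell

Reactive coarse-grained molecular dynamics of amphiphilic copolymer
micelles that disassemble by trigger-activated head-to-tail
depolymerization, with the complete analysis stack for micellization,
demicellization and cargo-release kinetics.

## Who this is for

Polymer physicists and drug-delivery modellers studying **degradable
polymeric micelles**: self-assembled aggregates of amphiphiles whose
hydrophobic blocks carry a labile end-cap. A small hydrophobic *trigger*
molecule removes the end-cap; the exposed chain end then depolymerizes
spontaneously, monomer by monomer, until the chain loses its hydrophobic
content, leaves the micelle, and releases the encapsulated cargo. The
package lets you compare amphiphile architectures — the linear diblock
A30B30 and the miktoarm stars A30(B15)2 and A30(B10)3, with one, two and
three end-caps respectively — under different trigger doses and reaction
probabilities.

## Model

Bead-spring chains of Lennard-Jones beads (all beads: m = 1, σ = 1,
implicit solvent, reduced units, τ = √(mσ²/ε)):

* non-bonded pairs: cut-and-shifted Lennard-Jones
  `U(r) = 4ε_ij[(σ/r)¹² − (σ/r)⁶ − (σ/r_c)¹² + (σ/r_c)⁶]`,
  r_c = 2^(1/6) σ for repulsive pairs (anything involving the hydrophilic
  A bead), r_c = 2.5 σ for attractive hydrophobic pairs. Attraction
  strength is set by an effective pair temperature: ε_ij = 1.8/T*_ij with
  the thermostat at k_BT = 1.8 ε, so lower T*_ij means deeper wells;
* bonds: FENE springs (k = 25 ε/σ², R0 = 1.5 σ) composed with a repulsive
  WCA core (Kremer–Grest);
* dynamics: BAOAB Langevin integration at T* = 1.8, dt = 0.006 τ,
  friction γ = 1/τ, periodic cubic box at bead concentration Φ = 0.12;
* reactions: a bond between an end-cap and its B neighbour breaks with
  probability RP_T per sweep while a trigger bead is within 1 σ of the
  end-cap; afterwards the terminal hydrophobic bond of that branch breaks
  with probability RP_B per sweep — strictly head-to-tail;
* analysis: micelles are chain clusters under the Stillinger criterion
  (any inter-chain nonbonded hydrophobic bead pair within 1.5 σ,
  periodic images included), with mass distributions P(N), preferential
  aggregation number N_p, gyration tensor metrics (⟨R_g²⟩, shape
  anisotropy κ²), cargo encapsulation/loading capacity, tracer
  autocorrelation, MSD exponents, and Korsmeyer–Peppas release fits
  M_t/M_∞ = k tⁿ on the initial 60 % of the release curve.

## Worked example

```python
import numpy as np
from demicell import (assemble_system, build_interaction_table,
                      SimulationProtocol, step_langevin, insert_triggers,
                      stillinger_clusters, encapsulation_report)
from demicell.reactions import (ReactionParams, ReactionHook,
                                DepolymerizationLedger, ledger_fractions)

# 20 linear chains + 40 cargo trimers at Phi = 0.12, strong cargo attraction
state = assemble_system({"A30B30": 20, "C3": 40}, phi=0.12, seed=11)
table = build_interaction_table({"B-C": 1.4, "C-C": 1.4})
proto = SimulationProtocol(n_pushoff=0, n_equil=0, n_prod=0)

step_langevin(state, proto, 3_000, seed=7, table=table.pushoff_copy())
step_langevin(state, proto, 50_000, seed=8, table=table)

clusters = stillinger_clusters(state)
report = encapsulation_report(state, clusters)
print(sorted(clusters.sizes.values()), round(report.frac_encapsulated, 2),
      round(report.loading_capacity, 1))

# trigger-activated depolymerization (4 triggers per chain)
state = insert_triggers(state, 80, seed=5)
params = ReactionParams(rp_t=1e-2, rp_b=1e-1, attempt_every=1)
ledger = DepolymerizationLedger.from_state(state)
hook = ReactionHook(params, ledger)
step_langevin(state, proto, 60_000, seed=9, table=table, reaction_hook=hook)
print([round(f, 2) for f in ledger_fractions(ledger)])
```

Output:

```
[19] 0.72 7.1
[0.9, 0.9]
```

Nineteen of the 20 chains assembled into one micelle (one chain is
free); 72 % of the cargo trimers sit in the micelle, a loading capacity
of 7.1 % w/w — close to the 7.6 % of the corresponding full-scale
mixture. After 60 000 reactive steps 90 % of the end-caps are removed
and 90 % of all hydrophobic beads have depolymerized: the micelle is
largely degraded.

A configuration-file driven pipeline (assembly → protocol → triggers →
reactions → analyses, with a manifest for byte-reproducibility) is
available both as `demicell.run_experiment` and as the `demicell` command
line (`build`, `run`, `analyze`, `kinetics`, `reproduce-figures`).

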