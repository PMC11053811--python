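# Methods

## Model

Amphiphiles, cargo and triggers are bead-spring molecules of identical
Lennard-Jones beads (m = 1, σ = 1; energies in ε, time in τ = √(mσ²/ε);
solvent implicit). Species:

| species    | layout                                   | end-caps |
|------------|------------------------------------------|----------|
| A30B30     | 30 A beads — 29 B beads — 1 end-cap      | 1        |
| A30(B15)2  | 30 A arm, two 15-bead hydrophobic branches joined at the last A bead | 2 |
| A30(B10)3  | 30 A arm, three 10-bead branches         | 3        |
| C3         | three hydrophobic C beads                | 0        |
| T          | one hydrophobic trigger bead             | 0        |

The miktoarm junction is the free end of the A arm (the conventional
star-copolymer topology; the junction bead is not otherwise special).
The end-cap is chemically labile but interacts exactly as a B bead.

### Interactions

Pairs interact through the cut-and-shifted Lennard-Jones potential; the
shift terms make U vanish continuously at the cutoff. Pairs involving
the hydrophilic A bead (and the inert X tag that consumed triggers or
optionally detached monomers receive) are purely repulsive:
r_c = 2^(1/6) σ, ε = 1. Hydrophobic pairs (B–B, B–C, C–C, T–T, B–T,
T–C) are attractive with r_c = 2.5 σ and a well depth set through an
effective pair temperature, ε_ij = k_BT / T*_ij with the thermostat at
k_BT = 1.8 ε. Lowering T*_ij below 1.8 therefore deepens the well —
T*_BC = 1.4 gives ε_BC ≈ 1.29 — which is the reading under which
"lower pair temperature" means "more attractive"; the mapping can be
inverted with `invert_eps_mapping` for sensitivity studies. Bonds are
FENE springs (k = 25 ε/σ², R0 = 1.5 σ) plus a repulsive WCA core, the
standard Kremer–Grest composition (bonded pairs are excluded from the
long-range pair sum); a bond reaching R0 aborts the run — it signals an
integration or parameter error, not a physical event.

### Dynamics

BAOAB-split Langevin dynamics at T* = 1.8, dt = 0.006 τ, in a periodic
cube with edge L = (N/Φ)^{1/3}, Φ = 0.12. The friction γ defaults to
1 τ⁻¹; it is not part of the physical model, so absolute times are
meaningful only relative to the diffusive scale set by γ, and all
kinetic comparisons in this package are made between runs at identical
γ. With γ = 0 the scheme reduces to velocity Verlet (the NVE
conservation test exploits this). Neighbour search uses a cell list
with a 0.8 σ Verlet skin, rebuilt when any bead has moved half a skin;
reactions force a rebuild because they change the exclusion list.

At dt = 0.006 the kinetic-temperature estimator carries a small
finite-timestep bias (measured ≈ −0.5 % on dense bonded systems,
vanishing at dt = 0.003); thermostat checks therefore average ~200
decorrelated samples so that sampling error does not compound it.

### Protocol

Three stages, after random-walk insertion of molecules (bond length
0.97 σ, soft overlap tolerance with 0.8 σ target clearance):

1. **push-off** — every cutoff collapsed to 2^(1/6) σ and the pair force
   capped at 200 ε/σ, which relaxes insertion overlaps smoothly and
   removes initial-configuration bias;
2. **equilibration** — full interaction table;
3. **production** — snapshots collected; reaction sweeps interleave here
   when triggers are present.

### Reactions

Depolymerization is a two-step stochastic process performed in sweeps:

* *end-cap scission*: every intact end-cap bond whose end-cap bead has
  at least one active trigger within R_cutoff = 1 σ (minimum image)
  breaks with probability RP_T — one Bernoulli draw per bond per sweep
  regardless of how many triggers are in range. On success the nearest
  participating trigger is consumed (retagged X) by default, so a
  stoichiometric dose acts at most once per end-cap; consumption can be
  disabled.
* *propagation*: once a branch has lost its end-cap, its terminal
  hydrophobic bond breaks with probability RP_B per sweep, one monomer
  at a time, through to the junction bond with the A arm. A branch with
  an intact end-cap never propagates; at most one bond per branch can
  break per sweep.

Each break frees exactly one hydrophobic bead, so the branch has 30
scissile bonds per chain for every architecture and the broken-bond
fraction equals the depolymerized-bead fraction: the ledger quantities
1 − [ec]_t/[ec]_0 and 1 − [B]_t/[B]_0 are bond counts and bead counts
at once. Detached monomers keep their hydrophobic identity by default
(`detached_bead_fate="keep_type"`); the `"inert"` option retags them X.
The sweep cadence (`attempt_every`, default every 100 steps) rescales
absolute rates only; comparisons between architectures are always made
under identical cadence.

## Analysis

* **Micelles** — two chains share a micelle when any nonbonded
  inter-chain hydrophobic bead pair is within 1.5 σ (Stillinger
  criterion). Implemented as connected components of the bead contact
  graph (periodic k-d tree) projected onto chains, which is equivalent
  to density-based clustering with a 1.5 σ neighbourhood and minimum
  two points. Chains are identified as connected components of the
  bond graph, so detached monomers (bond degree 0) never participate,
  and a chain stripped of all bonded hydrophobic beads is FREE. Cargo
  molecules join micelles through the same contacts but do not count
  toward the aggregation number N.
* **Mass distribution** — P(N) is chain-weighted over micellized chains
  only; N_p is the mode, ties resolved toward smaller N.
* **Shape** — micelles are unwrapped across periodic boundaries along a
  spanning tree of the bond-plus-contact graph before any gyration
  calculation (unique up to a lattice translation; a warning is issued
  for aggregates larger than half the box, where unwrapping is
  ambiguous). R_g² and κ² are computed over copolymer beads only so
  micelles of equal N compare at equal molecular weight.
* **Encapsulation** — a cargo molecule is encapsulated when any of its
  beads is within 1.5 σ of a hydrophobic bead of a micellized chain.
  Loading capacity is the w/w percentage of cargo mass over total
  carrier mass. Snapshot series use ten-block averaging.
* **Kinetics** — tracer autocorrelation C(t) of per-chain micelle sizes
  over all chains and time origins, with t_relax at the 1/e crossing;
  origin-averaged MSD with the exponent fitted on the last temporal
  decade (the analytic free-Langevin MSD 6D(t − 1 + e^{−t})/... has
  local slope above 1.05 until t ≈ 20/γ, so windows must sit beyond the
  transient); release fraction = initially-encapsulated cargo currently
  free over initially encapsulated (re-entry lowers it); and a
  Korsmeyer–Peppas fit M_t/M_∞ = k tⁿ by nonlinear least squares on the
  untransformed curve truncated at M_t/M_∞ ≤ 0.60, seeded by a log-log
  linear fit. 0.45 < n < 1 is labelled non-Fickian.

## Desk-scale study conditions

The reference conditions (1000 chains, 2000–4000 cargo, 10⁸-step
production) are far beyond a single core, so `demicell.scenarios`
defines a desk scale used by the qualitative checks and the acceptance
script, chosen once:

* 20 chains, 2 cargo trimers per chain (the 1000:2000 ratio), Φ = 0.12;
  trigger doses keep the reference ratios — stoichiometric = one per
  end-cap (20/40/60), constant = four per chain (80);
* stages 3 000 / 50 000 / 60 000 steps, snapshots every 5 000; reactive
  runs 100 000 steps;
* two uniform clock compressions for the reaction kinetics: sweeps every
  integration step, and both reaction probabilities scaled by 100
  (RP_T 10⁻⁴ → 10⁻², RP_B 10⁻³ → 10⁻¹). The compression preserves the
  regime RP_T ≪ RP_B (end-cap removal rate-limiting) and is identical
  across architectures, so orderings and dimensionless fractions are
  unaffected while absolute times shrink into the run length.

What the desk scale does and does not show: encapsulation fractions and
loading capacities are intensive and land close to the full-scale
values; architecture *orderings* of depolymerization and release are
mechanistically driven (trigger dose, parallel branch fronts) and
reproduce on average, but a 20-chain box has only 20–60 end-caps and a
handful of micelles, so any single seed carries visible configuration
noise, and the preferential aggregation number N_p is a mode over few
micelles with unit granularity. Fine distinctions printed at full scale
(e.g. a 30 % versus 35 % N_p rise between the two- and three-branch
stars) are below this resolution and are not asserted by the test
suite. Finite-size effects known at full scale (aggregation numbers
converge only above ~1000 chains) apply here too: desk N_p values are
not quantitative predictions.

The synthetic initial configurations emulate composition, density and
connectivity of the study mixtures but none of the chemistry of real
poly(benzyl-ether) systems: passing tests demonstrate correctness of
the algorithms and reproduction of the model's qualitative physics, not
agreement with any experiment.

## Numerical choices

* ε mapping from pair temperatures: ε_ij = 1.8/T*_ij (see above), the
  inverse available as a flag.
* Push-off force cap 200 ε/σ; without it, random-walk insertion
  overlaps can overstretch FENE bonds in the first few steps.
* Degenerate inputs are first-class errors: zero-variance tracer series,
  all-zero release curves, MSD of static beads, fits with fewer than
  five usable points, and systems without end-caps all raise typed
  exceptions rather than returning NaN.
* Tie-breaks: N_p ties go to the smaller N; when several triggers are in
  range of one end-cap the nearest is consumed; two end-caps competing
  for the last in-range trigger in one sweep are processed in branch
  order and the loser's scission is forgone.
* Determinism: every stochastic stage takes an explicit seed; the
  experiment runner derives named substream seeds (assembly,
  micellization, triggers, reactions) from one experiment seed so
  toggling a stage does not perturb the others; rerunning a spec
  reproduces output bundles byte for byte.

## Known limitations

* Absolute kinetic time axes depend on the Langevin friction and on the
  desk clock compressions; only orderings, fractions and ratios are
  comparable across scales.
* The truncated attractive potential has a force step at 2.5 σ; NVE
  energy is conserved to the integrator's accuracy only with the smooth
  WCA table (the drift check uses it), while thermostatted runs are
  unaffected.
* Dump-file-based analysis reconstructs bonds heuristically from
  consecutive intra-molecule distances (the dump dialect carries no
  topology); in-memory pipelines and data files carry exact topology.
* No pressure coupling, electrostatics, or explicit solvent; reverse
  (repolymerization) reactions and reactions among cargo are out of
  scope.
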