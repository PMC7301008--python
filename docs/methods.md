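# Model and methods

## Overview

`hextissue` simulates heterogeneous populations of tissue-cell agents on
a hexagonal grid coupled to triangular reaction–diffusion lattices for
glucose, oxygen and TGFα.  One scheduler tick represents one simulated
minute; diffusion and the intracellular ODEs run on 1-second sub-steps
(60 per tick).  Cell behavior emerges from a seven-state rule engine
(apoptotic, necrotic, quiescent, migratory, proliferative, senescent,
undecided) driven by two interchangeable subcellular modules:

* a **metabolism module** that converts local glucose and oxygen into
  ATP and cell mass through glycolysis and oxidative phosphorylation,
  at four complexity levels (complex / medium / simple / random);
* a **signaling module** that reduces an EGFR/TGFα/PLCγ network to 12,
  7 or 4 species (or a random coin flip) and decides between migration
  and proliferation from the per-tick fold change Δ of active PLCγ
  against the migratory threshold θ.

## Environment

The grid has radius R (agents occupy rings 0..R−1) plus a margin of M
hexes that carries lattice sites but no agents.  Hexagons are 30 μm
side-to-side and 8.7 μm tall; each owns six triangles of the molecule
lattices (Δs = 15 μm).  Every margin triangle is clamped to the
far-field concentration after each diffusion sub-step, modeling
vasculature exchange at the tissue boundary: glucose (5 mM) and oxygen
(100 mmHg) are supplied, while TGFα is clamped at its far-field level
(0.05 nM) so the boundary only *clears* cell-secreted growth factor and
never stimulates an empty environment.  Without this clearance term
TGFα accumulates without bound in any growing colony and the
migration/proliferation balance drifts over the whole simulation.

The explicit finite-difference stencil is used per molecule when the
von Neumann number λ = 4DΔt(1/Δs² + δ/Δz²) is below 1 (TGFα, D = 51
μm²/s, λ ≈ 0.91) and the pseudo-steady neighbor-average approximation
otherwise (glucose and oxygen).  Out-of-lattice neighbors are mirrored
(zero flux), so a closed lattice conserves mass exactly.

A location admits a new agent when (i) the summed agent volume stays
below the location capacity, (ii) every occupant remains below its own
crowding tolerance (MAX_HEIGHT), (iii) at most six agents share the
location, and (iv) at most one healthy-class (H) agent is present.
The capacity uses a 17.4 μm packing ceiling — twice the default cell
height — deliberately larger than the 8.7 μm nutrient-exchange height:
if both were equal, the per-agent tolerance could never bind and a
+50% crowding-tolerance phenotype would be inert.  The nutrient volume
of a location (for converting concentrations to amounts) remains
area × 8.7 μm ≈ 6.8 pL.

## Cell rules

Per tick each cell: ages and samples age-dependent apoptosis
(Φ((age−avg)/range) per tick); runs metabolism; checks energy — a
deficit (E < 0) sends active cells into quiescence, and a deficit
sustained longer than ENERGY_THRESHOLD minutes triggers necrosis (with
probability NECRO_FRAC, apoptosis instead); runs signaling, and — if
undecided — commits to migration (Δ > θ) or proliferation (Δ ≤ θ);
finally checks the replicative limit (DIVISION_POTENTIAL), branching to
senescence or apoptosis by SENES_FRAC.

Delayed actions are helper agents: migration completes after
HEX_SIZE/MIGRA_RATE minutes and moves the cell to the argmax of the
location score S = α(R−r+1)/2 + (1−α)[βG/G° + (1−β)u]; division is
re-checked every tick and fires once the cell has doubled its mass
(2·m_crit, metabolism-driven) and accumulated SYNTHESIS_TIME minutes of
S-phase progress — progress survives brief quiescent interruptions (a
transient energy dip does not undo DNA synthesis) and is reset only by
the completed division, which splits volume and module contents
50% ± 5% between parent and daughter; apoptotic removal fires after
DEATH_TIME and stimulates one quiescent neighbor to proliferate
(compensatory proliferation).  Necrotic cells keep occupying space but
are never stepped again.  Quiescent cells of populations allowed to
exit quiescence unstimulated re-test the contact-inhibition constraint
every 30 ticks (a cost/responsiveness compromise) and re-enter the
undecided state when energy is restored and space is available.

The R in the migration score is interpreted as the environment radius
(making α an affinity for the colony center); the printed variable
definitions are ambiguous between the environment radius and a
cell-distance, and the environment-radius reading gives the score a
fixed scale.

The migratory threshold operates on per-minute PLCγ fold changes, which
for a smoothly integrated ODE network sit very close to 1; the default
θ = 1.0001 lies in the middle of the observed Δ−1 distribution
(10⁻⁵–10⁻³, roughly log-uniform), so threshold modifications act on a
meaningful scale.  A −100% modification (θ = 0) makes every decision
migratory and abolishes proliferation, as expected for this limit.

## Metabolism

Stoichiometry is fixed: 2 ATP/glucose (glycolysis), 15 ATP/pyruvate
(oxphos), 2 pyruvate/glucose, 3 O₂/pyruvate — at most 32 ATP per fully
oxidized glucose.  The per-tick pipeline runs availability → demand →
glucose uptake → requirements → energy generation (oxphos, then
glycolysis with hypoxic compensation for complex/medium) → energy
update → mass generation → autophagy → cell/environment update.  Only
deficits carry over into the next tick's requirement; a surplus is not
a requirement.  Autophagy triggers under a deficit (down to
MIN_MASS_FRAC·m_crit) or to trim non-proliferating cells back toward
m_crit.  Because the requirement-driven pathways balance supply against
demand exactly, sub-femtomole round-off in the energy balance is
snapped to zero so it is never read as a deficit.

The complex variant's uptake scales with the surface area of a
cylindrical cell of height MAX_HEIGHT/2 (A = 2πrh + 2πr²), a proxy for
receptor count.

## Signaling

The ODE systems follow the three printed network reductions; regulatory
edges enter as saturating weights w = 1 ± X/(W + X).  Regulator wiring:
internal glucose → w_G (+, phosphorylation/uptake support), active
PLCγ → w_C (+ on the receptor dephosphorylation / uptake-reverse path,
i.e. net negative feedback), phosphorylated receptor complex → w_P
(+, PLCγ activation) and, in the complex network, → w_E and w_T
(+, transcription).  Rate constants are of order 10⁻⁴–10⁻² s⁻¹ so that
the receptor/transport pools settle within hours while the PLCγ pair
relaxes over ~10 minutes; the PLCγ pair (X₃+X₄, X₆+X₇ or X₁₀+X₁₁,
normalized to 1 nM) and the complex network's nucleotide pool
(X₈+X₉+X₁₂ = 10 nM) are conserved by construction for any rates.
Forward Euler would go unstable only for rates approaching 1/Δt = 1/s;
species are clamped at zero if a step undershoots.

## Default parameters and calibration

Physical constants are taken from standard physiology: glucose 5 mM and
oxygen 100 mmHg at the vasculature, oxygen solubility 1.3·10⁻⁶
fmol/(μm³·mmHg), diffusivities 110 / 2000 / 51 μm²/s for glucose,
oxygen and a ~17 kDa protein in tissue (glucose and oxygen fall in the
pseudo-steady regime, where the relaxation update is independent of the
exact diffusivity), cell density 1.07 pg/μm³,
initial volume 2250 ± 200 μm³, lifespan 12 ± 1 weeks, 50-division
replicative limit, 637 min S-phase.

The remaining rate-type parameters (uptake and growth kinetics, energy
demand, migration rate and threshold, the chemotaxis weights α and β)
have no single literature value; they were calibrated **once, jointly**
so that the default colony — a single seeded agent at the package's
reference scale R = 14, M = 4 — reproduces the canonical growth
benchmarks for epithelial-like tumor cells: early exponential growth
(r² ≈ 0.98 over the first week), population doubling ≈ 30–35 h
(count-based and exponential-fit), a 16–24 h cell cycle, linear
diameter growth near 1.45 μm/h, and a day-14 colony with an inactive
core and an active rim a few hexes wide.  The calibration is a property
of the defaults file, not of any individual experiment; all case-study
scenarios inherit it unchanged.

Two structural lessons from the calibration are worth recording.
First, growth must not be nutrient-throttled during the first week —
with demand set too high the colony decelerates by day 5 and the
exponential fit degrades; the defaults put starvation onset (and hence
the emergence of the quiescent core) in the second week.  Second, the
population-level doubling time exceeds the single-cell cycle because of
migration episodes and transient contact inhibition, so the migration
rate (0.05 μm/min, i.e. a 10-hour hexagon traversal in dense tissue)
doubles as the knob separating the two time scales.

## Problem sizes

The reference simulations used throughout the tests and the
reproduction script are scaled down from the full-size environment
(R = 34, M = 6, n = 50 replicates in the original study design) to
R = 14, M = 4 and n = 5 replicates, chosen so the full suite runs on a
single CPU in minutes while leaving the colony ample room (radius 13)
for 14 days of growth.  The builders in `hextissue.experiments` default
to the full-size environment.

## Synthetic data and scope

All experiments are self-generated simulations; there are no external
datasets.  The generator reproduces the *mechanisms* of tissue growth
(nutrient fields, contact inhibition, delayed actions, clonal parameter
inheritance) but not features of real tumor data such as measurement
noise, irregular vasculature, 3D mechanics, or immune interactions —
passing tests therefore validate internal consistency and the printed
growth benchmarks, not fidelity to any particular cell line.

## Known limitations

* The hexagonal/triangular geometry is the only concrete grid/lattice
  pair; rectangular/triangular agent grids are interface stubs.
* 3D runs stack 2D layers with the printed offset neighborhoods, but
  the molecule lattices of adjacent layers are vertically aligned (the
  half-hex layer offsets are not applied to the lattice mapping).
* No capillary-bed or angiogenesis components; sources sit at the
  margin only.
* Lactate is removed, not tracked as an environmental field; no pH.
* The null model and the random module variants are controls, not
  biological hypotheses.
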