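# lignoflux

Constraint-based and kinetic flux analysis of monolignol biosynthesis in
alfalfa (*Medicago sativa* L.) stems.

Lignin is assembled from three monomers — *p*-hydroxyphenyl (H), guaiacyl
(G) and syringyl (S) — whose relative abundance (especially the S/G ratio)
controls cell-wall digestibility and biofuel feedstock quality.  Because
successive stem internodes represent successive developmental stages, a
single alfalfa stem provides a whole developmental series of lignin
compositions, and transgenic lines with individually down-regulated pathway
enzymes (PAL, C4H, HCT, C3H, CCoAOMT, COMT) provide systematic
perturbations.  `lignoflux` is aimed at plant systems biologists who want
to turn such composition tables into steady-state flux statements: which
branch points move during development, how a knockdown redistributes flux,
and whether enzyme saturation kinetics alone could explain the observed
composition shifts.

## The models

**Per-internode FBA (wild type).**  On a 24-reaction irreversible pathway
network (stoichiometric matrix **N**), each internode's flux distribution
solves

```
max  v6 + v15 + v19                    (total monomer transport)
s.t. N v = 0                           (steady state)
     v1 = 1                            (normalization to the PAL step)
     0 ≤ v ≤ 1,  v22, v23, v24 ≥ 0.01  (irreversibility; overflow drains)
     v6  = h (v6+v15+v19)              (measured composition as
     v15 = g (v6+v15+v19)               proportionality constraints)
```

The three overflow drains (cinnamic acid → salicylate, *p*-coumaroyl-CoA →
flavonoids, 5-hydroxyconiferyl alcohol → 5H lignin) are structurally
required: without them several knockdowns admit no balanced flux state at
all.  The optimum is degenerate — the split between the CCoAOMT–CCR1 route
and the CCR2–COMT shunt, and between aldehyde- and alcohol-level F5H, is
free — so the package enumerates every vertex of the optimal face and
selects a unique reference by a deterministic policy (`min-norm` or
`main-route`).

**MOMA (transgenic lines).**  A knockdown with residual activity α caps
every reaction of the silenced enzyme at `v_j ≤ α v*_j` and replaces the
composition constraints with the mutant's measured values; the predicted
mutant state is the unique Euclidean projection
`argmin ‖v − v*‖₂` of the wild-type reference `v*` onto the mutant's
feasible polytope.

**Kinetic branch ensemble.**  A reduced five-species model of the
caffeoyl-CoA region (8 Michaelis–Menten or Hill reactions, 16 free
parameters in MM mode) is sampled 10,000 times with log-uniform vmax/Km;
admissible draws (converged positive steady state, wild-type-plausible S/G)
are subjected to 80% CCoAOMT or CCR1 knockdowns and the relative S/G change
is recorded.

## Worked example

`python examples/01_wildtype_fba.py` solves the internode 1–2 wild-type
problem under the composition 7% H / 85.5% G / 7.4% S:

```
optimal monomer production (v6+v15+v19): 0.9700
H transport share: 7.01 %  (the measured H fraction)
S/G transport flux ratio v19/v15: 0.0865  (~0.09, the young-internode S/G ratio)
the optimum is degenerate: 4 vertices on the optimal face
```

The objective is 0.97 because exactly the three overflow minima (3 × 0.01)
escape monomer production; the transport shares reproduce the measured
composition, with the S/G flux ratio matching the young-internode value of
about 0.09.  `examples/02_transgenic_moma.py` shows an 80% CCoAOMT
knockdown rerouting 0.54 flux units through the CCR2 shunt and proves that
a 45% C4H knockdown is unbalanceable at cinnamic acid without the overflow
drains; `examples/03_developmental_trends.py` classifies the developmental
partitioning trends and prints the v13–v14 correlation (ρ ≈ 1.0) across
mutant solutions; `examples/04_kinetic_ensemble.py` runs the Monte Carlo
ensembles, in which no admissible system shifts its steady-state S/G ratio
under either knockdown — evidence against a purely kinetic explanation.

The same stages are scriptable via the thin CLI
(`lignoflux simulate | fba | moma | trends | mc | run-all`).

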