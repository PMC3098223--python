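# Methods

## Pathway model

The network covers monolignol biosynthesis from phenylalanine to the three
cell-wall transport steps.  Reactions are irreversible with unit
stoichiometry; shikimate and CoA are treated as perfectly recycled
cofactors, so both HCT steps appear as simple conversions.  The reaction
map (v1 PAL, v2 C4H, v3 4CL, v4 CCR1, v5 CAD, v6 H transport, v7/v9 HCT,
v8 C3H, v10 CCR2, v11 CCoAOMT, v12 COMT, v13 CCR1, v14 CAD, v15 G
transport, v16/v20 F5H, v17/v21 COMT, v18 CAD, v19 S transport, v22–v24
overflows) is the unique assignment consistent with the branch-point
groupings used throughout the analysis.  Two points were genuinely open:

* **v23's origin.**  The flavonoid overflow is attached to
  *p*-coumaroyl-CoA (chalcone synthase consumes the CoA ester), not to
  *p*-coumaraldehyde.
* **v24 doubles as the 5H sink.**  5-hydroxyconiferyl alcohol incorporation
  into the polymer is not part of the H+G+S composition columns
  (thioacidolysis reports H/G/S only), so the drain and the 5H sink are one
  flux.

No CAD step from 5-hydroxyconiferyl aldehyde to the corresponding alcohol
is modeled; the 24-flux indexing leaves no slot for it, and nothing in the
flux analysis requires it.

## Wild-type FBA

Mass balance `N v = 0` over the 16 internal species, normalization
`v1 = 1`, bounds `0 ≤ v ≤ 1` with the three overflows held at a lower
bound of 0.01, and two independent proportionality equalities tying
(v6, v15, v19) to the measured H/G/S fractions.  Compositions are
normalized to sum to one on construction (printed percentages can sum to
99.9 from rounding); degenerate zero fractions are kept as hard equalities.
The LP maximizes v6+v15+v19 (HiGHS); the optimum always equals
`1 − Σ overflow lower bounds` because the drains are pinned at their minima.

**Alternate optima.**  The optimal face is characterized exactly: after
fixing the objective value, a per-variable LP range scan pins the
determined fluxes, the nullspace of the augmented equality system gives the
face dimension d (2 for generic compositions: the route split at
caffeoyl-CoA and the F5H level split), and vertices are enumerated
combinatorially by activating d bounds at a time.  Note that the 5H
overflow's 0.01 lower bound keeps the G/S machinery active even for an
all-H composition, so the route-split freedom never fully disappears.

**Reference selection.**  Two deterministic policies are provided, because
the criterion that singles out the physiological solution on the optimal
face is an open design choice:

* `min-norm` — the unique minimum-Euclidean-norm point of the face.  It
  splits parallel routes evenly, which contradicts the dispensability of
  the CCR2–COMT shunt in wild-type plants.
* `main-route` (pipeline default) — lexicographically minimize v10, then
  v16, then take the minimum-norm point.  This silences the shunt and
  routes S flux through the alcohol-level F5H/COMT pair (v20, v21), the
  parallel path that buffers changes in earlier precursors.  A consequence
  worth knowing: under this policy the coniferyl-alcohol inflow v14 equals
  v12 + v13, which is what makes the v13–v14 correlation across mutant
  solutions essentially perfect (ρ > 0.999).  With `min-norm` the same
  correlation drops to ≈0.89 because v16 absorbs a variable share of the
  S flux.  The tie-break on v16 rather than v20 was chosen for exactly
  this structural property; the underlying biology (how the two F5H levels
  share the S route in vivo) is not resolved by the flux analysis.

## MOMA

Knockdown inequalities `v_j ≤ α v*_j` (one per reaction of the silenced
enzyme) are applied as tightened upper bounds, making the mutant prediction
a Euclidean projection onto an affine-plus-box set.  The projection is
solved in the nullspace parametrization with `trust-constr` and refined by
an active-set KKT loop (primal feasibility, dual sign checks, inconsistent
working sets rejected), giving ~1e-10 agreement with an independent
Dykstra alternating-projection computation.  Feasibility is pre-checked by
LP; when infeasible, each internal metabolite's balance row is removed in
turn and the metabolites whose removal restores feasibility are reported
as the blocking balances (cinnamic acid for a strong C4H knockdown on the
unextended network).

`v1 = 1` is kept in mutants — constant phenylalanine supply is what makes
the unextended network provably infeasible under a C4H knockdown — except
when the silenced enzyme is PAL itself: a cap `v1 ≤ α` contradicts the
fixed normalization, so the pipeline then relaxes v1 to the bound
`v1 ≤ 1` and lets the knockdown constraint govern the entry flux.

## Trend classification

Partition fractions (each outgoing flux over the total flux entering its
branch-point metabolite) are computed per internode and classified into
five categories.  The arrows are qualitative in origin; the numeric rules
here are package defaults, configurable and scale-free: strictly monotone →
monotone up/down; total range below 5% of the mean magnitude (or magnitude
below 1e-9, solver noise around zero) → unchanged; otherwise the sign of a
Spearman rank correlation with |ρ| ≥ 0.6 decides a minor trend, and weaker
association falls back to unchanged.

## Kinetic branch model

Five species (caffeoyl-CoA, feruloyl-CoA, caffeyl aldehyde, coniferyl
aldehyde, coniferyl alcohol), eight saturable reactions, constant influx J
into caffeoyl-CoA.  Everything downstream of v16/v20 is lumped into the S
sink and v15 is the G sink, fixing the parameter count at 16 (8 × {vmax,
Km}) in MM mode; Hill mode adds 8 cooperativity exponents.  COMT's three
activities are treated as independent reactions (no shared-capacity
competition), and J is a boundary condition, not a 17th parameter.

Because every rate is monotone increasing in its substrate, the steady
state is unique and globally attracting.  It is computed exactly by
cascading scalar inversions (brentq on each branch total, closed-form MM/
Hill inversion on each linear step); a reaction whose capacity falls below
the flux it must carry is reported as non-convergent with the accumulating
species named.  Stiff ODE integration (LSODA from empty pools) is retained
as a cross-check method and agrees to 1e-6; the algebraic route is used
throughout the ensembles for speed and exactness.

## Monte Carlo ensemble

Per draw, vmax and Km are log-uniform on [0.1, 10] (model units) and Hill
exponents uniform on [1, 4]; these ranges, and the admissibility rule
below, are package defaults standing in for unpublished settings, and all
are configurable.  J = 0.5 was fixed once so that roughly half (measured
57%) of unconstrained MM draws admit a steady state.  Admissibility =
convergence + positive finite pools + baseline S/G inside the observed
wild-type developmental window [0.09, 0.64].  Knockdowns multiply the
target vmax (v11 for CCoAOMT, v13 for CCR1) by 0.2; draws whose perturbed
model has no steady state are flagged and excluded, and "significant
increase" means a relative S/G change above +5%.

A structural fact dominates the results: with J fixed, the steady-state
inflow into coniferyl aldehyde equals J however the two routes split it,
and the S/G split depends only on the four branch-point reactions, which
the knockdowns do not touch.  Admissible systems therefore show *exactly
zero* steady-state S/G change under either knockdown — the strongest
possible version of the conclusion that saturation kinetics alone cannot
produce the S/G shifts observed in CCoAOMT- or CCR1-deficient plants.
Nonzero responses would require transient (finite-time) readouts or an
upstream step saturating below J, neither of which survives the strict
steady-state screen used here.

## Synthetic study generator

The generator emulates the study's observation table: 7 lines × 7
internode stages with H share falling linearly from 7/99.9 to 1% and S/G
rising linearly from 0.074/0.855 to 0.64 in the wild type (hitting the
printed anchor compositions exactly), line-specific multiplicative shifts
in the reported directions (S/G above wild type for CCoAOMT ×1.6, PAL
×1.35, HCT ×1.15; below for C4H ×0.65, COMT ×0.35; H share ×2.5 for C3H
and ×1.3 for CCoAOMT), residual activities α (C4H 0.45; CCoAOMT/COMT 0.20;
PAL 0.40; HCT 0.25; C3H 0.30), and Gaussian noise of σ = 0.1 on the
log-ratio coordinates, giving a replicate S/G s.d. of ≈0.03 at
mid-developmental ratios.  Total lignin rises 60 → 150 mg/g cell wall and
scales with residual activity (0.55 + 0.45 α).

What the generator does *not* emulate: internode-specific enzyme
activities (one α per line), measurement correlation between adjacent
internodes, the 5H monomer, and any regulatory coupling between lines.
Passing tests on synthetic tables therefore demonstrate the machinery —
feasibility handling, trend recovery, the structural v13–v14 correlation —
not agreement with the original study's numeric flux values, which
would require its full observation and activity measurements.

## Numerical choices

LP/QP feasibility tolerance 1e-8; nullspace rank cutoff 1e-10; vertex
deduplication at 1e-6; steady-state root tolerance ~1e-14 (brentq) and net
rates < 1e-9 (ODE check); concentrations above 1e12 are treated as
unbounded accumulation.  Problem sizes used by the default pipeline and
test suite: 7 FBA + 42 MOMA solves per study and 2,000-draw ensembles
(fractions at n = 2,000 carry a sampling error of roughly ±1–2 percentage
points; the ensemble outcomes here are exact zeros, so the draw count only
affects the admissible-set size).  The CLI `mc` command defaults to the
full 10,000 draws.

## Known limitations

* Reversibility of HCT/C3H, a qualitative hypothesis in the literature,
  is not modeled (all reactions irreversible).
* The enumeration guard rejects optimal faces above dimension 6; the
  pathway never produces them, but exotic user-supplied bound edits could.
* The kinetic model's independent-COMT reading means v12 does not compete
  with v17/v21 for methylation capacity.
* Network TSV round-trips reconstruct boundary status structurally
  (species without a producer or consumer), which is exact for this
  pathway but would mislabel a hypothetical internal dead-end metabolite.
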