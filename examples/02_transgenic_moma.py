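"""MOMA prediction for a CCoAOMT-deficient line.

Starting from the wild-type reference, an 80% CCoAOMT knockdown
(v11 <= 0.2 v*11) combined with the mutant's S-shifted monomer composition
is resolved as the Euclidean-closest feasible flux distribution.  The
prediction shows the CCR2-COMT shunt (v10, v12) taking over the flux the
capped CCoAOMT-CCR1 route can no longer carry.  It also demonstrates the
structural role of the overflow drains: the same C4H knockdown that is
feasible here is provably unbalanceable at cinnamic acid on the 21-reaction
network without them.
"""

from lignoflux import (
    FBAProblem,
    KnockdownSpec,
    MonomerComposition,
    build_reference_network,
    check_feasibility,
    solve_moma,
    wildtype_reference,
)

net = build_reference_network("extended")
wt_comp = MonomerComposition.from_percent(7.0, 85.5, 7.4)
wt = wildtype_reference(FBAProblem(net, wt_comp), "main-route")

mut_comp = MonomerComposition.from_percent(8.0, 72.0, 20.0)  # S-shifted
res = solve_moma(net, KnockdownSpec("CCoAOMT", 0.2), mut_comp, wt)
print(f"feasible: {res.feasible}, adjustment distance ||v - v*|| = {res.distance:.4f}")
print(f"CCoAOMT flux v11: {wt['v11']:.4f} -> {res.fluxes['v11']:.4f}  (capped at 20%)")
print(f"CCR2 shunt  v10: {wt['v10']:.4f} -> {res.fluxes['v10']:.4f}  "
      f"(takes over the rerouted flux)")
print(f"overflow v23 (flavonoid drain): {wt['v23']:.4f} -> {res.fluxes['v23']:.4f}")

print("\nwhy the overflow drains are needed:")
un = build_reference_network("unextended")
wt_un = wildtype_reference(FBAProblem(un, wt_comp))
verdict = check_feasibility(un, KnockdownSpec("C4H", 0.45), wt_comp, wt_un)
print(f"  unextended network, C4H at 45%: feasible = {verdict.feasible}, "
      f"blocked balance at {verdict.blocked_metabolites}")
verdict = check_feasibility(net, KnockdownSpec("C4H", 0.45), wt_comp, wt)
print(f"  extended network, same knockdown: feasible = {verdict.feasible}")
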