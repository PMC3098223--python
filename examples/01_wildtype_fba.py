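"""Wild-type flux balance analysis of one internode.

Builds the extended 24-reaction monolignol network, constrains the three
transport fluxes to the measured internode 1-2 monomer composition
(7% H, 85.5% G, 7.4% S), maximizes total monomer production, enumerates the
alternate optima and selects the main-route reference distribution.
"""

from lignoflux import (
    FBAProblem,
    MonomerComposition,
    build_reference_network,
    enumerate_alternate_optima,
    select_reference_distribution,
    solve_fba,
)

net = build_reference_network("extended")
comp = MonomerComposition.from_percent(7.0, 85.5, 7.4)
problem = FBAProblem(net, comp)

opt = solve_fba(problem)
print(f"optimal monomer production (v6+v15+v19): {opt.objective_value:.4f}")
print(f"  -> 1 minus the three overflow drains pinned at their 0.01 lower bound")
print(f"H transport share: {100 * opt['v6'] / opt.transport_total:.2f} %  "
      f"(the measured H fraction)")
print(f"S/G transport flux ratio v19/v15: {opt['v19'] / opt['v15']:.4f}  "
      f"(~0.09, the young-internode S/G ratio)")

vertices = enumerate_alternate_optima(problem, opt)
print(f"\nthe optimum is degenerate: {len(vertices)} vertices on the optimal face")
print("  (the CCR2-COMT shunt split and the F5H level are undetermined)")

ref = select_reference_distribution(vertices, "main-route")
print("\nmain-route reference (shunt silenced):")
for rid in ("v10", "v11", "v13", "v14", "v15", "v16", "v19", "v20"):
    print(f"  {rid:>4} = {ref[rid]:.4f}")
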