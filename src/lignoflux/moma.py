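"""Transgenic flux prediction by minimization of metabolic adjustment.

A down-regulated line is modeled by (i) the mutant's own measured H/G/S
composition as proportionality equalities, and (ii) one knockdown
inequality v_j <= alpha * v*_j for every reaction j catalysed by the
silenced enzyme, where alpha is the residual activity fraction and v* the
wild-type reference distribution.  Within that reduced feasible space the
mutant state is predicted as the point of minimum Euclidean distance to v*
(a strictly convex QP, hence unique).

Because each knockdown inequality involves a single flux, it is applied as
a tightened upper bound; the QP is then a Euclidean projection onto an
affine-plus-box set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import qp
from .fba import FluxDistribution, MonomerComposition, assemble_constraints
from .network import PathwayNetwork, reactions_for_enzyme

__all__ = [
    "KnockdownSpec",
    "MOMAResult",
    "FeasibilityVerdict",
    "knockdown_constraints",
    "solve_moma",
    "check_feasibility",
]

FEAS_TOL = 1e-8


@dataclass(frozen=True)
class KnockdownSpec:
    """Residual activity fraction alpha for one down-regulated enzyme."""

    enzyme: str
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class MOMAResult:
    fluxes: FluxDistribution | None
    distance: float | None
    feasible: bool


@dataclass
class FeasibilityVerdict:
    feasible: bool
    #: Names of metabolites whose balance row blocks feasibility (empty when
    #: feasible, or when no single-row certificate exists).
    blocked_metabolites: tuple[str, ...] = ()


def knockdown_constraints(
    net: PathwayNetwork, spec: KnockdownSpec, wildtype_fluxes: FluxDistribution
) -> dict[str, float]:
    """Upper bounds alpha * v*_j for every reaction of the silenced enzyme.

    Transport and overflow steps are not gene products and cannot be
    knocked down.
    """
    if spec.enzyme in ("TRANSPORT", "OVERFLOW"):
        raise ValueError(f"{spec.enzyme} is not a gene knockdown target")
    rids = reactions_for_enzyme(net, spec.enzyme)
    if not rids:
        raise ValueError(f"enzyme {spec.enzyme!r} catalyses no reaction in this variant")
    return {rid: spec.alpha * wildtype_fluxes[rid] for rid in sorted(rids)}


def _mutant_system(net, spec, mutant_composition, wildtype_fluxes, fix_v1):
    cs = assemble_constraints(net, mutant_composition, fix_v1=fix_v1)
    ub = cs.ub.copy()
    for rid, cap in knockdown_constraints(net, spec, wildtype_fluxes).items():
        i = cs.index(rid)
        ub[i] = min(ub[i], cap)
    return cs, ub


def solve_moma(
    net: PathwayNetwork,
    spec: KnockdownSpec,
    mutant_composition: MonomerComposition,
    wildtype_fluxes: FluxDistribution,
    *,
    fix_v1: bool = True,
) -> MOMAResult:
    """Predict the mutant flux distribution closest to the wild type.

    ``fix_v1=False`` drops the v1 = 1 normalization equality (keeping only
    v1 <= 1); required when the knocked-down enzyme is PAL, whose cap on v1
    contradicts the fixed normalization.  Returns
    ``MOMAResult(feasible=False)`` — never an exception — when the mutant
    constraint set is empty.
    """
    cs, ub = _mutant_system(net, spec, mutant_composition, wildtype_fluxes, fix_v1)
    target = wildtype_fluxes.as_array(cs.order)
    try:
        x = qp.project_to_affine_box(cs.A_eq, cs.b_eq, cs.lb, ub, target)
    except qp.InfeasibleError:
        return MOMAResult(fluxes=None, distance=None, feasible=False)
    dist = float(np.linalg.norm(x - target))
    fluxes = FluxDistribution(
        values={rid: float(x[i]) for i, rid in enumerate(cs.order)},
        objective_value=None,
        selection_policy_tag=f"moma:{spec.enzyme}:{spec.alpha:g}",
    )
    return MOMAResult(fluxes=fluxes, distance=dist, feasible=True)


def check_feasibility(
    net: PathwayNetwork,
    spec: KnockdownSpec,
    mutant_composition: MonomerComposition,
    wildtype_fluxes: FluxDistribution,
    *,
    fix_v1: bool = True,
) -> FeasibilityVerdict:
    """LP feasibility of the mutant constraint set, with a certificate.

    When infeasible, each internal metabolite's balance row is removed in
    turn; metabolites whose removal restores feasibility are reported as the
    blocking balances (e.g. cinnamic acid for a strong C4H knockdown on the
    unextended network, where v1 = 1 forces v2 = 1 > alpha).
    """
    cs, ub = _mutant_system(net, spec, mutant_composition, wildtype_fluxes, fix_v1)
    if qp.is_feasible(cs.A_eq, cs.b_eq, cs.lb, ub):
        return FeasibilityVerdict(feasible=True)
    blocked = []
    for k, label in enumerate(cs.row_labels):
        if not label.startswith("balance:"):
            continue
        keep = [i for i in range(cs.A_eq.shape[0]) if i != k]
        if qp.is_feasible(cs.A_eq[keep], cs.b_eq[keep], cs.lb, ub):
            blocked.append(net.metabolite_name(label.split(":", 1)[1]))
    return FeasibilityVerdict(feasible=False, blocked_metabolites=tuple(blocked))
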