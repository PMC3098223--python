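"""Reduced kinetic model of the caffeoyl-CoA branch region.

Five species — caffeoyl-CoA, feruloyl-CoA, caffeyl aldehyde, coniferyl
aldehyde and coniferyl alcohol — are connected by eight irreversible
Michaelis-Menten (or Hill) reactions:

* the route split at caffeoyl-CoA: v11 (CCoAOMT, to feruloyl-CoA) versus
  v10 (CCR2, to caffeyl aldehyde),
* the reunion at coniferyl aldehyde: v13 (CCR1) and v12 (COMT),
* the G/S branch points: v14 (CAD) versus v16 (F5H) at coniferyl aldehyde,
  and v15 (transport, G sink) versus v20 (F5H, S sink) at coniferyl
  alcohol.  Everything downstream of v16/v20 is lumped into the S sink, so
  the model carries exactly 16 free parameters (8 x {vmax, Km}) in MM mode.

A constant influx J feeds caffeoyl-CoA.  Because every rate is a monotone
increasing function of its substrate, the steady state is unique and
globally attracting, and can be found exactly by cascading 1-D inversions;
stiff ODE integration from empty pools is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "BranchReactionKinetics",
    "BranchModel",
    "SteadyState",
    "PerturbationResult",
    "reaction_rate",
    "steady_state",
    "perturbation_response",
    "BRANCH_REACTIONS",
    "BRANCH_SPECIES",
    "KNOCKDOWN_TARGETS",
]

BRANCH_SPECIES: tuple[str, ...] = (
    "caffeoyl_coa",
    "feruloyl_coa",
    "caffeyl_aldehyde",
    "coniferyl_aldehyde",
    "coniferyl_alcohol",
)

#: reaction id -> substrate species of the reduced model
BRANCH_REACTIONS: dict[str, str] = {
    "v10": "caffeoyl_coa",
    "v11": "caffeoyl_coa",
    "v12": "caffeyl_aldehyde",
    "v13": "feruloyl_coa",
    "v14": "coniferyl_aldehyde",
    "v15": "coniferyl_alcohol",
    "v16": "coniferyl_aldehyde",
    "v20": "coniferyl_alcohol",
}

#: enzyme knocked down in the ensemble experiments -> perturbed reaction
KNOCKDOWN_TARGETS: dict[str, str] = {"CCoAOMT": "v11", "CCR1": "v13"}

_CONC_CAP = 1e12  # beyond this a pool is treated as accumulating without bound


@dataclass(frozen=True)
class BranchReactionKinetics:
    """Saturable rate law vmax * c^n / (Km^n + c^n); n = 1 is plain MM.

    ``vmax = 0`` denotes an absent reaction (rate identically zero), used
    for reduced sub-models; sampled parameter sets always have vmax > 0.
    """

    reaction_id: str
    vmax: float
    km: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if self.vmax < 0 or self.km <= 0 or self.hill_n < 1:
            raise ValueError(
                f"{self.reaction_id}: require vmax >= 0, km > 0, hill_n >= 1"
            )


def reaction_rate(kinetics: BranchReactionKinetics, substrate_conc: float) -> float:
    """Hill/MM rate at the given substrate concentration."""
    c = float(substrate_conc)
    if c < 0:
        raise ValueError("substrate concentration must be non-negative")
    if c == 0.0 or kinetics.vmax == 0.0:
        return 0.0
    n = kinetics.hill_n
    cn = c**n
    return kinetics.vmax * cn / (kinetics.km**n + cn)


def _invert_rate(kinetics: BranchReactionKinetics, flux: float) -> float:
    """Concentration at which the rate equals ``flux`` (requires
    flux < vmax)."""
    if flux <= 0:
        return 0.0
    return kinetics.km * (flux / (kinetics.vmax - flux)) ** (1.0 / kinetics.hill_n)


@dataclass(frozen=True)
class BranchModel:
    """Kinetics for the eight reactions plus the sink wiring (v15 -> G pool,
    v16 and v20 -> S pool)."""

    kinetics: dict[str, BranchReactionKinetics]
    mode: str = "mm"  # "mm" or "hill"

    def __post_init__(self) -> None:
        if set(self.kinetics) != set(BRANCH_REACTIONS):
            raise ValueError(
                f"model requires kinetics for exactly {sorted(BRANCH_REACTIONS)}"
            )
        if self.mode not in ("mm", "hill"):
            raise ValueError("mode must be 'mm' or 'hill'")
        if self.mode == "mm" and any(k.hill_n != 1.0 for k in self.kinetics.values()):
            raise ValueError("MM mode requires hill_n == 1 everywhere")

    @property
    def n_free_parameters(self) -> int:
        """16 (8 x {vmax, Km}) in MM mode; +8 Hill exponents otherwise."""
        return 2 * len(BRANCH_REACTIONS) + (
            len(BRANCH_REACTIONS) if self.mode == "hill" else 0
        )

    def with_vmax_scaled(self, reaction_id: str, factor: float) -> "BranchModel":
        kin = dict(self.kinetics)
        k = kin[reaction_id]
        kin[reaction_id] = replace(k, vmax=k.vmax * factor)
        return BranchModel(kin, self.mode)


@dataclass
class SteadyState:
    concentrations: dict[str, float]
    fluxes: dict[str, float]
    converged: bool
    diagnostic: str = ""

    @property
    def g_flux(self) -> float:
        return self.fluxes.get("v15", float("nan"))

    @property
    def s_flux(self) -> float:
        return self.fluxes.get("v16", float("nan")) + self.fluxes.get("v20", float("nan"))

    @property
    def sg_ratio(self) -> float:
        return self.s_flux / self.g_flux if self.g_flux > 0 else float("nan")


def _failed(reason: str) -> SteadyState:
    return SteadyState(concentrations={}, fluxes={}, converged=False, diagnostic=reason)


def _solve_branch(k_list, target: float) -> float | None:
    """Concentration c with sum_k rate_k(c) = target; None if the combined
    capacity cannot carry the flux."""
    if target <= 0:
        return 0.0
    cap = sum(k.vmax for k in k_list)
    if target >= cap:
        return None

    def g(c):
        return sum(reaction_rate(k, c) for k in k_list) - target

    hi = max(k.km for k in k_list)
    while g(hi) < 0:
        hi *= 4.0
        if hi > _CONC_CAP:
            return None
    return brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-15)


def _algebraic_steady_state(model: BranchModel, J: float) -> SteadyState:
    kin = model.kinetics
    c1 = _solve_branch([kin["v10"], kin["v11"]], J)
    if c1 is None:
        return _failed("caffeoyl-CoA accumulates: influx exceeds route capacity")
    f10 = reaction_rate(kin["v10"], c1)
    f11 = reaction_rate(kin["v11"], c1)

    if f11 >= kin["v13"].vmax and f11 > 0:
        return _failed("feruloyl-CoA accumulates: v13 capacity below route flux")
    c2 = _invert_rate(kin["v13"], f11)
    if f10 >= kin["v12"].vmax and f10 > 0:
        return _failed("caffeyl aldehyde accumulates: v12 capacity below route flux")
    c3 = _invert_rate(kin["v12"], f10)

    c4 = _solve_branch([kin["v14"], kin["v16"]], J)
    if c4 is None:
        return _failed("coniferyl aldehyde accumulates: v14+v16 capacity below influx")
    f14 = reaction_rate(kin["v14"], c4)
    f16 = reaction_rate(kin["v16"], c4)

    c5 = _solve_branch([kin["v15"], kin["v20"]], f14)
    if c5 is None:
        return _failed("coniferyl alcohol accumulates: v15+v20 capacity below inflow")
    f15 = reaction_rate(kin["v15"], c5)
    f20 = reaction_rate(kin["v20"], c5)

    conc = dict(zip(BRANCH_SPECIES, (c1, c2, c3, c4, c5)))
    fluxes = {
        "v10": f10, "v11": f11, "v12": f10, "v13": f11,
        "v14": f14, "v15": f15, "v16": f16, "v20": f20,
    }
    return SteadyState(concentrations=conc, fluxes=fluxes, converged=True)


def _ode_rhs(model: BranchModel, J: float):
    kin = model.kinetics

    def rhs(_t, y):
        c1, c2, c3, c4, c5 = np.maximum(y, 0.0)
        r = {rid: reaction_rate(kin[rid], {"caffeoyl_coa": c1,
                                           "feruloyl_coa": c2,
                                           "caffeyl_aldehyde": c3,
                                           "coniferyl_aldehyde": c4,
                                           "coniferyl_alcohol": c5}[sub])
             for rid, sub in BRANCH_REACTIONS.items()}
        return [
            J - r["v10"] - r["v11"],
            r["v11"] - r["v13"],
            r["v10"] - r["v12"],
            r["v12"] + r["v13"] - r["v14"] - r["v16"],
            r["v14"] - r["v15"] - r["v20"],
        ]

    return rhs


def _ode_steady_state(model: BranchModel, J: float, *, rate_tol: float = 1e-9,
                      t_max: float = 1e7) -> SteadyState:
    rhs = _ode_rhs(model, J)
    y = np.zeros(5)
    t_end = 1e2
    while t_end <= t_max:
        sol = solve_ivp(rhs, (0.0, t_end), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            return _failed(f"integration failure: {sol.message}")
        y = sol.y[:, -1]
        if np.max(np.abs(rhs(0.0, y))) < rate_tol:
            kin = model.kinetics
            conc = dict(zip(BRANCH_SPECIES, np.maximum(y, 0.0)))
            fluxes = {rid: reaction_rate(kin[rid], conc[sub])
                      for rid, sub in BRANCH_REACTIONS.items()}
            return SteadyState(concentrations=conc, fluxes=fluxes, converged=True)
        if np.max(y) > _CONC_CAP:
            return _failed("a metabolite pool grows without bound")
        t_end *= 10.0
    return _failed(f"net rates above tolerance at t = {t_max:g}")


def steady_state(model: BranchModel, J: float, *, method: str = "algebraic") -> SteadyState:
    """Steady state of the branch model under constant influx J > 0.

    ``method='algebraic'`` (default) inverts the monotone cascade exactly;
    ``method='ode'`` integrates from empty pools until net rates vanish.
    Both report ``converged=False`` with a diagnostic when some capacity is
    below the flux it must carry (unbounded accumulation).
    """
    if J <= 0:
        raise ValueError("influx J must be positive")
    if method == "algebraic":
        return _algebraic_steady_state(model, J)
    if method == "ode":
        return _ode_steady_state(model, J)
    raise ValueError("method must be 'algebraic' or 'ode'")


@dataclass
class PerturbationResult:
    sg_baseline: float
    sg_perturbed: float | None
    relative_change: float | None
    baseline: SteadyState
    perturbed: SteadyState


def perturbation_response(
    model: BranchModel, J: float, target_enzyme: str, factor: float,
    *, method: str = "algebraic",
) -> PerturbationResult:
    """S/G response to scaling the target enzyme's vmax by ``factor``
    (0.2 emulates an 80% knockdown of CCoAOMT -> v11 or CCR1 -> v13)."""
    if target_enzyme not in KNOCKDOWN_TARGETS:
        raise ValueError(f"target must be one of {sorted(KNOCKDOWN_TARGETS)}")
    if factor <= 0:
        raise ValueError("factor must be positive")
    base = steady_state(model, J, method=method)
    if not base.converged:
        raise ValueError(f"baseline does not converge: {base.diagnostic}")
    pert = steady_state(
        model.with_vmax_scaled(KNOCKDOWN_TARGETS[target_enzyme], factor),
        J, method=method,
    )
    if not pert.converged:
        return PerturbationResult(base.sg_ratio, None, None, base, pert)
    rel = (pert.sg_ratio - base.sg_ratio) / base.sg_ratio
    return PerturbationResult(base.sg_ratio, pert.sg_ratio, rel, base, pert)
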