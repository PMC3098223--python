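"""Per-internode flux balance analysis of the wild-type pathway.

The LP maximizes total monomer transport (v6 + v15 + v19) subject to

* steady-state mass balance N v = 0 over internal metabolites,
* normalization v1 = 1 (all fluxes relative to the pathway entry step),
* irreversibility 0 <= v_i <= 1, with the three overflow drains held at a
  small lower bound (0.01) in the extended variant, and
* proportionality constraints tying the three transport fluxes to the
  measured H/G/S monomer composition of the internode.

The optimum is degenerate: the split between the CCoAOMT--CCR1 route and
the CCR2--COMT shunt, and between aldehyde- and alcohol-level F5H
hydroxylation, is not determined by the constraints.  The optimal face is
therefore enumerated vertex-by-vertex and a unique reference distribution is
selected by a deterministic policy (minimum-norm point of the face, or the
"main-route" policy that first silences the shunt).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import qp
from .network import PathwayNetwork, TRANSPORT_REACTIONS, stoichiometric_matrix
from .qp import InfeasibleError

__all__ = [
    "MonomerComposition",
    "FBAProblem",
    "FluxDistribution",
    "ConstraintSet",
    "composition_constraints",
    "assemble_constraints",
    "solve_fba",
    "enumerate_alternate_optima",
    "select_reference_distribution",
    "wildtype_reference",
    "InfeasibleError",
    "POLICIES",
]

FEAS_TOL = 1e-8
POLICIES = ("min-norm", "main-route")


@dataclass(frozen=True)
class MonomerComposition:
    """H/G/S fractions of total thioacidolysis monomer yield.

    Fractions are normalized to sum to one on construction; negative inputs
    are rejected.
    """

    h: float
    g: float
    s: float

    def __post_init__(self) -> None:
        vals = np.array([self.h, self.g, self.s], dtype=float)
        if np.any(vals < 0):
            raise ValueError("monomer fractions must be non-negative")
        total = vals.sum()
        if total <= 0:
            raise ValueError("monomer fractions must not all be zero")
        vals = vals / total
        object.__setattr__(self, "h", float(vals[0]))
        object.__setattr__(self, "g", float(vals[1]))
        object.__setattr__(self, "s", float(vals[2]))

    @classmethod
    def from_percent(cls, h_pct: float, g_pct: float, s_pct: float) -> "MonomerComposition":
        return cls(h_pct / 100.0, g_pct / 100.0, s_pct / 100.0)

    @property
    def sg_ratio(self) -> float:
        return self.s / self.g if self.g > 0 else float("inf")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.h, self.g, self.s)


@dataclass(frozen=True)
class FBAProblem:
    """Wild-type LP for one internode: network + measured composition."""

    network: PathwayNetwork
    composition: MonomerComposition


@dataclass
class FluxDistribution:
    """A normalized steady-state flux vector (v1 = 1)."""

    values: dict[str, float]
    objective_value: float | None = None
    selection_policy_tag: str | None = None

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def as_array(self, order) -> np.ndarray:
        return np.array([self.values[r] for r in order], dtype=float)

    @property
    def transport_total(self) -> float:
        return sum(self.values[r] for r in TRANSPORT_REACTIONS)


@dataclass
class ConstraintSet:
    """Dense equality system + box bounds over the network's reactions."""

    order: tuple[str, ...]
    A_eq: np.ndarray
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    row_labels: tuple[str, ...]

    def index(self, rid: str) -> int:
        return self.order.index(rid)


def composition_constraints(comp: MonomerComposition) -> list[tuple[dict[str, float], float]]:
    """Two independent proportionality equalities on (v6, v15, v19).

    The measured composition requires v6 = h (v6+v15+v19) and
    v15 = g (v6+v15+v19); the analogous S equality is their consequence.
    Returned as (coefficient map, rhs) pairs with rhs = 0.
    """
    h, g, _ = comp.as_tuple()
    return [
        ({"v6": 1.0 - h, "v15": -h, "v19": -h}, 0.0),
        ({"v6": -g, "v15": 1.0 - g, "v19": -g}, 0.0),
    ]


def assemble_constraints(
    net: PathwayNetwork,
    comp: MonomerComposition | None,
    *,
    v1_value: float = 1.0,
    fix_v1: bool = True,
) -> ConstraintSet:
    """Stack mass balance, the v1 normalization and (optionally) the
    composition equalities into one dense system.

    With ``fix_v1=False`` the normalization equality is dropped and v1 is
    only bounded above by 1 (constant phenylalanine supply); this is the
    form needed when the entry step itself is knocked down.
    """
    order = net.reaction_ids
    N = stoichiometric_matrix(net)
    rows = [N.to_numpy()]
    labels = [f"balance:{m}" for m in N.index]
    rhs = [np.zeros(N.shape[0])]

    if fix_v1:
        e1 = np.zeros(len(order))
        e1[order.index("v1")] = 1.0
        rows.append(e1[None, :])
        labels.append("normalization:v1")
        rhs.append([v1_value])

    if comp is not None:
        for k, (coeffs, b) in enumerate(composition_constraints(comp)):
            row = np.zeros(len(order))
            for rid, c in coeffs.items():
                row[order.index(rid)] = c
            rows.append(row[None, :])
            labels.append(f"composition:{k}")
            rhs.append([b])

    lb = np.array([net.reaction(r).lower_bound for r in order])
    ub = np.array([net.reaction(r).upper_bound for r in order])
    return ConstraintSet(
        order=order,
        A_eq=np.vstack(rows),
        b_eq=np.concatenate([np.atleast_1d(r) for r in rhs]),
        lb=lb,
        ub=ub,
        row_labels=tuple(labels),
    )


def _objective_vector(cs: ConstraintSet) -> np.ndarray:
    c = np.zeros(len(cs.order))
    for rid in TRANSPORT_REACTIONS:
        c[cs.index(rid)] = 1.0
    return c


def _to_distribution(cs: ConstraintSet, x: np.ndarray, obj: float | None,
                     tag: str | None = None) -> FluxDistribution:
    values = {rid: float(x[i]) for i, rid in enumerate(cs.order)}
    return FluxDistribution(values=values, objective_value=obj, selection_policy_tag=tag)


def solve_fba(problem: FBAProblem) -> FluxDistribution:
    """Maximize monomer production for one internode.

    Raises :class:`InfeasibleError` (with a plain message, no solver trace)
    when the constraint set is empty.
    """
    cs = assemble_constraints(problem.network, problem.composition)
    c = _objective_vector(cs)
    try:
        x, obj = qp.solve_lp(c, cs.A_eq, cs.b_eq, cs.lb, cs.ub, maximize=True)
    except InfeasibleError:
        raise InfeasibleError(
            "wild-type FBA problem is infeasible for the given composition"
        ) from None
    return _to_distribution(cs, x, obj)


def _optimal_face(cs: ConstraintSet, optimum: float):
    """Equality system of the optimal face, with variables that are fixed on
    the face (per-variable LP range below tolerance) pinned explicitly."""
    c = _objective_vector(cs)
    A_face = np.vstack([cs.A_eq, c[None, :]])
    b_face = np.concatenate([cs.b_eq, [optimum]])

    n = len(cs.order)
    lo = np.empty(n)
    hi = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        _, lo[i] = qp.solve_lp(e, A_face, b_face, cs.lb, cs.ub)
        _, hi[i] = qp.solve_lp(e, A_face, b_face, cs.lb, cs.ub, maximize=True)
    fixed = np.where(hi - lo < 1e-9)[0]
    rows = [A_face]
    rhs = [b_face]
    for i in fixed:
        e = np.zeros(n); e[i] = 1.0
        rows.append(e[None, :])
        rhs.append([0.5 * (lo[i] + hi[i])])
    A_all = np.vstack(rows)
    b_all = np.concatenate([np.atleast_1d(r) for r in rhs])
    return A_all, b_all, lo, hi, fixed


def enumerate_alternate_optima(
    problem: FBAProblem, optimum: FluxDistribution | None = None
) -> list[FluxDistribution]:
    """Enumerate every vertex of the optimal face.

    The face is an affine slice of the flux polytope; after pinning the
    variables with zero range, its dimension d is small (2 for generic
    wild-type compositions).  Vertices are found combinatorially by
    activating d bounds at a time and keeping the feasible, distinct
    solutions.
    """
    if optimum is None:
        optimum = solve_fba(problem)
    cs = assemble_constraints(problem.network, problem.composition)
    obj = float(optimum.objective_value)
    A_all, b_all, lo, hi, fixed = _optimal_face(cs, obj)
    Z = qp.nullspace(A_all)
    d = Z.shape[1]
    n = len(cs.order)

    if d == 0:
        x = qp._project_affine(optimum.as_array(cs.order), A_all, b_all)
        return [_to_distribution(cs, x, obj)]
    if d > 6:  # cannot happen for this pathway; guard against misuse
        raise RuntimeError(f"optimal face dimension {d} too large to enumerate")

    free = [i for i in range(n) if i not in set(fixed)]
    seen: dict[tuple, np.ndarray] = {}
    for combo in itertools.combinations(free, d):
        for sides in itertools.product((0, 1), repeat=d):
            rows = [A_all]
            rhs = [b_all]
            for i, side in zip(combo, sides):
                e = np.zeros(n); e[i] = 1.0
                rows.append(e[None, :])
                rhs.append([cs.lb[i] if side == 0 else cs.ub[i]])
            E = np.vstack(rows)
            f = np.concatenate([np.atleast_1d(r) for r in rhs])
            x, res, rank, _ = np.linalg.lstsq(E, f, rcond=None)
            if rank < n:
                continue
            if np.max(np.abs(E @ x - f)) > 1e-7:
                continue
            if np.any(x < cs.lb - 1e-7) or np.any(x > cs.ub + 1e-7):
                continue
            key = tuple(np.round(x, 6))
            if key not in seen:
                seen[key] = np.clip(x, cs.lb, cs.ub)
    if not seen:
        raise RuntimeError("vertex enumeration found no feasible vertex")
    return [_to_distribution(cs, x, obj) for x in seen.values()]


def select_reference_distribution(
    vertices: list[FluxDistribution], policy: str = "min-norm"
) -> FluxDistribution:
    """Deterministically pick one point of the optimal face.

    ``min-norm``: the (unique) minimum-Euclidean-norm point of the convex
    hull of the vertices.  ``main-route``: lexicographically minimize v10,
    then v16, over the face before taking the minimum-norm point — this
    keeps the CCR2--COMT shunt silent (it is dispensable in wild-type
    plants) and routes S flux through the alcohol-level F5H/COMT pair, so
    that the coniferyl-alcohol inflow v14 tracks the CCR1 flux v13.
    """
    if not vertices:
        raise ValueError("empty vertex set")
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    order = tuple(vertices[0].values.keys())
    V = np.stack([v.as_array(order) for v in vertices])  # k x n

    chosen = V
    if policy == "main-route":
        for rid in ("v10", "v16"):
            col = chosen[:, order.index(rid)]
            chosen = chosen[col <= col.min() + 1e-9]

    x = _min_norm_in_hull(chosen)
    values = {rid: float(x[i]) for i, rid in enumerate(order)}
    return FluxDistribution(
        values=values,
        objective_value=vertices[0].objective_value,
        selection_policy_tag=policy,
    )


def _min_norm_in_hull(V: np.ndarray) -> np.ndarray:
    """Minimum-norm point of conv{rows of V} via a simplex-constrained QP."""
    k = V.shape[0]
    if k == 1:
        return V[0]
    G = V @ V.T
    from scipy.optimize import minimize

    res = minimize(
        lambda lam: float(lam @ G @ lam),
        np.full(k, 1.0 / k),
        jac=lambda lam: 2.0 * (G @ lam),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda lam: lam.sum() - 1.0,
                      "jac": lambda lam: np.ones(k)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-16},
    )
    lam = np.clip(res.x, 0.0, None)
    lam /= lam.sum()
    return lam @ V


def wildtype_reference(problem: FBAProblem, policy: str = "min-norm") -> FluxDistribution:
    """Solve, enumerate the optimal face and select the reference point."""
    opt = solve_fba(problem)
    vertices = enumerate_alternate_optima(problem, opt)
    return select_reference_distribution(vertices, policy)
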