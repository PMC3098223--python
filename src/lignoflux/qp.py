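"""Internal convex-programming helpers (small dense problems only).

Every optimization in this package lives on a polytope with at most a few
dozen variables, so the tooling here is deliberately simple: HiGHS for LPs
(via :func:`scipy.optimize.linprog`) and a nullspace-parametrized SLSQP with
an active-set KKT polish for Euclidean-projection QPs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, optimize

FEAS_TOL = 1e-8
RANK_TOL = 1e-10


class InfeasibleError(RuntimeError):
    """Raised when a constraint set has no solution."""


def solve_lp(c, A_eq, b_eq, lb, ub, *, maximize=False):
    """Solve an LP over {A_eq v = b_eq, lb <= v <= ub}; returns the vertex
    solution and the (signed, original-sense) objective value."""
    sign = -1.0 if maximize else 1.0
    res = optimize.linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError("linear program is infeasible")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return res.x, sign * res.fun


def is_feasible(A_eq, b_eq, lb, ub) -> bool:
    try:
        solve_lp(np.zeros(len(lb)), A_eq, b_eq, lb, ub)
    except InfeasibleError:
        return False
    return True


def nullspace(A: np.ndarray, rcond: float = RANK_TOL) -> np.ndarray:
    if A.size == 0:
        raise ValueError("empty constraint matrix")
    return linalg.null_space(A, rcond=rcond)

def _project_affine(target, E, f):
    """Euclidean projection of ``target`` onto {v : E v = f}."""
    resid = E @ target - f
    correction, *_ = np.linalg.lstsq(E, resid, rcond=None)
    # lstsq gives the minimum-norm solution of E x = resid, which is the
    # row-space correction required by the normal equations.
    return target - correction


def project_to_affine_box(A_eq, b_eq, lb, ub, target, *, tol=FEAS_TOL):
    """Euclidean projection of ``target`` onto {A_eq v = b_eq, lb<=v<=ub}.

    Raises :class:`InfeasibleError` when the set is empty.
    """
    A_eq = np.asarray(A_eq, dtype=float)
    b_eq = np.asarray(b_eq, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    target = np.asarray(target, dtype=float)
    n = target.size

    # Feasibility gate (also produces a feasible starting vertex).
    x_feas, _ = solve_lp(np.zeros(n), A_eq, b_eq, lb, ub)

    Z = nullspace(A_eq)
    v0 = _project_affine(target, A_eq, b_eq)
    if Z.shape[1] == 0:
        v = v0
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            raise InfeasibleError("affine solution violates bounds")
        return np.clip(v, lb, ub)

    # v = v0 + Z y; unconstrained optimum is y = 0 because v0 is already the
    # affine projection of the target and Z has orthonormal columns.
    def fun(y):
        d = v0 + Z @ y - target
        return 0.5 * float(d @ d)

    def jac(y):
        return Z.T @ (v0 + Z @ y - target)

    # trust-constr from a feasible vertex; SLSQP stalls on degenerate faces.
    y_start, *_ = np.linalg.lstsq(Z, x_feas - v0, rcond=None)
    box = optimize.LinearConstraint(Z, lb - v0, ub - v0)
    with warnings.catch_warnings():
        # the face is deliberately rank-deficient; SVD fallback is fine
        warnings.simplefilter("ignore", UserWarning)
        res = optimize.minimize(
            fun, y_start, jac=jac, constraints=[box], method="trust-constr",
            hess=lambda y: Z.T @ Z,
            options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
        )
    best = v0 + Z @ res.x
    if np.any(best < lb - 1e-6) or np.any(best > ub + 1e-6):
        raise RuntimeError("QP solver failed to produce a feasible point")

    polished = _active_set_polish(A_eq, b_eq, lb, ub, target, best)
    if polished is not None and np.max(np.abs(A_eq @ polished - b_eq)) < 1e-8:
        best = polished
    best = np.clip(best, lb, ub)
    if np.max(np.abs(A_eq @ best - b_eq)) > 1e-7:
        raise RuntimeError("QP solution violates equality constraints")
    return best


def _active_set_polish(A_eq, b_eq, lb, ub, target, v, *, tol_act=3e-5,
                       max_rounds=40):
    """Refine an approximate projection to machine precision.

    Starting from the working set of nearly-active bounds, repeatedly solve
    the equality-constrained projection, add primal-violated bounds, and
    drop bounds whose KKT multiplier has the wrong sign.  Returns None if
    the loop fails to settle (the caller keeps the unpolished point).
    """
    n = v.size
    eye = np.eye(n)
    active_lo = set(np.where(v - lb < tol_act)[0])
    active_hi = set(np.where(ub - v < tol_act)[0]) - active_lo
    for _ in range(max_rounds):
        rows = [A_eq]
        rhs = [b_eq]
        for i in sorted(active_lo):
            rows.append(eye[i][None, :]); rhs.append([lb[i]])
        for i in sorted(active_hi):
            rows.append(eye[i][None, :]); rhs.append([ub[i]])
        E = np.vstack(rows)
        f = np.concatenate([np.atleast_1d(r) for r in rhs])
        cand = _project_affine(target, E, f)
        if np.max(np.abs(E @ cand - f)) > 1e-9:
            # the working set over-constrains an inconsistent system; the
            # true active set is smaller than the near-active one
            return None

        viol_lo = set(np.where(cand < lb - 1e-9)[0]) - active_lo
        viol_hi = set(np.where(cand > ub + 1e-9)[0]) - active_hi
        if viol_lo or viol_hi:
            active_lo |= viol_lo
            active_hi |= viol_hi - active_lo
            continue

        # dual check: v - t = A_eq' mu + sum_lo lam_i e_i - sum_hi nu_i e_i,
        # lam, nu >= 0
        cols = [A_eq.T]
        cols += [eye[:, [i]] for i in sorted(active_lo)]
        cols += [-eye[:, [i]] for i in sorted(active_hi)]
        M = np.hstack(cols)
        mult, *_ = np.linalg.lstsq(M, cand - target, rcond=None)
        if np.max(np.abs(M @ mult - (cand - target))) > 1e-7:
            return None  # stationarity not met; keep unpolished point
        k = A_eq.shape[0]
        lam = mult[k:k + len(active_lo)]
        nu = mult[k + len(active_lo):]
        drop = None
        for j, i in enumerate(sorted(active_lo)):
            if lam[j] < -1e-9:
                drop = ("lo", i)
                break
        if drop is None:
            for j, i in enumerate(sorted(active_hi)):
                if nu[j] < -1e-9:
                    drop = ("hi", i)
                    break
        if drop is None:
            return np.clip(cand, lb, ub)
        if drop[0] == "lo":
            active_lo.discard(drop[1])
        else:
            active_hi.discard(drop[1])
    return None
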