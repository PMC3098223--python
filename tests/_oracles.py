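"""Independent oracles used by the test suite.

Everything here is deliberately decoupled from the package's own constraint
assembly: the LP oracle builds its constraint matrix from a literal
incidence list typed out below, the MOMA oracle is Dykstra's alternating
projection (affine subspace + box), and the vertex oracle probes the
optimal face with random linear objectives solved by the dual simplex.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

# Literal (substrate, product) incidence of the extended 24-reaction map,
# written out by hand; boundary species are None.
EDGES = {
    "v1": (None, "cinnamic"),
    "v2": ("cinnamic", "coumaric"),
    "v3": ("coumaric", "coumaroyl_coa"),
    "v4": ("coumaroyl_coa", "coumaraldehyde"),
    "v5": ("coumaraldehyde", "coumaryl_alc"),
    "v6": ("coumaryl_alc", None),
    "v7": ("coumaroyl_coa", "coumaroyl_shik"),
    "v8": ("coumaroyl_shik", "caffeoyl_shik"),
    "v9": ("caffeoyl_shik", "caffeoyl_coa"),
    "v10": ("caffeoyl_coa", "caffeyl_ald"),
    "v11": ("caffeoyl_coa", "feruloyl_coa"),
    "v12": ("caffeyl_ald", "coniferyl_ald"),
    "v13": ("feruloyl_coa", "coniferyl_ald"),
    "v14": ("coniferyl_ald", "coniferyl_alc"),
    "v15": ("coniferyl_alc", None),
    "v16": ("coniferyl_ald", "oh5_ald"),
    "v17": ("oh5_ald", "sinapyl_ald"),
    "v18": ("sinapyl_ald", "sinapyl_alc"),
    "v19": ("sinapyl_alc", None),
    "v20": ("coniferyl_alc", "oh5_alc"),
    "v21": ("oh5_alc", "sinapyl_alc"),
    "v22": ("cinnamic", None),
    "v23": ("coumaroyl_coa", None),
    "v24": ("oh5_alc", None),
}
ORDER = tuple(EDGES)
OVERFLOWS = ("v22", "v23", "v24")


def dense_lp_system(h: float, g: float):
    """Equality matrix and bounds of the wild-type LP, assembled from the
    literal incidence list above."""
    species = sorted({m for pair in EDGES.values() for m in pair if m})
    n = len(ORDER)
    rows = []
    for sp in species:
        row = np.zeros(n)
        for j, rid in enumerate(ORDER):
            sub, prod = EDGES[rid]
            if sub == sp:
                row[j] -= 1.0
            if prod == sp:
                row[j] += 1.0
        rows.append(row)
    e1 = np.zeros(n)
    e1[ORDER.index("v1")] = 1.0
    rows.append(e1)
    rhs = [0.0] * len(species) + [1.0]
    for frac, mask in ((h, ("v6",)), (g, ("v15",))):
        row = np.zeros(n)
        for rid in ("v6", "v15", "v19"):
            row[ORDER.index(rid)] -= frac
        for rid in mask:
            row[ORDER.index(rid)] += 1.0
        rows.append(row)
        rhs.append(0.0)
    A = np.vstack(rows)
    b = np.array(rhs)
    lb = np.array([0.01 if r in OVERFLOWS else 0.0 for r in ORDER])
    ub = np.ones(n)
    return A, b, lb, ub


def lp_oracle_objective(h: float, g: float) -> float:
    """Optimal total transport flux by an independent dense LP solve."""
    A, b, lb, ub = dense_lp_system(h, g)
    c = np.zeros(len(ORDER))
    for rid in ("v6", "v15", "v19"):
        c[ORDER.index(rid)] = -1.0
    res = linprog(c, A_eq=A, b_eq=b, bounds=list(zip(lb, ub)), method="highs-ds")
    assert res.status == 0, res.message
    return -res.fun


def dykstra_project(A, b, lb, ub, target, *, block=5000, max_iters=400_000,
                    tol=1e-10):
    """Dykstra alternating projection onto {A v = b} ∩ [lb, ub]."""
    Ap = np.linalg.pinv(A)
    x = target.copy()
    p = np.zeros_like(x)
    q = np.zeros_like(x)
    prev = np.inf
    done = 0
    while done < max_iters:
        for _ in range(block):
            y = (x + p) - Ap @ (A @ (x + p) - b)
            p = x + p - y
            z = np.clip(y + q, lb, ub)
            q = y + q - z
            x = z
        done += block
        d = float(np.linalg.norm(x - target))
        feas = max(float(np.max(np.abs(A @ x - b))),
                   float(np.max(np.maximum(lb - x, x - ub))))
        if abs(d - prev) < tol and feas < 1e-9:
            break
        prev = d
    return x


def probe_face_vertices(A_face, b_face, lb, ub, rng, n_probes=200):
    """Distinct vertex solutions of random LPs over a polytope face."""
    n = A_face.shape[1]
    found = {}
    for _ in range(n_probes):
        c = rng.standard_normal(n)
        res = linprog(c, A_eq=A_face, b_eq=b_face, bounds=list(zip(lb, ub)),
                      method="highs-ds")
        if res.status == 0:
            found[tuple(np.round(res.x, 6))] = res.x
    return list(found.values())
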