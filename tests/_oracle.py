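"""Independent reference solver for the joint flow model.

Re-derives the optimization problem from scratch — dense matrices, explicit
loops in a different row/variable order than the package — and solves it
with a different algorithm (interior point rather than dual simplex).  Used
to cross-check objective values on small instances; objective is the only
valid comparator since optimal flow patterns may be non-unique.
"""

import numpy as np
from scipy.optimize import linprog


def oracle_objective(capacity_matrix, activations, gamma, rho):
    """Optimal cost of the flow + correction program, solved independently.

    capacity_matrix: dense symmetric N x N matrix of D values (zero = absent
    edge, excluded from the candidate set).  activations: N x M nonneg.
    """
    d = np.asarray(capacity_matrix, float)
    r = np.atleast_2d(np.asarray(activations, float))
    n, m = r.shape
    edges = [(i, j) for j in range(n) for i in range(j) if d[i, j] > 0]
    L = len(edges)
    # variables ordered mode-major: [f^0 over edges, f^1 over edges, ..., P]
    nvar = L * m + L

    def f_idx(l, k):
        return k * L + l

    def p_idx(l):
        return m * L + l

    c = np.zeros(nvar)
    for k in range(m):
        for l, (i, j) in enumerate(edges):
            c[f_idx(l, k)] = 1.0 / d[i, j]
    for l, (i, j) in enumerate(edges):
        c[p_idx(l)] = rho * (1.0 + 1.0 / d[i, j])

    rows = []
    rhs = []
    # demand rows first (opposite family order to the implementation)
    for k in range(m):
        for i in range(n):
            row = np.zeros(nvar)
            for l, (a, b) in enumerate(edges):
                if a == i or b == i:
                    row[f_idx(l, k)] = -1.0
            rows.append(row)
            rhs.append(-r[i, k])
    for l, (i, j) in enumerate(edges):
        row = np.zeros(nvar)
        for k in range(m):
            row[f_idx(l, k)] = 1.0
        row[p_idx(l)] = -gamma
        rows.append(row)
        rhs.append(gamma * d[i, j])
    for k in range(m):
        for l, (i, j) in enumerate(edges):
            row = np.zeros(nvar)
            row[f_idx(l, k)] = 1.0
            rows.append(row)
            rhs.append(max(r[i, k], r[j, k]))

    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=(0, None),
                  method="highs-ipm")
    if not res.success:
        return None
    return float(res.fun)
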