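"""Independent oracles used by the test suite and the acceptance report.

The LP oracle enumerates basic feasible solutions (vertices) of the flux
polytope by brute force and takes the best objective value.  It rebuilds
the constraint matrices directly from the model object, independently of
the solver path under test.
"""

from itertools import combinations

import numpy as np


def model_lp_data(model, ratio_constraints=(), fixed_fluxes=None):
    """Rebuild (c, A_eq, b_eq, lb, ub) for a model: mass balance over
    internal metabolites plus optional ratio equalities / fixed fluxes."""
    fixed_fluxes = fixed_fluxes or {}
    rids = [r.id for r in model.reactions]
    n = len(rids)
    internal = [m.id for m in model.metabolites if not m.is_external]
    midx = {m: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), n))
    for j, r in enumerate(model.reactions):
        for m, coeff in r.stoichiometry.items():
            if m in midx:
                S[midx[m], j] = coeff
    c = np.array([r.objective_coefficient for r in model.reactions])
    lb = np.array([r.lower_bound for r in model.reactions], float)
    ub = np.array([r.upper_bound for r in model.reactions], float)
    extra = []
    for num, den, ratio in ratio_constraints:
        row = np.zeros(n)
        row[rids.index(num)] = 1.0
        row[rids.index(den)] = -ratio
        extra.append(row)
    for rid, val in fixed_fluxes.items():
        j = rids.index(rid)
        lb[j] = ub[j] = val
    A_eq = np.vstack([S] + [e[None, :] for e in extra]) if extra else S
    b_eq = np.zeros(A_eq.shape[0])
    return c, A_eq, b_eq, lb, ub


def brute_force_lp_max(c, A_eq, b_eq, lb, ub, A_ub=None, b_ub=None,
                       tol=1e-8):
    """Maximum of c.v over {A_eq v = b_eq, A_ub v <= b_ub, lb <= v <= ub}
    by vertex enumeration.  All bounds must be finite.  Returns None when
    the polytope is empty."""
    n = len(c)
    A_ub = np.zeros((0, n)) if A_ub is None else np.asarray(A_ub, float)
    b_ub = np.zeros(0) if b_ub is None else np.asarray(b_ub, float)
    cand_rows = [row for row in A_ub]
    cand_rhs = list(b_ub)
    eye = np.eye(n)
    for i in range(n):
        cand_rows.append(eye[i])
        cand_rhs.append(ub[i])
        cand_rows.append(-eye[i])
        cand_rhs.append(-lb[i])

    rank_eq = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    k = n - rank_eq
    best = None
    for combo in combinations(range(len(cand_rows)), k):
        M = np.vstack([A_eq] + [cand_rows[i] for i in combo])
        rhs = np.concatenate([b_eq, [cand_rhs[i] for i in combo]])
        if np.linalg.matrix_rank(M) < n:
            continue
        v, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        if np.abs(M @ v - rhs).max() > tol:
            continue  # inconsistent active set
        if (v < lb - tol).any() or (v > ub + tol).any():
            continue
        if A_eq.size and np.abs(A_eq @ v - b_eq).max() > tol:
            continue
        if len(cand_rhs) and (np.array(cand_rows) @ v
                              > np.array(cand_rhs) + tol).any():
            continue
        val = float(c @ v)
        if best is None or val > best:
            best = val
    return best


def brute_force_fba(model, ratio_constraints=(), fixed_fluxes=None):
    c, A_eq, b_eq, lb, ub = model_lp_data(model, ratio_constraints,
                                          fixed_fluxes)
    return brute_force_lp_max(c, A_eq, b_eq, lb, ub)
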