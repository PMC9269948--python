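"""Linear-programming helpers shared by preprocessing, enumeration and
validation.

All LPs are solved with HiGHS through :func:`scipy.optimize.linprog` on the
sparse stoichiometric matrix.  Only internal (non-boundary) metabolite rows
enter the steady-state constraint; boundary metabolites may accumulate.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import DEFAULT_BOUND, GemModel

FVA_TOL = 1e-9
ACTIVE_TOL = 1e-6
ACTIVE_EPS = 1e-4


class SolverError(RuntimeError):
    pass


def steady_state_matrix(model: GemModel) -> sp.csr_matrix:
    """Rows of S over internal metabolites (the balance constraints)."""
    mask = model.internal_metabolite_mask()
    return model.S.tocsr()[mask, :]


def finite_bounds(model: GemModel) -> tuple[np.ndarray, np.ndarray]:
    lb = np.where(np.isfinite(model.lower), model.lower, -DEFAULT_BOUND)
    ub = np.where(np.isfinite(model.upper), model.upper, DEFAULT_BOUND)
    return lb.astype(float), ub.astype(float)


def _solve(c, A_eq, lb, ub, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res


def fva(
    model: GemModel,
    reactions: list[int] | None = None,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction minimum and maximum flux (one LP each way).

    Optional ``lb``/``ub`` override the model bounds (used for
    partially-fixed direction queries).  Raises :class:`SolverError` naming
    the reaction on solver failure.
    """
    A_eq = steady_state_matrix(model)
    if lb is None or ub is None:
        mlb, mub = finite_bounds(model)
        lb = mlb if lb is None else lb
        ub = mub if ub is None else ub
    n = model.n_reactions
    idxs = range(n) if reactions is None else reactions
    mins = np.zeros(n)
    maxs = np.zeros(n)
    c = np.zeros(n)
    for j in idxs:
        for sign, out in ((1.0, mins), (-1.0, maxs)):
            c[j] = sign
            res = _solve(c, A_eq, lb, ub)
            c[j] = 0.0
            if res.status != 0:
                raise SolverError(
                    f"FVA LP failed for reaction {model.reaction_ids[j]}: "
                    f"status {res.status} ({res.message})"
                )
            out[j] = sign * res.fun if sign > 0 else -res.fun
    return mins, maxs


def flux_consistent(
    model: GemModel,
    tol: float = ACTIVE_TOL,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of reactions able to carry non-zero flux.

    Exact (each undecided reaction is eventually checked by its own LP) but
    opportunistic: every LP solution marks all reactions it activates, so
    the typical call needs far fewer than 2n solves.  ``lb``/``ub``
    override the model bounds.
    """
    A_eq = steady_state_matrix(model)
    mlb, mub = finite_bounds(model)
    lb = mlb if lb is None else lb
    ub = mub if ub is None else ub
    n = model.n_reactions
    consistent = np.zeros(n, dtype=bool)
    c = np.zeros(n)
    for j in range(n):
        for sign in (-1.0, 1.0):
            if consistent[j]:
                break
            # c = +1 minimises v_j (explores the backward direction),
            # c = -1 maximises it (forward)
            if sign > 0 and lb[j] >= 0:
                continue
            if sign < 0 and ub[j] <= 0:
                continue
            c[j] = sign
            res = _solve(c, A_eq, lb, ub)
            c[j] = 0.0
            if res.status != 0:
                raise SolverError(
                    f"consistency LP failed for reaction {model.reaction_ids[j]}"
                )
            if abs(res.fun) > tol:
                consistent |= np.abs(res.x) > tol
    return consistent


def directed_bounds(
    model: GemModel, signs: dict[int, int] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp bounds so every reaction in ``signs`` flows in its assigned
    direction.  ``signs`` maps column index -> +1/-1 (dict for partial
    assignments, array with zeros for unassigned)."""
    lb, ub = finite_bounds(model)
    items = signs.items() if isinstance(signs, dict) else enumerate(signs)
    for j, s in items:
        if s > 0:
            lb[j] = max(lb[j], 0.0)
        elif s < 0:
            ub[j] = min(ub[j], 0.0)
    return lb, ub


def all_active(
    model: GemModel,
    signs: np.ndarray,
    eps: float = ACTIVE_EPS,
    tol: float = ACTIVE_TOL,
) -> tuple[bool, int | None]:
    """Can every reaction carry flux in its assigned direction simultaneously?

    ``signs`` gives one orientation per reaction (+1/-1).  A single LP
    maximises the sum of per-reaction activity slacks ``t_j`` with
    ``sign_j * v_j >= t_j`` and ``0 <= t_j <= eps``; if every slack reaches
    ``eps`` the answer is yes.  Reactions whose slack falls short are
    re-checked individually: if each can be active on its own the convex
    average of the individual solutions activates all of them, so the
    per-reaction check is decisive.  Returns (feasible, blocking column).
    """
    n = model.n_reactions
    if np.any(signs == 0):
        raise ValueError("all_active needs a complete orientation")
    lb, ub = directed_bounds(model, signs)
    if np.any(lb > ub):
        return False, int(np.nonzero(lb > ub)[0][0])
    A_eq = sp.hstack([steady_state_matrix(model), sp.csr_matrix((int(np.sum(model.internal_metabolite_mask())), n))]).tocsr()
    # -sign_j * v_j + t_j <= 0
    A_ub = sp.hstack([-sp.diags(signs.astype(float)), sp.eye(n)]).tocsr()
    c = np.concatenate([np.zeros(n), -np.ones(n)])
    lo = np.concatenate([lb, np.zeros(n)])
    hi = np.concatenate([ub, np.full(n, eps)])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(n),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack([lo, hi]),
        method="highs",
    )
    if res.status != 0:
        return False, None
    t = res.x[n:]
    short = np.nonzero(t < eps * 0.5)[0]
    if short.size == 0:
        return True, None
    # decisive per-reaction fallback
    A_eq_v = steady_state_matrix(model)
    cv = np.zeros(n)
    for j in short:
        cv[j] = -float(signs[j])
        r = _solve(cv, A_eq_v, lb, ub)
        cv[j] = 0.0
        if r.status != 0 or -r.fun <= tol:
            return False, int(j)
    return True, None
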