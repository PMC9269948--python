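"""Exact rational linear algebra for the loop law.

Stoichiometric coefficients are converted to :class:`fractions.Fraction`
exactly (binary floats are rationals), so null-space computations carry no
rounding error: ``S_int @ v == 0`` holds identically for every returned
vector.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, gcd

Vector = tuple[Fraction, ...]


def _rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form; returns (rows, pivot column indices)."""
    rows = [list(r) for r in rows]
    m = len(rows)
    ncols = len(rows[0]) if m else 0
    pivots: list[int] = []
    r = 0
    for c in range(ncols):
        pivot = next((i for i in range(r, m) if rows[i][c] != 0), None)
        if pivot is None:
            continue
        rows[r], rows[pivot] = rows[pivot], rows[r]
        inv = rows[r][c]
        rows[r] = [x / inv for x in rows[r]]
        for i in range(m):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    return rows[:r], pivots


def nullspace(rows: list[list[Fraction]], ncols: int) -> list[Vector]:
    """Basis of the null space of the matrix given by ``rows`` (RREF-derived,
    one basis vector per free column)."""
    if not rows:
        return [
            tuple(Fraction(int(i == j)) for i in range(ncols)) for j in range(ncols)
        ]
    red, pivots = _rref(rows)
    free = [c for c in range(ncols) if c not in pivots]
    basis = []
    for fcol in free:
        v = [Fraction(0)] * ncols
        v[fcol] = Fraction(1)
        for row, pcol in zip(red, pivots):
            v[pcol] = -row[fcol]
        basis.append(tuple(v))
    return basis


def _reduce(v: Vector) -> Vector:
    """Clear denominators, divide by content, make first non-zero positive."""
    den = 1
    for x in v:
        den = den * x.denominator // gcd(den, x.denominator)
    ints = [int(x * den) for x in v]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g == 0:
        return tuple(Fraction(0) for _ in v)
    ints = [x // g for x in ints]
    lead = next(x for x in ints if x != 0)
    if lead < 0:
        ints = [-x for x in ints]
    return tuple(Fraction(x) for x in ints)


def elementary_vectors(
    basis: list[Vector], max_subsets: int = 300_000
) -> tuple[list[Vector], bool]:
    """Support-minimal non-zero vectors of the subspace spanned by ``basis``.

    Every support-minimal vector vanishes on ``d - 1`` coordinates whose
    basis rows are independent, so enumerating one-dimensional solution
    spaces over all ``(d-1)``-subsets of coordinates finds them all;
    non-minimal candidates are filtered afterwards.  Returns
    ``(vectors, complete)``; ``complete`` is False when the subset budget is
    exceeded and the (reduced) basis itself is returned as a fallback.
    """
    d = len(basis)
    if d == 0:
        return [], True
    ncols = len(basis[0])
    if d == 1:
        v = _reduce(basis[0])
        return ([v] if any(x != 0 for x in v) else []), True
    if comb(ncols, d - 1) > max_subsets:
        return [_reduce(v) for v in basis], False
    candidates: dict[tuple, Vector] = {}
    cols = list(range(ncols))
    for zero_set in combinations(cols, d - 1):
        sub = [[basis[k][c] for k in range(d)] for c in zero_set]
        alphas = nullspace(sub, d)
        if len(alphas) != 1:
            continue
        alpha = alphas[0]
        v = tuple(
            sum(alpha[k] * basis[k][c] for k in range(d)) for c in range(ncols)
        )
        v = _reduce(v)
        if all(x == 0 for x in v):
            continue
        key = tuple(int(x > 0) - int(x < 0) for x in v)
        candidates.setdefault(key, v)
    vecs = list(candidates.values())
    supports = [frozenset(i for i, x in enumerate(v) if x != 0) for v in vecs]
    minimal = []
    for i, v in enumerate(vecs):
        if not any(
            j != i and supports[j] < supports[i] for j in range(len(vecs))
        ):
            minimal.append(v)
    return minimal, True
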