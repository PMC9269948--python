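"""Directed-topology enumeration by pattern-pruned depth-first search.

A directed topology (DT, a flux tope) of a module assigns one direction to
every reversible reaction such that all reactions of the module can carry
flux simultaneously at steady state without thermodynamically infeasible
internal cycles.  Rather than solving LPs per candidate, infeasible partial
assignments ("sign patterns") are generated up front from three sources:

* single-metabolite mass balance - around every internal metabolite there
  must be at least one producing and one consuming reaction, so when the
  irreversible neighbours do not already guarantee both, the all-producing
  and/or all-consuming orientation of the reversible neighbours is
  infeasible;
* paired-metabolite (pooled) mass balance - two internal metabolites
  interconverted by reactions touching exactly that pair behave as a single
  pooled metabolite, and the same balance argument applies to the pool;
* the loop law - every support-minimal null vector of the internal
  stoichiometric matrix is a closed cycle; a DT orienting all its reactions
  consistently would force flux around the cycle, violating the second law.

The DFS walks the directionality tree and prunes a subtree the moment the
partial assignment contains a full pattern, so counting needs no
optimisation runs.  A heuristic generator can propose extra patterns by
relocating constraints of known patterns onto unconstrained reactions;
candidates are only kept when an FVA oracle certifies that every matching
DT is infeasible, so all emitted patterns are sound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Callable, Iterator

import numpy as np

from . import lp
from ._rational import elementary_vectors, nullspace
from .model import GemModel

__all__ = [
    "SignPattern",
    "LoopLawBasis",
    "DTCensus",
    "ResourceError",
    "mass_balance_patterns",
    "merged_metabolite_patterns",
    "loop_patterns",
    "heuristic_patterns",
    "generate_patterns",
    "dfs_count",
    "enumerate_feasible",
    "module_census",
    "model_dof",
]


class ResourceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SignPattern:
    """A partial direction assignment certified infeasible.

    ``assignment`` maps reversible reaction ids to +1/-1; any DT agreeing
    with it on the whole support is infeasible.  An empty assignment means
    the module admits no feasible DT at all (e.g. an unavoidable cycle of
    irreversible reactions).
    """

    assignment: tuple[tuple[str, int], ...]
    rule_type: str  # mass_balance | merged_mass_balance | loop | heuristic
    witness: str = ""

    @classmethod
    def make(cls, assignment: dict[str, int], rule_type: str, witness: str = "") -> "SignPattern":
        return cls(
            assignment=tuple(sorted(assignment.items())),
            rule_type=rule_type,
            witness=witness,
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.assignment)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.assignment)

    def matches(self, signs: dict[str, int]) -> bool:
        return all(signs.get(r) == s for r, s in self.assignment)


@dataclass
class LoopLawBasis:
    """Null-space description of the internal stoichiometric matrix.

    ``vectors`` are support-minimal (elementary) null vectors over
    ``internal_reactions`` in exact rational arithmetic; ``complete`` is
    False when the elementary enumeration budget was exceeded and only a
    basis is available.
    """

    internal_reactions: list[str]
    vectors: list[tuple[Fraction, ...]]
    complete: bool = True

    def cycle_signs(self) -> list[dict[str, int]]:
        return [
            {
                r: (1 if x > 0 else -1)
                for r, x in zip(self.internal_reactions, vec)
                if x != 0
            }
            for vec in self.vectors
        ]


@dataclass
class DTCensus:
    """Result of a module enumeration."""

    module_id: int
    n: int
    n_feasible: int
    free_reactions: list[str] = field(default_factory=list)
    rejections: dict[int, int] = field(default_factory=dict)
    n_patterns: int = 0

    @property
    def dof(self) -> float:
        if self.n_feasible == 0:
            return float("-inf")
        return math.log2(self.n_feasible)


# ---------------------------------------------------------------------------
# module structure helpers


def reversible_ids(sub: GemModel) -> list[str]:
    return [r for j, r in enumerate(sub.reaction_ids) if sub.reversible[j]]


def _incidence(sub: GemModel):
    """(internal metabolite row -> [(col, coeff)]) and the internal row ids."""
    internal = sub.internal_metabolite_mask()
    rows: dict[int, list[tuple[int, float]]] = {}
    coo = sub.S.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if internal[i]:
            rows.setdefault(int(i), []).append((int(j), float(v)))
    return rows


def _balance_patterns_for_row(
    sub: GemModel,
    entries: list[tuple[int, float]],
    witness: str,
    rule_type: str,
) -> list[SignPattern]:
    """Mass-balance patterns for one (possibly pooled) metabolite row."""
    irrev_produces = irrev_consumes = False
    rev: list[tuple[str, float]] = []
    for j, c in entries:
        if sub.reversible[j]:
            rev.append((sub.reaction_ids[j], c))
        else:
            s = sub.fixed_sign(j)
            if s == 0:
                continue
            if c * s > 0:
                irrev_produces = True
            else:
                irrev_consumes = True
    out: list[SignPattern] = []
    if not irrev_produces:
        # all reversible neighbours consuming leaves no producer
        out.append(
            SignPattern.make(
                {r: (-1 if c > 0 else 1) for r, c in rev}, rule_type, witness
            )
        )
    if not irrev_consumes:
        out.append(
            SignPattern.make(
                {r: (1 if c > 0 else -1) for r, c in rev}, rule_type, witness
            )
        )
    return out


def mass_balance_patterns(sub: GemModel) -> list[SignPattern]:
    """At most two patterns per internal metabolite: the all-producing and
    all-consuming orientations of its reversible neighbours, emitted only
    when the irreversible neighbours do not already guarantee a producer
    (resp. consumer)."""
    rows = _incidence(sub)
    out: list[SignPattern] = []
    for i, entries in sorted(rows.items()):
        out.extend(
            _balance_patterns_for_row(
                sub, entries, sub.metabolite_ids[i], "mass_balance"
            )
        )
    return out


def merged_metabolite_patterns(sub: GemModel) -> list[SignPattern]:
    """Pooled balance around fully mixed metabolite pairs.

    Two internal metabolites A, B are fully mixed when some reaction's
    internal support is exactly {A, B} with opposite-sign coefficients (the
    interconversion conserves a weighted pool w_A A + w_B B).  The pool's
    balance gives patterns over the pool's external reversible neighbours -
    constraints that single-metabolite balances cannot see whenever each
    metabolite keeps the connector as a private escape route.  Chains of
    three or more pooled metabolites are not pooled further (pairs only).
    """
    rows = _incidence(sub)
    pairs: dict[tuple[int, int], tuple[Fraction, Fraction]] = {}
    support_by_col: dict[int, list[tuple[int, float]]] = {}
    for i, entries in rows.items():
        for j, c in entries:
            support_by_col.setdefault(j, []).append((i, c))
    for j, sup in support_by_col.items():
        if len(sup) != 2:
            continue
        (i1, c1), (i2, c2) = sorted(sup)
        if c1 * c2 >= 0:
            continue
        # weights conserve the pool: w1*c1 + w2*c2 = 0, both positive
        w1 = Fraction(abs(c2)).limit_denominator(10**6)
        w2 = Fraction(abs(c1)).limit_denominator(10**6)
        pairs.setdefault((i1, i2), (w1, w2))
    out: list[SignPattern] = []
    for (i1, i2), (w1, w2) in sorted(pairs.items()):
        pooled: dict[int, float] = {}
        for i, w in ((i1, w1), (i2, w2)):
            for j, c in rows[i]:
                pooled[j] = pooled.get(j, 0.0) + float(w) * c
        entries = [(j, c) for j, c in sorted(pooled.items()) if abs(c) > 1e-9]
        witness = f"{sub.metabolite_ids[i1]}+{sub.metabolite_ids[i2]}"
        out.extend(
            _balance_patterns_for_row(sub, entries, witness, "merged_mass_balance")
        )
    return out


def loop_patterns(
    sub: GemModel, max_dim: int = 12
) -> tuple[LoopLawBasis, list[SignPattern]]:
    """Loop-law patterns from the exact null space of S_int.

    S_int collects the columns of reactions whose metabolites are all
    internal (boundary-touching and single-metabolite exchange columns are
    excluded) over the internal metabolite rows.  Each support-minimal null
    vector is a closed cycle; for each orientation compatible with the
    irreversible reactions in its support, the restriction to reversible
    reactions is an infeasible pattern.
    """
    internal = sub.internal_metabolite_mask()
    int_cols = []
    for j in range(sub.n_reactions):
        col = sub.S.getcol(j).tocoo()
        if len(col.row) >= 2 and all(internal[i] for i in col.row):
            int_cols.append(j)
    int_rows = np.nonzero(internal)[0]
    matrix = [
        [Fraction(float(sub.S[i, j])) for j in int_cols] for i in int_rows
    ]
    matrix = [row for row in matrix if any(x != 0 for x in row)]
    basis = nullspace(matrix, len(int_cols))
    if len(basis) > max_dim:
        vectors, complete = [tuple(v) for v in basis], False
    else:
        vectors, complete = elementary_vectors(basis)
    ids = [sub.reaction_ids[j] for j in int_cols]
    law = LoopLawBasis(internal_reactions=ids, vectors=vectors, complete=complete)
    out: list[SignPattern] = []
    for vec in vectors:
        support = [(j, x) for j, x in zip(int_cols, vec) if x != 0]
        for orient in (1, -1):
            ok = True
            assign: dict[str, int] = {}
            for j, x in support:
                s = orient * (1 if x > 0 else -1)
                if sub.reversible[j]:
                    assign[sub.reaction_ids[j]] = s
                elif sub.fixed_sign(j) != s:
                    ok = False
                    break
            if ok:
                witness = "cycle:" + ",".join(
                    f"{sub.reaction_ids[j]}{'+' if orient * (1 if x > 0 else -1) > 0 else '-'}"
                    for j, x in support
                )
                out.append(SignPattern.make(assign, "loop", witness))
    return law, out


def _dedupe(patterns: list[SignPattern]) -> list[SignPattern]:
    """Drop exact duplicates and patterns subsumed by a smaller one."""
    uniq: dict[tuple, SignPattern] = {}
    for p in patterns:
        uniq.setdefault(p.assignment, p)
    ordered = sorted(uniq.values(), key=lambda p: len(p.assignment))
    kept: list[SignPattern] = []
    for p in ordered:
        items = set(p.assignment)
        if any(set(q.assignment) <= items for q in kept):
            continue
        kept.append(p)
    return kept


def fva_infeasibility_oracle(
    sub: GemModel, tol: float = lp.ACTIVE_TOL
) -> Callable[[dict[str, int]], bool]:
    """Certify that every DT matching a partial assignment is infeasible.

    Clamps the assigned directions and checks flux consistency: if some
    reaction of the module then cannot carry flux at all, no matching DT
    can have all reactions active.  Sound (never certifies a satisfiable
    pattern); not complete.
    """
    idx = sub.rxn_index()

    def oracle(assignment: dict[str, int]) -> bool:
        signs = {idx[r]: s for r, s in assignment.items()}
        lb, ub = lp.directed_bounds(sub, signs)
        consistent = lp.flux_consistent(sub, tol=tol, lb=lb, ub=ub)
        return not bool(consistent.all())

    return oracle


def heuristic_patterns(
    existing: list[SignPattern],
    oracle: Callable[[dict[str, int]], bool],
    reversible: list[str],
) -> list[SignPattern]:
    """Relocate one constraint of each known pattern (>= 3 fixed directions)
    onto each unconstrained reaction, both signs; keep only candidates the
    oracle certifies infeasible."""
    constrained = set().union(*(p.support for p in existing)) if existing else set()
    free = [r for r in reversible if r not in constrained]
    seen = {p.assignment for p in existing}
    out: list[SignPattern] = []
    for p in existing:
        if len(p.assignment) < 3:
            continue
        base = p.as_dict()
        for drop in base:
            rest = {r: s for r, s in base.items() if r != drop}
            for q in free:
                for s in (1, -1):
                    cand = dict(rest)
                    cand[q] = s
                    key = tuple(sorted(cand.items()))
                    if key in seen:
                        continue
                    seen.add(key)
                    items = set(key)
                    if any(set(e.assignment) <= items for e in existing):
                        continue
                    if oracle(cand):
                        out.append(
                            SignPattern.make(cand, "heuristic", witness=f"from:{p.witness}")
                        )
    return out


def generate_patterns(
    sub: GemModel,
    use_heuristic: bool = False,
    oracle: Callable[[dict[str, int]], bool] | None = None,
    max_dim: int = 12,
) -> tuple[list[SignPattern], LoopLawBasis]:
    """All pattern classes for one module, deduplicated and subsumption-
    pruned."""
    patterns = mass_balance_patterns(sub)
    patterns += merged_metabolite_patterns(sub)
    law, loops = loop_patterns(sub, max_dim=max_dim)
    patterns += loops
    patterns = _dedupe(patterns)
    if use_heuristic:
        if oracle is None:
            oracle = fva_infeasibility_oracle(sub)
        patterns = _dedupe(
            patterns + heuristic_patterns(patterns, oracle, reversible_ids(sub))
        )
    return patterns, law


# ---------------------------------------------------------------------------
# the search


def _prepare(sub: GemModel, patterns: list[SignPattern], max_n: int):
    rev = reversible_ids(sub)
    n = len(rev)
    constrained = sorted(
        {r for p in patterns for r in p.support},
        key=lambda r: (-sum(r in p.support for p in patterns), r),
    )
    free = [r for r in rev if r not in set(constrained)]
    if len(constrained) > max_n:
        raise ResourceError(
            f"{len(constrained)} pattern-constrained reactions exceed the DFS cap "
            f"{max_n}; N <= 2^{n}"
        )
    pos = {r: i for i, r in enumerate(constrained)}
    buckets: list[list[tuple[int, int, int]]] = [[] for _ in constrained]
    for idx, p in enumerate(patterns):
        sup = sig = 0
        last = -1
        for r, s in p.assignment:
            i = pos[r]
            sup |= 1 << i
            if s > 0:
                sig |= 1 << i
            last = max(last, i)
        if last >= 0:
            buckets[last].append((idx, sup, sig))
    return rev, constrained, free, buckets


def dfs_count(
    sub: GemModel,
    patterns: list[SignPattern],
    module_id: int = 0,
    max_n: int = 40,
) -> DTCensus:
    """Exact count of sign assignments matching no pattern.

    Reactions in no pattern are free and each doubles the count; the DFS
    runs over the constrained reactions ordered by descending pattern
    participation and prunes a subtree as soon as the partial assignment
    contains a full pattern.  Counts are arbitrary-precision integers.
    """
    rev = reversible_ids(sub)
    n = len(rev)
    rejections: dict[int, int] = {}
    for idx, p in enumerate(patterns):
        if not p.assignment:  # unconditional: module admits no DT
            return DTCensus(
                module_id=module_id,
                n=n,
                n_feasible=0,
                free_reactions=[],
                rejections={idx: 1 << n},
                n_patterns=len(patterns),
            )
    rev, constrained, free, buckets = _prepare(sub, patterns, max_n)
    k = len(constrained)

    def rec(d: int, signs: int) -> int:
        if d == k:
            return 1
        total = 0
        for bit in (0, 1):
            s = signs | (bit << d)
            pruned = False
            for idx, sup, sig in buckets[d]:
                if (s & sup) == sig:
                    rejections[idx] = rejections.get(idx, 0) + (1 << (k - d - 1))
                    pruned = True
                    break
            if not pruned:
                total += rec(d + 1, s)
        return total

    count = rec(0, 0) if k else 1
    mult = 1 << len(free)
    return DTCensus(
        module_id=module_id,
        n=n,
        n_feasible=count * mult,
        free_reactions=sorted(free),
        rejections={i: c * mult for i, c in rejections.items()},
        n_patterns=len(patterns),
    )


def enumerate_feasible(
    sub: GemModel,
    patterns: list[SignPattern],
    limit: int | None = None,
    max_n: int = 40,
) -> Iterator[dict[str, int]]:
    """Yield full sign assignments (over all reversible reactions) matching
    no pattern, in deterministic order."""
    if any(not p.assignment for p in patterns):
        return
    rev, constrained, free, buckets = _prepare(sub, patterns, max_n)
    k = len(constrained)
    count = 0

    def rec(d: int, signs: int) -> Iterator[int]:
        if d == k:
            yield signs
            return
        for bit in (0, 1):
            s = signs | (bit << d)
            if any((s & sup) == sig for _, sup, sig in buckets[d]):
                continue
            yield from rec(d + 1, s)

    for signs in rec(0, 0) if k else iter((0,)):
        base = {
            r: (1 if (signs >> i) & 1 else -1) for i, r in enumerate(constrained)
        }
        for combo in product((1, -1), repeat=len(free)):
            full = dict(base)
            full.update(zip(free, combo))
            yield full
            count += 1
            if limit is not None and count >= limit:
                return


def module_census(
    sub: GemModel,
    module_id: int = 0,
    use_heuristic: bool = False,
    max_n: int = 40,
) -> tuple[DTCensus, list[SignPattern], LoopLawBasis]:
    """Generate all patterns for a module and run the DFS count."""
    patterns, law = generate_patterns(sub, use_heuristic=use_heuristic)
    census = dfs_count(sub, patterns, module_id=module_id, max_n=max_n)
    return census, patterns, law


def model_dof(censuses: list[DTCensus], expected_modules: set[int] | None = None) -> float:
    """Network-level topological degrees of freedom: the sum of module DoFs
    (log2 of the Cartesian-product DT count).  -inf when any module has no
    feasible DT."""
    if expected_modules is not None:
        missing = expected_modules - {c.module_id for c in censuses}
        if missing:
            raise ValueError(f"missing censuses for modules: {sorted(missing)}")
    if any(c.n_feasible == 0 for c in censuses):
        return float("-inf")
    return float(sum(c.dof for c in censuses))
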