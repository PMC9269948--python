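"""Independent oracles for the DFS census, plus directionality cliques.

The feasibility verdict for a single DT is the ground truth the search is
measured against: every reaction must be able to carry flux in its assigned
direction (one activity LP with a decisive per-reaction fallback; convexity
turns per-reaction positivity into simultaneous positivity) and the
orientation must not contain any closed internal cycle (checked against the
exact loop-law basis).  Brute force enumerates all 2^n orientations;
random and targeted sampling scale the same verdict to modules too large to
enumerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx
import numpy as np
from scipy.stats import binomtest

from . import lp
from .dt_enum import DTCensus, LoopLawBasis, ResourceError, SignPattern, loop_patterns, reversible_ids
from .model import GemModel

__all__ = [
    "DtFeasibilityVerdict",
    "dt_feasibility",
    "brute_force_census",
    "random_sample_census",
    "targeted_sample_census",
    "directionality_cliques",
    "SampleCensus",
]


@dataclass(frozen=True)
class DtFeasibilityVerdict:
    assignment: tuple[tuple[str, int], ...]
    feasible: bool
    witness: str = ""  # violated cycle or blocked reaction when infeasible


def _full_signs(sub: GemModel, assignment: dict[str, int]) -> np.ndarray | str:
    signs = np.zeros(sub.n_reactions, dtype=int)
    idx = sub.rxn_index()
    for j in range(sub.n_reactions):
        if sub.reversible[j]:
            s = assignment.get(sub.reaction_ids[j])
            if s not in (1, -1):
                raise ValueError(f"missing direction for {sub.reaction_ids[j]}")
            signs[j] = s
        else:
            s = sub.fixed_sign(j)
            if s == 0:
                return sub.reaction_ids[j]
            signs[j] = s
    for r in assignment:
        if r not in idx:
            raise ValueError(f"unknown reaction {r}")
    return signs


def dt_feasibility(
    sub: GemModel,
    assignment: dict[str, int],
    law: LoopLawBasis | None = None,
    tol: float = lp.ACTIVE_TOL,
) -> DtFeasibilityVerdict:
    """Is a full orientation a feasible DT?

    Infeasible when the orientation contains a consistently directed
    internal cycle, or when some reaction cannot carry flux in its
    direction while all others do.
    """
    key = tuple(sorted(assignment.items()))
    signs = _full_signs(sub, assignment)
    if isinstance(signs, str):
        return DtFeasibilityVerdict(key, False, witness=f"clamped:{signs}")
    if law is None:
        law, _ = loop_patterns(sub)
    by_id = {r: int(signs[j]) for j, r in enumerate(sub.reaction_ids)}
    for cyc in law.cycle_signs():
        agree = all(by_id[r] == s for r, s in cyc.items())
        oppose = all(by_id[r] == -s for r, s in cyc.items())
        if agree or oppose:
            return DtFeasibilityVerdict(
                key, False, witness="loop:" + ",".join(sorted(cyc))
            )
    feasible, blocker = lp.all_active(sub, signs, tol=tol)
    witness = "" if feasible else (
        f"blocked:{sub.reaction_ids[blocker]}" if blocker is not None else "lp"
    )
    return DtFeasibilityVerdict(key, feasible, witness=witness)


def brute_force_census(
    sub: GemModel,
    tol: float = lp.ACTIVE_TOL,
    cap: int = 20,
    module_id: int = 0,
) -> DTCensus:
    """Exhaustive enumeration of all 2^n orientations with the LP + loop
    verdict.  Refuses above ``cap`` reversible reactions, quoting the LP
    count the run would need."""
    rev = reversible_ids(sub)
    n = len(rev)
    if n > cap:
        raise ResourceError(
            f"brute force over n={n} would need ~{2 * n * 2 ** n:.3g} LPs; cap is {cap}"
        )
    law, _ = loop_patterns(sub)
    feasible: set[tuple[int, ...]] = set()
    for combo in product((1, -1), repeat=n):
        assignment = dict(zip(rev, combo))
        if dt_feasibility(sub, assignment, law=law, tol=tol).feasible:
            feasible.add(combo)
    free = []
    for i, r in enumerate(rev):
        if all(
            tuple(-s if k == i else s for k, s in enumerate(f)) in feasible
            for f in feasible
        ) and feasible:
            free.append(r)
    return DTCensus(
        module_id=module_id,
        n=n,
        n_feasible=len(feasible),
        free_reactions=sorted(free),
    )


@dataclass
class SampleCensus:
    n_samples: int
    n_feasible: int
    fraction: float
    ci_low: float
    ci_high: float
    unexplained: list[tuple[tuple[str, int], ...]] = field(default_factory=list)


def _match_any(patterns: list[SignPattern], assignment: dict[str, int]) -> bool:
    return any(p.matches(assignment) for p in patterns)


def random_sample_census(
    sub: GemModel,
    n_samples: int,
    seed: int,
    patterns: list[SignPattern] | None = None,
    tol: float = lp.ACTIVE_TOL,
) -> SampleCensus:
    """Verdict on uniformly sampled orientations.

    Returns the feasible fraction with a 95% binomial CI; when ``patterns``
    are given, every infeasible sample is cross-checked against them and
    unexplained infeasibles (a completeness alarm) are reported.
    """
    rng = np.random.default_rng(seed)
    rev = reversible_ids(sub)
    law, _ = loop_patterns(sub)
    n_feas = 0
    unexplained = []
    draws = rng.integers(0, 2, size=(n_samples, len(rev)))
    for row in draws:
        assignment = {r: (1 if b else -1) for r, b in zip(rev, row)}
        verdict = dt_feasibility(sub, assignment, law=law, tol=tol)
        if verdict.feasible:
            n_feas += 1
        elif patterns is not None and not _match_any(patterns, assignment):
            unexplained.append(tuple(sorted(assignment.items())))
    ci = binomtest(n_feas, n_samples).proportion_ci(0.95)
    return SampleCensus(
        n_samples=n_samples,
        n_feasible=n_feas,
        fraction=n_feas / n_samples,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        unexplained=unexplained,
    )


def targeted_sample_census(
    sub: GemModel,
    k: int,
    seed: int = 0,
    budget: int = 2_000_000,
    patterns: list[SignPattern] | None = None,
    tol: float = lp.ACTIVE_TOL,
) -> SampleCensus:
    """Cover the full combinatorial of every k-subset of reversible
    reactions, completing the remaining directions at random; C(n,k) * 2^k
    tests in total."""
    rev = reversible_ids(sub)
    n = len(rev)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    total = math.comb(n, k) * 2**k
    if total > budget:
        raise ResourceError(f"targeted sampling needs {total} tests; budget {budget}")
    rng = np.random.default_rng(seed)
    law, _ = loop_patterns(sub)
    n_feas = 0
    unexplained = []
    for subset in combinations(range(n), k):
        for combo in product((1, -1), repeat=k):
            row = rng.integers(0, 2, size=n)
            assignment = {r: (1 if b else -1) for r, b in zip(rev, row)}
            for i, s in zip(subset, combo):
                assignment[rev[i]] = s
            verdict = dt_feasibility(sub, assignment, law=law, tol=tol)
            if verdict.feasible:
                n_feas += 1
            elif patterns is not None and not _match_any(patterns, assignment):
                unexplained.append(tuple(sorted(assignment.items())))
    ci = binomtest(n_feas, total).proportion_ci(0.95)
    return SampleCensus(
        n_samples=total,
        n_feasible=n_feas,
        fraction=n_feas / total,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        unexplained=unexplained,
    )


def directionality_cliques(
    samples: list[dict[str, int]], cutoff: float = 0.85
) -> list[list[str]]:
    """Maximal cliques of reactions whose directions co-vary across sampled
    feasible DTs (|Pearson r| > cutoff; Bron-Kerbosch via networkx).

    Constant-direction reactions have undefined correlation and are
    excluded with a warning entry in the result's graph; cliques of size 1
    are dropped.
    """
    if len(samples) < 2:
        raise ValueError("need at least two sampled DTs")
    rxns = sorted(samples[0])
    X = np.array([[s[r] for r in rxns] for s in samples], dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        import warnings

        dropped = [r for r, k in zip(rxns, keep) if not k]
        warnings.warn(f"constant-direction reactions excluded: {dropped}")
    rxns = [r for r, k in zip(rxns, keep) if k]
    X = X[:, keep]
    if X.shape[1] < 2:
        return []
    corr = np.corrcoef(X, rowvar=False)
    g = nx.Graph()
    g.add_nodes_from(rxns)
    for a, b in combinations(range(len(rxns)), 2):
        if abs(corr[a, b]) > cutoff:
            g.add_edge(rxns[a], rxns[b])
    return sorted(
        sorted(c) for c in nx.find_cliques(g) if len(c) >= 2
    )
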