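"""FVA-based model reduction and compression.

The pipeline is: flux variability analysis to find blocked reactions and
reversible reactions that only ever run one way, removal/tightening of
those, merging of duplicate columns (including irreversible opposite-
direction pairs, which become one reversible reaction), and lumping of
linear pathways.  Reactions chained through an internal metabolite with
exactly one producer and one consumer are fully coupled and carry
proportional flux, so the chain collapses to a single net reaction; if any
member is irreversible the lumped reaction is irreversible.  Every step
records provenance in a :class:`ReductionRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lp
from .model import GPR, DEFAULT_BOUND, GemModel, from_reaction_table

FVA_TOL = 1e-9


@dataclass
class FvaResult:
    minimum: np.ndarray
    maximum: np.ndarray

    def blocked_mask(self, tol: float = FVA_TOL) -> np.ndarray:
        return (np.abs(self.minimum) <= tol) & (np.abs(self.maximum) <= tol)


@dataclass
class ReductionRecord:
    """Provenance of a reduction step.

    ``lump_map`` maps a compressed reaction id to the ordered list of
    (original reaction id, multiplier): original flux = multiplier x
    compressed flux.
    """

    removed_blocked: set[str] = field(default_factory=set)
    newly_irreversible: dict[str, int] = field(default_factory=dict)
    lump_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    kind: str = "generic"

    def expand_flux(self, flux: dict[str, float]) -> dict[str, float]:
        """Map a flux vector of the compressed model back to the members.

        Chain members each carry their multiplier times the lumped flux;
        for merged duplicates the flux is routed through the first member
        (exact whenever it stays within that member's capacity).
        """
        out: dict[str, float] = {}
        for rid, v in flux.items():
            members = self.lump_map.get(rid, [(rid, 1.0)])
            if self.kind == "duplicates":
                members = members[:1]
            for orig, mult in members:
                out[orig] = out.get(orig, 0.0) + mult * v
        return out


def run_fva(model: GemModel, tol: float = FVA_TOL) -> FvaResult:
    """Minimum and maximum achievable flux for every reaction."""
    mins, maxs = lp.fva(model)
    mins[np.abs(mins) <= tol] = 0.0
    maxs[np.abs(maxs) <= tol] = 0.0
    return FvaResult(minimum=mins, maximum=maxs)


def reduce_model(
    model: GemModel, fva: FvaResult, tol: float = FVA_TOL
) -> tuple[GemModel, ReductionRecord]:
    """Remove blocked reactions and tighten directions FVA proved one-sided.

    A single global FVA already identifies every blocked reaction: removing
    columns whose flux is identically zero leaves the flux polytope
    unchanged, so no further blocked reactions can appear.
    """
    rec = ReductionRecord()
    blocked = fva.blocked_mask(tol)
    out = model.copy()
    for j in np.nonzero(blocked)[0]:
        rec.removed_blocked.add(model.reaction_ids[j])
    for j in range(model.n_reactions):
        if blocked[j] or not model.reversible[j]:
            continue
        if fva.minimum[j] >= -tol:
            out.lower[j] = 0.0
            out.reversible[j] = False
            rec.newly_irreversible[model.reaction_ids[j]] = 1
        elif fva.maximum[j] <= tol:
            out.upper[j] = 0.0
            out.reversible[j] = False
            rec.newly_irreversible[model.reaction_ids[j]] = -1
    keep = np.nonzero(~blocked)[0]
    out = _select_reactions(out, keep)
    return out, rec


def _select_reactions(model: GemModel, cols: np.ndarray) -> GemModel:
    S = model.S[:, cols]
    used_rows = np.nonzero(np.diff(S.tocsr().indptr))[0]
    mets = [model.metabolite_ids[i] for i in used_rows]
    rxns = [model.reaction_ids[j] for j in cols]
    out = GemModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S.tocsr()[used_rows, :].tocsc(),
        lower=model.lower[cols].copy(),
        upper=model.upper[cols].copy(),
        reversible=model.reversible[cols].copy(),
        boundary_metabolites=model.boundary_metabolites & set(mets),
        gpr={r: model.gpr[r] for r in rxns if r in model.gpr},
        notes={k: list(v) for k, v in model.notes.items()},
    )
    return out


def _canonical_column(stoich: dict[str, float]) -> tuple[tuple, float, int]:
    """Scale- and sign-invariant key of a stoichiometry column.

    Returns (key, scale, orientation): column = orientation * scale * key
    coefficients, with the lexicographically first metabolite's coefficient
    normalised to +1.
    """
    items = sorted(stoich.items())
    lead = items[0][1]
    orient = 1 if lead > 0 else -1
    scale = abs(lead)
    key = tuple((m, round(c / (orient * scale), 12)) for m, c in items)
    return key, scale, orient


def merge_duplicates(model: GemModel) -> tuple[GemModel, ReductionRecord]:
    """Merge columns identical up to sign and positive scaling.

    An irreversible pair pointing in opposite directions becomes a single
    reversible reaction; capacities add; GPRs are unioned.
    """
    rec = ReductionRecord(kind="duplicates")
    groups: dict[tuple, list[int]] = {}
    scales: dict[int, tuple[float, int]] = {}
    for j in range(model.n_reactions):
        key, scale, orient = _canonical_column(model.stoichiometry(j))
        groups.setdefault(key, []).append(j)
        scales[j] = (scale, orient)
    reactions = []
    gprs: dict[str, GPR] = {}
    for key, members in sorted(groups.items(), key=lambda kv: min(kv[1])):
        j0 = members[0]
        rid = model.reaction_ids[j0]
        stoich = model.stoichiometry(j0)
        if len(members) == 1:
            reactions.append((rid, stoich, model.lower[j0], model.upper[j0]))
            if rid in model.gpr:
                gprs[rid] = model.gpr[rid]
            continue
        scale0, orient0 = scales[j0]
        ub = lb = 0.0
        prov = []
        genes: set[str] = set()
        raws = []
        for j in members:
            scale, orient = scales[j]
            rel = (orient * scale) / (orient0 * scale0)  # member flux per unit merged flux
            prov.append((model.reaction_ids[j], 1.0 / rel))
            g = model.gpr.get(model.reaction_ids[j])
            if g is not None:
                genes |= set(g.genes)
                if g.raw:
                    raws.append(g.raw)
            mlb, mub = model.lower[j], model.upper[j]
            # member flux v_j = u / rel; capacity of u from member j
            cap_hi = mub * rel if rel > 0 else mlb * rel
            cap_lo = mlb * rel if rel > 0 else mub * rel
            ub += max(cap_hi, 0.0)
            lb += min(cap_lo, 0.0)
        reactions.append((rid, stoich, lb, ub))
        rec.lump_map[rid] = prov
        gprs[rid] = GPR(raw=" or ".join(f"({r})" for r in raws), genes=frozenset(genes))
    out = from_reaction_table(
        reactions, boundary_metabolites=set(model.boundary_metabolites), gpr=gprs
    )
    out.boundary_metabolites = model.boundary_metabolites & set(out.metabolite_ids)
    out.notes = {k: list(v) for k, v in model.notes.items()}
    return out, rec


def compress_linear_pathways(model: GemModel) -> tuple[GemModel, ReductionRecord]:
    """Lump maximal linear chains through internal degree-2 metabolites.

    Run after blocked-reaction removal.  The flux cone projected on the
    retained reactions is unchanged (the eliminated metabolite's balance is
    substituted into the surviving column).  Chains whose net stoichiometry
    cancels to zero are reported in the record and left unlumped.
    """
    rec = ReductionRecord(kind="chains")
    stoich: dict[str, dict[str, float]] = {
        rid: model.stoichiometry(j) for j, rid in enumerate(model.reaction_ids)
    }
    bounds: dict[str, tuple[float, float]] = {
        rid: (float(model.lower[j]), float(model.upper[j]))
        for j, rid in enumerate(model.reaction_ids)
    }
    prov: dict[str, list[tuple[str, float]]] = {
        rid: [(rid, 1.0)] for rid in model.reaction_ids
    }
    genes: dict[str, tuple[set[str], list[str]]] = {
        rid: (set(g.genes), [g.raw] if g.raw else [])
        for rid, g in model.gpr.items()
    }
    incident: dict[str, set[str]] = {}
    for rid, st in stoich.items():
        for m in st:
            incident.setdefault(m, set()).add(rid)
    skip: set[str] = set()

    def degree2_candidates():
        return [
            m
            for m, rs in incident.items()
            if len(rs) == 2 and m not in model.boundary_metabolites and m not in skip
        ]

    queue = degree2_candidates()
    while queue:
        m = queue.pop()
        rs = incident.get(m, set())
        if len(rs) != 2 or m in skip:
            continue
        r1, r2 = sorted(rs)
        c1, c2 = stoich[r1][m], stoich[r2][m]
        k = -c1 / c2  # flux of r2 per unit flux of r1
        new = dict(stoich[r1])
        for met, c in stoich[r2].items():
            new[met] = new.get(met, 0.0) + k * c
        new = {met: c for met, c in new.items() if abs(c) > 1e-12}
        if not new:
            rec.notes.append(f"chain through {m} cancels to zero; not lumped")
            skip.add(m)
            continue
        lb1, ub1 = bounds[r1]
        lb2, ub2 = bounds[r2]
        if k > 0:
            lb, ub = max(lb1, lb2 / k), min(ub1, ub2 / k)
        else:
            lb, ub = max(lb1, ub2 / k), min(ub1, lb2 / k)
        if lb > ub:
            rec.notes.append(f"chain through {m} has contradictory directions")
            skip.add(m)
            continue
        # update bookkeeping: r1 absorbs r2, metabolite m disappears
        for met in stoich[r2]:
            incident[met].discard(r2)
        for met in stoich[r1]:
            incident[met].discard(r1)
        stoich[r1] = new
        bounds[r1] = (lb, ub)
        prov[r1] = prov[r1] + [(orig, mult * k) for orig, mult in prov[r2]]
        g1 = genes.get(r1, (set(), []))
        g2 = genes.get(r2, (set(), []))
        genes[r1] = (g1[0] | g2[0], g1[1] + g2[1])
        del stoich[r2], bounds[r2], prov[r2]
        genes.pop(r2, None)
        for met in new:
            incident.setdefault(met, set()).add(r1)
        incident.pop(m, None)
        queue = degree2_candidates()

    order = [rid for rid in model.reaction_ids if rid in stoich]
    reactions = [(rid, stoich[rid], *bounds[rid]) for rid in order]
    gprs = {
        rid: GPR(raw=" and ".join(f"({r})" for r in genes[rid][1]), genes=frozenset(genes[rid][0]))
        for rid in order
        if rid in genes
    }
    out = from_reaction_table(
        reactions, boundary_metabolites=set(model.boundary_metabolites), gpr=gprs
    )
    out.boundary_metabolites = model.boundary_metabolites & set(out.metabolite_ids)
    out.notes = {k: list(v) for k, v in model.notes.items()}
    for rid in order:
        if len(prov[rid]) > 1:
            rec.lump_map[rid] = prov[rid]
    return out, rec


def preprocess(
    model: GemModel, tol: float = FVA_TOL
) -> tuple[GemModel, list[ReductionRecord], dict[str, int]]:
    """reduce -> merge duplicates -> compress; returns the summary counts
    (reactions / reversible reactions / metabolites per stage)."""
    summary = {
        "reactions_initial": model.n_reactions,
        "reversible_initial": int(model.reversible.sum()),
        "metabolites_initial": model.n_metabolites,
    }
    fva = run_fva(model, tol)
    reduced, rec1 = reduce_model(model, fva, tol)
    summary.update(
        blocked_removed=len(rec1.removed_blocked),
        newly_irreversible=len(rec1.newly_irreversible),
        reactions_reduced=reduced.n_reactions,
        reversible_reduced=int(reduced.reversible.sum()),
        metabolites_reduced=reduced.n_metabolites,
    )
    merged, rec2 = merge_duplicates(reduced)
    compressed, rec3 = compress_linear_pathways(merged)
    summary.update(
        reactions_final=compressed.n_reactions,
        reversible_final=int(compressed.reversible.sum()),
        metabolites_final=compressed.n_metabolites,
    )
    return compressed, [rec1, rec2, rec3], summary
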