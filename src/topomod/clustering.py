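"""Topological modules of structural reversible reactions.

Currency metabolites (cofactors, protons, moieties) are stripped from the
stoichiometry for clustering only; reactions are then linked whenever they
share a retained, non-boundary metabolite, and modules are the connected
components of this graph restricted to reversible reactions.  Irreversible
reactions are the insulation between modules: a bordering irreversible
reaction whose retained metabolites all occur inside one module is
"internal" to it, any other bordering one is "external".

For enumeration the full (currency-inclusive) stoichiometry of a module's
reactions is restored by :func:`module_subnetwork`; stripping is reversible
and used purely to define the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import CurrencyTable, GemModel

__all__ = [
    "ModulePartition",
    "strip_currency",
    "detect_antiporters",
    "build_reaction_graph",
    "cluster_modules",
    "module_subnetwork",
]


@dataclass
class ModulePartition:
    """Module id -> reversible members, plus each module's internal and
    external irreversible reactions."""

    modules: dict[int, frozenset[str]]
    internal_irreversible: dict[int, frozenset[str]] = field(default_factory=dict)
    external_irreversible: dict[int, frozenset[str]] = field(default_factory=dict)

    def module_of(self) -> dict[str, int]:
        return {r: mid for mid, members in self.modules.items() for r in members}

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def sizes(self) -> dict[int, int]:
        return {mid: len(members) for mid, members in self.modules.items()}

    def reversible_sets(self) -> set[frozenset[str]]:
        return set(self.modules.values())


def strip_currency(model: GemModel, ct: CurrencyTable) -> GemModel:
    """Zero out currency metabolites' coefficients except where the table
    keeps them (synthesis/degradation/building-block roles, or reactions
    flagged ambiguous)."""
    ct.validate(model)
    out = model.copy()
    if not ct.metabolites:
        return out
    midx = out.met_index()
    currency_rows = {midx[m]: m for m in ct.metabolites if m in midx}
    S = out.S.tolil()
    for i, met in currency_rows.items():
        row = S.rows[i]
        keep_cols = []
        keep_vals = []
        for pos, j in enumerate(row):
            rid = out.reaction_ids[j]
            if rid in ct.keep_all or (rid, met) in ct.exceptions:
                keep_cols.append(j)
                keep_vals.append(S.data[i][pos])
        S.rows[i] = keep_cols
        S.data[i] = keep_vals
    out.S = S.tocsc()
    out.notes.setdefault("currency_stripped", []).extend(sorted(ct.metabolites))
    return out


def _compartment(met_id: str) -> str | None:
    if met_id.endswith("]") and "[" in met_id:
        return met_id[met_id.rindex("[") + 1 : -1]
    return None


def _species(met_id: str) -> str:
    if met_id.endswith("]") and "[" in met_id:
        return met_id[: met_id.rindex("[")]
    return met_id


def detect_antiporters(model: GemModel) -> tuple[set[str], set[str]]:
    """Reversible 1:1 antiporters (A[c1] + B[c2] <-> A[c2] + B[c1], A != B)
    and a keep-list preserving transportability of every species.

    Returns ``(antiporters, keep)``: removing ``antiporters - keep`` leaves
    every (species, compartment pair) moved by a removed antiporter still
    transportable by some remaining reaction.  The keep-list is greedy in
    reaction-id order.
    """
    antiporters: set[str] = set()
    moves: dict[str, set[tuple[str, str, str]]] = {}
    transporters: dict[tuple[str, str, str], set[str]] = {}
    for j, rid in enumerate(model.reaction_ids):
        stoich = model.stoichiometry(j)
        species: dict[str, dict[str, float]] = {}
        for met, c in stoich.items():
            species.setdefault(_species(met), {})[_compartment(met) or "c"] = c
        rxn_moves = set()
        is_transport = False
        for sp, comps in species.items():
            if len(comps) == 2:
                (c1, v1), (c2, v2) = sorted(comps.items())
                if v1 * v2 < 0:
                    is_transport = True
                    src, dst = (c1, c2) if v1 < 0 else (c2, c1)
                    rxn_moves.add((sp, src, dst))
        if not is_transport:
            continue
        for mv in rxn_moves:
            transporters.setdefault(mv, set()).add(rid)
            if model.reversible[j]:
                transporters.setdefault((mv[0], mv[2], mv[1]), set()).add(rid)
        if (
            model.reversible[j]
            and len(species) == 2
            and all(len(c) == 2 for c in species.values())
            and len(rxn_moves) == 2
        ):
            dirs = {(src, dst) for _, src, dst in rxn_moves}
            if len({mv[0] for mv in rxn_moves}) == 2 and len(dirs) == 2:
                antiporters.add(rid)
                moves[rid] = rxn_moves
    keep: set[str] = set()
    removed: set[str] = set()
    for rid in sorted(antiporters):
        needed = False
        for mv in moves[rid]:
            fwd = transporters.get(mv, set()) - removed - {rid}
            rev = transporters.get((mv[0], mv[2], mv[1]), set()) - removed - {rid}
            if not fwd and not rev:
                needed = True
                break
        if needed:
            keep.add(rid)
        else:
            removed.add(rid)
    return antiporters, keep


def build_reaction_graph(model: GemModel) -> nx.Graph:
    """Graph over all reactions; an edge joins two reactions sharing at
    least one retained, non-boundary metabolite (edge attribute
    ``metabolites``).  Call after :func:`strip_currency`."""
    g = nx.Graph()
    met_sets: dict[str, set[str]] = {}
    incident: list[list[int]] = [[] for _ in range(model.n_metabolites)]
    Scoo = model.S.tocoo()
    for i, j in zip(Scoo.row, Scoo.col):
        incident[i].append(j)
    for j, rid in enumerate(model.reaction_ids):
        g.add_node(rid, reversible=bool(model.reversible[j]))
        met_sets[rid] = set()
    for i, met in enumerate(model.metabolite_ids):
        if met in model.boundary_metabolites:
            continue
        rxns = incident[i]
        for j in rxns:
            met_sets[model.reaction_ids[j]].add(met)
        for a in range(len(rxns)):
            for b in range(a + 1, len(rxns)):
                u, v = model.reaction_ids[rxns[a]], model.reaction_ids[rxns[b]]
                if u == v:
                    continue
                if g.has_edge(u, v):
                    g[u][v]["metabolites"].add(met)
                else:
                    g.add_edge(u, v, metabolites={met})
    nx.set_node_attributes(g, met_sets, "metabolites")
    return g


def cluster_modules(graph: nx.Graph) -> ModulePartition:
    """Connected components of the reversible-reaction subgraph, with
    bordering irreversible reactions classified internal/external.

    Modules are numbered 1..k by decreasing size, ties by smallest member
    id, so the numbering is deterministic.
    """
    rev_nodes = [n for n, d in graph.nodes(data=True) if d.get("reversible")]
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph.subgraph(rev_nodes))),
        key=lambda c: (-len(c), c[0]),
    )
    modules = {mid: frozenset(c) for mid, c in enumerate(comps, start=1)}
    module_mets = {
        mid: set().union(*(graph.nodes[r].get("metabolites", set()) for r in members))
        for mid, members in modules.items()
    }
    internal: dict[int, set[str]] = {mid: set() for mid in modules}
    external: dict[int, set[str]] = {mid: set() for mid in modules}
    member_of = {r: mid for mid, ms in modules.items() for r in ms}
    for n, d in graph.nodes(data=True):
        if d.get("reversible"):
            continue
        mets = d.get("metabolites", set())
        touched = {
            member_of[nb] for nb in graph.neighbors(n) if nb in member_of
        }
        if not touched:
            continue
        home = next(
            (mid for mid in touched if mets and mets <= module_mets[mid]), None
        )
        if home is not None:
            internal[home].add(n)
        else:
            for mid in touched:
                external[mid].add(n)
    return ModulePartition(
        modules=modules,
        internal_irreversible={m: frozenset(v) for m, v in internal.items()},
        external_irreversible={m: frozenset(v) for m, v in external.items()},
    )


def adjacency_matrix(graph: nx.Graph, part: ModulePartition) -> tuple[np.ndarray, list[str]]:
    """Reversible-reaction adjacency matrix ordered by module; block
    diagonal when the partition is valid."""
    order = [r for mid in sorted(part.modules) for r in sorted(part.modules[mid])]
    A = nx.to_numpy_array(graph, nodelist=order, weight=None)
    return A, order


def module_subnetwork(
    model: GemModel, part: ModulePartition, module_id: int
) -> GemModel:
    """Submodel of one module with original stoichiometry restored.

    Includes the module's reversible reactions and its internal and
    external irreversible reactions; metabolites also touched by reactions
    outside the submodel (or boundary in the parent) are marked boundary.

    ``model`` must be the full-stoichiometry model the partition was
    derived from (before currency stripping).
    """
    if module_id not in part.modules:
        raise KeyError(f"unknown module id {module_id}")
    wanted = (
        set(part.modules[module_id])
        | set(part.internal_irreversible.get(module_id, ()))
        | set(part.external_irreversible.get(module_id, ()))
    )
    idx = model.rxn_index()
    cols = sorted(idx[r] for r in wanted)
    keep = np.array(cols, dtype=int)
    S = model.S[:, keep]
    used_rows = np.nonzero(np.diff(S.tocsr().indptr))[0]
    outside = np.ones(model.n_reactions, dtype=bool)
    outside[keep] = False
    touched_outside = np.asarray(
        (model.S[:, outside] != 0).sum(axis=1)
    ).ravel() > 0
    mets = [model.metabolite_ids[i] for i in used_rows]
    boundary = {
        model.metabolite_ids[i]
        for i in used_rows
        if touched_outside[i] or model.metabolite_ids[i] in model.boundary_metabolites
    }
    rxns = [model.reaction_ids[j] for j in keep]
    sub = GemModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S.tocsr()[used_rows, :].tocsc(),
        lower=model.lower[keep].copy(),
        upper=model.upper[keep].copy(),
        reversible=model.reversible[keep].copy(),
        boundary_metabolites=boundary,
        gpr={r: model.gpr[r] for r in rxns if r in model.gpr},
    )
    return sub
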