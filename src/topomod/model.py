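"""In-memory representation of constraint-based metabolic models.

A :class:`GemModel` holds the sparse stoichiometric matrix ``S`` (rows are
metabolites, columns are reactions), per-reaction flux bounds and
reversibility flags, the set of boundary (unbalanced) metabolites and the
gene-protein-reaction (GPR) association of each reaction.  Metabolite
identifiers carry their compartment as a bracket suffix (``"agm[p]"``);
SBML/JSON species identifiers are normalised to this form on load.

Three input dialects are supported: SBML Level 3 and the common
constraint-based JSON schema (both read through cobrapy), and a plain
TSV triplet (metabolite, reaction, coefficient) for small fixtures.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_BOUND = 1000.0

__all__ = [
    "GemModel",
    "GPR",
    "DirectionalityConstraints",
    "CurrencyTable",
    "ModelValidationError",
    "ModelFormatError",
    "load_model",
    "write_model",
    "apply_constraints",
    "apply_aliases",
]


class ModelValidationError(ValueError):
    """Raised when a model or auxiliary table violates an invariant."""


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed in the named dialect."""


@dataclass(frozen=True)
class GPR:
    """Gene association of one reaction: the raw boolean rule plus the
    flat gene set (only the gene set is used downstream)."""

    raw: str = ""
    genes: frozenset[str] = frozenset()

    @classmethod
    def from_rule(cls, rule: str) -> "GPR":
        rule = (rule or "").strip()
        tokens = re.split(r"[()\s]+", rule)
        genes = frozenset(t for t in tokens if t and t.lower() not in ("and", "or"))
        return cls(raw=rule, genes=genes)


@dataclass
class GemModel:
    """A stoichiometric model.

    Invariants (checked by :meth:`validate`): ``S`` has no all-zero column,
    every reaction with a negative lower bound is flagged reversible,
    boundary metabolites are a subset of the metabolite set and
    ``lower <= upper`` for every reaction.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lower: np.ndarray
    upper: np.ndarray
    reversible: np.ndarray
    boundary_metabolites: set[str] = field(default_factory=set)
    gpr: dict[str, GPR] = field(default_factory=dict)
    notes: dict[str, list[str]] = field(default_factory=dict)

    # -- basic accessors -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def met_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolite_ids)}

    def rxn_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.reaction_ids)}

    def stoichiometry(self, rxn: str | int) -> dict[str, float]:
        """Metabolite -> coefficient for one reaction column."""
        j = rxn if isinstance(rxn, int) else self.rxn_index()[rxn]
        col = self.S.getcol(j).tocoo()
        return {self.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}

    def internal_metabolite_mask(self) -> np.ndarray:
        """True for metabolites that must be balanced at steady state."""
        return np.array(
            [m not in self.boundary_metabolites for m in self.metabolite_ids],
            dtype=bool,
        )

    def fixed_sign(self, j: int) -> int:
        """Allowed flux sign of an irreversible reaction column
        (+1 forward-only, -1 backward-only, 0 clamped to zero)."""
        if self.lower[j] >= 0 and self.upper[j] > 0:
            return 1
        if self.upper[j] <= 0 and self.lower[j] < 0:
            return -1
        return 0

    def copy(self) -> "GemModel":
        return GemModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower=self.lower.copy(),
            upper=self.upper.copy(),
            reversible=self.reversible.copy(),
            boundary_metabolites=set(self.boundary_metabolites),
            gpr=dict(self.gpr),
            notes={k: list(v) for k, v in self.notes.items()},
        )

    def validate(self, allow_zero_columns: bool = False) -> None:
        if self.n_reactions == 0 or self.n_metabolites == 0:
            raise ModelValidationError("empty model")
        if self.S.shape != (self.n_metabolites, self.n_reactions):
            raise ModelValidationError(
                f"S shape {self.S.shape} does not match "
                f"{self.n_metabolites} metabolites x {self.n_reactions} reactions"
            )
        if len(set(self.reaction_ids)) != self.n_reactions:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != self.n_metabolites:
            raise ModelValidationError("duplicate metabolite ids")
        if not allow_zero_columns:
            nnz = np.diff(self.S.tocsc().indptr)
            flagged = set(self.notes.get("zero_stoichiometry", ()))
            bad = [
                self.reaction_ids[j]
                for j in np.nonzero(nnz == 0)[0]
                if self.reaction_ids[j] not in flagged
            ]
            if bad:
                raise ModelValidationError(f"all-zero stoichiometry columns: {bad}")
        if np.any(self.lower > self.upper):
            j = int(np.nonzero(self.lower > self.upper)[0][0])
            raise ModelValidationError(
                f"lower > upper for reaction {self.reaction_ids[j]}"
            )
        both_open = (self.lower < 0) & (self.upper > 0)
        if np.any(both_open != self.reversible):
            j = int(np.nonzero(both_open != self.reversible)[0][0])
            raise ModelValidationError(
                "reversible flag inconsistent with bounds for reaction "
                f"{self.reaction_ids[j]} (reversible means both directions open)"
            )
        missing = self.boundary_metabolites - set(self.metabolite_ids)
        if missing:
            raise ModelValidationError(f"unknown boundary metabolites: {sorted(missing)}")


@dataclass
class DirectionalityConstraints:
    """Per-reaction direction overrides plus a medium definition.

    ``direction`` maps reaction id to one of ``forward_only``,
    ``backward_only`` or ``free``; ``medium`` maps exchange reaction id to
    its (lower, upper) bounds.
    """

    direction: dict[str, str] = field(default_factory=dict)
    medium: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self, model: GemModel) -> None:
        known = set(model.reaction_ids)
        unknown = sorted((set(self.direction) | set(self.medium)) - known)
        if unknown:
            raise ModelValidationError(f"constraints reference unknown reactions: {unknown}")
        bad = [r for r, d in self.direction.items()
               if d not in ("forward_only", "backward_only", "free")]
        if bad:
            raise ModelValidationError(f"invalid direction values for: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DirectionalityConstraints":
        df = pd.read_csv(path, sep="\t", comment="#")
        dc = cls()
        for _, row in df.iterrows():
            rid = str(row["reaction"])
            if "direction" in df.columns and isinstance(row.get("direction"), str):
                dc.direction[rid] = row["direction"]
            if "lower" in df.columns and not pd.isna(row.get("lower")):
                dc.medium[rid] = (float(row["lower"]), float(row["upper"]))
        return dc


@dataclass
class CurrencyTable:
    """Currency metabolites to strip for clustering, with per-reaction
    exceptions where a listed metabolite is retained (synthesis,
    degradation or building-block role) and reactions where role
    assignment is ambiguous so all metabolites are kept."""

    metabolites: set[str] = field(default_factory=set)
    exceptions: set[tuple[str, str]] = field(default_factory=set)  # (reaction, metabolite)
    keep_all: set[str] = field(default_factory=set)  # reactions kept intact

    def validate(self, model: GemModel) -> None:
        known = set(model.reaction_ids)
        referenced = {r for r, _ in self.exceptions} | self.keep_all
        unknown = sorted(referenced - known)
        if unknown:
            raise ModelValidationError(f"currency table references unknown reactions: {unknown}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CurrencyTable":
        """Read a two-section table: rows with kind `currency` list global
        currency metabolites, `keep` rows list (reaction, metabolite)
        exceptions, `keep_all` rows list ambiguous reactions."""
        df = pd.read_csv(path, sep="\t", comment="#")
        ct = cls()
        for _, row in df.iterrows():
            kind = str(row["kind"])
            met = None if pd.isna(row.get("metabolite")) else str(row["metabolite"])
            rxn = None if pd.isna(row.get("reaction")) else str(row["reaction"])
            if kind == "currency" and met:
                ct.metabolites.add(met)
            elif kind == "keep" and met and rxn:
                ct.exceptions.add((rxn, met))
            elif kind == "keep_all" and rxn:
                ct.keep_all.add(rxn)
        return ct


# ---------------------------------------------------------------------------
# construction helpers


def from_reaction_table(
    reactions: list[tuple[str, dict[str, float], float, float]],
    boundary_metabolites: set[str] | None = None,
    gpr: dict[str, GPR] | None = None,
) -> GemModel:
    """Build a GemModel from (id, stoichiometry, lower, upper) tuples.

    Metabolites whose id carries the external tag ``[e]`` are boundary in
    addition to any explicitly supplied set.
    """
    met_ids: list[str] = []
    met_pos: dict[str, int] = {}
    rows, cols, vals = [], [], []
    rxn_ids, lbs, ubs = [], [], []
    for j, (rid, stoich, lb, ub) in enumerate(reactions):
        rxn_ids.append(rid)
        lbs.append(float(lb))
        ubs.append(float(ub))
        for m, c in stoich.items():
            if c == 0:
                continue
            if m not in met_pos:
                met_pos[m] = len(met_ids)
                met_ids.append(m)
            rows.append(met_pos[m])
            cols.append(j)
            vals.append(float(c))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    lower = np.array(lbs)
    upper = np.array(ubs)
    boundary = set(boundary_metabolites or set())
    boundary |= {m for m in met_ids if m.endswith("[e]")}
    model = GemModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower=lower,
        upper=upper,
        reversible=(lower < 0) & (upper > 0),
        boundary_metabolites=boundary & set(met_ids),
        gpr=dict(gpr or {}),
    )
    return model


def _normalise_met_id(met_id: str, compartment: str | None) -> str:
    if "[" in met_id and met_id.endswith("]"):
        return met_id
    if compartment and met_id.endswith(f"_{compartment}"):
        met_id = met_id[: -(len(compartment) + 1)]
    comp = compartment or "c"
    return f"{met_id}[{comp}]"


def _from_cobra(cmodel) -> GemModel:
    met_names = {}
    for met in cmodel.metabolites:
        met_names[met.id] = _normalise_met_id(met.id, met.compartment)
    reactions = []
    gprs: dict[str, GPR] = {}
    exchange_only: dict[str, bool] = {}
    for rxn in cmodel.reactions:
        stoich = {met_names[m.id]: float(c) for m, c in rxn.metabolites.items()}
        reactions.append((rxn.id, stoich, float(rxn.lower_bound), float(rxn.upper_bound)))
        gprs[rxn.id] = GPR.from_rule(rxn.gene_reaction_rule)
        boundary_rxn = len(rxn.metabolites) == 1
        for m in rxn.metabolites:
            name = met_names[m.id]
            exchange_only[name] = exchange_only.get(name, True) and boundary_rxn
    boundary = {
        met_names[m.id]
        for m in cmodel.metabolites
        if (m.compartment or "").lower() in ("e", "extracellular")
        or getattr(m, "boundary_condition", False)
    }
    boundary |= {m for m, only in exchange_only.items() if only}
    model = from_reaction_table(reactions, boundary_metabolites=boundary, gpr=gprs)
    return model


def to_cobra(model: GemModel, name: str = "model"):
    """Convert to a cobrapy model.  Boundary metabolites are dropped from
    the stoichiometries (the cobra convention for unbalanced species), so
    flux analyses agree with the internal steady-state constraint."""
    import cobra

    cmodel = cobra.Model(name)
    mets = {}
    for m in model.metabolite_ids:
        if m in model.boundary_metabolites:
            continue
        comp = m[m.rindex("[") + 1 : -1] if m.endswith("]") and "[" in m else "c"
        met = cobra.Metabolite(m.replace("[", "_").rstrip("]"), compartment=comp)
        mets[m] = met
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower[j])
        rxn.upper_bound = float(model.upper[j])
        rxns.append(rxn)
    cmodel.add_reactions(rxns)
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            mets[m]: c
            for m, c in model.stoichiometry(j).items()
            if m in mets
        }
        cmodel.reactions.get_by_id(rid).add_metabolites(stoich)
    return cmodel


def load_model(path: str | Path, dialect: str = "auto") -> GemModel:
    """Read a model in SBML, JSON or TSV-triplet form and validate it.

    ``dialect="auto"`` infers the format from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = {".xml": "sbml", ".sbml": "sbml", ".json": "json"}.get(
            path.suffix.lower(), "tsv-triplet"
        )
    if dialect == "sbml":
        import cobra.io

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # pragma: no cover - libsbml error paths
            raise ModelFormatError(f"SBML parse failure in {path.name}: {exc}") from exc
        model = _from_cobra(cmodel)
    elif dialect == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"JSON parse failure in {path.name}: {exc}") from exc
        if "reactions" in payload and payload.get("metabolites") is not None and \
                payload["reactions"] and "stoichiometry" in payload["reactions"][0]:
            model = _from_json_dialect(payload)
        else:  # cobra community JSON schema
            import cobra.io

            try:
                cmodel = cobra.io.load_json_model(str(path))
            except Exception as exc:
                raise ModelFormatError(f"JSON model parse failure in {path.name}: {exc}") from exc
            model = _from_cobra(cmodel)
    elif dialect == "tsv-triplet":
        model = _from_tsv_triplet(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    model.validate()
    return model


def _from_json_dialect(payload: dict) -> GemModel:
    reactions = []
    gprs = {}
    for rxn in payload["reactions"]:
        reactions.append(
            (
                rxn["id"],
                {m: float(c) for m, c in rxn["stoichiometry"].items()},
                float(rxn.get("lower", -DEFAULT_BOUND)),
                float(rxn.get("upper", DEFAULT_BOUND)),
            )
        )
        gprs[rxn["id"]] = GPR.from_rule(rxn.get("gpr", ""))
    boundary = {m["id"] for m in payload.get("metabolites", []) if m.get("boundary")}
    return from_reaction_table(reactions, boundary_metabolites=boundary, gpr=gprs)


def _from_tsv_triplet(path: Path) -> GemModel:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
        triplet_cols = ["metabolite", "reaction", "coefficient"]
        if not all(c in df.columns for c in triplet_cols):
            raise ModelFormatError(
                f"{path.name}: expected columns {triplet_cols}, got {list(df.columns)}"
            )
    except pd.errors.ParserError as exc:
        raise ModelFormatError(f"TSV parse failure in {path.name}: {exc}") from exc
    stoich: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        rid = str(row["reaction"])
        if rid not in stoich:
            stoich[rid] = {}
            order.append(rid)
        stoich[rid][str(row["metabolite"])] = float(row["coefficient"])
    bounds: dict[str, tuple[float, float]] = {}
    gprs: dict[str, GPR] = {}
    sidecar = path.with_name(path.stem + ".reactions.tsv")
    if sidecar.exists():
        side = pd.read_csv(sidecar, sep="\t", comment="#")
        for _, row in side.iterrows():
            rid = str(row["reaction"])
            bounds[rid] = (float(row["lower"]), float(row["upper"]))
            if "gpr" in side.columns and isinstance(row.get("gpr"), str):
                gprs[rid] = GPR.from_rule(row["gpr"])
    reactions = [
        (rid, stoich[rid], *bounds.get(rid, (-DEFAULT_BOUND, DEFAULT_BOUND)))
        for rid in order
    ]
    return from_reaction_table(reactions, gpr=gprs)


def write_model(model: GemModel, path: str | Path) -> None:
    """Write the model in the JSON dialect (UTF-8)."""
    path = Path(path)
    payload = {
        "metabolites": [
            {"id": m, "boundary": m in model.boundary_metabolites}
            for m in model.metabolite_ids
        ],
        "reactions": [
            {
                "id": rid,
                "stoichiometry": model.stoichiometry(j),
                "lower": float(model.lower[j]),
                "upper": float(model.upper[j]),
                "gpr": model.gpr.get(rid, GPR()).raw,
            }
            for j, rid in enumerate(model.reaction_ids)
        ],
    }
    path.write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# constraint / alias application


def apply_constraints(model: GemModel, dc: DirectionalityConstraints) -> GemModel:
    """Clamp bounds according to direction overrides and the medium.

    ``forward_only`` sets the lower bound to 0 (and clears the reversible
    flag), ``backward_only`` sets the upper bound to 0, ``free`` opens the
    reaction to the default symmetric bounds.  Idempotent.
    """
    dc.validate(model)
    out = model.copy()
    idx = out.rxn_index()
    for rid, d in dc.direction.items():
        j = idx[rid]
        if d == "forward_only":
            out.lower[j] = max(out.lower[j], 0.0)
            out.reversible[j] = False
        elif d == "backward_only":
            out.upper[j] = min(out.upper[j], 0.0)
            if out.lower[j] >= 0:
                out.lower[j] = -DEFAULT_BOUND
            out.reversible[j] = False
        elif d == "free":
            out.lower[j] = -DEFAULT_BOUND
            out.upper[j] = DEFAULT_BOUND
            out.reversible[j] = True
    for rid, (lb, ub) in dc.medium.items():
        j = idx[rid]
        out.lower[j] = lb
        out.upper[j] = ub
        out.reversible[j] = lb < 0 < ub
    return out


def apply_aliases(
    model: GemModel,
    alias_map: dict[str, str],
    adjustments: list[tuple[str, str, float]] | None = None,
) -> GemModel:
    """Merge aliased metabolite rows into their target row.

    ``alias_map`` maps source metabolite id -> target metabolite id (must be
    functional).  ``adjustments`` are (reaction, metabolite, coefficient
    delta) triples applied verbatim after the merge (e.g. adding water when
    several carbonate species are pooled).  Columns whose stoichiometry
    cancels to zero are retained but flagged in ``notes['zero_stoichiometry']``
    with a warning.
    """
    if not alias_map:
        return model.copy()
    unknown = sorted(set(alias_map) - set(model.metabolite_ids))
    if unknown:
        raise ModelValidationError(f"alias sources not in model: {unknown}")
    out = model.copy()
    midx = out.met_index()
    S = out.S.tolil()
    for src, dst in alias_map.items():
        if dst not in midx:
            raise ModelValidationError(f"alias target not in model: {dst}")
        i_src, i_dst = midx[src], midx[dst]
        S[i_dst, :] = S[i_dst, :] + S[i_src, :]
        S[i_src, :] = 0
    keep = [i for m, i in midx.items() if m not in alias_map]
    keep.sort()
    out.metabolite_ids = [out.metabolite_ids[i] for i in keep]
    S = S.tocsr()[keep, :].tolil()
    midx = {m: i for i, m in enumerate(out.metabolite_ids)}
    ridx = out.rxn_index()
    for rid, met, delta in adjustments or ():
        met = alias_map.get(met, met)
        S[midx[met], ridx[rid]] += delta
    out.S = S.tocsc()
    out.S.eliminate_zeros()
    out.boundary_metabolites = {
        alias_map.get(m, m) for m in out.boundary_metabolites
    } & set(out.metabolite_ids)
    nnz = np.diff(out.S.indptr)
    zeroed = [out.reaction_ids[j] for j in np.nonzero(nnz == 0)[0]]
    if zeroed:
        warnings.warn(f"aliasing cancelled all stoichiometry of: {zeroed}")
        out.notes.setdefault("zero_stoichiometry", []).extend(zeroed)
    return out
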