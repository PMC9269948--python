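"""Synthetic modular metabolic networks with known ground truth.

The generator emulates the structure the clustering and enumeration stages
exploit in real reconstructions: clusters of reversible reactions insulated
from each other by irreversible reactions, decorated with shared currency
metabolites, with most modules containing a single reversible pathway.

Module archetypes:

``single``
    one reversible interconversion, both metabolites exchangeable both
    ways (the dominant module type in real networks);
``chain``
    a linear reversible pathway, open at both ends, with optional
    irreversible feed/drain attachments at interior metabolites (these
    create single-metabolite balance patterns);
``cycle``
    a reversible ring with two fully open metabolites (creates loop-law
    patterns);
``diamond``
    two parallel reversible branches between an irreversible inlet and
    outlet (exactly one feasible DT);
``mixed_pair``
    a metabolite pair interconverted by two currency-coupled reactions,
    each metabolite with its own reversible escape - the situation where
    only the pooled-pair balance rule rejects the infeasible orientations;
``random_sparse``
    a random reversible subnetwork (not in the default mix: the local
    balance and loop rules are not guaranteed complete on arbitrary
    topologies, so it serves as an opt-in stress test).

On the default archetypes the single-metabolite, pooled-pair and loop rules
are complete, so the pattern-pruned DFS count provably equals brute force;
this is what makes the generated censuses usable as ground truth.

Modules are joined into one network by irreversible connector reactions
(reversible components stay disjoint) and optionally share currency
metabolite pairs attached with probability ``currency_prob``.  Expression
matrices plant intra-module correlation through a per-module latent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import lp
from .clustering import ModulePartition
from .model import GPR, CurrencyTable, GemModel, from_reaction_table

__all__ = ["FixtureSpec", "generate_network", "generate_expression", "fixture_currency_table"]

CURRENCY_PAIRS = (("atp[c]", "adp[c]"), ("nadh[c]", "nad[c]"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic network + expression draw."""

    n_modules: int = 10
    single_fraction: float = 0.7  # share of single-reaction modules
    archetypes: tuple[str, ...] = ("chain", "cycle", "diamond", "mixed_pair")
    chain_len: tuple[int, int] = (3, 6)
    cycle_len: tuple[int, int] = (3, 5)
    attachment_prob: float = 0.4  # irreversible feed/drain at interior metabolites
    currency_prob: float = 0.3
    inter_module_connectors: int = 2
    genes_per_reaction: int = 2
    n_samples: int = 150
    rho_intra: float = 0.0
    rho_extra: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.single_fraction <= 1 and 0 <= self.currency_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if not (-1 <= self.rho_extra <= self.rho_intra <= 1):
            raise ValueError("need -1 <= rho_extra <= rho_intra <= 1")
        if self.n_modules < 1:
            raise ValueError("need at least one module")


class _Builder:
    def __init__(self):
        self.reactions: list[tuple[str, dict[str, float], float, float]] = []
        self.gpr: dict[str, GPR] = {}
        self.exchange_keeps: list[tuple[str, str]] = []

    def add(self, rid, stoich, lb=-1000.0, ub=1000.0):
        self.reactions.append((rid, dict(stoich), lb, ub))

    def open_met(self, met: str, tag: str):
        """Irreversible import and export for one metabolite."""
        self.add(f"{tag}_in", {f"x_{tag}[e]": -1.0, met: 1.0}, 0.0, 1000.0)
        self.add(f"{tag}_out", {met: -1.0, f"x_{tag}[e]": 1.0}, 0.0, 1000.0)

    def feed(self, met: str, tag: str):
        self.add(f"{tag}_feed", {f"x_{tag}[e]": -1.0, met: 1.0}, 0.0, 1000.0)

    def drain(self, met: str, tag: str):
        self.add(f"{tag}_drain", {met: -1.0, f"x_{tag}[e]": 1.0}, 0.0, 1000.0)


def _build_module(b: _Builder, m: int, kind: str, spec: FixtureSpec, rng) -> tuple[list[str], list[str]]:
    """Append one module; returns (reversible reaction ids, metabolite ids)."""
    rev: list[str] = []
    p = f"M{m}"

    def met(i):
        return f"m{m}_{i}[c]"

    if kind == "single":
        b.add(f"{p}_R0", {met(0): -1.0, met(1): 1.0})
        rev.append(f"{p}_R0")
        b.open_met(met(0), f"{p}e0")
        b.open_met(met(1), f"{p}e1")
        mets = [met(0), met(1)]
    elif kind == "chain":
        k = int(rng.integers(spec.chain_len[0], spec.chain_len[1] + 1))
        for i in range(k):
            b.add(f"{p}_R{i}", {met(i): -1.0, met(i + 1): 1.0})
            rev.append(f"{p}_R{i}")
        b.open_met(met(0), f"{p}e0")
        b.open_met(met(k), f"{p}e1")
        for i in range(1, k):
            if rng.random() < spec.attachment_prob:
                if rng.random() < 0.5:
                    b.feed(met(i), f"{p}a{i}")
                else:
                    b.drain(met(i), f"{p}a{i}")
        mets = [met(i) for i in range(k + 1)]
    elif kind == "cycle":
        k = int(rng.integers(spec.cycle_len[0], spec.cycle_len[1] + 1))
        for i in range(k):
            b.add(f"{p}_R{i}", {met(i): -1.0, met((i + 1) % k): 1.0})
            rev.append(f"{p}_R{i}")
        b.open_met(met(0), f"{p}e0")
        b.open_met(met(1), f"{p}e1")
        for i in range(2, k):
            if rng.random() < spec.attachment_prob:
                if rng.random() < 0.5:
                    b.feed(met(i), f"{p}a{i}")
                else:
                    b.drain(met(i), f"{p}a{i}")
        mets = [met(i) for i in range(k)]
    elif kind == "diamond":
        a, c, d, bb = met(0), met(1), met(2), met(3)
        b.feed(a, f"{p}in")
        b.drain(bb, f"{p}out")
        for i, (x, y) in enumerate(((a, c), (c, bb), (a, d), (d, bb))):
            b.add(f"{p}_R{i}", {x: -1.0, y: 1.0})
            rev.append(f"{p}_R{i}")
        mets = [a, c, d, bb]
    elif kind == "mixed_pair":
        a, bb, x, y = met(0), met(1), met(2), met(3)
        (c1a, c1b), (c2a, c2b) = CURRENCY_PAIRS
        b.add(f"{p}_R0", {a: -1.0, bb: 1.0, c1a: -1.0, c1b: 1.0})
        b.add(f"{p}_R1", {a: -1.0, bb: 1.0, c2a: -1.0, c2b: 1.0})
        b.add(f"{p}_R2", {a: -1.0, x: 1.0})
        b.add(f"{p}_R3", {bb: -1.0, y: 1.0})
        rev += [f"{p}_R{i}" for i in range(4)]
        b.open_met(x, f"{p}e0")
        b.open_met(y, f"{p}e1")
        if rng.random() < spec.attachment_prob:
            b.feed(a, f"{p}in")
        mets = [a, bb, x, y]
    elif kind == "random_sparse":
        k = int(rng.integers(3, 7))
        # random spanning tree over k+1 metabolites plus one chord
        degree = [0] * (k + 1)
        for i in range(k):
            src = int(rng.integers(0, i + 1))
            b.add(f"{p}_R{i}", {met(src): -1.0, met(i + 1): 1.0})
            rev.append(f"{p}_R{i}")
            degree[src] += 1
            degree[i + 1] += 1
        u, v = sorted(rng.choice(k + 1, size=2, replace=False))
        b.add(f"{p}_R{k}", {met(int(u)): -1.0, met(int(v)): 1.0})
        rev.append(f"{p}_R{k}")
        degree[int(u)] += 1
        degree[int(v)] += 1
        opened = 0
        for i in range(k + 1):
            if degree[i] == 1 or (opened < 2 and i in (0, k)):
                b.open_met(met(i), f"{p}e{i}")
                opened += 1
        mets = [met(i) for i in range(k + 1)]
    else:
        raise ValueError(f"unknown archetype {kind!r}")
    return rev, mets


def _assemble(spec: FixtureSpec, rng) -> tuple[GemModel, ModulePartition]:
    b = _Builder()
    n_single = round(spec.single_fraction * spec.n_modules)
    kinds = ["single"] * n_single + [
        str(rng.choice(spec.archetypes))
        for _ in range(spec.n_modules - n_single)
    ]
    rng.shuffle(kinds)
    modules: dict[int, frozenset[str]] = {}
    anchor_mets: list[list[str]] = []
    for m, kind in enumerate(kinds, start=1):
        rev, mets = _build_module(b, m, kind, spec, rng)
        modules[m] = frozenset(rev)
        anchor_mets.append(mets)
        for rid in rev:
            genes = [f"g_{rid}_{t}" for t in range(spec.genes_per_reaction)]
            b.gpr[rid] = GPR(raw=" and ".join(genes), genes=frozenset(genes))
    # inter-module irreversible connectors (a ring over modules)
    nm = len(kinds)
    if nm > 1:
        for m in range(nm):
            nxt = (m + 1) % nm
            for c in range(spec.inter_module_connectors):
                src = anchor_mets[m][c % len(anchor_mets[m])]
                dst = anchor_mets[nxt][c % len(anchor_mets[nxt])]
                b.add(f"C{m + 1}_{nxt + 1}_{c}", {src: -1.0, dst: 1.0}, 0.0, 1000.0)
    # currency decoration on reversible core reactions
    used_currency: set[str] = set()
    decorated = []
    for rid, stoich, lb, ub in b.reactions:
        if lb < 0 and not any(c in stoich for pair in CURRENCY_PAIRS for c in pair):
            if rng.random() < spec.currency_prob:
                ca, cb = CURRENCY_PAIRS[int(rng.integers(0, len(CURRENCY_PAIRS)))]
                stoich = dict(stoich)
                stoich[ca] = stoich.get(ca, 0.0) - 1.0
                stoich[cb] = stoich.get(cb, 0.0) + 1.0
        decorated.append((rid, stoich, lb, ub))
    b.reactions = decorated
    for rid, stoich, _, _ in b.reactions:
        used_currency |= {
            c for pair in CURRENCY_PAIRS for c in pair if c in stoich
        }
    for c in sorted(used_currency):
        tag = "cur_" + c.split("[")[0]
        b.feed(c, tag)
        b.drain(c, tag)
        b.exchange_keeps += [(f"{tag}_feed", c), (f"{tag}_drain", c)]
    model = from_reaction_table(b.reactions, gpr=b.gpr)
    part = ModulePartition(modules=modules)
    model.notes["currency_keep"] = [f"{r}:{m}" for r, m in b.exchange_keeps]
    return model, part


def generate_network(
    spec: FixtureSpec, verify: bool = True, max_retries: int = 5
) -> tuple[GemModel, ModulePartition]:
    """Build a network from the spec; with ``verify`` every reaction is
    checked to be able to carry flux (regenerating with fresh draws up to
    ``max_retries`` times before raising)."""
    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_retries):
        model, part = _assemble(spec, rng)
        model.validate()
        if not verify:
            return model, part
        if lp.flux_consistent(model).all():
            return model, part
    raise RuntimeError(
        f"could not generate a fully unblocked network in {max_retries} attempts"
    )


def fixture_currency_table(model: GemModel) -> CurrencyTable:
    """Currency table matching the generator's conventions: every currency
    species is stripped except in its own exchange reactions (its synthesis
    and degradation)."""
    ct = CurrencyTable()
    all_currency = {c for pair in CURRENCY_PAIRS for c in pair}
    present = all_currency & set(model.metabolite_ids)
    ct.metabolites = present
    for entry in model.notes.get("currency_keep", ()):
        rid, met = entry.split(":", 1)
        if rid in set(model.reaction_ids):
            ct.exceptions.add((rid, met))
    return ct


def generate_expression(
    spec: FixtureSpec,
    part: ModulePartition,
    gpr: dict[str, GPR],
    seed: int | None = None,
) -> pd.DataFrame:
    """Genes x samples matrix with planted correlation structure.

    Genes of reactions in the same module load on a shared latent factor
    so that intra-module gene pairs correlate at ``rho_intra``; a global
    factor gives cross-module correlation ``rho_extra``; the remainder is
    independent Gaussian noise.  Deterministic given spec + seed.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    member_of = part.module_of()
    genes: list[str] = []
    gene_module: list[int] = []
    for rid in sorted(member_of):
        for gene in sorted(gpr.get(rid, GPR()).genes):
            genes.append(gene)
            gene_module.append(member_of[rid])
    if not genes:
        raise ValueError("no genes found in the partition's GPRs")
    n = spec.n_samples
    rho_i, rho_e = spec.rho_intra, spec.rho_extra
    global_factor = rng.standard_normal(n)
    factors = {m: rng.standard_normal(n) for m in sorted(set(gene_module))}
    rows = []
    for gene, m in zip(genes, gene_module):
        eps = rng.standard_normal(n)
        x = (
            np.sqrt(max(rho_e, 0.0)) * global_factor
            + np.sqrt(max(rho_i - rho_e, 0.0)) * factors[m]
            + np.sqrt(max(1.0 - rho_i, 0.0)) * eps
        )
        rows.append(x)
    df = pd.DataFrame(
        np.array(rows), index=genes, columns=[f"s{j}" for j in range(n)]
    )
    return df


def with_seed(spec: FixtureSpec, seed: int) -> FixtureSpec:
    return replace(spec, seed=seed)
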