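"""Shared fixtures: tiny hand-built models and the synthetic-network
pipeline helper used across the suite."""

from __future__ import annotations

import pytest

from topomod import (
    FixtureSpec,
    build_reaction_graph,
    cluster_modules,
    fixture_currency_table,
    generate_network,
    module_subnetwork,
    strip_currency,
)
from topomod.model import from_reaction_table


def open_exchanges(met, tag):
    """Irreversible import + export pair through a boundary partner."""
    return [
        (f"{tag}_in", {f"x_{tag}[e]": -1, met: 1}, 0, 1000),
        (f"{tag}_out", {met: -1, f"x_{tag}[e]": 1}, 0, 1000),
    ]


@pytest.fixture
def triangle():
    """Closed reversible triangle: no orientation is feasible."""
    return from_reaction_table(
        [
            ("r1", {"A[c]": -1, "B[c]": 1}, -1000, 1000),
            ("r2", {"B[c]": -1, "C[c]": 1}, -1000, 1000),
            ("r3", {"C[c]": -1, "A[c]": 1}, -1000, 1000),
        ]
    )


@pytest.fixture
def diamond():
    """Two parallel reversible branches between irreversible inlet and
    outlet: exactly one feasible DT."""
    return from_reaction_table(
        [
            ("in", {"x[e]": -1, "A[c]": 1}, 0, 1000),
            ("r1", {"A[c]": -1, "C[c]": 1}, -1000, 1000),
            ("r2", {"C[c]": -1, "B[c]": 1}, -1000, 1000),
            ("r3", {"A[c]": -1, "D[c]": 1}, -1000, 1000),
            ("r4", {"D[c]": -1, "B[c]": 1}, -1000, 1000),
            ("out", {"B[c]": -1, "y[e]": 1}, 0, 1000),
        ]
    )


@pytest.fixture
def single_module():
    """One reversible interconversion with both metabolites fully open."""
    return from_reaction_table(
        [("r", {"A[c]": -1, "B[c]": 1}, -1000, 1000)]
        + open_exchanges("A[c]", "a")
        + open_exchanges("B[c]", "b")
    )


@pytest.fixture
def mixed_pair():
    """Metabolite pair interconverted by two currency-coupled reactions;
    the pooled-pair balance rule is required for an exact census."""
    return from_reaction_table(
        [
            ("r1", {"A[c]": -1, "B[c]": 1, "atp[c]": -1, "adp[c]": 1}, -1000, 1000),
            ("r2", {"A[c]": -1, "B[c]": 1, "nadh[c]": -1, "nad[c]": 1}, -1000, 1000),
            ("rA", {"A[c]": -1, "X[c]": 1}, -1000, 1000),
            ("rB", {"B[c]": -1, "Y[c]": 1}, -1000, 1000),
        ]
        + open_exchanges("X[c]", "x")
        + open_exchanges("Y[c]", "y"),
        boundary_metabolites={"atp[c]", "adp[c]", "nadh[c]", "nad[c]"},
    )


def run_pipeline(model):
    """strip currency -> reaction graph -> module partition."""
    ct = fixture_currency_table(model)
    stripped = strip_currency(model, ct)
    graph = build_reaction_graph(stripped)
    part = cluster_modules(graph)
    return stripped, graph, part


def iter_module_subnets(seeds, spec_kwargs=None, max_n=12):
    """Yield (seed, module id, subnetwork) over a battery of generated
    networks, restricted to modules with at most ``max_n`` reversible
    reactions."""
    for seed in seeds:
        spec = FixtureSpec(seed=seed, **(spec_kwargs or {}))
        model, _ = generate_network(spec)
        _, _, part = run_pipeline(model)
        for mid in sorted(part.modules):
            sub = module_subnetwork(model, part, mid)
            if int(sub.reversible.sum()) <= max_n:
                yield seed, mid, sub
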